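"""Net-charge fingerprint of the two CLDN10 pore variants.

Each listed residue faces the pore four times (tetrameric scaffold);
summing formal charges of the non-shielded residues gives the net pore
charge — positive pores attract anions, negative ones cations, which is
exactly the selectivity the transport statistics then quantify.
"""
from parapore import CLDN10A_PORE_LINING, CLDN10B_PORE_LINING, pore_net_charge
from parapore.charge import charge_ladder

for spec in (CLDN10A_PORE_LINING, CLDN10B_PORE_LINING):
    q = pore_net_charge(spec)
    charged = [e["residue"] for e in charge_ladder(spec) if e["contribution"]]
    print(f"{spec.name}: net pore charge {q:+d}e "
          f"(charged, non-shielded: {', '.join(charged)})")
print("opposite net charges -> opposite charge selectivity of the two pores")
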
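"""Pore-diameter profile of an ideal and a constricted cylinder.

At each station along the pore axis the profiler fits the maximal inscribed
sphere (grid search + local polish) — the same read-out HOLE gives for a
channel, here on geometry with a known answer: shell atoms (radius 1.5 Å)
centred at 5 Å give an inscribed diameter of 2 × (5 − 1.5) = 7 Å, and a
constriction ring at 4 Å gives 2 × (4 − 1.5) = 5 Å.
"""
import numpy as np

from parapore import PoreAxisSpec, SynthPoreParams, Trajectory, build_toy_pore, pore_profile

spec = PoreAxisSpec(x_min=-25, x_max=25, station_spacing=0.5, search_radius=7.0)

topo, frame = build_toy_pore(
    SynthPoreParams(pore_radius=3.5, scaffold_atom_radius=1.5,
                    include_marker_tetrads=False)
)
prof = pore_profile(Trajectory(topo, [frame]), spec)
interior = (prof.stations > -24) & (prof.stations < 24)
print(f"ideal cylinder: mean diameter {np.mean(prof.mean_diameter[interior]):.2f} A, "
      f"spread {np.ptp(prof.mean_diameter[interior]):.3f} A  (expect 7.00, flat)")

topo2, frame2 = build_toy_pore(
    SynthPoreParams(pore_radius=3.5, scaffold_atom_radius=1.5,
                    include_marker_tetrads=False,
                    constriction_rings=((10.0, 4.0),))
)
prof2 = pore_profile(Trajectory(topo2, [frame2]), spec)
print(f"constricted:    min mean diameter {prof2.min_mean_diameter:.2f} A at "
      f"station {prof2.min_station:.1f} A  (expect 5.00 at 10.0)")
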
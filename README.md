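# parapore

Analysis toolkit for molecular-dynamics studies of **paracellular ion
channels** — the claudin-lined pores that conduct ions *between* epithelial
cells, parallel to the membranes. Simulations of such channels (e.g. the
anion-selective CLDN10a and cation-selective CLDN10b pores) need a set of
read-outs that general MD tooling does not provide out of the box, in
particular permeation statistics that are robust to the ion leakage
inherent to periodic simulation boxes of non-continuous junction strands.

`parapore` packages those read-outs as a tested Python library with a thin
CLI, plus a synthetic toy-pore generator with known ground truth so every
statistic can be validated end to end.

## What it computes

* **Contact-map fingerprints** — mean closest-atom distances between two
  residue ranges, averaged over the equivalent interfaces of an oligomer
  and a time window; strict `< 5 Å` contact classification.
* **Interface metrics** — backbone N–H…O=C hydrogen-bond counts between
  strand segments; named atom-pair distance series (mean over equivalent
  pairs); persistence counts (pairs interacting in more than 35 % of
  frames at a 4 Å heavy-atom cutoff); Shrake–Rupley SASA with side-chain
  normalisation; backbone RMSD with Kabsch superposition.
* **Pore-diameter profile** — the maximal inscribed sphere at stations
  along a fixed pore axis (the HOLE read-out), as mean ± SD diameter per
  station over a trajectory window.
* **Ion-transport statistics** — the selectivity pipeline:

  1. the crossing plane is the per-frame centre of mass of the
     *bottleneck tetrad* (four symmetry-equivalent pore-centre residues);
  2. an axis-aligned *cuboid*, bounded by the entrance-residue Cα
     coordinates, restricts counting to ions that traverse the pore
     rather than leaking around it;
  3. the **total displacement** of the selected ions is
     `D = Σᵢ Σₜ (xᵢ(t+1) − xᵢ(t))`
     on the unwrapped pore-axis coordinate (telescoping to the endpoint
     differences);
  4. per-species OLS regression of `D` against applied voltage gives the
     selectivity slopes (Å/V): the conducted species shows a large slope
     with R² ≈ 1, the excluded species a flat line.

  Plus mean ion counts in the cuboid and per-residue ion contact-time
  profiles (% of frames closer than 4 Å to an ion).
* **Charge fingerprint** — net pore charge from a pore-lining residue
  list (formal charges × tetrad multiplicity, shielded residues
  excluded). The built-in CLDN10a/CLDN10b linings give **+8 e** and
  **−12 e**, the first-order explanation of their opposite selectivity.
* **Synthetic data** — a cylindrical pseudo-atom pore with bottleneck
  (`BNK`) and entrance (`ENT`) marker tetrads, and a seeded drift–diffusion
  ion walk with species- and voltage-dependent drift, reflecting radial
  walls and periodic-with-bookkeeping axial boundaries.

## Worked example

`examples/03_ion_transport_selectivity.py` runs the full selectivity
pipeline on an anion-selective synthetic pore (only Cl⁻ drifts with
voltage, mobility 0.25 Å frame⁻¹ V⁻¹, 20 ions/species, 1000 frames):

```
V = -1.4 V: D(Cl-) =  -6976.9 A  (20 ions selected, mean 17.1 in cuboid)
V = -0.8 V: D(Cl-) =  -3979.9 A  (20 ions selected, mean 17.0 in cuboid)
V = -0.4 V: D(Cl-) =  -1981.9 A  (20 ions selected, mean 16.9 in cuboid)
V = +0.4 V: D(Cl-) =   2014.1 A  (20 ions selected, mean 17.5 in cuboid)
V = +0.8 V: D(Cl-) =   4012.1 A  (20 ions selected, mean 17.1 in cuboid)
V = +1.4 V: D(Cl-) =   7009.1 A  (20 ions selected, mean 17.1 in cuboid)
CL: slope   4995.0 A/V   R^2 = 1.0000
NA: slope      0.0 A/V   R^2 = 0.0000
```

`D` is linear in voltage for the drifting species and flat for the other:
the signature of a charge-selective pore. The recovered slope matches the
ground truth `20 ions × 999 steps × 0.25 Å frame⁻¹ V⁻¹ = 4995 Å/V`
exactly, because the diffusion noise is voltage-independent.

The other example scripts each exercise one capability (synthetic
generator, pore profile, interface metrics, charge fingerprint) and print
the expected analytic values next to the computed ones.

## Command line

```bash
parapore synth --preset anion-selective --voltage 1.4 --seed 7 -o run/
parapore displace --run run/ -o out/
parapore selectivity out*/transport.json -o sel/
parapore profile --traj run/pore.pdb --range -25:25 --search-radius 7 -o prof/
parapore charge --builtin cldn10a -o chg/
```

Every run writes a JSON manifest (parameters, input hashes, seed, version)
next to its outputs; identical argv + seed reproduce byte-identical results.

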
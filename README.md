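# gsmech

Ensemble-analysis machinery for explaining how point mutations of human
glutamine synthetase (GS) — R324C, R324S and R341C, all linked to congenital
glutamine deficiency — impair the first, ATP-binding step of the catalytic
cycle. The package re-implements, as a tested and reusable library plus CLI,
the analyses such a study runs over molecular-dynamics conformational
ensembles:

- **Geometric ensemble statistics** — Kabsch superposition, RMSD/RMSF with
  replicate SEM, core-region selection (the 90% of residues with lowest
  RMSF), group distances, hydrogen-bond and salt-bridge occupancies, and the
  Student/Welch/one-sample significance tests.
- **Water-mediated hydrogen-bond bridges** — chains solute → water(s) → solute
  with every link satisfying the strong (d ≤ 2.8 Å, ∠DHA ≥ 120°) or weak
  (d ≤ 3.2 Å) criteria; these discriminate a serine from a cysteine at
  position 324. Plus water density grids (0.33 Å spacing, 80%-of-maximum
  isopleths) and radial distribution functions.
- **Secondary structure** — an electrostatic backbone H-bond criterion
  (E = 0.084·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)·332 kcal/mol, bond if
  E < −0.5) feeding a helix/loop classification and the per-residue loop
  probability of helix 8.
- **Effective binding energies** — single-trajectory per-frame aggregation,
  ΔΔG = ΔG_mutant − ΔG_wild-type with root-sum-square SEM propagation
  (SEM_total = √(SEM_mut² + SEM_wt²)), drift diagnostics, one-sample t-tests
  against zero, and conversion to association-constant changes
  (fold = e^{ΔΔG/RT}).
- **Rigidity analysis** — body-bar constraint networks (rotatable covalent
  bond 5 bars, locked 6, H-bond/salt bridge 5, hydrophobic tether 2), the
  (6,6) pebble game for rigid-cluster decomposition, thermal unfolding over
  a 0–6 kcal/mol H-bond energy-cutoff ladder, per-residue-pair stability
  maps rc_ij and Welch-tested difference maps.

Because no trajectories are deposited for this system, the package ships a
first-class **synthetic-data module**: generators for harmonic ensembles with
designed per-atom fluctuations, binding-site geometries with designed bridge
occupancy, helix/coil switching with designed loop probability, energy series
with designed mean/drift/noise, and random body-bar networks — each returning
machine-readable ground truth so every downstream stage is testable.

## Worked example

```python
import numpy as np
from gsmech import bridge_frequency, kassoc_change, select
from gsmech.synth import GeneratorSpec, gen_bridge_site

# a binding site whose 7.5 A donor-phosphate gap is bridged by two waters
# in 31% of frames (serine-like) — three replicates of 2000 frames
spec = GeneratorSpec(seed=1, n_frames=2000, n_replicates=3)
ens, truth = gen_bridge_site(spec, gap=7.5, occupancy=0.31)
ea = select(ens.topology, truth["endpoint_a"])
eb = select(ens.topology, truth["endpoint_b"])
freq = bridge_frequency(ens, ea, eb, hbond_class="weak")
print(f"weak bridge frequency: {100*freq.grand_mean:.1f} +/- {100*freq.sem:.1f} %")

# a 5.93 kcal/mol penalty on ATP binding, as an association-constant change
conv = kassoc_change(5.93, temperature=300.0)
print(f"log10 decrease: {conv.log10_units:.1f} units ({conv.fold:,.0f}-fold)")
```

prints

```
weak bridge frequency: 30.6 +/- 0.4 %
log10 decrease: 4.3 units (20,889-fold)
```

The detected bridge frequency recovers the designed 31% occupancy within its
replicate SEM, and the 5.93 kcal/mol binding penalty corresponds to a 4.3
log-unit (~10⁴-fold) drop in the ATP association constant at 300 K.

The same analyses are scriptable from the shell:

```bash
gsmech simulate bridge --seed 1 --n-frames 500 --out site.pdb --truth truth.json
gsmech bridges site.pdb --endpoint-a "resname DON and name OG" \
                        --endpoint-b "resname PO4 and element O" --hbond-class weak
gsmech run demo.toml     # full pipeline from a TOML config
```

## Selection grammar

Selections are the package's own minimal grammar: `resid N` / `resid N-M`,
`resname X`, `name X`, `chain X`, `element X`, `water`, `all`, `none`,
combined with `and`, `or`, `not` and parentheses, e.g.
`"resid 266-288 and chain A"`.

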
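# ensa — conformational-state analysis of disordered peptide ensembles

`ensa` analyses time-ordered conformational ensembles of short
intrinsically disordered peptides — the amyloid-β monomer (Aβ40/Aβ42) is
the motivating system — and answers the questions a simulator asks of
such data:

* **Which interaction patterns recur?**  Each frame is reduced to a
  binary *contact fingerprint*: bit (i, j) is 1 iff the main-chain
  centres of mass of residues i and j are closer than 4.5 Å (sequence
  separation ≥ 3).  Normalised Hamming distances h between fingerprints
  feed a Gaussian affinity A = exp(−h/2σ²); the frames are embedded by
  the leading singular vectors of A (7 by default) and partitioned by
  k-medoids, so every cluster representative is an actual frame.
* **Collapsed or extended?**  The summed Shrake–Rupley solvent-accessible
  surface area (probe 1.4 Å) of a hydrophobic residue set (default
  F4, V18, F20, A21, I31, L34, V36) classifies each frame as collapsed
  (CS, SASA < 550 Å²), extended (ES, SASA > 650 Å²) or intermediate,
  yielding state probabilities and per-cluster appearance times.
* **What secondary structure, and does it agree with NMR?**  A
  Kabsch–Sander hydrogen-bond assigner (E = 27.888·(1/r_ON + 1/r_CH −
  1/r_OH − 1/r_CN) kcal/mol, bond iff E < −0.5) gives per-residue
  helix/strand/coil occupancies, and scalar couplings are back-calculated
  through the Karplus equation
  ³J(HN−Hα)(φ) = a·cos²(φ−60°) + b·cos(φ−60°) + c
  (default a, b, c = 7.7, −1.9, 0.06 Hz) for RMSD/Pearson comparison
  against experimental tables.

Because μs-scale trajectories are rarely shareable, the package ships a
synthetic-ensemble generator (`ensa.synthetic`) that builds backbones
from dihedrals (NeRF), plants two-state mixtures with a guaranteed
hydrophobic-SASA gap, Markov-switching trajectories, archetype contact
fingerprints, and simulated J-coupling tables — every analysis stage is
testable against a known truth.

## Worked example

```python
from ensa import clustering, states
from ensa.synthetic import GeneratorSpec, generate_two_state_ensemble
from ensa.sasa import hydrophobic_sasa

spec = GeneratorSpec(seed=1, mixing=0.7)        # 70% collapsed frames
ensemble, labels = generate_two_state_ensemble(spec, n_frames=200)

import numpy as np
sasas = np.array([hydrophobic_sasa(f, ensemble.topology)
                  for f in ensemble.frames])
thr = states.calibrate_thresholds(sasas[labels == 0], sasas[labels == 1])
series = states.state_series(ensemble, thresholds=thr)
print(states.state_probabilities(series).to_dict())
```

prints

```
{'CS': 0.7, 'ES': 0.3, 'INT': 0.0}
```

— the planted 70/30 collapsed/extended mixture is recovered exactly,
because the generated populations are separated by ≈300 Å² of
hydrophobic SASA while the calibrated thresholds sit at the population
midpoint.  Continuing with clustering:

```python
F = clustering.fingerprint_matrix(ensemble)
A = clustering.affinity_matrix(F)
emb, svals = clustering.spectral_embed(A, n_vectors=7)
result = clustering.cluster(emb, k=2, seed=1)
```

groups the frames by contact pattern; `result.medoid_indices` are real
frames suitable for inspection or superposition
(`ensa.geometry.kabsch_rmsd`).

A `click` CLI wraps the same functions:

```bash
ensa generate --n-frames 200 --seed 1 --out demo.pdb
ensa states demo.pdb
ensa run config.yaml          # full pipeline from a YAML config
```

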
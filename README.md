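# gpcrdyn

Trajectory analysis of G-protein-coupled receptor (GPCR) conformational
dynamics, built around the somatostatin receptor SSTR2 — a class A GPCR
over-expressed in neuroendocrine tumours whose loop dynamics and ligand
interactions discriminate agonists (somatostatin SST14, octreotide) from
antagonists (CYN154806).

The package is a library for computational structural biologists who have
molecular-dynamics trajectories (or the deposited ones of an SSTR2 study)
and want the complete analysis battery as reusable, tested code:

* **Collective variables.** Loop gating is tracked by the pair (δ, β):
  δ = |r_tip − r_TM|, the distance from the ECL2 tip (centroid of the
  Q187/W188/G189 Cα atoms) to the centroid of all transmembrane-helix Cα
  atoms, and β, the angle at the ECL2 base (A181/I195 Cα centroid)
  between the W188 Cα and the ECL3 base (S281/P288 Cα centroid).
  Activation is tracked by d = |Cα(C225) − Cα(S305)| and the angle θ at
  Cα(C268) between Cα(T255) and Cα(I80).
* **State classifiers.** ECL2 is *closed* iff 24 < δ < 33 Å and
  29° < β < 48°; the receptor is *active* iff d < 19 Å and θ > 45°,
  *inactive* iff both criteria fail, *intermediate* otherwise. Occupancies
  are reported per replica and pooled.
* **Flexibility.** Kabsch superposition on the rigid TM core, per-residue
  Cα RMSF, and the trapezoidal RMSF integral as a scalar flexibility
  score.
* **Surfaces.** Shrake–Rupley accessible (SASA) and approximate
  solvent-excluded (SES) areas by sphere-point sampling, reported as
  mean ± sd over frames.
* **Clustering.** Average-linkage agglomeration of frames on the
  receptor-superposed ligand RMSD matrix, with populations and
  minimum-mean-distance representative frames.
* **Interaction fingerprints.** A from-scratch geometric detector for
  hydrophobic, hydrogen-bond, π-π, salt-bridge and cation-π contacts,
  aggregated across replicas into persistence percentages (reported at
  ≥ 10%), with Ballesteros–Weinstein labels and top/middle/bottom pocket
  regions.
* **Energetics.** Aggregation of externally computed MM-GBSA tables:
  cluster-population-weighted ΔG_bind = Σᵢ wᵢ ΔGᵢ with weighted-RMS
  spread, and the per-residue decomposition filtered at −1.0 kcal/mol.
* **Synthetic ground truth.** A seven-helix pseudo-receptor whose loop
  tip switches between closed/open anchor geometries under a two-state
  Markov chain, plus a posable toy ligand that realizes chosen
  interaction types exactly — so every stage is testable without any
  download.

I/O covers multi-model PDB, DCD and XTC (via MDAnalysis), tidy CSV/JSON
report tables, and a YAML-configured pipeline with a thin `gpcrdyn` CLI
(`validate`, `synth`, `cv`, `classify`, `rmsf`, `surface`, `cluster`,
`fingerprint`, `energy`, `all`).

## Worked example

```python
from gpcrdyn import (SyntheticSpec, default_bw_map, ecl2_cv,
                     generate_receptor_trajectory, occupancy)
from gpcrdyn.synthetic import occupancy_interval

spec = SyntheticSpec(n_frames=10_000, p_closed=0.282, seed=42)
traj, hidden = generate_receptor_trajectory(spec)
delta, beta = ecl2_cv(traj, default_bw_map())
occ = occupancy([(delta, beta)])
print(f"closed occupancy: {occ.pooled_percent['closed']:.2f} %")
print("99% interval:", occupancy_interval(0.282, 10_000, 20.0))
```

prints

```
closed occupancy: 26.59 %
99% interval: (22.10..., 34.30...)
```

The planted closed-state probability (28.2%) is recovered within the 99%
interval of a correlated two-state chain; with the chain's ~20-frame
dwell times, 10,000 frames carry far fewer independent samples than
i.i.d. counting would suggest, which is exactly the situation when
estimating loop occupancies from real trajectories. The scripts in
`examples/` walk through each capability the same way (flexibility,
surfaces, clustering, fingerprints, energy aggregation, full pipeline);
each prints the numbers it computes and says what they mean.

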
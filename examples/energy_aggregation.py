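"""Aggregate externally computed binding-energy tables.

Takes per-cluster MM-GBSA means with cluster populations, forms the
population-weighted binding free energy with propagated spread, and
filters a per-residue decomposition at the -1.0 kcal/mol threshold.
"""

from gpcrdyn import per_residue_report, weighted_binding_energy
from gpcrdyn.fingerprints import default_regions

means = [-80.0, -60.0]        # kcal/mol per conformational cluster
weights = [0.75, 0.25]        # cluster populations (fractions)
sds = [10.0, 12.0]

dg, sd = weighted_binding_energy(means, weights, sds)
print(f"weighted dG_bind     : {dg:.1f} +/- {sd:.1f} kcal/mol")

decomp = {
    "agonist":    {122: -2.1, 286: -1.5, 294: -0.4, 298: -1.1},
    "antagonist": {122: -1.9, 286: -0.2, 294: -1.6, 298: -0.3},
}
report = per_residue_report(decomp, threshold=-1.0, regions=default_regions())
print(report.to_string(index=False))
# Residues are kept when at least one ligand contributes -1.0 kcal/mol or
# better, and rows are grouped top -> middle -> bottom pocket regions.
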
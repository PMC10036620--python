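"""Interaction fingerprints with persistence on a planted complex.

Plants five interaction types (salt bridge, pi-pi stacking, hydrophobic,
hydrogen bond, cation-pi) at chosen receptor residues, detects them on
every frame, aggregates them into persistence percentages, and prints
the region-partitioned report.
"""

import numpy as np

from gpcrdyn import (
    SyntheticSpec,
    default_bw_map,
    default_regions,
    detect_interactions,
    generate_complex_trajectory,
    partition_report,
    persistence,
)

plan = (("saltbridge", 122), ("pipi", 208), ("hydrophobic", 272), ("hbond", 298), ("cationpi", 106))
traj, manifest = generate_complex_trajectory(SyntheticSpec(n_frames=50, ligand_plan=plan, seed=5))

top = traj.topology
receptor = np.array([i for i, a in enumerate(top.atoms) if a.chain == "A"])
ligand = np.array([i for i, a in enumerate(top.atoms) if a.chain == "L"])
streams = [detect_interactions(traj.coords[f], top, receptor, ligand) for f in range(traj.n_frames)]
matrix = persistence(streams, report_threshold=10.0)

bw = default_bw_map()
print("planted manifest     :", manifest)
for (rres, lres, typ), pct in sorted(matrix.reported().items()):
    label = bw.bw_label(rres) or bw.loop_of(rres)
    print(f"  {rres:>4} ({label}) -- ligand {lres} : {typ:<12} {pct:5.1f} %")
print(partition_report(matrix, default_regions()).to_string(index=False))
# Every planted contact persists in 100% of frames and nothing spurious
# appears; the report groups residues by pocket region (top/middle/bottom).
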
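"""Ligand surface-area series over a trajectory.

Builds a small rigid ligand, jitters it over frames, and reports the
solvent-accessible surface area as mean +/- sd across frames — the
estimator used to compare the steric bulk of different ligands.
"""

import numpy as np

from gpcrdyn import surface_series
from gpcrdyn.traj_model import ATOMIC_MASSES, AtomRecord, Topology, Trajectory

atoms = [
    AtomRecord(i + 1, f"C{i+1}", "C", "LIG", 1, "L", ATOMIC_MASSES["C"]) for i in range(6)
]
base = np.array(
    [[0.0, 0, 0], [1.5, 0, 0], [3.0, 0, 0], [0.0, 1.5, 0], [1.5, 1.5, 0], [0.0, 0, 1.5]]
)
rng = np.random.default_rng(3)
coords = base[None] + rng.normal(0, 0.05, size=(20, 6, 3))
traj = Trajectory(Topology(atoms), coords)

series = surface_series(traj, range(6), probe=1.4, n_points=2000)
print(f"frames               : {len(series.totals)}")
print(f"SASA mean +/- sd     : {series.mean:.0f} +/- {series.sd:.0f} A^2")
# A compact hexa-carbon fragment buries much of each atom's sphere; the
# small sd reflects only the positional jitter.
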
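"""Radial density layering recovered by the cylindrical-shell analysis.

Generates a synthetic trajectory whose waters follow a known three-layer
high-low-high radial density profile around the complex axis, aligns it on
the 12 O4 atoms, and accumulates per-shell density maps.  The per-shell
density (occupancy / annulus area), normalised by the outermost bulk shell,
should match the generator's requested layer densities.
"""

import numpy as np

from cdsolv.config import default_config, resolve_selections
from cdsolv.maps import SPC, accumulate_shell_map, build_shells
from cdsolv.synth import (
    SyntheticTrajectorySpec, WaterFieldSpec, build_scaffold, generate_trajectory,
)
from cdsolv.trajectory import align_bulk

layers = ((6.5, 8.0, 2.0), (8.0, 9.5, 0.5), (9.5, 11.0, 1.5))
scaffold = build_scaffold()
traj = generate_trajectory(
    scaffold,
    WaterFieldSpec(n_waters=5000, box=(30.0,) * 3, mode="layered",
                   layers=layers, seed=1),
    SyntheticTrajectorySpec(n_frames=20),
    seed=2,
)
sel = resolve_selections(default_config(), traj.atoms)
aligned = align_bulk(traj, sel.alignment)
shells = build_shells()


def shell_density(idx):
    m = accumulate_shell_map(aligned, shells[idx], SPC, axial_extent=15.0)
    s = shells[idx]
    return m.occupancy / (np.pi * (s.r_max ** 2 - s.r_min ** 2))


base = shell_density(12)   # [12,13) A: bulk reference
print("shell    recovered  generator")
for idx, truth in ((7, 2.0), (8, 0.5), (10, 1.5), (12, 1.0)):
    s = shells[idx]
    print(f"[{s.r_min:4.1f},{s.r_max:4.1f})  {shell_density(idx)/base:9.3f}  {truth:9.3f}")
print("\nRecovered relative densities match the high-low-high layering the")
print("generator was asked for; the same analysis applied to a real")
print("trajectory reads off the solvent layering around the complex.")
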
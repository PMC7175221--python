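"""Per-ring water counting and minimum-hydration frame selection.

Each of the twelve sugar rings (six per macrocycle) is assigned, per frame,
the number of distinct water molecules whose oxygen lies within a cutoff
(3 or 5 Angstrom) of either *any ring atom* or the *ring centroid*.
Distances use the minimum-image convention under the orthorhombic box, so
no explicit pre-wrapping is required; counts are exact (KD-tree accelerated
but identical to an all-pairs computation).

At a water/air interface, the ring with the smallest count in a frame is
the one facing the air; collecting each ring's argmin frames conditions the
density maps on that ring's exposure.  Ties assign the frame to every tied
ring (keeping each ring's map unbiased) and are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .trajectory import Frame, Trajectory, water_sites

__all__ = [
    "HydrationError",
    "RingDefinition",
    "HydrationSeries",
    "ring_hydration",
    "hydration_series",
    "select_min_hydration_frames",
]

DEFAULT_CUTOFFS = (3.0, 5.0)
MODES = ("any_atom", "ring_center")


class HydrationError(ValueError):
    pass


@dataclass(frozen=True)
class RingDefinition:
    """One sugar ring: which macrocycle it belongs to, its index, its atoms."""

    cd: str                      # "CD1" | "CD2"
    ring_index: int              # 1..6
    atom_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.atom_indices:
            raise HydrationError(f"ring {self.cd}/{self.ring_index} has no atoms")

    @property
    def label(self) -> str:
        return f"{self.cd}:{self.ring_index}"

    def center(self, positions: np.ndarray) -> np.ndarray:
        return positions[list(self.atom_indices)].mean(axis=0)


def _min_image_kdtree(points: np.ndarray, box: np.ndarray) -> cKDTree:
    return cKDTree(np.mod(points, box), boxsize=box)


def ring_hydration(
    frame: Frame,
    ring: RingDefinition,
    cutoff: float,
    mode: str = "any_atom",
    water_oxygens: np.ndarray | None = None,
    atoms=None,
) -> int:
    """Distinct waters whose oxygen is within ``cutoff`` of the ring.

    ``mode='any_atom'`` measures to the nearest ring atom; ``'ring_center'``
    to the ring centroid.  Each water counts at most once per ring.
    """
    if cutoff <= 0:
        raise HydrationError("cutoff must be positive")
    if mode not in MODES:
        raise HydrationError(f"unknown mode {mode!r}")
    if water_oxygens is None:
        if atoms is None:
            raise HydrationError("need water_oxygens or an atom table")
        water_oxygens = water_sites(atoms)[:, 0]
    if len(water_oxygens) == 0:
        return 0
    for idx in ring.atom_indices:
        if idx < 0 or idx >= frame.positions.shape[0]:
            raise HydrationError(f"ring atom index {idx} out of range")

    ow = frame.positions[np.asarray(water_oxygens, dtype=int)]
    tree = _min_image_kdtree(ow, frame.box)
    if mode == "any_atom":
        refs = frame.positions[list(ring.atom_indices)]
    else:
        refs = ring.center(frame.positions)[None, :]
    hits: set[int] = set()
    for r in np.mod(refs, frame.box):
        hits.update(tree.query_ball_point(r, cutoff))
    return len(hits)


@dataclass
class HydrationSeries:
    """Tidy counts: columns frame, time_ps, cd, ring, cutoff, mode, count."""

    table: pd.DataFrame
    rings: tuple[RingDefinition, ...]

    def counts(self, cd: str, ring_index: int, cutoff: float, mode: str) -> np.ndarray:
        t = self.table
        sel = t[
            (t.cd == cd) & (t.ring == ring_index)
            & (t.cutoff == cutoff) & (t["mode"] == mode)
        ].sort_values("frame")
        return sel["count"].to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def hydration_series(
    traj: Trajectory,
    rings: Sequence[RingDefinition],
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    modes: Sequence[str] = MODES,
) -> HydrationSeries:
    """Full per-frame x ring x cutoff x mode count tensor."""
    for c in cutoffs:
        if c <= 0:
            raise HydrationError("cutoff must be positive")
    oxygens = water_sites(traj.atoms)[:, 0]
    rows = []
    for fi in range(traj.n_frames):
        frame = traj.frame(fi)
        ow = frame.positions[oxygens]
        tree = _min_image_kdtree(ow, frame.box)
        for ring in rings:
            ring_pos = frame.positions[list(ring.atom_indices)]
            center = ring_pos.mean(axis=0)[None, :]
            for mode, refs in (("any_atom", ring_pos), ("ring_center", center)):
                if mode not in modes:
                    continue
                refs_w = np.mod(refs, frame.box)
                for cutoff in cutoffs:
                    hits: set[int] = set()
                    for r in refs_w:
                        hits.update(tree.query_ball_point(r, cutoff))
                    rows.append(
                        {
                            "frame": fi,
                            "time_ps": float(traj.times[fi]),
                            "cd": ring.cd,
                            "ring": ring.ring_index,
                            "cutoff": float(cutoff),
                            "mode": mode,
                            "count": len(hits),
                        }
                    )
    return HydrationSeries(table=pd.DataFrame(rows), rings=tuple(rings))


@dataclass
class MinHydrationSelection:
    """Frame sets per ring index, plus the frames where ties occurred."""

    frame_sets: dict[int, np.ndarray]
    tied_frames: np.ndarray

    def report(self) -> str:
        lines = [
            f"ring {r}: {len(f)} frames" for r, f in sorted(self.frame_sets.items())
        ]
        lines.append(f"tied frames: {len(self.tied_frames)}")
        return "\n".join(lines)


def select_min_hydration_frames(
    series: HydrationSeries,
    cd: str = "CD1",
    cutoff: float = 3.0,
    mode: str = "any_atom",
) -> MinHydrationSelection:
    """Assign each frame to the least-hydrated ring of one macrocycle.

    For every frame the ring (among that CD's six) with the smallest count
    claims the frame; ties give the frame to every tied ring.  Without ties
    the returned sets partition the frames.
    """
    t = series.table
    sub = t[(t.cd == cd) & (t.cutoff == cutoff) & (t["mode"] == mode)]
    if sub.empty:
        raise HydrationError(
            f"series has no entries for cd={cd!r} cutoff={cutoff} mode={mode!r}"
        )
    wide = sub.pivot_table(index="frame", columns="ring", values="count")
    rings = list(wide.columns)
    counts = wide.to_numpy()
    mins = counts.min(axis=1, keepdims=True)
    winners = counts == mins
    frames = wide.index.to_numpy()
    frame_sets = {
        int(r): frames[winners[:, j]] for j, r in enumerate(rings)
    }
    tied = frames[winners.sum(axis=1) > 1]
    return MinHydrationSelection(frame_sets=frame_sets, tied_frames=tied)
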
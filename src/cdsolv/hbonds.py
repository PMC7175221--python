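"""Geometric hydrogen-bond detection and lifetime statistics.

A donor-acceptor pair is bonded in a frame when the donor-acceptor distance
is at most ``da_cutoff`` (default 3.5 Angstrom) and the hydrogen-donor-
acceptor angle is at most ``angle_cutoff`` (default 30 degrees) - the
documented defaults of the widely used GROMACS geometric criterion.
Distances and displacement vectors use the minimum-image convention.

The lifetime reported is the *continuous* (uninterrupted-run) estimate:
the mean duration of maximal contiguous bonded runs of each (donor,
acceptor) pair at the trajectory's frame spacing, a run of k frames
counting as k * dt.  Runs touching either end of the trajectory are
censored (the true dwell is longer than observed); they are included at
their observed length and their number is reported.  A forgiveness window
(``forgive_frames``) can bridge short ruptures; it defaults to 0 (a
single unbonded frame breaks a run).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .trajectory import Frame, Trajectory

__all__ = [
    "HBondError",
    "HBondCriteria",
    "HBondGroupSpec",
    "HBondSeries",
    "detect_hbonds",
    "hbond_statistics",
]


class HBondError(ValueError):
    pass


@dataclass(frozen=True)
class HBondCriteria:
    da_cutoff: float = 3.5        # Angstrom, donor heavy atom to acceptor
    angle_cutoff: float = 30.0    # degrees, H-donor-acceptor

    def __post_init__(self) -> None:
        if self.da_cutoff <= 0 or self.angle_cutoff <= 0:
            raise HBondError("cutoffs must be positive")


@dataclass(frozen=True)
class HBondGroupSpec:
    """Named donor/acceptor selection, e.g. 'O2H2 (CD1) -> O3 (CD2)'.

    ``donors`` are (heavy, hydrogen) index pairs; ``acceptors`` are heavy-
    atom indices.
    """

    label: str
    donors: tuple[tuple[int, int], ...]
    acceptors: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.donors or not self.acceptors:
            raise HBondError(f"group {self.label!r}: empty donors or acceptors")


def _min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - np.round(d / box) * box


def detect_hbonds(
    frame: Frame, criteria: HBondCriteria, group: HBondGroupSpec
) -> set[tuple[int, int]]:
    """Bonded (donor-heavy, acceptor) pairs in one frame.

    Self pairs (donor heavy == acceptor) are excluded.  Candidate pairs are
    found with a periodic KD-tree on the acceptors; the result equals the
    all-pairs computation exactly.
    """
    pos, box = frame.positions, frame.box
    donors = np.asarray(group.donors, dtype=int)
    acceptors = np.asarray(group.acceptors, dtype=int)
    for d, h in donors:
        if h < 0 or h >= pos.shape[0]:
            raise HBondError(f"donor hydrogen index {h} out of range")

    acc_tree = cKDTree(np.mod(pos[acceptors], box), boxsize=box)
    cand = acc_tree.query_ball_point(np.mod(pos[donors[:, 0]], box), criteria.da_cutoff)

    cos_cut = np.cos(np.deg2rad(criteria.angle_cutoff))
    out: set[tuple[int, int]] = set()
    for di, acc_list in enumerate(cand):
        if not acc_list:
            continue
        d_idx, h_idx = donors[di]
        a_idx = acceptors[np.asarray(acc_list, dtype=int)]
        a_idx = a_idx[a_idx != d_idx]
        if a_idx.size == 0:
            continue
        dh = _min_image(pos[h_idx] - pos[d_idx], box)
        da = _min_image(pos[a_idx] - pos[d_idx], box)
        dist = np.linalg.norm(da, axis=1)
        ok = dist <= criteria.da_cutoff
        nh = np.linalg.norm(dh)
        if nh == 0:
            raise HBondError(f"donor {d_idx} and its hydrogen coincide")
        cosang = (da @ dh) / (dist * nh + 1e-300)
        ok &= cosang >= cos_cut
        for a in a_idx[ok]:
            out.add((int(d_idx), int(a)))
    return out


@dataclass
class HBondSeries:
    """Per-frame bond sets plus summary statistics for one group."""

    label: str
    per_frame: list[set[tuple[int, int]]]
    frame_spacing: float          # ps
    average_count: float
    lifetime: float               # ps, mean continuous run duration (NaN if no bonds)
    n_runs: int
    n_censored: int

    def to_row(self) -> dict:
        return {
            "group": self.label,
            "mean_count": self.average_count,
            "lifetime_ps": self.lifetime,
            "n_runs": self.n_runs,
            "n_censored": self.n_censored,
        }


def _run_lengths(bonded: np.ndarray, forgive: int) -> tuple[list[int], int]:
    """Maximal contiguous True runs; gaps <= forgive frames are bridged.

    Returns (run lengths in frames, number of runs touching either end).
    Bridged gap frames do not add to the run length.
    """
    idx = np.nonzero(bonded)[0]
    if idx.size == 0:
        return [], 0
    runs: list[tuple[int, int, int]] = []   # (start, end, n_bonded)
    start = prev = idx[0]
    n_in = 1
    for i in idx[1:]:
        if i - prev - 1 <= forgive:
            n_in += 1
        else:
            runs.append((start, prev, n_in))
            start = i
            n_in = 1
        prev = i
    runs.append((start, prev, n_in))
    n = len(bonded)
    censored = sum(1 for s, e, _ in runs if s == 0 or e == n - 1)
    return [n_in for _, _, n_in in runs], censored


def hbond_statistics(
    traj: Trajectory,
    criteria: HBondCriteria,
    group: HBondGroupSpec,
    forgive_frames: int = 0,
) -> HBondSeries:
    """Average bonds per frame and mean continuous lifetime for one group."""
    if traj.n_frames == 0:
        raise HBondError("empty trajectory")
    per_frame = [
        detect_hbonds(traj.frame(i), criteria, group) for i in range(traj.n_frames)
    ]
    avg = float(np.mean([len(s) for s in per_frame]))

    pairs = sorted(set().union(*per_frame)) if any(per_frame) else []
    dt = traj.frame_spacing if traj.n_frames > 1 else 0.0
    lengths: list[int] = []
    censored = 0
    for pair in pairs:
        bonded = np.array([pair in s for s in per_frame])
        ls, c = _run_lengths(bonded, forgive_frames)
        lengths.extend(ls)
        censored += c
    lifetime = float(np.mean(lengths) * dt) if lengths else float("nan")
    return HBondSeries(
        label=group.label,
        per_frame=per_frame,
        frame_spacing=dt,
        average_count=avg,
        lifetime=lifetime,
        n_runs=len(lengths),
        n_censored=censored,
    )
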
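"""Hexagon-area dynamics and interface orientation of the complex.

Each macrocycle ring presents six chemically equivalent oxygens per class
(O2, O3, O4, O5, O6).  The area of the hexagon they span, per frame, is a
compact readout of ring breathing and of the large-amplitude primary-rim
(O6) motion.  Area is computed by projecting the six vertices onto their
least-squares plane and applying the shoelace formula *in topological ring
order* - angular re-sorting would silently repair self-intersections that
the analysis is meant to expose as area changes.

Orientation at a water/air interface follows the aeronautical convention
with the interface as the horizontal plane (normal = z):

* pitch: elevation of the body axis out of the interface plane, positive
  when the CD1 end tilts toward the air; in [-90, 90] degrees.
* yaw: azimuth of the axis projection in the interface plane, (-180, 180].
* roll: rotation of the body roll reference about the axis, accumulated
  (unwrapped) across frames so full turns are counted.

The complex-to-water distance uses only the component along the interface
normal (slab geometry makes that the meaningful coordinate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .trajectory import (
    AlignmentReference,
    Trajectory,
    TrajectoryError,
    body_frame,
    water_sites,
)

__all__ = [
    "GeometryError",
    "HexagonSeries",
    "OrientationSeries",
    "hexagon_area",
    "hexagon_series",
    "orientation_series",
    "moving_average",
]

OXYGEN_CLASSES = ("O2", "O3", "O4", "O5", "O6")
_WATER_MASSES = np.array([15.999, 1.008, 1.008])


class GeometryError(ValueError):
    pass


def hexagon_area(points: np.ndarray) -> float:
    """Planar polygon area (A^2) of six ordered vertices.

    The vertices are projected onto their least-squares plane (principal
    plane of the centered coordinates) and the shoelace formula is applied
    in the given order.  Degenerate (collinear/coincident) inputs raise.
    """
    p = np.asarray(points, dtype=float)
    if p.shape != (6, 3):
        raise GeometryError("hexagon_area expects six 3-vectors")
    c = p - p.mean(axis=0)
    u, s, vt = np.linalg.svd(c, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise GeometryError("degenerate hexagon: vertices are collinear or coincident")
    proj = c @ vt[:2].T           # coordinates in the plane
    x, y = proj[:, 0], proj[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def moving_average(series: np.ndarray, window: int) -> np.ndarray:
    """Simple boxcar average, 'valid' mode (length n - window + 1)."""
    if window < 1:
        raise GeometryError("window must be >= 1")
    kernel = np.ones(window) / window
    return np.convolve(np.asarray(series, float), kernel, mode="valid")


@dataclass
class HexagonSeries:
    """Tidy per-frame hexagon areas: columns time_ps, cd, oxygen_class, area."""

    table: pd.DataFrame
    smoothing_window_ns: float | None = None

    def series(self, cd: str, oxygen_class: str) -> np.ndarray:
        sel = self.table[(self.table.cd == cd) & (self.table.oxygen_class == oxygen_class)]
        return sel.area.to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def hexagon_series(
    traj: Trajectory,
    class_selections: Mapping[tuple[str, str], Sequence[int]],
    smooth_ns: float | None = None,
) -> HexagonSeries:
    """Per-frame hexagon areas for each (cd, oxygen class) selection.

    ``class_selections`` maps (cd, class) -> six atom indices in ring order.
    When ``smooth_ns`` is given an additional smoothed table is produced by
    boxcar-averaging with a window of round(smooth_ns * 1000 / frame spacing)
    frames ('valid' alignment; times are window centres).
    """
    for key, idx in class_selections.items():
        if len(idx) != 6:
            raise GeometryError(f"selection {key} has {len(idx)} atoms, need 6")

    rows = []
    for fi in range(traj.n_frames):
        pos = traj.positions[fi]
        t = float(traj.times[fi])
        for (cd, oclass), idx in class_selections.items():
            rows.append(
                {
                    "time_ps": t,
                    "cd": cd,
                    "oxygen_class": oclass,
                    "area": hexagon_area(pos[list(idx)]),
                }
            )
    table = pd.DataFrame(rows)

    if smooth_ns is not None:
        dt = traj.frame_spacing
        if dt <= 0:
            raise GeometryError("smoothing needs a multi-frame trajectory")
        window = max(1, int(round(smooth_ns * 1000.0 / dt)))
        smoothed = []
        for (cd, oclass), grp in table.groupby(["cd", "oxygen_class"], sort=False):
            area = moving_average(grp.area.to_numpy(), window)
            t = moving_average(grp.time_ps.to_numpy(), window)
            smoothed.append(
                pd.DataFrame(
                    {"time_ps": t, "cd": cd, "oxygen_class": oclass, "area": area}
                )
            )
        table = pd.concat(smoothed, ignore_index=True)
    return HexagonSeries(table=table, smoothing_window_ns=smooth_ns)


@dataclass
class OrientationSeries:
    """Yaw/pitch/unwrapped-roll (degrees) and axis-normal water-COM distance."""

    time_ps: np.ndarray
    yaw: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray               # cumulative, unbounded
    com_distance: np.ndarray       # Angstrom, |z(O4 centre) - z(water COM)|
    yaw_undefined: np.ndarray      # bool; yaw carried over (axis ~ normal)

    @property
    def roll_turns(self) -> float:
        """Net signed full turns accumulated over the series."""
        return float(self.roll[-1] - self.roll[0]) / 360.0

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "time_ps": self.time_ps,
                "yaw_deg": self.yaw,
                "pitch_deg": self.pitch,
                "roll_deg": self.roll,
                "com_distance_A": self.com_distance,
                "yaw_undefined": self.yaw_undefined.astype(int),
            }
        ).to_csv(path, sep="\t", index=False)


def orientation_series(
    traj: Trajectory,
    ref: AlignmentReference,
    interface_normal: int = 2,
) -> OrientationSeries:
    """Per-frame yaw/pitch/roll of the body axis relative to the interface.

    Roll is measured against a horizon frame built from the interface
    normal: e1 = normal orthogonalised to the axis, e2 = axis x e1.  That
    anchor makes roll insensitive to any in-plane (about-normal) rotation
    of the whole system, so the series is the same before and after the
    interface alignment.  Roll increments are unwrapped and reported
    relative to the first frame.  When the axis is (numerically) parallel
    to the normal, yaw is undefined; the previous value is carried and the
    frame flagged.
    """
    if traj.n_frames < 1:
        raise GeometryError("empty trajectory")
    nrm = np.zeros(3)
    nrm[interface_normal] = 1.0
    plane = [i for i in range(3) if i != interface_normal]

    sites = water_sites(traj.atoms)
    if sites.shape[0] == 0:
        raise GeometryError("no water residues; water centre of mass undefined")
    site_masses = np.repeat(_WATER_MASSES[None, :], sites.shape[0], axis=0)
    total_mass = site_masses.sum()

    yaw = np.empty(traj.n_frames)
    pitch = np.empty(traj.n_frames)
    raw_roll = np.empty(traj.n_frames)
    comd = np.empty(traj.n_frames)
    undef = np.zeros(traj.n_frames, dtype=bool)

    for fi in range(traj.n_frames):
        pos = traj.positions[fi]
        bf = body_frame(pos, ref)
        a = bf.axis
        pitch[fi] = np.degrees(np.arcsin(np.clip(a @ nrm, -1.0, 1.0)))
        p = np.hypot(a[plane[0]], a[plane[1]])
        if p < 1e-9:
            undef[fi] = True
            yaw[fi] = yaw[fi - 1] if fi > 0 else 0.0
        else:
            yaw[fi] = np.degrees(np.arctan2(a[plane[1]], a[plane[0]]))
        e1 = nrm - (nrm @ a) * a
        n1 = np.linalg.norm(e1)
        if n1 < 1e-9:
            raw_roll[fi] = raw_roll[fi - 1] if fi > 0 else 0.0
        else:
            e1 /= n1
            e2 = np.cross(a, e1)
            raw_roll[fi] = np.arctan2(bf.roll_ref @ e2, bf.roll_ref @ e1)

        w = pos[sites]                               # (n, 3 sites, 3)
        com = (site_masses[:, :, None] * w).sum(axis=(0, 1)) / total_mass
        comd[fi] = abs(bf.origin[interface_normal] - com[interface_normal])

    roll = np.degrees(np.unwrap(raw_roll))
    roll -= roll[0]
    return OrientationSeries(
        time_ps=traj.times.copy(), yaw=yaw, pitch=pitch, roll=roll,
        com_distance=comd, yaw_undefined=undef,
    )
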
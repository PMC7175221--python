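"""Trajectory model, rigid-body superposition and the two alignment modes.

Coordinates are handled in Angstrom throughout; unit conversion happens at
the I/O boundary (MDAnalysis already reports Angstrom for GRO/PDB/XTC/TRR).
Only orthorhombic boxes are supported.

Alignment conventions
---------------------
The complex body frame is defined by the 12 ether oxygens (O4) of the two
stacked macrocycle rings: origin at their common centroid, body axis the
unit vector from the CD2 O4-centroid to the CD1 O4-centroid (CD1 being the
ring nearer the surfactant head), and a roll reference pointing from the
axis to a designated O4 atom.

* ``align_bulk`` fits every frame on the 12 O4 atoms to a fixed reference
  conformation (derived from the first frame) whose body axis lies along a
  chosen lab axis.
* ``align_interface`` is two-stage: the final frame is rotated about the
  interface normal (z) so its axis projection points along the target axis,
  then every frame is fitted to that structure with the rotation restricted
  to be about z (plus translation).  The restriction keeps the water
  surface horizontal, so the tilt (pitch) and spin (roll) of the complex
  survive alignment and remain measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "AtomTable",
    "Frame",
    "Trajectory",
    "AlignmentReference",
    "AlignmentInfo",
    "BodyFrame",
    "TrajectoryError",
    "read_trajectory",
    "write_trajectory",
    "kabsch",
    "rigid_fit",
    "align_bulk",
    "align_interface",
    "wrap_solvent",
    "body_frame",
    "water_sites",
    "assign_cd_rings",
]

_AXIS_INDEX = {"X": 0, "Y": 1, "Z": 2}


class TrajectoryError(ValueError):
    pass


@dataclass
class AtomTable:
    """Per-atom metadata aligned with the position arrays."""

    names: np.ndarray      # str
    resids: np.ndarray     # int
    resnames: np.ndarray   # str

    def __post_init__(self) -> None:
        self.names = np.asarray(self.names, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype=object)
        if not (len(self.names) == len(self.resids) == len(self.resnames)):
            raise TrajectoryError("atom table columns differ in length")

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class Frame:
    """Positions (Angstrom), orthorhombic box lengths (Angstrom), time (ps)."""

    positions: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise TrajectoryError("positions must be (n_atoms, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise TrajectoryError("box must be 3 positive lengths")
        if not np.all(np.isfinite(self.positions)):
            raise TrajectoryError("non-finite positions")


@dataclass(frozen=True)
class AlignmentReference:
    """The 12 O4 fit atoms (6 per ring) and the lab axis to align to."""

    o4_cd1: tuple[int, ...]
    o4_cd2: tuple[int, ...]
    target_axis: str = "X"

    def __post_init__(self) -> None:
        idx = tuple(self.o4_cd1) + tuple(self.o4_cd2)
        if len(set(idx)) != 12 or len(self.o4_cd1) != 6 or len(self.o4_cd2) != 6:
            raise TrajectoryError("alignment reference needs 12 distinct O4 indices, 6 per CD")
        if self.target_axis not in _AXIS_INDEX:
            raise TrajectoryError(f"target_axis must be X, Y or Z, got {self.target_axis!r}")

    @property
    def indices(self) -> np.ndarray:
        return np.array(self.o4_cd1 + self.o4_cd2, dtype=int)


@dataclass(frozen=True)
class AlignmentInfo:
    """Metadata stamped on an aligned trajectory."""

    mode: str                    # "bulk" | "interface"
    reference: AlignmentReference
    ref_o4_coords: np.ndarray    # (12, 3) reference conformation of the fit atoms


@dataclass(frozen=True)
class BodyFrame:
    origin: np.ndarray
    axis: np.ndarray
    roll_ref: np.ndarray

    def __post_init__(self) -> None:
        for v in (self.axis, self.roll_ref):
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise TrajectoryError("body frame vectors must be unit length")
        if abs(float(self.axis @ self.roll_ref)) > 1e-9:
            raise TrajectoryError("axis and roll_ref must be orthogonal")


@dataclass
class Trajectory:
    positions: np.ndarray        # (n_frames, n_atoms, 3) Angstrom
    boxes: np.ndarray            # (n_frames, 3)
    times: np.ndarray            # (n_frames,) ps
    atoms: AtomTable
    alignment: AlignmentInfo | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise TrajectoryError("positions must be (n_frames, n_atoms, 3)")
        if self.positions.shape[1] != len(self.atoms):
            raise TrajectoryError("atom table does not match positions")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise TrajectoryError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    @property
    def frame_spacing(self) -> float:
        if self.n_frames < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def frame(self, i: int) -> Frame:
        return Frame(self.positions[i], self.boxes[i], float(self.times[i]))

    def copy(self) -> "Trajectory":
        return Trajectory(
            self.positions.copy(), self.boxes.copy(), self.times.copy(),
            self.atoms, self.alignment,
        )


# ---------------------------------------------------------------------------
# I/O (MDAnalysis behind the module surface)
# ---------------------------------------------------------------------------

def read_trajectory(structure_path, trajectory_path=None) -> Trajectory:
    """Read a structure (GRO/PDB) plus optional coordinate trajectory (XTC/TRR).

    A structure without a trajectory yields a single-frame trajectory; a
    multi-model PDB yields one frame per model.  Triclinic boxes are
    rejected.
    """
    import MDAnalysis as mda

    try:
        if trajectory_path is None:
            u = mda.Universe(str(structure_path))
        else:
            u = mda.Universe(str(structure_path), str(trajectory_path))
    except Exception as exc:  # noqa: BLE001 - surface the format problem
        raise TrajectoryError(f"cannot read input: {exc}") from exc

    pos, boxes, times = [], [], []
    for its, ts in enumerate(u.trajectory):
        dims = ts.dimensions
        if dims is None or np.all(dims[:3] == 0):
            raise TrajectoryError("input has no box information")
        if not np.allclose(dims[3:], 90.0, atol=1e-3):
            raise TrajectoryError("only orthorhombic boxes are supported")
        pos.append(ts.positions.astype(float).copy())
        boxes.append(np.asarray(dims[:3], dtype=float))
        t = float(ts.time) if ts.time is not None else float(its)
        times.append(t)
    times_arr = np.asarray(times)
    if len(times_arr) > 1 and np.any(np.diff(times_arr) <= 0):
        times_arr = np.arange(len(times_arr), dtype=float)

    atoms = AtomTable(
        names=np.array([a.name for a in u.atoms], dtype=object),
        resids=np.array([a.resid for a in u.atoms], dtype=int),
        resnames=np.array([a.resname for a in u.atoms], dtype=object),
    )
    return Trajectory(np.array(pos), np.array(boxes), times_arr, atoms)


def write_trajectory(traj: Trajectory, structure_path, trajectory_path=None) -> None:
    """Write a GRO (first frame) and optionally an XTC/TRR trajectory."""
    import MDAnalysis as mda

    n = traj.n_atoms
    resids = traj.atoms.resids
    uniq, res_index = np.unique(resids, return_inverse=True)
    u = mda.Universe.empty(
        n, n_residues=len(uniq), atom_resindex=res_index, trajectory=True
    )
    u.add_TopologyAttr("names", list(traj.atoms.names))
    res_names = [None] * len(uniq)
    for i, r in enumerate(res_index):
        res_names[r] = traj.atoms.resnames[i]
    u.add_TopologyAttr("resnames", res_names)
    u.add_TopologyAttr("resids", list(uniq))

    u.atoms.positions = traj.positions[0]
    u.dimensions = [*traj.boxes[0], 90.0, 90.0, 90.0]
    u.atoms.write(str(structure_path))

    if trajectory_path is not None:
        with mda.Writer(str(trajectory_path), n) as w:
            for i in range(traj.n_frames):
                u.atoms.positions = traj.positions[i]
                u.dimensions = [*traj.boxes[i], 90.0, 90.0, 90.0]
                u.trajectory.ts.time = float(traj.times[i])
                u.trajectory.ts.frame = i
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# Rigid-body superposition
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares proper rotation R and translation t with R@x+t ~ reference.

    Classic SVD solution; a reflection in the optimal orthogonal transform is
    corrected to the best proper rotation (det +1).  Degenerate (collinear)
    references raise.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.shape[0] < 3:
        raise TrajectoryError("need >= 3 paired fit atoms")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    qs = np.linalg.svd(Q - qc, compute_uv=False)
    if qs[1] < 1e-8 * max(qs[0], 1.0):
        raise TrajectoryError("fit reference is degenerate (collinear points)")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def rigid_fit(mobile: Frame, reference_coords: np.ndarray, fit_indices) -> Frame:
    """Superpose a frame onto reference coordinates over the fit atoms."""
    fit_indices = np.asarray(fit_indices, dtype=int)
    R, t = kabsch(mobile.positions[fit_indices], np.asarray(reference_coords, float))
    new_pos = mobile.positions @ R.T + t
    return Frame(new_pos, mobile.box.copy(), mobile.time)


def body_frame(
    positions: np.ndarray, ref: AlignmentReference, roll_atom: int | None = None
) -> BodyFrame:
    """Compute the body frame from the 12 O4 positions of one frame."""
    p1 = positions[list(ref.o4_cd1)]
    p2 = positions[list(ref.o4_cd2)]
    origin = np.concatenate([p1, p2]).mean(axis=0)
    axis = p1.mean(axis=0) - p2.mean(axis=0)
    nrm = np.linalg.norm(axis)
    if nrm < 1e-12:
        raise TrajectoryError("O4 centroids coincide; body axis undefined")
    axis = axis / nrm
    ra = ref.o4_cd1[0] if roll_atom is None else roll_atom
    v = positions[ra] - origin
    v = v - (v @ axis) * axis
    nv = np.linalg.norm(v)
    if nv < 1e-12:
        raise TrajectoryError("roll reference atom lies on the body axis")
    return BodyFrame(origin=origin, axis=axis, roll_ref=v / nv)


def _reference_conformation(positions: np.ndarray, ref: AlignmentReference) -> np.ndarray:
    """Rotate/translate a conformation so its body frame maps onto the lab frame.

    The body axis goes to the target axis, the roll reference to the next lab
    axis (cyclically), and the origin to (0, 0, 0).
    """
    bf = body_frame(positions, ref)
    e3 = np.cross(bf.axis, bf.roll_ref)
    B = np.stack([bf.axis, bf.roll_ref, e3])       # rows: body basis
    k = _AXIS_INDEX[ref.target_axis]
    lab = np.eye(3)
    L = np.stack([lab[k], lab[(k + 1) % 3], lab[(k + 2) % 3]])
    R = L.T @ B                                     # body basis -> lab basis
    return (positions - bf.origin) @ R.T


def align_bulk(traj: Trajectory, ref: AlignmentReference) -> Trajectory:
    """Fit every frame on the 12 O4 atoms to an axis-aligned fixed reference.

    The reference conformation is the first frame, rotated so the O4-centroid
    segment lies along ``ref.target_axis`` and centred at the origin.
    """
    ref_pos = _reference_conformation(traj.positions[0], ref)
    ref_o4 = ref_pos[ref.indices]
    out = traj.copy()
    for i in range(traj.n_frames):
        f = rigid_fit(traj.frame(i), ref_o4, ref.indices)
        out.positions[i] = f.positions
    out.alignment = AlignmentInfo(mode="bulk", reference=ref, ref_o4_coords=ref_o4)
    return out


def _z_rotation_fit(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation about z plus translation mapping mobile onto reference."""
    pc, qc = mobile.mean(axis=0), reference.mean(axis=0)
    P = mobile - pc
    Q = reference - qc
    # 2D Kabsch in the xy plane
    num = np.sum(P[:, 0] * Q[:, 1] - P[:, 1] * Q[:, 0])
    den = np.sum(P[:, 0] * Q[:, 0] + P[:, 1] * Q[:, 1])
    theta = np.arctan2(num, den)
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    t = qc - R @ pc
    return R, t


def align_interface(traj: Trajectory, ref: AlignmentReference) -> Trajectory:
    """Two-stage interface alignment preserving the horizontal water surface.

    Stage 1 rotates the *final* frame about the interface normal (z) so the
    in-plane projection of the body axis points along the target axis, and
    shifts the O4 centroid to x = y = 0 (z kept).  Stage 2 fits every frame
    to that structure on the O4 atoms with the rotation restricted to be
    about z.  Tilt out of the interface plane and spin about the body axis
    are invariant under stage 2 and remain measurable downstream.
    """
    if traj.n_frames < 1:
        raise TrajectoryError("empty trajectory")
    if ref.target_axis == "Z":
        raise TrajectoryError("interface alignment needs an in-plane target axis")
    k = _AXIS_INDEX[ref.target_axis]

    final = traj.positions[-1].copy()
    bf = body_frame(final, ref)
    a_xy = bf.axis.copy()
    a_xy[2] = 0.0
    n_xy = np.linalg.norm(a_xy)
    if n_xy < 1e-9:
        R1 = np.eye(3)  # axis perpendicular to the interface: in-plane heading undefined
    else:
        cur = np.arctan2(a_xy[1], a_xy[0])
        tgt = 0.0 if k == 0 else np.pi / 2.0
        th = tgt - cur
        c, s = np.cos(th), np.sin(th)
        R1 = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    final_aligned = (final - bf.origin) @ R1.T
    final_aligned[:, 2] += bf.origin[2]     # keep the slab at its original height
    ref_o4 = final_aligned[ref.indices]

    out = traj.copy()
    for i in range(traj.n_frames):
        R, t = _z_rotation_fit(traj.positions[i][ref.indices], ref_o4)
        out.positions[i] = traj.positions[i] @ R.T + t
    out.alignment = AlignmentInfo(mode="interface", reference=ref, ref_o4_coords=ref_o4)
    return out


# ---------------------------------------------------------------------------
# Solvent handling
# ---------------------------------------------------------------------------

_WATER_RESNAMES = {"SOL", "WAT", "HOH", "SPC", "TIP3", "T3P"}


def water_sites(atoms: AtomTable, resnames: set[str] | None = None) -> np.ndarray:
    """Group water atoms as an (n_waters, 3) index array [O, H1, H2].

    Waters are identified by residue name; within each residue the oxygen is
    the site whose element is O.
    """
    resnames = resnames or _WATER_RESNAMES
    from .topology import infer_element

    sites = []
    mask = np.array([rn in resnames for rn in atoms.resnames])
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return np.empty((0, 3), dtype=int)
    for rid in np.unique(atoms.resids[idx]):
        members = idx[atoms.resids[idx] == rid]
        elems = [infer_element(atoms.names[i]) for i in members]
        ox = [i for i, e in zip(members, elems) if e == "O"]
        hy = [i for i, e in zip(members, elems) if e == "H"]
        if len(ox) != 1 or len(hy) != 2:
            raise TrajectoryError(
                f"water residue {rid} has {len(ox)} O and {len(hy)} H sites"
            )
        sites.append([ox[0], hy[0], hy[1]])
    return np.array(sites, dtype=int)


def wrap_solvent(
    frame: Frame,
    center: np.ndarray,
    sites: np.ndarray,
) -> Frame:
    """Shift whole solvent molecules by box vectors to the image nearest center.

    The molecule is moved as a unit (keyed on its oxygen), so intramolecular
    geometry is untouched.
    """
    pos = frame.positions.copy()
    center = np.asarray(center, dtype=float)
    if sites.size:
        o = pos[sites[:, 0]]
        shift = -np.round((o - center) / frame.box) * frame.box
        for col in range(sites.shape[1]):
            pos[sites[:, col]] += shift
    return Frame(pos, frame.box.copy(), frame.time)


def assign_cd_rings(
    positions: np.ndarray,
    o4_set_a: Sequence[int],
    o4_set_b: Sequence[int],
    head_index: int,
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Decide which O4 ring is CD1 (nearer the surfactant head atom).

    Returns (o4_cd1, o4_cd2) ordered so CD1 has the smaller mean distance to
    the head atom.
    """
    s = positions[head_index]
    da = np.linalg.norm(positions[list(o4_set_a)] - s, axis=1).mean()
    db = np.linalg.norm(positions[list(o4_set_b)] - s, axis=1).mean()
    if da <= db:
        return tuple(o4_set_a), tuple(o4_set_b)
    return tuple(o4_set_b), tuple(o4_set_a)
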
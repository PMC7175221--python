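"""Synthetic structures, water fields and trajectories for the analysis stack.

Nothing here simulates physics: the generator produces *statistical
structure* with known parameters (radial density layering, dipole
orientation bias, rigid-body motion, a dry cap over one ring) so that every
analysis module can be validated by parameter recovery.  All outputs are
reproducible from (spec, seed).

The scaffold is an idealised two-ring nanocylinder: six oxygens per class
(O2, O3, O4, O5, O6) per ring at 60-degree spacing, polar hydrogens on
O2/O3/O6, and a single charged head atom (S) on the axis beyond CD1.  It
stands in for the 2:1 macrocycle-surfactant complex geometrically - the
analyses depend only on atom labels and selections, not on chemistry.

Waters are rigid three-site molecules with SPC geometry so the dipole
machinery is exercised end to end.  The default layered profile emulates
the three 1.5-Angstrom high-low-high density layers that form around a
tightly solvated cylindrical solute before bulk behaviour is reached.

This module also builds reference topology texts (united-atom and all-atom
hexasaccharide macrocycle, dodecyl-sulfate surfactant): synthetic stand-ins
with the correct stoichiometry, connectivity and nominal masses, written in
the GROMACS dialect so the parser is exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .trajectory import AtomTable, Trajectory

__all__ = [
    "SynthError",
    "ScaffoldSpec",
    "Scaffold",
    "WaterFieldSpec",
    "DryCapSpec",
    "SyntheticTrajectorySpec",
    "build_scaffold",
    "scaffold_positions",
    "sample_waters",
    "water_sites_from_dipoles",
    "generate_trajectory",
    "telegraph_series",
    "alpha_cd_topology",
    "sds_topology",
]

OXYGEN_CLASSES = ("O2", "O3", "O4", "O5", "O6")
_POLAR_H_FOR = {"O2": "H2", "O3": "H3", "O6": "H6"}
_HALF_HOH = np.deg2rad(109.47 / 2.0)


class SynthError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Scaffold
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaffoldSpec:
    """Geometry of the idealised two-ring nanocylinder (Angstrom).

    ``ring_radius`` and ``axial_offset`` are per oxygen class; the offset is
    measured from each ring's O4 plane, negative toward the inter-ring
    interface, positive toward the outside.  The O4 planes sit at
    +/- ``o4_separation`` / 2 along the body axis (x), CD1 on the + side.
    The head atom sits on the axis at ``head_offset`` beyond CD1's O4 plane.
    ``petal_amplitude_deg`` animates the O6 sites on azimuthal arcs with
    opposite handedness in the two rings (positive sense in CD2, negative
    in CD1).
    """

    ring_radius: dict = field(
        default_factory=lambda: {"O2": 5.0, "O3": 5.1, "O4": 4.2, "O5": 3.9, "O6": 3.3}
    )
    axial_offset: dict = field(
        default_factory=lambda: {"O2": -2.5, "O3": -2.6, "O4": 0.0, "O5": -0.8, "O6": 2.4}
    )
    o4_separation: float = 8.0
    head_offset: float = 3.0
    cd2_phase_deg: float = 30.0
    oh_length: float = 1.0
    petal_amplitude_deg: float = 0.0
    petal_period_ns: float = 2.0
    breathing_amplitude: float = 0.0      # Angstrom, radial oscillation of O6
    breathing_period_ns: float = 1.0

    def __post_init__(self) -> None:
        for cls in OXYGEN_CLASSES:
            if self.ring_radius.get(cls, 0.0) <= 0:
                raise SynthError(f"ring radius for {cls} must be positive")


@dataclass
class Scaffold:
    """Built scaffold: positions in the body frame plus selection indices."""

    spec: ScaffoldSpec
    positions: np.ndarray                     # (n_atoms, 3), axis along x, origin at O4 centre
    names: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    class_indices: dict                       # (cd, class) -> tuple of 6 indices, ring order
    ring_indices: dict                        # (cd, ring 1..6) -> tuple of member indices
    head_index: int

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    @property
    def o4_cd1(self) -> tuple[int, ...]:
        return self.class_indices[("CD1", "O4")]

    @property
    def o4_cd2(self) -> tuple[int, ...]:
        return self.class_indices[("CD2", "O4")]

    def atom_table(self) -> AtomTable:
        return AtomTable(names=self.names, resids=self.resids, resnames=self.resnames)


def _scaffold_site(
    spec: ScaffoldSpec, cd: str, cls: str, ring: int,
    petal_phase: float, breath_phase: float,
) -> np.ndarray:
    sign = 1.0 if cd == "CD1" else -1.0
    phase = 0.0 if cd == "CD1" else np.deg2rad(spec.cd2_phase_deg)
    theta = np.deg2rad(60.0 * ring) + phase
    r = spec.ring_radius[cls]
    if cls == "O6":
        if spec.petal_amplitude_deg:
            # azimuthal arc motion, opposite handedness in the two rings
            hand = -1.0 if cd == "CD1" else 1.0
            theta += hand * np.deg2rad(spec.petal_amplitude_deg) * np.sin(petal_phase)
        if spec.breathing_amplitude:
            r += spec.breathing_amplitude * np.sin(breath_phase)
    x = sign * (spec.o4_separation / 2.0 + spec.axial_offset[cls])
    return np.array([x, r * np.cos(theta), r * np.sin(theta)])


def scaffold_positions(spec: ScaffoldSpec, time_ns: float = 0.0) -> np.ndarray:
    """Body-frame coordinates at a given time (petal/breathing modes only)."""
    petal_phase = 2.0 * np.pi * time_ns / spec.petal_period_ns
    breath_phase = 2.0 * np.pi * time_ns / spec.breathing_period_ns
    rows = []
    for cd in ("CD1", "CD2"):
        for ring in range(6):
            for cls in OXYGEN_CLASSES:
                o = _scaffold_site(spec, cd, cls, ring, petal_phase, breath_phase)
                rows.append(o)
                if cls in _POLAR_H_FOR:
                    radial = o.copy()
                    radial[0] = 0.0
                    nr = np.linalg.norm(radial)
                    rows.append(o + spec.oh_length * radial / nr)
    head_x = spec.o4_separation / 2.0 + spec.head_offset
    rows.append(np.array([head_x, 0.0, 0.0]))
    return np.array(rows)


def build_scaffold(spec: ScaffoldSpec | None = None) -> Scaffold:
    """Deterministic scaffold construction with labelled selections."""
    spec = spec or ScaffoldSpec()
    names, resids, resnames = [], [], []
    class_indices: dict = {}
    ring_indices: dict = {}
    idx = 0
    for cdi, cd in enumerate(("CD1", "CD2")):
        for ring in range(6):
            resid = cdi * 6 + ring + 1
            members = []
            for cls in OXYGEN_CLASSES:
                names.append(cls)
                resids.append(resid)
                resnames.append(cd)
                class_indices.setdefault((cd, cls), []).append(idx)
                members.append(idx)
                idx += 1
                if cls in _POLAR_H_FOR:
                    names.append(_POLAR_H_FOR[cls])
                    resids.append(resid)
                    resnames.append(cd)
                    members.append(idx)
                    idx += 1
            ring_indices[(cd, ring + 1)] = tuple(members)
    names.append("S")
    resids.append(13)
    resnames.append("SDS")
    head_index = idx

    return Scaffold(
        spec=spec,
        positions=scaffold_positions(spec, 0.0),
        names=np.array(names, dtype=object),
        resids=np.array(resids, dtype=int),
        resnames=np.array(resnames, dtype=object),
        class_indices={k: tuple(v) for k, v in class_indices.items()},
        ring_indices=ring_indices,
        head_index=head_index,
    )


# ---------------------------------------------------------------------------
# Water fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaterFieldSpec:
    """Point-dipole water field with controllable radial structure.

    ``mode``: 'uniform' (flat density in the box, outside the core),
    'layered' (relative density per radial band around the body axis) or
    'oriented' (layered/uniform density plus dipoles drawn from a
    von Mises-Fisher distribution about the local radial direction with
    concentration ``kappa``; ``kappa=None`` means exactly radial).
    Radii are cylindrical distances from the body (x) axis.  ``core_radius``
    excludes the volume occupied by the scaffold.
    """

    n_waters: int = 1500
    box: tuple[float, float, float] = (40.0, 40.0, 40.0)
    mode: str = "uniform"
    layers: tuple[tuple[float, float, float], ...] = (
        (6.5, 8.0, 1.8), (8.0, 9.5, 0.6), (9.5, 11.0, 1.5),
    )
    kappa: float | None = 8.0
    core_radius: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("uniform", "layered", "oriented"):
            raise SynthError(f"unknown water mode {self.mode!r}")
        for lo, hi, d in self.layers:
            if d < 0 or hi <= lo:
                raise SynthError("layer densities must be >= 0 with hi > lo")

    def relative_density(self, r: np.ndarray) -> np.ndarray:
        w = np.ones_like(r)
        if self.mode in ("layered", "oriented"):
            for lo, hi, d in self.layers:
                w = np.where((r >= lo) & (r < hi), d, w)
        w = np.where(r < self.core_radius, 0.0, w)
        return w


def _sample_vmf(mus: np.ndarray, kappa: float | None, rng: np.random.Generator) -> np.ndarray:
    """von Mises-Fisher samples, one per row of ``mus`` (unit mean vectors)."""
    n = mus.shape[0]
    if kappa is None or np.isinf(kappa):
        return mus.copy()
    # Wood (1994) via inverse-CDF for the pole-aligned colatitude
    u = rng.random(n)
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    st = np.sqrt(np.clip(1.0 - w * w, 0.0, None))
    local = np.column_stack([st * np.cos(phi), st * np.sin(phi), w])
    # rotate e_z -> mu for each sample
    out = np.empty_like(local)
    z = np.array([0.0, 0.0, 1.0])
    for i in range(n):
        mu = mus[i]
        v = np.cross(z, mu)
        s = np.linalg.norm(v)
        c = float(z @ mu)
        if s < 1e-12:
            out[i] = local[i] if c > 0 else -local[i]
            continue
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / (s * s))
        out[i] = R @ local[i]
    return out


def sample_waters(
    spec: WaterFieldSpec, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample oxygen positions and dipole directions in the body frame.

    Returns (o_positions (n, 3), dipole_directions (n, 3) unit vectors).
    The box is centred on the origin.  Raises if the requested density is
    infeasible (zero everywhere).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    probe = spec.relative_density(np.linspace(0.0, float(np.hypot(box[1], box[2])), 512))
    wmax = float(probe.max())
    if wmax <= 0:
        raise SynthError("density profile is zero everywhere; infeasible request")

    accepted: list[np.ndarray] = []
    n_have = 0
    for _ in range(1000):
        m = max(4 * (spec.n_waters - n_have), 1024)
        pts = (rng.random((m, 3)) - 0.5) * box
        r = np.hypot(pts[:, 1], pts[:, 2])
        w = spec.relative_density(r)
        keep = rng.random(m) < w / wmax
        got = pts[keep]
        accepted.append(got)
        n_have += got.shape[0]
        if n_have >= spec.n_waters:
            break
    else:
        raise SynthError("rejection sampling failed to reach the requested count")
    o_pos = np.concatenate(accepted)[: spec.n_waters]

    if spec.mode == "oriented":
        radial = o_pos.copy()
        radial[:, 0] = 0.0
        nr = np.linalg.norm(radial, axis=1, keepdims=True)
        nr[nr < 1e-12] = 1.0
        dirs = _sample_vmf(radial / nr, spec.kappa, rng)
    else:
        v = rng.normal(size=(spec.n_waters, 3))
        dirs = v / np.linalg.norm(v, axis=1, keepdims=True)
    return o_pos, dirs


def water_sites_from_dipoles(
    o_pos: np.ndarray,
    dipole_dirs: np.ndarray,
    rng: np.random.Generator,
    oh_length: float = 1.0,
) -> np.ndarray:
    """Place the two hydrogens of each rigid SPC-geometry water.

    The H-H bisector from the oxygen points along the requested dipole
    direction; the azimuth of the H plane about that axis is random.
    Returns (n, 3 sites, 3) coordinates ordered O, H1, H2.
    """
    n = o_pos.shape[0]
    d = dipole_dirs / np.linalg.norm(dipole_dirs, axis=1, keepdims=True)
    helper = rng.normal(size=(n, 3))
    p = helper - (helper * d).sum(axis=1, keepdims=True) * d
    np_norm = np.linalg.norm(p, axis=1, keepdims=True)
    np_norm[np_norm < 1e-12] = 1.0
    p /= np_norm
    cos_h, sin_h = np.cos(_HALF_HOH), np.sin(_HALF_HOH)
    h1 = o_pos + oh_length * (cos_h * d + sin_h * p)
    h2 = o_pos + oh_length * (cos_h * d - sin_h * p)
    return np.stack([o_pos, h1, h2], axis=1)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DryCapSpec:
    """Remove waters within ``radius`` of one ring's centre (body frame)."""

    cd: str = "CD1"
    ring_index: int = 1
    radius: float = 6.0


@dataclass(frozen=True)
class SyntheticTrajectorySpec:
    """Rigid-body motion and solvent dynamics of a synthetic trajectory.

    Translation/rotation random walks are per-frame step amplitudes (the
    rotation step is an angle about a random axis).  ``roll_rate_deg_per_ns``
    spins the scaffold about its own axis.  ``flip_frame`` rotates the body
    90 degrees about the lab y axis from that frame onward (parallel ->
    perpendicular interface event).  With ``water_jitter`` set, one water
    field is sampled and jittered per frame; otherwise waters are resampled
    independently every frame.
    """

    n_frames: int = 100
    frame_spacing_ps: float = 10.0
    translation_step: float = 0.0
    rotation_step_deg: float = 0.0
    roll_rate_deg_per_ns: float = 0.0
    flip_frame: int | None = None
    water_jitter: float | None = None
    interface: DryCapSpec | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise SynthError("n_frames must be >= 1")


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def generate_trajectory(
    scaffold: Scaffold,
    water_spec: WaterFieldSpec,
    traj_spec: SyntheticTrajectorySpec,
    seed: int | None = None,
    structure_path=None,
    trajectory_path=None,
) -> Trajectory:
    """Assemble frames from the scaffold and the water field.

    All randomness derives from ``seed`` (falling back to the water spec's
    seed), so outputs are reproducible.  When paths are given, the standard
    structure/trajectory formats are written via the trajectory module.
    """
    rng = np.random.default_rng(water_spec.seed if seed is None else seed)
    sspec = scaffold.spec
    n_scaffold = scaffold.n_atoms
    box = np.asarray(water_spec.box, dtype=float)
    half_box = box / 2.0

    if traj_spec.water_jitter is not None:
        o0, d0 = sample_waters(water_spec, rng)

    # dry-cap geometry in the body frame
    cap = traj_spec.interface
    if cap is not None:
        ring = scaffold.ring_indices[(cap.cd, cap.ring_index)]
        cap_center = scaffold.positions[list(ring)].mean(axis=0)

    all_pos = []
    times = np.arange(traj_spec.n_frames) * traj_spec.frame_spacing_ps
    Rrw = np.eye(3)
    crw = np.zeros(3)
    n_waters_kept: int | None = None
    for fi in range(traj_spec.n_frames):
        t_ns = times[fi] / 1000.0
        body = scaffold_positions(sspec, t_ns)

        if traj_spec.water_jitter is not None:
            o = o0 + rng.normal(scale=traj_spec.water_jitter, size=o0.shape)
            d = d0
        else:
            o, d = sample_waters(water_spec, rng)

        if cap is not None:
            keep = np.linalg.norm(o - cap_center, axis=1) >= cap.radius
            o, d = o[keep], d[keep]
        if n_waters_kept is None:
            n_waters_kept = o.shape[0]
        elif o.shape[0] != n_waters_kept:
            # constant atom count across frames: pad by recycling, trim excess
            if o.shape[0] > n_waters_kept:
                o, d = o[:n_waters_kept], d[:n_waters_kept]
            else:
                extra = n_waters_kept - o.shape[0]
                o = np.concatenate([o, o[:extra]])
                d = np.concatenate([d, d[:extra]])
        sites = water_sites_from_dipoles(o, d, rng)

        # body -> lab: roll about body axis, optional flip, random-walk pose
        roll = np.deg2rad(traj_spec.roll_rate_deg_per_ns) * t_ns
        R = _rotation_about(np.array([1.0, 0.0, 0.0]), roll)
        if traj_spec.flip_frame is not None and fi >= traj_spec.flip_frame:
            # tip the CD1 end of the axis up toward the air (+z)
            R = _rotation_about(np.array([0.0, 1.0, 0.0]), -np.pi / 2.0) @ R
        if traj_spec.rotation_step_deg:
            step = np.deg2rad(traj_spec.rotation_step_deg)
            Rrw = _rotation_about(rng.normal(size=3), step * rng.standard_normal()) @ Rrw
        if traj_spec.translation_step:
            crw = crw + rng.normal(scale=traj_spec.translation_step, size=3)
        R = Rrw @ R

        frame_pos = np.empty((n_scaffold + 3 * n_waters_kept, 3))
        frame_pos[:n_scaffold] = body @ R.T + crw + half_box
        frame_pos[n_scaffold:] = (sites.reshape(-1, 3)) @ R.T + crw + half_box
        all_pos.append(frame_pos)

    names = list(scaffold.names)
    resids = list(scaffold.resids)
    resnames = list(scaffold.resnames)
    rid0 = int(max(resids)) + 1
    for wi in range(n_waters_kept):
        names.extend(["OW", "HW1", "HW2"])
        resids.extend([rid0 + wi] * 3)
        resnames.extend(["SOL"] * 3)
    atoms = AtomTable(
        names=np.array(names, dtype=object),
        resids=np.array(resids, dtype=int),
        resnames=np.array(resnames, dtype=object),
    )
    traj = Trajectory(
        positions=np.array(all_pos),
        boxes=np.tile(box, (traj_spec.n_frames, 1)),
        times=times.astype(float),
        atoms=atoms,
    )
    if structure_path is not None:
        from .trajectory import write_trajectory

        write_trajectory(traj, structure_path, trajectory_path)
    return traj


def telegraph_series(
    n_frames: int,
    dt_ps: float,
    mean_on_ps: float,
    mean_off_ps: float,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Discrete-time on/off telegraph occupancy with geometric dwells.

    The per-frame exit probability is dt/tau for each state, i.e. dwell
    times are geometric - the discrete-time exponential - with mean exactly
    tau.  Used as the known-truth generator for lifetime-estimator checks.
    """
    if min(mean_on_ps, mean_off_ps) < dt_ps:
        raise SynthError("dwell means must be at least one frame spacing")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    p_on_exit = dt_ps / mean_on_ps
    p_off_exit = dt_ps / mean_off_ps
    out = np.empty(n_frames, dtype=bool)
    state = rng.random() < mean_on_ps / (mean_on_ps + mean_off_ps)
    u = rng.random(n_frames)
    for i in range(n_frames):
        out[i] = state
        if state:
            state = not (u[i] < p_on_exit)
        else:
            state = u[i] < p_off_exit
    return out


# ---------------------------------------------------------------------------
# Reference topology texts (synthetic stand-ins, correct stoichiometry)
# ---------------------------------------------------------------------------

def _format_topology(name: str, atoms: list[tuple], bonds: list[tuple[int, int]]) -> str:
    """atoms: (type, resnr, resname, atomname, charge, mass) per atom."""
    lines = ["[ moleculetype ]", "; name  nrexcl", f"{name:<8s} 3", "", "[ atoms ]",
             ";   nr  type  resnr  resid  atom  cgnr    charge      mass"]
    for i, (typ, resnr, resname, aname, q, m) in enumerate(atoms, start=1):
        lines.append(
            f"{i:6d}  {typ:<4s} {resnr:6d}  {resname:<5s} {aname:<5s} {resnr:5d} "
            f"{q:9.3f} {m:9.4f}"
        )
    lines += ["", "[ bonds ]", ";  ai    aj  funct"]
    for i, j in bonds:
        lines.append(f"{i:5d} {j:5d}      1")
    lines.append("")
    return "\n".join(lines)


def alpha_cd_topology(representation: str = "united") -> str:
    """Six-unit pyranose macrocycle topology text (C36H60O30, nominal masses).

    ``united``: only the 18 hydroxyl hydrogens are explicit (CH carbons
    carry their hydrogens' mass); ``all_atom``: all 60 hydrogens explicit.
    Hydrogen masses are a nominal 1 Da.
    """
    if representation not in ("united", "all_atom"):
        raise SynthError(f"unknown representation {representation!r}")
    atoms: list[tuple] = []
    bonds: list[tuple[int, int]] = []
    ua = representation == "united"
    per_gpu: list[tuple[str, str, float, list[str]]] = []
    # (atom name, type, mass, bonded-to names within the unit)
    c_mass = 13.019 if ua else 12.011
    c6_mass = 14.027 if ua else 12.011
    per_gpu = [
        ("C1", "CH1" if ua else "C", c_mass, ["O5"]),
        ("C2", "CH1" if ua else "C", c_mass, ["C1"]),
        ("O2", "OA", 15.9994, ["C2"]),
        ("H2", "H", 1.0, ["O2"]),
        ("C3", "CH1" if ua else "C", c_mass, ["C2"]),
        ("O3", "OA", 15.9994, ["C3"]),
        ("H3", "H", 1.0, ["O3"]),
        ("C4", "CH1" if ua else "C", c_mass, ["C3"]),
        ("O4", "OA", 15.9994, ["C4"]),
        ("C5", "CH1" if ua else "C", c_mass, ["C4"]),
        ("O5", "OA", 15.9994, ["C5"]),
        ("C6", "CH2" if ua else "C", c6_mass, ["C5"]),
        ("O6", "OA", 15.9994, ["C6"]),
        ("H6", "H", 1.0, ["O6"]),
    ]
    if not ua:
        per_gpu += [
            ("H1A", "HC", 1.0, ["C1"]),
            ("H2A", "HC", 1.0, ["C2"]),
            ("H3A", "HC", 1.0, ["C3"]),
            ("H4A", "HC", 1.0, ["C4"]),
            ("H5A", "HC", 1.0, ["C5"]),
            ("H6A", "HC", 1.0, ["C6"]),
            ("H6B", "HC", 1.0, ["C6"]),
        ]
    size = len(per_gpu)
    name_to_local = {a[0]: k for k, a in enumerate(per_gpu)}
    charges = {"OA": -0.548, "H": 0.398, "HC": 0.0}
    for g in range(6):
        base = g * size
        for aname, typ, mass, partners in per_gpu:
            atoms.append((typ, g + 1, "GPU", aname, charges.get(typ, 0.150), mass))
        for aname, _, _, partners in per_gpu:
            for p in partners:
                bonds.append((base + name_to_local[p] + 1, base + name_to_local[aname] + 1))
        # glycosidic linkage O4(g) - C1(g+1)
        nxt = ((g + 1) % 6) * size
        bonds.append((base + name_to_local["O4"] + 1, nxt + name_to_local["C1"] + 1))
    return _format_topology("ACD", atoms, bonds)


def sds_topology(representation: str = "united") -> str:
    """Dodecyl-sulfate (sodium salt) topology text, nominal H mass 1 Da."""
    if representation not in ("united", "all_atom"):
        raise SynthError(f"unknown representation {representation!r}")
    ua = representation == "united"
    atoms: list[tuple] = []
    bonds: list[tuple[int, int]] = []

    def add(typ, aname, q, m):
        atoms.append((typ, 1, "SDS", aname, q, m))
        return len(atoms)

    prev = None
    for c in range(1, 13):
        if ua:
            typ, m = ("CH3", 15.035) if c == 1 else ("CH2", 14.027)
            ci = add(typ, f"C{c}", 0.0, m)
        else:
            ci = add("C", f"C{c}", 0.0, 12.011)
            n_h = 3 if c == 1 else 2
            for k in range(n_h):
                hi = add("HC", f"H{c}{'ABC'[k]}", 0.0, 1.0)
                bonds.append((ci, hi))
        if prev is not None:
            bonds.append((prev, ci))
        prev = ci
    oe = add("OE", "OE", -0.36, 15.9994)
    bonds.append((prev, oe))
    s = add("S", "S", 1.284, 32.06)
    bonds.append((oe, s))
    for k in range(1, 4):
        ok = add("OM", f"O{k}S", -0.654, 15.9994)
        bonds.append((s, ok))
    add("NA", "NA", 1.0, 22.9898)     # counter-ion, unbonded
    return _format_topology("SDS", atoms, bonds)
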
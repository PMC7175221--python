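"""Run configuration: selection vocabulary and analysis parameters.

A single YAML file names every selection role (oxygen classes per ring
system, sugar-ring memberships, surfactant head, water residues) and the
analysis parameters; command-line flags override config keys.  Selections
resolve to concrete atom indices against the structure's atom table, with
cardinality checks (six atoms per oxygen class per CD, twelve O4 in total).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .hydration import RingDefinition
from .trajectory import AlignmentReference, AtomTable

__all__ = [
    "ConfigError",
    "RunConfig",
    "Selections",
    "default_config",
    "load_config",
    "resolve_selections",
]

OXYGEN_CLASSES = ("O2", "O3", "O4", "O5", "O6")


class ConfigError(ValueError):
    pass


DEFAULTS: dict = {
    "selections": {
        "cd1_resname": "CD1",
        "cd2_resname": "CD2",
        "oxygen_classes": list(OXYGEN_CLASSES),
        "head_name": "S",
        "water_resnames": ["SOL", "WAT", "HOH"],
        "polar_h_names": ["H2", "H3", "H6"],
    },
    "analysis": {
        "target_axis": "X",
        "last_n": None,
        "cutoffs": [3.0, 5.0],
        "smooth_ns": None,
        "water_model": "SPC",
        "hbond": {"da_cutoff": 3.5, "angle_cutoff": 30.0},
    },
    "seed": 0,
}


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class RunConfig:
    data: dict

    def __getitem__(self, key: str):
        return self.data[key]

    @property
    def selections(self) -> dict:
        return self.data["selections"]

    @property
    def analysis(self) -> dict:
        return self.data["analysis"]

    @property
    def seed(self) -> int:
        return int(self.data.get("seed", 0))


def default_config() -> RunConfig:
    return RunConfig(_deep_merge(DEFAULTS, {}))


def load_config(path=None, overrides: Mapping | None = None) -> RunConfig:
    data = DEFAULTS
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"config {path} must be a mapping")
        data = _deep_merge(data, user)
    if overrides:
        data = _deep_merge(data, overrides)
    return RunConfig(data)


@dataclass
class Selections:
    """Resolved atom-index sets for every analysis role."""

    class_indices: dict                   # (cd label, class) -> tuple of 6 indices
    rings: tuple[RingDefinition, ...]     # 12 rings
    head_index: int
    alignment: AlignmentReference

    def o4(self, cd: str) -> tuple[int, ...]:
        return self.class_indices[(cd, "O4")]


def resolve_selections(config: RunConfig, atoms: AtomTable) -> Selections:
    """Map every selection role to concrete indices, checking cardinalities."""
    sel = config.selections
    names = atoms.names
    resnames = atoms.resnames
    resids = atoms.resids

    class_indices: dict = {}
    for cd_key, cd_label in (("cd1_resname", "CD1"), ("cd2_resname", "CD2")):
        resname = sel[cd_key]
        cd_mask = resnames == resname
        if not cd_mask.any():
            raise ConfigError(f"role {cd_key}: no atoms with resname {resname!r}")
        for cls in sel["oxygen_classes"]:
            idx = np.nonzero(cd_mask & (names == cls))[0]
            if len(idx) != 6:
                raise ConfigError(
                    f"role {cd_label}/{cls}: matched {len(idx)} atoms, expected 6 "
                    f"(matches: {idx.tolist()})"
                )
            # ring order: by residue index
            order = np.argsort(resids[idx], kind="stable")
            class_indices[(cd_label, cls)] = tuple(int(i) for i in idx[order])

    head = np.nonzero(names == sel["head_name"])[0]
    if len(head) != 1:
        raise ConfigError(
            f"role head_name: matched {len(head)} atoms named {sel['head_name']!r}, "
            "expected exactly 1"
        )

    rings = []
    for cd_key, cd_label in (("cd1_resname", "CD1"), ("cd2_resname", "CD2")):
        resname = sel[cd_key]
        cd_mask = resnames == resname
        rids = sorted(set(resids[cd_mask].tolist()))
        if len(rids) != 6:
            raise ConfigError(
                f"role {cd_label} rings: found {len(rids)} residues, expected 6"
            )
        for k, rid in enumerate(rids, start=1):
            members = np.nonzero(cd_mask & (resids == rid))[0]
            rings.append(
                RingDefinition(
                    cd=cd_label, ring_index=k,
                    atom_indices=tuple(int(i) for i in members),
                )
            )

    o4_all = class_indices[("CD1", "O4")] + class_indices[("CD2", "O4")]
    if len(set(o4_all)) != 12:
        raise ConfigError("role O4: the two rings' O4 selections overlap")

    alignment = AlignmentReference(
        o4_cd1=class_indices[("CD1", "O4")],
        o4_cd2=class_indices[("CD2", "O4")],
        target_axis=config.analysis.get("target_axis", "X"),
    )
    return Selections(
        class_indices=class_indices,
        rings=tuple(rings),
        head_index=int(head[0]),
        alignment=alignment,
    )
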
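"""Shared fixtures: small topologies, the synthetic scaffold, seeded RNGs.

Everything is generated programmatically; no data files are shipped.
"""

from __future__ import annotations

import numpy as np
import pytest

from cdsolv import topology as tp
from cdsolv.config import default_config, resolve_selections
from cdsolv.synth import (
    ScaffoldSpec,
    SyntheticTrajectorySpec,
    WaterFieldSpec,
    alpha_cd_topology,
    build_scaffold,
    generate_trajectory,
    sds_topology,
)

HYDROXYL_ITP = """\
[ moleculetype ]
; name  nrexcl
HYDX 3

[ atoms ]
;   nr  type  resnr  resid  atom  cgnr    charge      mass
     1  OA        1  FRG   O3        1    -0.548   16.0000
     2  H         1  FRG   H3        1     0.398    1.0000

[ bonds ]
;  ai    aj  funct
    1     2      1
"""


@pytest.fixture(scope="session")
def hydroxyl_text() -> str:
    return HYDROXYL_ITP


@pytest.fixture(scope="session")
def hydroxyl(hydroxyl_text):
    return tp.parse_topology(hydroxyl_text).molecule()


@pytest.fixture(scope="session")
def ua_acd():
    """United-atom six-unit macrocycle: 18 explicit (polar) hydrogens."""
    return tp.parse_topology(alpha_cd_topology("united")).molecule()


@pytest.fixture(scope="session")
def aa_acd():
    """All-atom macrocycle: 60 hydrogens, composition C36H60O30."""
    return tp.parse_topology(alpha_cd_topology("all_atom")).molecule()


@pytest.fixture(scope="session")
def sds_aa():
    return tp.parse_topology(sds_topology("all_atom")).molecule()


@pytest.fixture(scope="session")
def sds_ua():
    return tp.parse_topology(sds_topology("united")).molecule()


@pytest.fixture(scope="session")
def scaffold():
    return build_scaffold(ScaffoldSpec())


@pytest.fixture(scope="session")
def small_traj(scaffold):
    """10 rigid-motion frames with 200 uniform waters."""
    return generate_trajectory(
        scaffold,
        WaterFieldSpec(n_waters=200, seed=101),
        SyntheticTrajectorySpec(
            n_frames=10, translation_step=0.5, rotation_step_deg=4.0
        ),
        seed=102,
    )


@pytest.fixture(scope="session")
def selections(small_traj):
    return resolve_selections(default_config(), small_traj.atoms)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
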
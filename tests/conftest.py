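"""Shared fixtures: the three test systems and a finite-difference helper."""

from __future__ import annotations

import numpy as np
import pytest

from qmmmkit.charges import merge_charges_me
from qmmmkit.fixtures import build_fixture
from qmmmkit.topology import Structure

FIXTURE_IDS = ("ethanol_methanol", "dipeptide_two_junctions",
               "bonded_cl_dithiolene_analogue")


@pytest.fixture(scope="session")
def ethanol():
    return build_fixture("ethanol_methanol", seed=11)


@pytest.fixture(scope="session")
def nma():
    return build_fixture("dipeptide_two_junctions", seed=11)


@pytest.fixture(scope="session")
def dme():
    return build_fixture("bonded_cl_dithiolene_analogue", seed=11)


@pytest.fixture(scope="session", params=FIXTURE_IDS)
def any_fixture(request):
    return build_fixture(request.param, seed=11)


def merged_for(fixture):
    return merge_charges_me(fixture.mm_charges, fixture.qm_charges,
                            fixture.region_map, fixture.unit_partition)


def fd_gradient(energy_fn, coords: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Central finite-difference gradient of ``energy_fn(Structure)``."""
    grad = np.zeros_like(coords)
    for i in range(coords.shape[0]):
        for x in range(3):
            plus = coords.copy()
            plus[i, x] += step
            minus = coords.copy()
            minus[i, x] -= step
            grad[i, x] = (energy_fn(Structure(plus))
                          - energy_fn(Structure(minus))) / (2.0 * step)
    return grad
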
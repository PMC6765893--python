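"""Shared fixtures.

Expensive finite-element solves (strip validation, refinement pair) are
session-scoped so the acceptance checks and unit tests share one run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from fibreo import synthetic as syn
from fibreo.constitutive import FibrilFrame, MaterialParams


@pytest.fixture(scope="session")
def params() -> MaterialParams:
    return MaterialParams()


@pytest.fixture(scope="session")
def frame(params) -> FibrilFrame:
    return FibrilFrame.from_params(params)


@pytest.fixture(scope="session")
def fixture_trend():
    return syn.fixture_trend()


@pytest.fixture(scope="session")
def fixture_K():
    return syn.fixture_distribution()


def random_tension_state(rng, frame, spread=0.05, offset=1.03):
    """Random deformation gradient with all fibril invariants clear of the gate."""
    from fibreo.constitutive import kinematics

    while True:
        F = offset * np.eye(3) + spread * rng.standard_normal((3, 3))
        if np.linalg.det(F) < 0.5:
            continue
        st = kinematics(F, frame)
        inv = np.concatenate([st.I4, st.I6, st.I6m])
        if np.all(np.abs(inv - 1.0) > 2e-3):
            return F


@pytest.fixture(scope="session")
def strip_validation_noisy(fixture_trend):
    """Strip validation with the shipped fixture at default noise (one FE solve)."""
    from fibreo.mechanics import strip_validation

    data = syn.gen_strip_dataset(syn.StripDatasetSpec(seed=7), fixture_trend)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return strip_validation(fixture_trend, data)


@pytest.fixture(scope="session")
def strip_self_consistency_result(fixture_trend):
    """Noise-free round trip of the strip pipeline (one FE solve)."""
    from fibreo.mechanics.strip import strip_self_consistency

    points0 = syn.gen_strip_dataset(
        syn.StripDatasetSpec(noise_total=0.0, noise_bin=0.0, seed=1), fixture_trend
    )[0.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return strip_self_consistency(fixture_trend, points0)


@pytest.fixture(scope="session")
def strip_refinement_pair():
    """Mid-region axial strain at 8 % for the base and density-doubled meshes."""
    from fibreo.constitutive import MaterialParams as MP
    from fibreo.mechanics.fem import StaticSolver
    from fibreo.mechanics.strip import FE_PENALTY_D, build_strip_model

    out = {}
    for nx, ny, nz in ((20, 2, 2), (40, 4, 4)):
        mesh, lc = build_strip_model(nx, ny, nz)
        solver = StaticSolver(mesh, params=MP(D=FE_PENALTY_D))
        hist = solver.solve(lc.dirichlet, schedule=(0.25, 0.5, 0.75, 1.0))
        st = hist[-1]
        mask = mesh.regions == "C"
        out[(nx, ny, nz)] = float(np.mean(st.axial_strain[mask]))
    return out
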
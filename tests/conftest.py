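"""Shared fixtures: study head model, sphere geometry, concentric meshes."""

from __future__ import annotations

import numpy as np
import pytest

from irritmap.headmodel import Montage, SourceSpace, SphereModel
from irritmap.pipeline import build_study_headmodel

RADII_MM = (8.5, 9.2, 10.0)
SIGMA = 0.33


@pytest.fixture(scope="session")
def study_head():
    """The canonical simulation-study head model (expensive; share it)."""
    return build_study_headmodel()


@pytest.fixture(scope="session")
def equal_sigma_sphere() -> SphereModel:
    """Three shells with equal conductivity: analytically a single sphere."""
    return SphereModel(
        center=np.zeros(3), radii=np.array(RADII_MM),
        conductivities=np.full(3, SIGMA),
    )


@pytest.fixture(scope="session")
def surface_montage() -> Montage:
    """32 electrodes spread over the full outer sphere."""
    rng = np.random.default_rng(2024)
    v = rng.normal(size=(32, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return Montage([f"E{i}" for i in range(32)], v * RADII_MM[-1])


def random_interior_sources(n: int, max_ecc: float, seed: int) -> SourceSpace:
    """Random dipole positions inside the innermost shell."""
    rng = np.random.default_rng(seed)
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    r = rng.uniform(0.0, max_ecc, size=(n, 1)) * RADII_MM[0]
    return SourceSpace(positions=d * r)
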
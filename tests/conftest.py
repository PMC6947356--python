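"""Shared fixtures: default joint, coarse configs, and the full study run."""

from __future__ import annotations

import numpy as np
import pytest

from pfjsim import Config, JointParams, build_joint, run_study
from pfjsim.study import _CaseRunner


@pytest.fixture(scope="session")
def default_joint():
    return build_joint(JointParams())


@pytest.fixture(scope="session")
def default_runner():
    """Case runner on the default (paper-faithful) configuration."""
    return _CaseRunner(Config())


@pytest.fixture(scope="session")
def full_study(default_runner):
    """The complete 7-configuration x 5-angle study at default settings."""
    table = run_study(Config())
    assert all(r.converged for r in table.rows)
    return table


@pytest.fixture()
def coarse_config():
    """Small-mesh configuration for fast I/O and determinism tests."""
    cfg = Config()
    cfg.geometry.mesh_resolution = 800
    return cfg


@pytest.fixture()
def flat_patch():
    """Uniform flat 10x10 mm patch of 100 faces at z = 0 (for foundation
    oracles): returns (centroids, areas)."""
    n, side = 10, 10.0
    xs = (np.arange(n) + 0.5) * side / n - side / 2
    cx, cy = np.meshgrid(xs, xs)
    cent = np.stack([cx.ravel(), cy.ravel(), np.zeros(n * n)], axis=1)
    areas = np.full(n * n, (side / n) ** 2)
    return cent, areas
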
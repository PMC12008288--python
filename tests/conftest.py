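"""Shared fixtures: a small synthetic study that every stage can run on."""

from __future__ import annotations

import numpy as np
import pytest

from ctrlenergy import ControlConfig, ControlEnergyModel
from ctrlenergy.synth import (
    SynthConfig,
    gen_bold,
    gen_connectome,
    gen_receptor_map,
    gen_reference_series,
)


def stable_system(n: int, rng: np.random.Generator, margin: float = 0.5) -> np.ndarray:
    """Random Hurwitz-stable matrix with spectral abscissa -margin."""
    a = rng.standard_normal((n, n))
    return a - (np.max(np.linalg.eigvals(a).real) + margin) * np.eye(n)


@pytest.fixture(scope="session")
def synth_cfg() -> SynthConfig:
    # desk-scale study: 40 regions (32 cortical), 6 subjects, 8 min scans
    return SynthConfig(
        n_regions=40, n_cortical=32, n_subjects=6, n_volumes=240,
        injection_volume=70, seed=11,
    )


@pytest.fixture(scope="session")
def connectome(synth_cfg):
    return gen_connectome(synth_cfg)


@pytest.fixture(scope="session")
def receptor_map(synth_cfg):
    rmap, coords = gen_receptor_map(synth_cfg)
    return rmap, coords


@pytest.fixture(scope="session")
def bold(synth_cfg, connectome, receptor_map):
    rmap, _ = receptor_map
    return gen_bold(synth_cfg, connectome, rmap)


@pytest.fixture(scope="session")
def fitted(synth_cfg, connectome, bold):
    drug, placebo = bold
    model = ControlEnergyModel(
        drug, placebo, connectome, config=ControlConfig(integration_steps=201)
    )
    return model.fit(n_perm=300, seed=1)


@pytest.fixture(scope="session")
def references(synth_cfg, fitted):
    div_drug, intensity = gen_reference_series(synth_cfg, fitted.group_global["drug"])
    div_pcb, _ = gen_reference_series(synth_cfg, fitted.group_global["placebo"])
    return div_drug, div_pcb, intensity
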
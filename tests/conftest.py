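"""Shared fixtures: small patches and pre-relaxed states reused across tests.

Everything is generated programmatically at fixed seeds; expensive fixtures
are session-scoped so dynamics runs are paid for once.
"""
import numpy as np
import pytest

from pgmech import (PatchConfig, preset, generate_patch, build_patch,
                    ForceFieldParams, relax_patch)


@pytest.fixture(scope="session")
def ff_params():
    return ForceFieldParams()


@pytest.fixture(scope="session")
def tiny_config():
    """A 4-strand, short-strand patch for fast unit tests."""
    return PatchConfig(mean_length=4, sd_length=1.0, n_strands=4,
                      spacing=2.5, spacing_jitter=0.3, seed=11)


@pytest.fixture(scope="session")
def tiny_patch(tiny_config):
    return generate_patch(tiny_config)


@pytest.fixture(scope="session")
def small_linked_patch(ff_params):
    """A cross-linked 6-strand patch (cached build)."""
    cfg = PatchConfig(mean_length=6, sd_length=1.5, n_strands=6,
                      spacing=2.5, spacing_jitter=0.3, seed=7)
    return build_patch(cfg, seed=7, params=ff_params, n_relax_steps=2500)


@pytest.fixture(scope="session")
def small_relaxed_patch(small_linked_patch, ff_params):
    relaxed, _ = relax_patch(small_linked_patch, ff_params, n_steps=4000,
                             seed=13)
    return relaxed


@pytest.fixture(scope="session")
def avg17_relaxed_patch(ff_params):
    """The 12-strand avg17 construct, cross-linked and box-relaxed."""
    patch = build_patch(preset("avg17", seed=1), seed=1, params=ff_params)
    relaxed, _ = relax_patch(patch, ff_params, n_steps=8000, seed=5)
    return relaxed


@pytest.fixture(scope="session")
def avg17_sweep(avg17_relaxed_patch, ff_params):
    """A scaled-down clamped-strain sweep on the avg17 construct."""
    from pgmech import run_elasticity_sweep
    return run_elasticity_sweep(
        avg17_relaxed_patch, ff_params,
        glycan_strains=[0.05, 0.1, 0.175],
        peptide_strains=[0.15, 0.3, 0.45],
        repeats=2, seed=9, n_steps=2500)


@pytest.fixture(scope="session")
def wlc_reference_ensemble():
    """The calibration ensemble: 500 chains x 320 segments at lp=13.6 nm."""
    from pgmech import generate_wlc_ensemble
    return generate_wlc_ensemble(500, 320, b=0.515, lp=13.6, seed=7)
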
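"""Shared fixtures: geometries and cached transport runs.

Transport runs are session-scoped so that several tests can share one kernel
warm-up and one set of paired-phase simulations.
"""

import numpy as np
import pytest

import ringoxsim as rx


@pytest.fixture(scope="session")
def model1_dia():
    return rx.build_finger_model(1, rx.CardiacPhase.DIASTOLE)


@pytest.fixture(scope="session")
def model1_sys():
    return rx.build_finger_model(1, rx.CardiacPhase.SYSTOLE)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def pair_150_943(model1_dia, model1_sys):
    """CRN phase pair, model 1, source 150 deg, 943 nm, 2e5 photons."""
    src = rx.SourceSpec(theta_deg=150.0, wavelength=943, n_photons=200_000, seed=42)
    return (
        rx.run_simulation(model1_dia, src),
        rx.run_simulation(model1_sys, src),
    )


@pytest.fixture(scope="session")
def small_sweep():
    """Minimal sweep: one model, one source angle, small budget."""
    cfg = rx.SweepConfig(
        models=(1,), source_angles=(150.0,), photons=20_000, seed=3
    )
    return rx.run_sweep(cfg)
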
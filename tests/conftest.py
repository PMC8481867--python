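"""Shared fixtures: reference parameters and small synthetic cohorts.

Everything is generated programmatically; expensive cohorts are session
scoped so multiple tests share them.
"""

import numpy as np
import pytest

from bvkinetics import CohortConfig, InputProtocol, ModelParams, generate_cohort
from bvkinetics.cohort import ovine_hemorrhage_protocol


@pytest.fixture(scope="session")
def reference_params() -> ModelParams:
    """A calibrated-sheep-like parameter triple used across examples."""
    return ModelParams(alpha_u=3.0, alpha_v=1.40, k_p=0.14)


@pytest.fixture(scope="session")
def study_protocol() -> InputProtocol:
    """The weight-normalized study protocol for a 30 kg subject with a
    constant infusion replacing the full hemorrhage volume."""
    w = 30.0
    infusion = [(30.0, 180.0, 35.0 * w / 150.0)]
    return InputProtocol.from_schedules(infusion, ovine_hemorrhage_protocol(w), 180.0)


@pytest.fixture(scope="session")
def noise_free_cohort() -> list:
    return generate_cohort(CohortConfig(n_subjects=5, noise_sd=0.0, seed=42))


@pytest.fixture(scope="session")
def noisy_cohort() -> list:
    return generate_cohort(CohortConfig(n_subjects=10, noise_sd=0.10, seed=7))


def random_params(rng: np.random.Generator) -> ModelParams:
    """Random valid parameters over a broad physiological range."""
    return ModelParams(
        alpha_u=float(rng.uniform(-0.5, 8.0)),
        alpha_v=float(rng.uniform(-0.5, 8.0)),
        k_p=float(np.exp(rng.uniform(np.log(0.02), np.log(0.5)))),
    )


def random_protocol(rng: np.random.Generator, t_final: float = 180.0) -> InputProtocol:
    """Random piecewise-constant protocol with 2-6 segments."""
    n_seg = int(rng.integers(2, 7))
    cuts = np.sort(rng.uniform(5, t_final - 5, size=n_seg - 1))
    bounds = np.concatenate([[0.0], cuts, [t_final]])
    segs = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        u = float(rng.uniform(0, 30)) if rng.random() < 0.7 else 0.0
        v = float(rng.uniform(0, 60)) if rng.random() < 0.5 else 0.0
        segs.append((a, b, u, v))
    return InputProtocol(segs)
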
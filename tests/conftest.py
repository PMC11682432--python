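import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rsict2 as r

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_protocol():
    """Cohort-2 preset on a small grid: fast but exercises every stage."""
    return r.COHORT2_PROTOCOL.with_grid((20, 20, 8))


@pytest.fixture(scope="session")
def noiseless_patient(small_protocol):
    """One csPCa patient with exact (noise-free, unit-gain) signals."""
    return r.generate_patient(
        small_protocol,
        lesion_specs=(r.LesionSpec(),),
        noise=r.NoiseModel.none(),
        seed=7,
        gain=1.0,
    )


@pytest.fixture(scope="session")
def noiseless_maps(noiseless_patient):
    pm, row = r.process_patient(noiseless_patient)
    return pm, row


@pytest.fixture(scope="session")
def small_cohort():
    """Ten patients on a small grid with default tissue/noise settings."""
    proto = r.COHORT1_PROTOCOL.with_grid((24, 24, 8))
    return r.generate_cohort(10, cspca_prevalence=0.5, protocol=proto, seed=11)


@pytest.fixture(scope="session")
def small_cohort_maps(small_cohort):
    pms, rows = [], []
    for p in small_cohort:
        pm, row = r.process_patient(p)
        pms.append(pm)
        rows.append(row)
    import pandas as pd

    return pms, pd.DataFrame(rows)


def active_set_nnls(design: np.ndarray, signal: np.ndarray) -> np.ndarray:
    """Brute-force NNLS oracle: enumerate every compartment subset, solve
    the unconstrained least-squares problem on it, and keep the feasible
    (all-non-negative) solution with the smallest residual."""
    import itertools

    n = design.shape[1]
    best, best_resid = np.zeros(n), float(np.sum(signal**2))
    for k in range(1, n + 1):
        for subset in itertools.combinations(range(n), k):
            sub = design[:, subset]
            coef, *_ = np.linalg.lstsq(sub, signal, rcond=None)
            if np.any(coef < 0):
                continue
            resid = float(np.sum((signal - sub @ coef) ** 2))
            if resid < best_resid - 1e-15:
                best_resid = resid
                best = np.zeros(n)
                best[list(subset)] = coef
    return best
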
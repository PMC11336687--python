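import numpy as np
import pytest

from altdyn import run, summarize_run
from altdyn.experiments import analyze_run, reduced_params

N_COHORT = 20


@pytest.fixture(scope="session")
def reduced_cohort():
    """Twenty seeded runs at the reduced-scale study conditions."""
    return [run(reduced_params(seed=s)) for s in range(N_COHORT)]


@pytest.fixture(scope="session")
def reduced_analytics(reduced_cohort):
    """Per-sample combined analytics for each cohort run."""
    return [analyze_run(r) for r in reduced_cohort]


@pytest.fixture(scope="session")
def reduced_summaries(reduced_cohort):
    return [summarize_run(r) for r in reduced_cohort]


@pytest.fixture(scope="session")
def small_run():
    """One reduced-scale run used for structural checks."""
    return run(reduced_params(seed=0))


def ls_slope(t, y):
    """Least-squares slope ignoring NaNs; NaN when under 3 points."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    m = np.isfinite(y)
    if m.sum() < 3:
        return float("nan")
    return float(np.polyfit(t[m], y[m], 1)[0])
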
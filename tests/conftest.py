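import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from clonefate.model import (
    DIE,
    DIFFERENTIATE,
    DIVIDE,
    REMAIN,
    FateModelParams,
    TimeDistribution,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def defaults():
    from clonefate.synthetic import default_ground_truth

    return default_ground_truth()


@pytest.fixture(scope="session")
def recovery_params() -> FateModelParams:
    """Known tables for estimation round-trips.

    Event-time supports are short relative to the 100 h horizon and both
    subsequent regimes are subcritical, so that effectively every drawn
    event fires before the horizon and the estimator's censoring
    convention (unfired events count as remain-unchanged) does not bias
    the recovered frequencies.
    """
    D = TimeDistribution.discretized_gamma
    U = TimeDistribution.uniform
    return FateModelParams(
        first_event_probs={DIVIDE: 0.50, DIFFERENTIATE: 0.32, REMAIN: 0.18},
        first_event_time_dists={DIVIDE: D(2.5, 5.0, 8, 30), DIFFERENTIATE: U(8, 24)},
        subsequent_event_probs={
            "gfp_neg": {DIVIDE: 0.30, DIFFERENTIATE: 0.22, DIE: 0.25, REMAIN: 0.23},
            "gfp_pos": {DIVIDE: 0.30, DIE: 0.38, REMAIN: 0.32},
        },
        subsequent_event_time_dists={
            "gfp_neg": {
                DIVIDE: D(2.0, 2.5, 4, 16),
                DIFFERENTIATE: U(2, 10),
                DIE: D(1.5, 2.5, 3, 16),
            },
            "gfp_pos": {DIVIDE: D(2.0, 2.5, 4, 16), DIE: D(1.5, 2.5, 3, 16)},
        },
    )


def simple_params(
    first_probs,
    first_times=None,
    sub_neg=None,
    sub_pos=None,
    sub_times=None,
    horizon=100,
    n_founders=5,
) -> FateModelParams:
    """Minimal valid parameter set for targeted unit tests."""
    first_times = first_times or {}
    dists = {}
    for ev, p in first_probs.items():
        if ev != REMAIN and p > 0:
            dists[ev] = TimeDistribution.point_mass(first_times.get(ev, 10))
    sub_neg = sub_neg or {REMAIN: 1.0}
    sub_pos = sub_pos or {REMAIN: 1.0}
    sub_times = sub_times or {}
    sub_dists = {"gfp_neg": {}, "gfp_pos": {}}
    for state, probs in (("gfp_neg", sub_neg), ("gfp_pos", sub_pos)):
        for ev, p in probs.items():
            if ev != REMAIN and p > 0:
                sub_dists[state][ev] = TimeDistribution.point_mass(
                    sub_times.get((state, ev), sub_times.get(ev, 10))
                )
    return FateModelParams(
        first_event_probs=first_probs,
        first_event_time_dists=dists,
        subsequent_event_probs={"gfp_neg": sub_neg, "gfp_pos": sub_pos},
        subsequent_event_time_dists=sub_dists,
        horizon_hours=horizon,
        n_founders=n_founders,
    )


def brute_force_gini(sizes) -> float:
    """Independent O(N^2) pairwise double sum: sum |x_i - x_j| / (2 N^2 mu)."""
    x = np.asarray(sizes, dtype=float)
    n = x.size
    mu = x.mean()
    if mu == 0:
        return float("nan")
    return float(np.abs(x[:, None] - x[None, :]).sum() / (2 * n * n * mu))
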
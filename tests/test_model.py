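import math

import numpy as np
import pytest

from clonefate.model import (
    DIE,
    DIFFERENTIATE,
    DIVIDE,
    REMAIN,
    CellState,
    FateModelParams,
    TimeDistribution,
    init_founder,
    make_variant,
    resolve_event,
    run_clone,
    run_population,
    sample_event,
    sample_event_time,
)

from .conftest import simple_params


# -- time distributions -------------------------------------------------------


def test_time_distribution_validation():
    with pytest.raises(ValueError):
        TimeDistribution(np.array([5, 3]), np.array([0.5, 0.5]))  # not increasing
    with pytest.raises(ValueError):
        TimeDistribution(np.array([1, 2]), np.array([0.5, 0.4]))  # mass below 1
    with pytest.raises(ValueError):
        TimeDistribution.from_pmf({0: 1.0})  # support starts before hour 1


def test_point_mass_sampling_is_degenerate():
    d = TimeDistribution.point_mass(20)
    rng = np.random.default_rng(0)
    assert {sample_event_time(d, rng) for _ in range(50)} == {20}
    assert d.median == 20


def test_uniform_sampling_frequencies():
    d = TimeDistribution.uniform(10, 19)
    rng = np.random.default_rng(42)
    draws = np.array([sample_event_time(d, rng) for _ in range(100_000)])
    freqs = np.bincount(draws, minlength=20)[10:20] / draws.size
    assert np.abs(freqs - 0.1).max() < 0.005


def test_two_point_distribution_mean():
    d = TimeDistribution.from_pmf({24: 0.3, 48: 0.7})
    rng = np.random.default_rng(1)
    draws = [sample_event_time(d, rng) for _ in range(100_000)]
    assert np.mean(draws) == pytest.approx(0.3 * 24 + 0.7 * 48, abs=0.15)
    assert d.mean == pytest.approx(40.8)


def test_median_is_smallest_hour_reaching_half():
    d = TimeDistribution.from_pmf({5: 0.4, 9: 0.2, 30: 0.4})
    assert d.median == 9


# -- event sampling -----------------------------------------------------------


def test_sample_event_degenerate_choices():
    rng = np.random.default_rng(0)
    assert all(sample_event({DIVIDE: 1.0}, rng) == DIVIDE for _ in range(20))
    assert sample_event({REMAIN: 1.0}, rng) == REMAIN


def test_sample_event_rejects_unnormalized():
    with pytest.raises(ValueError):
        sample_event({DIVIDE: 0.5, DIE: 0.4}, np.random.default_rng(0))


def test_sample_event_frequencies():
    rng = np.random.default_rng(7)
    draws = [sample_event({DIVIDE: 0.5, DIE: 0.5}, rng) for _ in range(100_000)]
    assert draws.count(DIVIDE) / len(draws) == pytest.approx(0.5, abs=0.01)


# -- founders -----------------------------------------------------------------


def test_founder_forced_division_schedule():
    p = simple_params({DIVIDE: 1.0}, first_times={DIVIDE: 30})
    f = init_founder(p, 0, np.random.default_rng(0))
    assert (f.scheduled_event, f.scheduled_hour) == (DIVIDE, 30)
    assert f.generation == 0 and not f.differentiated and f.birth_hour == 0


def test_founder_remain_never_fires():
    p = simple_params({REMAIN: 1.0})
    f = init_founder(p, 0, np.random.default_rng(0))
    assert f.scheduled_event == REMAIN and math.isinf(f.scheduled_hour)


def test_founder_event_fractions():
    p = simple_params({DIVIDE: 0.6, DIFFERENTIATE: 0.3, REMAIN: 0.1})
    rng = np.random.default_rng(5)
    events = [init_founder(p, i, rng).scheduled_event for i in range(10_000)]
    for ev, frac in ((DIVIDE, 0.6), (DIFFERENTIATE, 0.3), (REMAIN, 0.1)):
        assert events.count(ev) / 1e4 == pytest.approx(frac, abs=0.02)


# -- event resolution ---------------------------------------------------------


def _cell(event, hour=10, differentiated=False):
    return CellState(0, 0, True, differentiated, 0, event, hour)


def test_division_yields_two_daughters_inheriting_state():
    p = simple_params({DIVIDE: 1.0}, sub_neg={REMAIN: 1.0})
    out = resolve_event(_cell(DIVIDE), p, 10, np.random.default_rng(0))
    assert len(out) == 2
    for d in out:
        assert d.generation == 1 and not d.differentiated and d.birth_hour == 10


def test_differentiation_is_division_independent():
    p = simple_params({DIVIDE: 1.0}, sub_pos={REMAIN: 1.0})
    out = resolve_event(_cell(DIFFERENTIATE), p, 10, np.random.default_rng(0))
    assert len(out) == 1 and out[0].differentiated and out[0].generation == 0


def test_death_removes_cell():
    p = simple_params({DIVIDE: 1.0})
    assert resolve_event(_cell(DIE, differentiated=True), p, 10, np.random.default_rng(0)) == []


def test_resolving_dead_cell_raises():
    p = simple_params({DIVIDE: 1.0})
    dead = CellState(0, 0, False, False, 0, DIE, 5)
    with pytest.raises(ValueError):
        resolve_event(dead, p, 5, np.random.default_rng(0))


def test_differentiated_cell_cannot_differentiate_again():
    p = simple_params({DIVIDE: 1.0})
    with pytest.raises(ValueError):
        resolve_event(_cell(DIFFERENTIATE, differentiated=True), p, 10, np.random.default_rng(0))


# -- single-clone simulation --------------------------------------------------


def test_remain_only_clone_is_constant():
    p = simple_params({REMAIN: 1.0})
    res = run_clone(p, 0, np.random.default_rng(0))
    assert (res.living == 1).all() and (res.gfp == 0).all() and (res.dead_cum == 0).all()


def test_hand_traced_divide_then_daughter_deaths():
    p = simple_params(
        {DIVIDE: 1.0},
        first_times={DIVIDE: 30},
        sub_neg={DIE: 1.0},
        sub_times={("gfp_neg", DIE): 10},
    )
    res = run_clone(p, 0, np.random.default_rng(0))
    assert (res.living[:30] == 1).all()
    assert (res.living[30:40] == 2).all()
    assert (res.living[40:] == 0).all()
    assert res.dead_cum[-1] == 2
    assert res.final_generations.size == 0


def test_hand_traced_differentiate_then_remain():
    p = simple_params({DIFFERENTIATE: 1.0}, first_times={DIFFERENTIATE: 20})
    res = run_clone(p, 0, np.random.default_rng(0))
    assert (res.gfp[:20] == 0).all() and (res.gfp[20:] == 1).all()
    assert (res.living == 1).all()


def test_events_beyond_horizon_never_fire():
    p = simple_params({DIVIDE: 1.0}, first_times={DIVIDE: 30}, horizon=20)
    res = run_clone(p, 0, np.random.default_rng(0))
    assert (res.living == 1).all() and len(res.events) == 0


def test_event_log_waits_are_regime_relative():
    p = simple_params(
        {DIVIDE: 1.0},
        first_times={DIVIDE: 30},
        sub_neg={DIVIDE: 1.0},
        sub_times={("gfp_neg", DIVIDE): 12},
        horizon=45,
    )
    res = run_clone(p, 0, np.random.default_rng(0))
    first = res.events[0]
    assert (first.hour, first.wait, first.is_first) == (30, 30, True)
    for ev in res.events[1:]:
        assert ev.wait == 12 and not ev.is_first


# -- populations --------------------------------------------------------------


def test_population_bitwise_determinism():
    p = simple_params(
        {DIVIDE: 0.7, REMAIN: 0.3},
        first_times={DIVIDE: 20},
        sub_neg={DIVIDE: 0.4, DIE: 0.3, REMAIN: 0.3},
        sub_times={("gfp_neg", DIVIDE): 10, ("gfp_neg", DIE): 5},
        n_founders=20,
    )
    a = run_population(p, 2, master_seed=99)
    b = run_population(p, 2, master_seed=99)
    for ta, tb in zip(a, b):
        assert np.array_equal(ta.living, tb.living)
        assert np.array_equal(ta.gfp, tb.gfp)
        assert np.array_equal(ta.dead_cum, tb.dead_cum)
    # distinct runs differ
    assert not np.array_equal(a[0].living, a[1].living)


def test_all_remain_population_is_static():
    p = simple_params({REMAIN: 1.0}, n_founders=133)
    trajs = run_population(p, 2, 0)
    for t in trajs:
        assert (t.living.sum(axis=0) == 133).all()


def test_branching_expectation_division_only():
    # founder divides at 10; each daughter divides w.p. 0.5 after exactly 10 h,
    # otherwise remains. Expected active lineages stay at 2, each round parks
    # one expected cell, so E[N(horizon)] = 2 + number of completed rounds.
    p = simple_params(
        {DIVIDE: 1.0},
        first_times={DIVIDE: 10},
        sub_neg={DIVIDE: 0.5, REMAIN: 0.5},
        sub_times={("gfp_neg", DIVIDE): 10},
        horizon=50,
        n_founders=2000,
    )
    traj = run_population(p, 1, 31)[0]
    expected = 2 + 4  # rounds at h = 20, 30, 40, 50
    mean_final = traj.living[:, -1].mean()
    assert mean_final == pytest.approx(expected, rel=0.05)


def test_population_counts_conserve_and_gfp_monotone(defaults):
    small = make_variant(defaults, "full")
    small.n_founders = 40
    t = run_population(small, 1, 4)[0]
    assert (t.gfp <= t.living).all()
    assert (np.diff(t.dead_cum, axis=1) >= 0).all()
    nd = make_variant(small, "no_death")
    t2 = run_population(nd, 1, 4)[0]
    assert (np.diff(t2.living.sum(axis=0)) >= 0).all()
    assert (np.diff(t2.gfp.sum(axis=0)) >= 0).all()


# -- variants -----------------------------------------------------------------


def test_variant_full_is_identity(defaults):
    v = make_variant(defaults, "full")
    assert v.to_dict() == defaults.to_dict()


def test_variant_no_death_renormalizes():
    p = simple_params(
        {DIVIDE: 1.0},
        sub_neg={DIVIDE: 0.5, DIE: 0.2, REMAIN: 0.3},
        sub_times={("gfp_neg", DIVIDE): 10, ("gfp_neg", DIE): 5},
    )
    v = make_variant(p, "no_death")
    assert v.subsequent_event_probs["gfp_neg"] == pytest.approx(
        {DIVIDE: 0.625, REMAIN: 0.375}
    )


def test_variant_fixed_first_uses_median(defaults):
    v = make_variant(defaults, "fixed_first")
    d = v.first_event_time_dists[DIVIDE]
    assert d.hours.size == 1
    assert d.hours[0] == defaults.first_event_time_dists[DIVIDE].median


def test_variant_synchronized_immortal_combines_all(defaults):
    v = make_variant(defaults, "synchronized_immortal")
    for state in ("gfp_neg", "gfp_pos"):
        assert DIE not in v.subsequent_event_probs[state]
        assert v.subsequent_event_time_dists[state][DIVIDE].hours.size == 1
    assert v.first_event_time_dists[DIVIDE].hours.size == 1


def test_unknown_variant_rejected(defaults):
    with pytest.raises(ValueError):
        make_variant(defaults, "bogus")


# -- serialisation ------------------------------------------------------------


@pytest.mark.parametrize("suffix", [".json", ".yaml"])
def test_params_roundtrip(tmp_path, defaults, suffix):
    path = tmp_path / f"params{suffix}"
    defaults.save(path)
    loaded = FateModelParams.load(path)
    assert loaded.to_dict() == defaults.to_dict()


def test_params_validation_rejects_missing_time_dist():
    with pytest.raises(ValueError):
        FateModelParams(
            first_event_probs={DIVIDE: 1.0},
            first_event_time_dists={},
            subsequent_event_probs={"gfp_neg": {REMAIN: 1.0}, "gfp_pos": {REMAIN: 1.0}},
            subsequent_event_time_dists={"gfp_neg": {}, "gfp_pos": {}},
        )
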
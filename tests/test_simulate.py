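"""Synthetic cohort generator: calibration, structure, and round-trips."""

import numpy as np
import pytest
from scipy import stats as sps

from flysleep.exceptions import InfeasibleSummaryError
from flysleep.powerlaw import fit_powerlaw
from flysleep.scoring import DAY, NIGHT, AnimalPeriodSummary, score_sleep, summarize_period
from flysleep.simulate import (
    PRESETS,
    REBOUND_PRESETS,
    CohortSpec,
    calibrate_count_distribution,
    make_cohort,
    make_rebound_scenario,
    preset,
    realize_trace,
)


def fit_cohort(pairs, **kwargs):
    eligible = [p for p in pairs if p.bout_count > 0]
    x = np.array([p.bout_count for p in eligible], dtype=float)
    y = np.array([p.mean_bout_length for p in eligible], dtype=float)
    return fit_powerlaw(x, y, **kwargs)


# --- count-distribution calibration ---------------------------------------


def test_calibrated_counts_match_target_moments():
    """Shifted negative binomial hits mean 4.9 / SD 4.2 within 5% at n=10k."""
    dist = calibrate_count_distribution(4.9, 4.2)
    assert dist.family == "shifted-negbinom"
    assert dist.mean == pytest.approx(4.9, rel=1e-9)
    assert dist.sd == pytest.approx(4.2, rel=1e-9)
    draws = dist.rvs(10_000, np.random.default_rng(0))
    assert draws.min() >= 1
    assert np.mean(draws) == pytest.approx(4.9, rel=0.05)
    assert np.std(draws, ddof=1) == pytest.approx(4.2, rel=0.05)


def test_degenerate_sd_is_point_mass():
    dist = calibrate_count_distribution(4.9, 0.0)
    assert dist.family == "point-mass"
    assert (dist.rvs(100, np.random.default_rng(0)) == 5).all()


def test_mean_one_tiny_sd_all_counts_one():
    dist = calibrate_count_distribution(1.0, 1e-9)
    assert (dist.rvs(50, np.random.default_rng(0)) == 1).all()


def test_underdispersed_falls_back_to_poisson(caplog):
    with caplog.at_level("WARNING"):
        dist = calibrate_count_distribution(10.0, 1.0)  # sd^2 < mean - 1
    assert dist.family == "shifted-poisson"
    assert "falling back" in caplog.text


# --- cohort generation ------------------------------------------------------


def test_cohort_size_and_invariants():
    pairs = make_cohort(PRESETS["control_night"])
    assert len(pairs) == 124  # 31 animals x 4 nights
    assert len({p.animal_id for p in pairs}) == 31
    for p in pairs:
        assert 0 <= p.total_sleep <= 720
        assert p.total_sleep == pytest.approx(p.bout_count * p.mean_bout_length)
        assert p.total_sleep >= 5 * p.bout_count
        assert p.total_sleep + (p.bout_count - 1) <= 720


def test_cohort_deterministic_given_seed():
    a = make_cohort(PRESETS["control_night"])
    b = make_cohort(PRESETS["control_night"])
    assert [(p.total_sleep, p.bout_count) for p in a] == [
        (p.total_sleep, p.bout_count) for p in b
    ]


def test_noiseless_regulated_cohort_is_exact_power_law():
    """Zero total-sleep SD: all points on y = T0/x, so b = -1, R² = 1."""
    spec = preset("control_night", mean_total_sleep=600.0, sd_total_sleep=0.0)
    fit = fit_cohort(make_cohort(spec))
    assert fit.a == pytest.approx(600.0, rel=1e-8)
    assert fit.b == pytest.approx(-1.0, abs=1e-9)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_control_night_mean_total_sleep_calibrated():
    """Sample mean within 3 standard errors of the printed 672.6 min."""
    pairs = make_cohort(PRESETS["control_night"])
    mean = np.mean([p.total_sleep for p in pairs])
    se = 29.9 / np.sqrt(124)
    assert abs(mean - 672.6) <= 3 * se


def test_regulated_fit_recovers_total_sleep_scale():
    """Tight regulation: b near -1 and a within 10% of mean total sleep."""
    spec = preset("control_night", sd_total_sleep=672.6 * 0.05)
    fit = fit_cohort(make_cohort(spec))
    assert -1.2 <= fit.b <= -0.8
    assert abs(fit.a - 672.6) <= 0.10 * 672.6


def test_unregulated_cohort_decouples_length_from_count():
    """Unregulated mode: mean bout length is independent of bout count."""
    pairs = make_cohort(PRESETS["fumin_night"])
    x = np.array([p.bout_count for p in pairs], dtype=float)
    y = np.array([np.log(p.mean_bout_length) for p in pairs], dtype=float)
    _, p_val = sps.pearsonr(x, y)
    assert p_val > 0.01  # no detectable association


def test_unregulated_median_r2_below_0_1():
    r2s = []
    for seed in range(25):
        fit = fit_cohort(make_cohort(preset("fumin_night", seed=seed, n_animals=31)))
        r2s.append(fit.r_squared)
    assert np.median(r2s) < 0.1


def test_r2_monotone_in_total_sleep_spread():
    """Mean R² never rises as the relative SD of total sleep grows."""
    rel_sds = [0.02, 0.05, 0.10, 0.20]
    mean_r2 = []
    for rel in rel_sds:
        vals = []
        for seed in range(50):
            spec = preset("control_night", seed=seed,
                          sd_total_sleep=672.6 * rel)
            vals.append(fit_cohort(make_cohort(spec)).r_squared)
        mean_r2.append(np.mean(vals))
    assert all(hi >= lo for hi, lo in zip(mean_r2, mean_r2[1:]))


def test_infeasible_spec_rejected():
    with pytest.raises(ValueError):
        CohortSpec("g", NIGHT, 5, 1, mean_total_sleep=800.0, sd_total_sleep=1.0,
                   count_mean=3.0, count_sd=1.0)


# --- trace realization ------------------------------------------------------


def test_realize_full_sleep_period_is_all_zero():
    s = AnimalPeriodSummary("a", 1, NIGHT, 720, 1, 720.0)
    trace = realize_trace(s, seed=0)
    assert (trace.counts == 0).all()
    assert trace.start_zt == 720


def test_realize_two_bout_arrangement_constraints():
    """total 12, count 2: two zero runs >= 5 summing to 12, separated."""
    from conftest import brute_force_sleep_runs

    s = AnimalPeriodSummary("a", 1, DAY, 12, 2, 6.0)
    for seed in range(30):
        trace = realize_trace(s, seed=seed)
        runs = brute_force_sleep_runs(trace.counts)
        assert len(runs) == 2
        lengths = sorted(length for _, length in runs)
        assert sum(lengths) == 12 and lengths[0] >= 5


@pytest.mark.parametrize("preset_name", ["control_day", "control_night", "fumin_night"])
def test_realize_round_trips_through_scoring(preset_name):
    """score_sleep(realize_trace(s)) reproduces every summary exactly."""
    spec = preset(preset_name, n_animals=8, n_periods=1)
    rng = np.random.default_rng(99)
    for s in make_cohort(spec):
        trace = realize_trace(s, activity_rate=spec.activity_rate, rng=rng)
        rescored = summarize_period(
            score_sleep(trace), s.animal_id, s.day_index, s.period)
        assert rescored.total_sleep == s.total_sleep
        assert rescored.bout_count == s.bout_count
        if s.bout_count:
            assert rescored.mean_bout_length == pytest.approx(s.mean_bout_length)


def test_realize_infeasible_rejected():
    with pytest.raises(InfeasibleSummaryError):
        realize_trace(AnimalPeriodSummary("a", 1, DAY, 9, 2, 4.5), seed=0)
    with pytest.raises(InfeasibleSummaryError):
        realize_trace(AnimalPeriodSummary("a", 1, DAY, 716, 6, 716 / 6), seed=0)


# --- deprivation / rebound --------------------------------------------------


def test_rebound_scenario_structure():
    scen = REBOUND_PRESETS["rebound_control"]
    pairs = make_rebound_scenario(scen)
    nights = {d: [p for p in pairs if p.period == NIGHT and p.day_index == d]
              for d in range(1, 5)}
    days = {d: [p for p in pairs if p.period == DAY and p.day_index == d]
            for d in range(1, 6)}
    assert all(len(nights[d]) == 7 for d in range(1, 5))
    assert all(len(days[d]) == 7 for d in range(1, 6))
    # deprivation night: near-zero sleep in every animal
    assert np.mean([p.total_sleep for p in nights[4]]) < 60
    # baseline nights remain long
    assert np.mean([p.total_sleep for p in nights[1]]) > 600


def test_rebound_day5_mean_calibrated():
    """Day-5 mean within 3 standard errors of the printed 496 min (n=7)."""
    pairs = make_rebound_scenario(REBOUND_PRESETS["rebound_control"])
    day5 = [p.total_sleep for p in pairs if p.period == DAY and p.day_index == 5]
    assert len(day5) == 7
    assert abs(np.mean(day5) - 496.0) <= 3 * 50.2 / np.sqrt(7)


def test_rebound_exceeds_baseline_day_across_seeds():
    from dataclasses import replace

    scen = REBOUND_PRESETS["rebound_control"]
    for seed in range(100):
        pairs = make_rebound_scenario(replace(scen, seed=seed))
        day5 = np.mean([p.total_sleep for p in pairs
                        if p.period == DAY and p.day_index == 5])
        baseline = np.mean([p.total_sleep for p in pairs
                            if p.period == DAY and p.day_index <= 4])
        assert day5 > baseline


def test_fully_deprived_night_degenerate():
    from dataclasses import replace

    scen = replace(REBOUND_PRESETS["rebound_control"],
                   deprivation_night_sleep_mean=0.0, deprivation_sd=0.0)
    pairs = make_rebound_scenario(scen)
    night4 = [p for p in pairs if p.period == NIGHT and p.day_index == 4]
    assert all(p.total_sleep == 0 and p.bout_count == 0 for p in night4)
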
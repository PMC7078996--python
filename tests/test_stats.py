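"""Rank statistics, composite decision rules and reporting conventions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import iontospike as isp
from iontospike.protocols import donor_plan, inhibitor_plan, nmda_protocol
from iontospike.stats import (RateSeries, association_test, dunn_pairwise,
                              epoch_composite_decision, extract_rate_series,
                              first_spike_latency, kruskal_wallis, ks_two_sample,
                              nmda_enhancement, percent_of_baseline,
                              percent_of_count, population_summary,
                              psth_difference)
from iontospike.synthetic import ConfigurationError


def _table(sweeps, times):
    return pd.DataFrame({"sweep": np.asarray(sweeps, dtype=np.int64),
                         "time_s": np.asarray(times, dtype=float)})


# ------------------------------------------------------------------ rates


def test_rate_series_arithmetic_and_window_exclusion():
    # one spike at 0.1 s in each of 10 sweeps -> 10 / (0.2 s x 10) = 5 Hz
    spikes = _table(np.arange(10), np.full(10, 0.1))
    rs = extract_rate_series(spikes, "driven", 10.0, 10)
    assert rs.rates == pytest.approx([5.0])
    # a spike at 0.25 s is in the post-tone exclusion zone: neither window
    sp2 = _table(np.arange(10), np.full(10, 0.25))
    assert extract_rate_series(sp2, "driven", 10.0, 10).rates.sum() == 0
    assert extract_rate_series(sp2, "spontaneous", 10.0, 10).rates.sum() == 0


def test_windows_are_disjoint_and_cover_no_spike_twice():
    rng = np.random.default_rng(0)
    spikes = _table(rng.integers(0, 100, 5000), rng.uniform(0, 1, 5000))
    dr = extract_rate_series(spikes, "driven", 10.0, 100)
    sp = extract_rate_series(spikes, "spontaneous", 10.0, 100)
    n_dr = dr.rates.sum() * 0.2 * 10
    n_sp = sp.rates.sum() * 0.7 * 10
    t = spikes["time_s"]
    assert n_dr == pytest.approx(((t >= 0) & (t < 0.2)).sum())
    assert n_sp == pytest.approx(((t >= 0.3) & (t < 1.0)).sum())
    assert n_dr + n_sp <= len(spikes)


def test_homogeneous_poisson_rates_agree_across_windows():
    rng = np.random.default_rng(1)
    counts = rng.poisson(50.0, 600)  # 50 Hz over each full 1-s sweep
    sw = np.repeat(np.arange(600), counts)
    spikes = _table(sw, rng.uniform(0, 1, counts.sum()))
    dr = extract_rate_series(spikes, "driven", 10.0, 600)
    sp = extract_rate_series(spikes, "spontaneous", 10.0, 600)
    assert dr.rates.mean() == pytest.approx(50.0, abs=1.5)
    assert sp.rates.mean() == pytest.approx(50.0, abs=1.0)


# ------------------------------------------------------------------ rank tests


def test_kruskal_wallis_hand_computed_h():
    groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
    kw = kruskal_wallis(groups)
    assert kw.h == pytest.approx(7.2)  # mean ranks 2, 5, 8 of 1..9
    h_sp, p_sp = sps.kruskal(*groups)
    assert kw.h == pytest.approx(h_sp) and kw.p == pytest.approx(p_sp)


def test_kruskal_wallis_matches_scipy_with_ties():
    rng = np.random.default_rng(2)
    for _ in range(20):
        sizes = rng.integers(2, 8, size=rng.integers(2, 5))
        groups = [np.round(rng.normal(size=s), 1) for s in sizes]
        kw = kruskal_wallis(groups)
        h_sp, p_sp = sps.kruskal(*groups)
        assert kw.h == pytest.approx(h_sp, abs=1e-10)
        assert kw.p == pytest.approx(p_sp, abs=1e-12)


def test_two_group_h_equals_squared_tie_corrected_rank_z():
    rng = np.random.default_rng(3)
    for _ in range(10):
        a = np.round(rng.normal(size=6), 1)
        b = np.round(rng.normal(0.4, 1.0, size=8), 1)
        kw = kruskal_wallis([a, b])
        # tie-corrected normal-approximation z of the rank-sum test
        n1, n2 = len(a), len(b)
        n = n1 + n2
        ranks = sps.rankdata(np.concatenate([a, b]))
        r1 = ranks[:n1].sum()
        _, c = np.unique(np.concatenate([a, b]), return_counts=True)
        tie = (c.astype(float) ** 3 - c).sum()
        var = n1 * n2 / 12.0 * (n + 1 - tie / (n * (n - 1.0)))
        z = (r1 - n1 * (n + 1) / 2.0) / np.sqrt(var)
        assert kw.h == pytest.approx(z ** 2, rel=1e-9)


def test_kruskal_wallis_identical_values_gives_h_zero_p_one():
    kw = kruskal_wallis([[2.0, 2.0], [2.0, 2.0, 2.0]])
    assert kw.h == 0.0 and kw.p == 1.0


def test_dunn_identical_groups_and_hand_oracle():
    pairs = dunn_pairwise([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
    assert pairs[0].z == pytest.approx(0.0) and pairs[0].p == pytest.approx(1.0)
    # {1,2,3} vs {7,8,9} inside a 3-group layout of 1..9:
    # z = (8 - 2) / sqrt((9*10/12) * (2/3)) = 2.683
    res = dunn_pairwise([[1, 2, 3], [4, 5, 6], [7, 8, 9]], pairs=[(0, 2)])[0]
    assert res.z == pytest.approx(6.0 / np.sqrt(7.5 * 2 / 3.0), rel=1e-12)
    assert res.direction == 1


def test_dunn_adjusted_p_monotone_and_empty_group_rejected():
    rng = np.random.default_rng(4)
    groups = [rng.normal(size=5) for _ in range(4)]
    for pair in dunn_pairwise(groups):
        assert pair.p_adj >= pair.p
    with pytest.raises(ConfigurationError):
        dunn_pairwise([[1.0], []])


def test_exact_permutation_agrees_with_shuffle_oracle_small():
    rng = np.random.default_rng(5)
    for _ in range(3):
        sizes = [4, 4, 4]
        x = np.round(rng.normal(size=12), 1)
        groups = np.split(x, np.cumsum(sizes)[:-1])
        kw = kruskal_wallis(groups, method="exact")
        ns = 30000
        ranks = sps.rankdata(x)
        idx = np.argsort(rng.random((ns, 12)), axis=1)
        permr = ranks[idx]
        num = sum(permr[:, 4 * i: 4 * i + 4].sum(axis=1) ** 2 / 4.0 for i in range(3))
        _, c = np.unique(x, return_counts=True)
        tie = 1 - (c.astype(float) ** 3 - c).sum() / (12 ** 3 - 12)
        h_all = (12.0 / (12 * 13) * num - 3 * 13) / tie
        p_mc = float(np.mean(h_all >= kw.h - 1e-9))
        assert abs(kw.p - p_mc) < 4 * np.sqrt(max(p_mc * (1 - p_mc), 1e-5) / ns)


# ------------------------------------------------------------------ decisions


def _series_from_epoch_values(plan, values, filler=10.0):
    n_bins = int(round(plan.recording_duration_s / plan.bin_width_s))
    rates = np.full(n_bins, filler)
    t_start = np.arange(n_bins) * plan.bin_width_s
    for label, vals in values.items():
        t0, _ = plan.epochs[label]
        i0 = int(round(t0 / plan.bin_width_s))
        rates[i0:i0 + len(vals)] = vals
    return RateSeries(window="driven", bin_width_s=plan.bin_width_s,
                      rates=rates, t_start=t_start)


def _noisy(center, n, rng, sd=1.0):
    return center + rng.normal(0.0, sd, n)


def test_donor_rule_requires_recovery():
    plan = donor_plan()
    rng = np.random.default_rng(6)
    lo = {lab: _noisy(100.0, 12, rng) for lab in ("B", "R1", "R2")}
    hi = {lab: _noisy(160.0, 12, rng) for lab in ("E40", "E80", "E120")}
    # effect persists through R3: third criterion fails by construction
    no_rec = _series_from_epoch_values(plan, {**lo, **hi,
                                              "R3": _noisy(160.0, 12, rng)})
    assert not isp.donor_decision(no_rec, plan).flagged
    # with recovery the same contrast is flagged as an increase
    rec = _series_from_epoch_values(plan, {**lo, **hi, "R3": _noisy(100.0, 12, rng)})
    d = isp.donor_decision(rec, plan)
    assert d.flagged and d.direction == "increase"


def test_donor_rule_missing_epoch_rejected():
    plan = donor_plan()
    series = RateSeries(window="driven", bin_width_s=10.0,
                        rates=np.zeros(100), t_start=np.arange(100) * 10.0)
    with pytest.raises(ConfigurationError):
        isp.donor_decision(series, plan)
    with pytest.raises(ConfigurationError):
        isp.inhibitor_decision(_series_from_epoch_values(donor_plan(), {}),
                               inhibitor_plan())


def test_inhibitor_rule_requires_return_towards_baseline():
    plan = inhibitor_plan()
    rng = np.random.default_rng(7)
    vals = {"B": _noisy(50.0, 10, rng), "E": _noisy(85.0, 10, rng),
            "R": _noisy(85.0, 10, rng)}  # E differs from B but R stays high
    assert not isp.inhibitor_decision(_series_from_epoch_values(plan, vals),
                                      plan).flagged
    vals["R"] = _noisy(50.0, 10, rng)
    d = isp.inhibitor_decision(_series_from_epoch_values(plan, vals), plan)
    assert d.flagged and d.direction == "increase"


def test_composite_decision_direction_decrease():
    plan = inhibitor_plan()
    rng = np.random.default_rng(8)
    vals = {"B": _noisy(80.0, 10, rng), "E": _noisy(40.0, 10, rng),
            "R": _noisy(80.0, 10, rng)}
    d = isp.inhibitor_decision(_series_from_epoch_values(plan, vals), plan)
    assert d.flagged and d.direction == "decrease"


# ------------------------------------------------------------------ NMDA


def _nmda_series(period_rates, baseline_rate=1.0):
    """Build a 10-s-bin series with given burst-bin rates per period."""
    proto = nmda_protocol()
    rates = np.zeros(360)
    t_start = np.arange(360) * 10.0
    for lab, starts in proto.app_starts.items():
        b0 = int((starts[0] - 180.0) / 10)
        rates[b0:b0 + 18] = baseline_rate
        vals = period_rates[lab]
        for i, s in enumerate(starts[-3:]):
            i0 = int(s / 10)
            rates[i0:i0 + 6] = vals[6 * i: 6 * i + 6]
    return RateSeries(window="spontaneous", bin_width_s=10.0,
                      rates=rates, t_start=t_start)


def test_nmda_identical_periods_not_significant():
    vals = np.array([3.0, 3.1, 3.2, 3.3, 3.4, 3.5] * 3)
    series = _nmda_series({"B": vals, "E": vals, "R": vals})
    enh = nmda_enhancement(series)
    assert not enh.decision.flagged
    # identical responses every application -> identical percents per period
    ref = sorted(enh.periods["B"]["percent"])
    for lab in ("E", "R"):
        assert np.allclose(sorted(enh.periods[lab]["percent"]), ref)
    assert ref == [340.0, 340.0, 340.0, 350.0, 350.0, 350.0]  # top 6 of 18


def test_nmda_enhanced_period_flagged_with_rank_oracle_values():
    # E percents {300..350} vs B and R percents {195..220}: KW significant
    # and the (B, E) Dunn comparison significant
    lo = np.array([1.95, 2.0, 2.05, 2.1, 2.15, 2.2])
    hi = np.array([3.0, 3.1, 3.2, 3.3, 3.4, 3.5])
    pad_lo = np.concatenate([np.full(12, 0.5), lo])
    pad_hi = np.concatenate([np.full(12, 0.5), hi])
    series = _nmda_series({"B": pad_lo, "E": pad_hi, "R": pad_lo})
    enh = nmda_enhancement(series)
    assert enh.decision.kw.p < 0.05
    pair_be = [p for p in enh.decision.pairs if p.a == "B" and p.b == "E"][0]
    assert pair_be.p_adj < 0.05 and pair_be.direction == 1
    assert enh.decision.flagged and enh.decision.direction == "increase"
    assert np.allclose(sorted(enh.periods["E"]["percent"]),
                       [300, 310, 320, 330, 340, 350])


def test_nmda_zero_baseline_switches_to_absolute_differences():
    vals = np.array([3.0, 3.1, 3.2, 3.3, 3.4, 3.5] * 3)
    series = _nmda_series({"B": vals, "E": vals, "R": vals}, baseline_rate=0.0)
    enh = nmda_enhancement(series)
    assert enh.percent_mode == "absolute"
    assert any("zero baseline" in n for n in enh.decision.notes)


def test_nmda_log_percent_mode_for_spontaneous_window():
    vals = np.array([3.0, 3.1, 3.2, 3.3, 3.4, 3.5] * 3)
    series = _nmda_series({"B": vals, "E": vals * 1.5, "R": vals})
    enh = nmda_enhancement(series, log_percent=True)
    assert enh.percent_mode == "log_percent"


def test_nmda_power_exceeds_null_rate(chopper_unit):
    null = power = 0
    n_runs = 40
    for seed in range(n_runs):
        s0 = isp.generate_session(chopper_unit, isp.nmda_schedules(),
                                  [isp.nmda_effects()[0]], n_sweeps=3600,
                                  seed=7000 + seed)
        r0 = extract_rate_series(s0.spikes, "spontaneous", 10.0, 3600)
        null += int(nmda_enhancement(r0).decision.flagged)
        s1 = isp.generate_session(chopper_unit, isp.nmda_schedules(),
                                  isp.nmda_effects(), n_sweeps=3600,
                                  seed=8000 + seed)
        r1 = extract_rate_series(s1.spikes, "spontaneous", 10.0, 3600)
        power += int(nmda_enhancement(r1).decision.flagged)
    assert null <= 4
    assert power >= n_runs // 2
    assert power > 4 * null or null == 0


# ------------------------------------------------------------------ latency, PSTH


def test_first_spike_latency_constant_and_empty():
    spikes = _table(np.arange(600), np.full(600, 0.008))
    fsl = first_spike_latency(spikes, 600)
    assert np.allclose(fsl["mean_latency_s"], 0.008)
    assert len(first_spike_latency(_table([], []), 600)) == 0


def test_first_spike_latency_drops_when_driven_gain_rises(chopper_unit):
    session = isp.generate_session(chopper_unit, [isp.donor_schedule()],
                                   [isp.donor_effect({40.0: 1.5, 80.0: 1.8,
                                                      120.0: 2.0})],
                                   n_sweeps=3600, seed=31)
    fsl = first_spike_latency(session.spikes, 3600)
    lat = fsl.set_index("t_start_s")["mean_latency_s"]
    assert lat[2700.0] < lat[0.0]  # E120 block vs initial baseline


def test_psth_difference_identical_ranges_zero():
    sw = np.concatenate([np.arange(300, 900), np.arange(1500, 2100)])
    t = np.full(1200, 0.05)
    res = psth_difference(_table(sw, t))
    assert np.allclose(res.diff, 0.0) and res.ks_d == 0.0


def test_psth_difference_detects_uniform_rate_increase(chopper_unit):
    session = isp.generate_session(
        chopper_unit, [isp.donor_schedule()],
        [isp.donor_effect({40.0: 1.4, 80.0: 1.4, 120.0: 1.4})],
        n_sweeps=2100, seed=32)
    res = psth_difference(session.spikes)  # 301-900 baseline vs 1501-2100 drug
    # mean probability difference positive through the tone
    assert res.diff.sum() > 0
    coarse = res.diff.reshape(50, -1).sum(axis=1)  # 4-ms lumps
    assert (coarse > 0).mean() > 0.9


def test_psth_difference_shift_detected_by_ks():
    rng = np.random.default_rng(9)
    # exponentially decaying spike-time density (PSTH-like); a +5 ms shift
    # then moves a detectable mass fraction of the distribution
    t0 = np.clip(rng.exponential(0.03, 600), 0.0, 0.19)
    t1 = np.clip(t0 + 0.005, 0.0, 0.1999)
    sw = np.concatenate([rng.integers(300, 900, 600),
                         rng.integers(1500, 2100, 600)])
    res = psth_difference(_table(sw, np.concatenate([t0, t1])))
    assert res.ks_p < 0.01


def test_psth_difference_rejects_overlap_and_empty():
    with pytest.raises(ConfigurationError):
        psth_difference(_table([500], [0.1]), (301, 900), (800, 1200))
    with pytest.raises(ConfigurationError):
        psth_difference(_table([500], [0.1]), (301, 900), (1501, 2100))


# ------------------------------------------------------------------ K-S, association


def test_ks_trivial_cases_and_brute_force_oracle():
    assert ks_two_sample([1, 2, 3], [1, 2, 3])[0] == 0.0
    assert ks_two_sample([1, 2, 3], [4, 5, 6])[0] == 1.0
    rng = np.random.default_rng(10)
    for _ in range(10):
        x = rng.normal(size=rng.integers(5, 60))
        y = rng.normal(0.3, 1.2, rng.integers(5, 60))
        d, p = ks_two_sample(x, y)
        grid = np.concatenate([x, y])
        d_brute = max(abs((x <= g).mean() - (y <= g).mean()) for g in grid)
        assert d == pytest.approx(d_brute, abs=1e-12)
        assert 0.0 <= d <= 1.0 and 0.0 <= p <= 1.0


def test_association_identical_rows_p_one():
    p, method = association_test([[5, 5], [5, 5]])
    assert method == "exact" and p == pytest.approx(1.0)


def test_association_2x2_matches_hypergeometric():
    table = [[8, 2], [1, 5]]
    p, method = association_test(table)
    assert method == "exact"
    assert p == pytest.approx(sps.fisher_exact(table)[1], rel=1e-9)


def test_association_enumeration_agrees_with_monte_carlo():
    table = [[6, 3], [2, 7], [5, 5]]
    p_exact, m1 = association_test(table)
    p_mc, m2 = association_test(table, exact_max_total=5, n_mc=100000, seed=3)
    assert m1 == "exact" and m2 == "monte-carlo"
    se = np.sqrt(p_exact * (1 - p_exact) / 100000)
    assert abs(p_exact - p_mc) < 3 * se + 2e-5
    with pytest.raises(ConfigurationError):
        association_test([[1, -1], [0, 2]])


# ------------------------------------------------------------------ summaries


def test_percent_reporting_conventions():
    assert percent_of_count(4, 22) == 18
    assert percent_of_baseline(10.5, 5.5) == pytest.approx(52.380952, rel=1e-6)
    assert percent_of_baseline(211.0, 291.0) == pytest.approx(137.9, abs=0.05)
    with pytest.raises(ConfigurationError):
        percent_of_baseline(0.0, 5.0)


def test_population_summary_mean_of_ratios_and_zero_baseline_handling():
    def dec(flagged, direction):
        return isp.DecisionResult(flagged=flagged, direction=direction,
                                  protocol="inhibitor", kw=None)

    outcomes = [
        {"unit": "a", "decision": dec(True, "increase"),
         "baseline_rate": 100.0, "effect_rate": 150.0},
        {"unit": "b", "decision": dec(True, "increase"),
         "baseline_rate": 100.0, "effect_rate": 130.0},
        {"unit": "c", "decision": dec(True, "increase"),
         "baseline_rate": 0.0, "effect_rate": 10.0},
        {"unit": "d", "decision": dec(False, "none")},
    ]
    rep = population_summary(outcomes)
    inc = rep["directions"]["increase"]
    assert inc["n_flagged"] == 3 and inc["n_zero_baseline"] == 1
    assert inc["percent_of_baseline_mean"] == pytest.approx(140.0)
    assert inc["percent_of_baseline_sd"] == pytest.approx(np.sqrt(200.0), rel=1e-9)
    assert rep["pct_flagged"] == 75
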
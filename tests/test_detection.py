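"""Spike detection and waveform-metric tests against synthetic ground truth."""

import numpy as np
import pandas as pd
import pytest

import iontospike as isp
from iontospike.detection import (DetectionConfig, compute_shape_series,
                                  default_threshold, detect_spikes, shape_metrics,
                                  sweep_mean_waveform)
from iontospike.synthetic import ConfigurationError, RawTrace, biphasic_template

from conftest import match_events

FS = 25000.0


def test_default_threshold_matches_gaussian_analytic_span():
    rng = np.random.default_rng(0)
    sigma = 2.0
    thr = default_threshold(rng.normal(0.0, sigma, int(5 * FS)))
    # 2 x (2 x 3.29 sigma): the central 99.9% Gaussian span, doubled
    assert thr == pytest.approx(13.16 * sigma, rel=0.05)


def test_default_threshold_rejects_flat_segment():
    with pytest.raises(ConfigurationError):
        default_threshold(np.ones(1000))
    with pytest.raises(ConfigurationError):
        default_threshold(np.array([1.0]))


def test_auto_threshold_noise_crossings_below_five_percent_of_sweeps():
    rng = np.random.default_rng(1)
    noise = rng.normal(0.0, 1.0, int(60 * FS))
    thr = default_threshold(noise[: int(FS)])
    events = detect_spikes(RawTrace(noise, FS), DetectionConfig(threshold=thr))
    assert len(events) < 0.05 * 60  # false events in fewer than 5% of sweeps


def test_zero_noise_detection_is_exact(chopper_unit):
    session = isp.generate_session(chopper_unit, seed=11, n_sweeps=20)
    tpl = biphasic_template(FS, ptp_amplitude=1.0)
    trace = isp.synthesize_trace(session, tpl, noise_sd=0.0)
    events = detect_spikes(trace, DetectionConfig(threshold=0.5 * np.abs(tpl).max()))
    hit, fp = match_events(events, session.spikes, tol_s=1.5 / FS + 0.0005)
    assert len(events) == len(session.spikes)
    assert fp == 0


def test_threshold_above_template_amplitude_detects_nothing(chopper_unit):
    session = isp.generate_session(chopper_unit, seed=12, n_sweeps=5)
    tpl = biphasic_template(FS, ptp_amplitude=1.0)
    trace = isp.synthesize_trace(session, tpl, noise_sd=0.0)
    events = detect_spikes(trace, DetectionConfig(threshold=2.0))
    assert len(events) == 0


def _insert_templates(times_s, tpl, dur_s, amplitudes=None):
    x = np.zeros(int(dur_s * FS))
    for i, t in enumerate(times_s):
        a = 1.0 if amplitudes is None else amplitudes[i]
        i0 = int(round(t * FS))
        x[i0:i0 + len(tpl)] += a * tpl
    return x


def test_mean_waveform_single_spike_and_two_amplitude_average():
    tpl = biphasic_template(FS, ptp_amplitude=1.0)
    cfg = DetectionConfig(threshold=0.3, window_pre_ms=0.4, window_post_ms=1.2)
    x = _insert_templates([0.2, 0.6], tpl, 1.0, amplitudes=[1.0, 3.0])
    trace = RawTrace(x, FS)
    ev = detect_spikes(trace, cfg)
    assert len(ev) == 2
    mw = sweep_mean_waveform(trace, ev, 0, cfg)
    amp, _ = shape_metrics(mw, FS)
    # non-overlapping aligned templates: peak-to-peak of the mean = (a + b)/2
    assert amp == pytest.approx((1.0 + 3.0) / 2.0, rel=0.02)
    assert sweep_mean_waveform(trace, ev, 3, cfg) is None  # no events -> missing


def test_mean_waveform_converges_to_template_with_n():
    tpl = biphasic_template(FS, ptp_amplitude=1.0)
    cfg = DetectionConfig(threshold=0.3, window_pre_ms=0.4, window_post_ms=1.2)
    rng = np.random.default_rng(3)
    trough = np.argmin(tpl) / FS  # alignment point of the template
    errs = []
    for n in (5, 80):
        times = 0.01 + np.arange(n) * 0.01
        x = _insert_templates(times, tpl, n * 0.01 + 0.1)
        x += rng.normal(0.0, 0.1, len(x))
        trace = RawTrace(x, FS, sweep_s=n * 0.01 + 0.1)
        # truth-aligned events: isolates the 1/sqrt(n) averaging property
        # from detection alignment jitter
        ev = pd.DataFrame({"sweep": np.zeros(n, dtype=int),
                           "time_s": times + trough})
        mw = sweep_mean_waveform(trace, ev, 0, cfg)
        i = np.argmin(mw)
        j = np.argmin(tpl)
        k = min(j, i, len(tpl) - max(j, i) - 1)
        errs.append(np.abs(mw[i - k:i + k] - tpl[j - k:j + k]).std())
    assert errs[1] < errs[0] / 2  # error shrinks like 1/sqrt(n)


def test_shape_metrics_triangle_and_gaussian_widths():
    # triangular lobe of height h over base 2w -> half-amplitude width = w
    w_samp = 40
    tri = np.concatenate([np.zeros(20), np.linspace(0, 1, w_samp + 1),
                          np.linspace(1, 0, w_samp + 1)[1:], np.zeros(20)])
    amp, width = shape_metrics(tri, FS)
    assert amp == pytest.approx(1.0)
    assert width == pytest.approx(w_samp / FS * 1000.0, rel=0.03)
    # Gaussian lobe of SD s -> FWHM = 2 s sqrt(2 ln 2)
    s = 8.0
    t = np.arange(200.0)
    g = -np.exp(-0.5 * ((t - 100) / s) ** 2)
    _, width_g = shape_metrics(g, FS)
    assert width_g == pytest.approx(2 * s * np.sqrt(2 * np.log(2)) / FS * 1000.0,
                                    rel=0.02)


def test_shape_metrics_scale_shift_and_offset_invariance():
    tpl = biphasic_template(FS, ptp_amplitude=2.0)
    pad = np.concatenate([np.zeros(12), tpl, np.zeros(12)])
    amp, width = shape_metrics(pad, FS)
    amp2, width2 = shape_metrics(1.5 * pad, FS)
    assert amp2 == pytest.approx(1.5 * amp)  # amplitude linear in scaling
    assert width2 == pytest.approx(width)  # width scale-invariant
    amp3, width3 = shape_metrics(pad + 7.3, FS)  # DC offset
    assert amp3 == pytest.approx(amp)
    assert width3 == pytest.approx(width)
    amp4, width4 = shape_metrics(np.concatenate([np.zeros(6), pad]), FS)
    assert width4 == pytest.approx(width, rel=0.02)  # time shift


def test_monotone_waveform_width_undefined():
    _, width = shape_metrics(np.linspace(0.0, 1.0, 50), FS)
    assert np.isnan(width)


def test_shape_change_detects_width_drift_not_amplitude(chopper_unit):
    session = isp.generate_session(
        chopper_unit, [isp.donor_schedule()],
        [isp.donor_effect(shape_effect=(1.0, 1.2))], n_sweeps=3600, seed=21)
    series = isp.simulate_shape_series(session, seed=22)
    res = isp.shape_change_test(series, isp.donor_plan())
    assert res["width_ms"].flagged and res["width_ms"].direction == "increase"
    assert not res["amplitude"].flagged  # amplitude held constant
    # measured width rises ~20% during the final ejection block
    spb = 10
    bins = series["sweep"].to_numpy() // spb
    wid = series["width_ms"].to_numpy()
    w_b = np.nanmean(wid[(bins >= 48) & (bins < 60)])
    w_e = np.nanmean(wid[(bins >= 288) & (bins < 300)])
    assert w_e / w_b == pytest.approx(1.2, abs=0.04)


def test_shape_change_null_rate_low(chopper_unit):
    flagged = 0
    for seed in range(40):
        session = isp.generate_session(chopper_unit, [isp.donor_schedule()], [],
                                       n_sweeps=3600, seed=500 + seed)
        series = isp.simulate_shape_series(session, seed=900 + seed)
        res = isp.shape_change_test(series, isp.donor_plan())
        flagged += int(res["width_ms"].flagged or res["amplitude"].flagged)
    assert flagged <= 2  # < 5% of null sessions


def test_shape_change_underpowered_epochs_flagged_as_such():
    series = pd.DataFrame({"sweep": np.arange(3600),
                           "amplitude": np.full(3600, np.nan),
                           "width_ms": np.full(3600, np.nan),
                           "n_spikes": np.zeros(3600, dtype=int)})
    series.loc[:10, ["amplitude", "width_ms"]] = 1.0
    res = isp.shape_change_test(series, isp.donor_plan())
    assert not res["width_ms"].flagged
    assert any("underpowered" in n for n in res["width_ms"].notes)


def test_shape_effect_width_drift_visible_in_trace(chopper_unit):
    # end-to-end: trace synthesis -> detection -> per-sweep metrics
    session = isp.generate_session(
        chopper_unit, [isp.EjectionSchedule(channel="SIN-1",
                                            blocks=((80.0, 10.0, 40.0),),
                                            recording_duration_s=60.0)],
        [isp.donor_effect(levels={80.0: 1.0}, tau_s=5.0,
                          shape_effect=(1.0, 1.25))],
        n_sweeps=60, seed=23)
    tpl = biphasic_template(FS, ptp_amplitude=1.0)
    trace = isp.synthesize_trace(session, tpl, noise_sd=0.01, seed=24)
    cfg = DetectionConfig(threshold=0.3, window_pre_ms=0.4, window_post_ms=1.2)
    events = detect_spikes(trace, cfg)
    series = compute_shape_series(trace, events, cfg)
    w_base = series.loc[series["sweep"] < 8, "width_ms"].mean()
    w_drug = series.loc[(series["sweep"] >= 35) & (series["sweep"] < 40),
                        "width_ms"].mean()
    assert w_drug / w_base == pytest.approx(1.25, abs=0.08)
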
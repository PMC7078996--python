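"""Rate-series extraction, rank statistics and the drug-response decision rules.

The statistical machinery mirrors the analysis conventions of iontophoresis
experiments on tone-driven cochlear-nucleus units:

* firing rates are computed per analysis window — *driven* (the 200 ms tone)
  or *spontaneous* (the final 700 ms of each 1-s sweep; the 100 ms after
  tone offset is excluded to allow post-stimulus recovery) — in 10-s or
  60-s bins;
* labelled analysis epochs are compared with a tie-corrected Kruskal-Wallis
  test followed by Dunn's multiple-comparison test (Bonferroni adjustment
  over the explicitly tested pairs);
* a unit is deemed drug-responsive only by a composite rule: concordant
  significant changes between recovery and ejection epochs *and* a
  significant return towards baseline after the final ejection.

The H statistic, tie correction, Dunn z, exact small-sample permutation
distributions and the composite rules are implemented here; only midranks
and tail probabilities come from scipy.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .protocols import EpochPlan, NmdaProtocol
from .synthetic import ConfigurationError, SweepStructure

__all__ = [
    "RateSeries",
    "KWResult",
    "DunnPair",
    "DecisionResult",
    "NmdaEnhancement",
    "PsthDifference",
    "extract_rate_series",
    "kruskal_wallis",
    "dunn_pairwise",
    "donor_decision",
    "inhibitor_decision",
    "epoch_composite_decision",
    "nmda_enhancement",
    "first_spike_latency",
    "psth_difference",
    "ks_two_sample",
    "association_test",
    "percent_of_count",
    "percent_of_baseline",
    "population_summary",
]

#: Dead time between tone offset and the spontaneous analysis window.
POST_TONE_EXCLUSION_S = 0.1


# --------------------------------------------------------------------------
# rate series
# --------------------------------------------------------------------------


@dataclass
class RateSeries:
    """Per-bin firing rates for one analysis window."""

    window: str  # 'driven' or 'spontaneous'
    bin_width_s: float
    rates: np.ndarray
    t_start: np.ndarray  # start time (s) of each bin in the recording

    def epoch_values(self, t0: float, t1: float) -> np.ndarray:
        m = (self.t_start >= t0 - 1e-9) & (self.t_start < t1 - 1e-9)
        return self.rates[m]


def analysis_window(window: str, sweep: SweepStructure = SweepStructure()):
    """(start, end) of an analysis window within the sweep, in seconds."""
    if window == "driven":
        return sweep.tone_on_s, sweep.tone_off_s
    if window == "spontaneous":
        return sweep.tone_off_s + POST_TONE_EXCLUSION_S, sweep.sweep_s
    raise ConfigurationError(f"unknown analysis window {window!r}")


def extract_rate_series(spikes: pd.DataFrame, window: str, bin_width_s: float,
                        n_sweeps: int, sweep: SweepStructure = SweepStructure()
                        ) -> RateSeries:
    """Firing rate of one analysis window in consecutive time bins.

    Each bin covers ``bin_width_s / sweep_s`` whole sweeps; its rate is the
    spike count inside the analysis window across those sweeps divided by
    (window duration x sweeps per bin).  Spikes between tone offset and the
    start of the spontaneous window contribute to neither series.
    """
    spb = bin_width_s / sweep.sweep_s
    if abs(spb - round(spb)) > 1e-9 or spb < 1:
        raise ConfigurationError("bin width must be a whole number of sweeps")
    spb = int(round(spb))
    w0, w1 = analysis_window(window, sweep)
    n_bins = n_sweeps // spb
    sw = spikes["sweep"].to_numpy()
    t = spikes["time_s"].to_numpy()
    sel = (t >= w0) & (t < w1) & (sw < n_bins * spb)
    counts = np.bincount(sw[sel] // spb, minlength=n_bins)[:n_bins]
    rates = counts / ((w1 - w0) * spb)
    t_start = np.arange(n_bins) * bin_width_s
    return RateSeries(window=window, bin_width_s=bin_width_s,
                      rates=rates, t_start=t_start)


# --------------------------------------------------------------------------
# rank statistics
# --------------------------------------------------------------------------


@dataclass
class KWResult:
    h: float
    df: int
    p: float
    group_sizes: tuple
    tie_correction: float
    method: str = "asymptotic"


@dataclass
class DunnPair:
    a: object
    b: object
    z: float
    p: float
    p_adj: float
    direction: int  # sign of mean-rank(b) - mean-rank(a)
    n_a: int
    n_b: int


def _pooled_ranks(groups):
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ConfigurationError("need >= 2 groups, each with >= 1 value")
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)  # midranks
    sizes = np.array([len(g) for g in groups])
    return groups, pooled, ranks, sizes


def _tie_term(pooled):
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _h_from_rank_sums(rank_sums, sizes, n, tie_corr):
    h = 12.0 / (n * (n + 1.0)) * np.sum(rank_sums ** 2 / sizes, axis=-1) - 3.0 * (n + 1.0)
    return h / tie_corr


def _enumerate_rank_sums(ranks, sizes):
    """Group rank sums for every distinct assignment of ranks to groups.

    Brute-force permutation support for small samples: the returned array
    has one row per assignment and one column per group.  The last group is
    implied by the total; the second-to-last level is vectorised.
    """
    ranks = np.asarray(ranks, dtype=float)
    sizes = list(sizes)
    total = ranks.sum()
    k = len(sizes)
    if k == 2:
        combs = np.fromiter(itertools.chain.from_iterable(
            itertools.combinations(range(len(ranks)), sizes[0])),
            dtype=np.intp).reshape(-1, sizes[0])
        s0 = ranks[combs].sum(axis=1)
        return np.column_stack([s0, total - s0])
    rows = []

    def rec(avail, si, acc):
        if si == k - 2:
            sub = ranks[avail]
            combs = np.fromiter(itertools.chain.from_iterable(
                itertools.combinations(range(len(avail)), sizes[si])),
                dtype=np.intp).reshape(-1, sizes[si])
            s_i = sub[combs].sum(axis=1)
            s_last = sub.sum() - s_i
            head = np.tile(acc, (len(s_i), 1)) if acc else np.empty((len(s_i), 0))
            rows.append(np.column_stack([head, s_i, s_last]))
            return
        for comb in itertools.combinations(range(len(avail)), sizes[si]):
            idx = np.fromiter(comb, dtype=np.intp)
            rec(np.delete(avail, idx), si + 1, acc + [ranks[avail[idx]].sum()])

    rec(np.arange(len(ranks)), 0, [])
    return np.concatenate(rows, axis=0)


_EXACT_MAX_N = 16


def kruskal_wallis(groups, method: str = "asymptotic") -> KWResult:
    """Tie-corrected Kruskal-Wallis H test.

    ``method='asymptotic'`` uses the chi-square approximation with k-1
    degrees of freedom; ``method='exact'`` computes the permutation p-value
    by full enumeration of group assignments (only feasible for pooled
    samples of up to 16 values).
    """
    groups, pooled, ranks, sizes = _pooled_ranks(groups)
    n = len(pooled)
    df = len(groups) - 1
    tie = _tie_term(pooled)
    tie_corr = 1.0 - tie / (n ** 3 - n)
    if tie_corr <= 0:  # all values identical
        return KWResult(h=0.0, df=df, p=1.0, group_sizes=tuple(sizes),
                        tie_correction=0.0, method=method)
    bounds = np.cumsum(sizes)[:-1]
    rank_sums = np.array([s.sum() for s in np.split(ranks, bounds)])
    h = float(_h_from_rank_sums(rank_sums, sizes, n, tie_corr))
    if method == "asymptotic":
        p = float(sps.chi2.sf(h, df))
    elif method == "exact":
        if n > _EXACT_MAX_N:
            raise ConfigurationError(f"exact method limited to N <= {_EXACT_MAX_N}")
        all_sums = _enumerate_rank_sums(ranks, sizes)
        h_all = _h_from_rank_sums(all_sums, sizes, n, tie_corr)
        p = float(np.mean(h_all >= h - 1e-9))
    else:
        raise ConfigurationError(f"unknown method {method!r}")
    return KWResult(h=h, df=df, p=min(max(p, np.nextafter(0, 1)), 1.0),
                    group_sizes=tuple(sizes), tie_correction=tie_corr, method=method)


def dunn_pairwise(groups, pairs=None, adjustment: str = "bonferroni",
                  method: str = "asymptotic", labels=None):
    """Dunn's post-hoc rank comparisons after a Kruskal-Wallis layout.

    For pair (a, b): ``z = (Rbar_b - Rbar_a) / sd`` with the tie-corrected
    pooled-rank standard deviation
    ``sd = sqrt((N(N+1)/12 - T/(12(N-1))) * (1/n_a + 1/n_b))`` where
    ``T = sum(t^3 - t)`` over tied groups.  Two-sided p-values; the adjusted
    p is ``min(1, m * p)`` over the ``m`` requested pairs (Bonferroni).
    ``direction`` is the sign of the mean-rank difference (b relative to a).
    """
    groups, pooled, ranks, sizes = _pooled_ranks(groups)
    n = len(pooled)
    k = len(groups)
    if pairs is None:
        pairs = list(itertools.combinations(range(k), 2))
    if adjustment not in ("bonferroni", "none"):
        raise ConfigurationError(f"unknown adjustment {adjustment!r}")
    m = len(pairs) if adjustment == "bonferroni" else 1
    bounds = np.cumsum(sizes)[:-1]
    rank_sums = np.array([s.sum() for s in np.split(ranks, bounds)])
    mean_ranks = rank_sums / sizes
    tie = _tie_term(pooled)
    var_base = n * (n + 1.0) / 12.0 - tie / (12.0 * (n - 1.0))
    all_sums = None
    if method == "exact":
        if n > _EXACT_MAX_N:
            raise ConfigurationError(f"exact method limited to N <= {_EXACT_MAX_N}")
        all_sums = _enumerate_rank_sums(ranks, sizes)
    out = []
    for i, j in pairs:
        sd = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if sd == 0:
            z = 0.0
        else:
            z = (mean_ranks[j] - mean_ranks[i]) / sd
        if method == "asymptotic":
            p = float(2.0 * sps.norm.sf(abs(z)))
        elif method == "exact":
            z_all = (all_sums[:, j] / sizes[j] - all_sums[:, i] / sizes[i]) / sd
            p = float(np.mean(np.abs(z_all) >= abs(z) - 1e-9))
        else:
            raise ConfigurationError(f"unknown method {method!r}")
        p = min(p, 1.0)
        la, lb = (labels[i], labels[j]) if labels else (i, j)
        out.append(DunnPair(a=la, b=lb, z=float(z), p=p,
                            p_adj=min(1.0, m * p), direction=int(np.sign(z)),
                            n_a=int(sizes[i]), n_b=int(sizes[j])))
    return out


# --------------------------------------------------------------------------
# composite decision rules
# --------------------------------------------------------------------------


@dataclass
class DecisionResult:
    """Per-unit verdict of a protocol's composite significance rule."""

    flagged: bool
    direction: str  # 'increase' / 'decrease' / 'none'
    protocol: str
    kw: KWResult | None
    pairs: list = field(default_factory=list)
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "flagged": self.flagged, "direction": self.direction,
            "protocol": self.protocol,
            "kw": None if self.kw is None else {
                "h": float(self.kw.h), "df": int(self.kw.df), "p": float(self.kw.p),
                "group_sizes": [int(s) for s in self.kw.group_sizes]},
            "pairs": [{"a": p.a, "b": p.b, "z": p.z, "p": p.p,
                       "p_adj": p.p_adj, "direction": p.direction}
                      for p in self.pairs],
            "notes": list(self.notes),
        }


def _epoch_groups(series: RateSeries, plan: EpochPlan) -> dict:
    if abs(series.bin_width_s - plan.bin_width_s) > 1e-9:
        raise ConfigurationError("rate-series bin width does not match the plan")
    groups = {}
    for label, (t0, t1) in plan.epochs.items():
        vals = series.epoch_values(t0, t1)
        expected = plan.bins_per_epoch(label)
        if len(vals) != expected:
            raise ConfigurationError(
                f"epoch {label!r}: expected {expected} bins, got {len(vals)}")
        groups[label] = vals
    return groups


def epoch_composite_decision(groups: dict, protocol: str, alpha: float = 0.05
                             ) -> DecisionResult:
    """Apply a protocol's composite significance rule to labelled value groups.

    donor: omnibus KW over the seven epochs, then Dunn on (R1, E80),
    (R2, E120) and (E120, R3); flagged iff the first two changes are
    significant in the same direction and the third is a significant change
    in the opposite direction (return towards baseline).

    inhibitor / nmda: omnibus KW over (B, E, R), Dunn on (B, E) and (E, R);
    flagged iff both are significant and E differs from both sides in the
    same sense (the E-to-R change reverses the B-to-E change).
    """
    if protocol == "donor":
        order = ["B", "E40", "R1", "E80", "R2", "E120", "R3"]
        test_pairs = [("R1", "E80"), ("R2", "E120"), ("E120", "R3")]
    elif protocol in ("inhibitor", "nmda"):
        order = ["B", "E", "R"]
        test_pairs = [("B", "E"), ("E", "R")]
    else:
        raise ConfigurationError(f"unknown protocol {protocol!r}")
    missing = [lab for lab in order if lab not in groups]
    if missing:
        raise ConfigurationError(f"missing epochs: {missing}")
    arrays = [np.asarray(groups[lab], dtype=float) for lab in order]
    idx = {lab: i for i, lab in enumerate(order)}
    kw = kruskal_wallis(arrays)
    pairs = dunn_pairwise(arrays, pairs=[(idx[a], idx[b]) for a, b in test_pairs],
                          labels=order)
    sig = [p.p_adj < alpha for p in pairs]
    dirs = [p.direction for p in pairs]
    notes = []
    if protocol == "donor":
        concordant = dirs[0] != 0 and dirs[0] == dirs[1]
        reverses = dirs[2] == -dirs[0]
        flagged = kw.p < alpha and all(sig) and concordant and reverses
        lead = dirs[0]
    else:
        concordant = dirs[0] != 0 and dirs[1] == -dirs[0]
        flagged = kw.p < alpha and all(sig) and concordant
        lead = dirs[0]
    if kw.p >= alpha:
        notes.append("omnibus Kruskal-Wallis not significant")
    direction = "none"
    if flagged:
        direction = "increase" if lead > 0 else "decrease"
    return DecisionResult(flagged=flagged, direction=direction, protocol=protocol,
                          kw=kw, pairs=pairs, notes=notes)


def donor_decision(series: RateSeries, plan: EpochPlan, alpha: float = 0.05
                   ) -> DecisionResult:
    """Composite decision for the three-dose NO-donor protocol."""
    if plan.protocol != "donor":
        raise ConfigurationError("plan is not a donor plan")
    return epoch_composite_decision(_epoch_groups(series, plan), "donor", alpha)


def inhibitor_decision(series: RateSeries, plan: EpochPlan, alpha: float = 0.05
                       ) -> DecisionResult:
    """Composite decision for the single-block NOS-inhibitor protocol."""
    if plan.protocol != "inhibitor":
        raise ConfigurationError("plan is not an inhibitor plan")
    return epoch_composite_decision(_epoch_groups(series, plan), "inhibitor", alpha)


# --------------------------------------------------------------------------
# NMDA enhancement
# --------------------------------------------------------------------------


@dataclass
class NmdaEnhancement:
    """Percent-of-baseline NMDA burst responses per period, plus the verdict."""

    periods: dict  # label -> {baseline_rate, top_rates, percent}
    decision: DecisionResult
    percent_mode: str  # 'percent', 'log_percent' or 'absolute'
    window: str


def nmda_enhancement(series: RateSeries, proto: NmdaProtocol | None = None,
                     alpha: float = 0.05, log_percent: bool = False
                     ) -> NmdaEnhancement:
    """Score NMDA-evoked excitation before/during/after a modulator block.

    Per period (B, E, R): of the 10-s bins inside the final three NMDA
    applications, the six with the highest spike rate are kept (ties broken
    by earliest time) and expressed as a percentage of that period's
    baseline rate (mean over the 180 s before its first application).  The
    three six-value groups are compared by Kruskal-Wallis plus Dunn on
    (B, E) and (E, R).  ``log_percent`` reports log10 percentages (used for
    spontaneous windows with very low baselines); rank statistics are
    invariant to this monotone transform.
    """
    if proto is None:
        proto = NmdaProtocol()
    if abs(series.bin_width_s - 10.0) > 1e-9:
        raise ConfigurationError("NMDA analysis requires 10-s bins")
    periods = {}
    notes = []
    mode = "percent"
    values = {}
    for label, starts in proto.app_starts.items():
        sel_rates, sel_t = [], []
        for s in starts[-proto.n_final_apps:]:
            m = (series.t_start >= s - 1e-9) & (series.t_start < s + proto.app_dur_s - 1e-9)
            sel_rates.append(series.rates[m])
            sel_t.append(series.t_start[m])
        r = np.concatenate(sel_rates)
        t = np.concatenate(sel_t)
        top = np.lexsort((t, -r))[:proto.n_top_bins]
        top_rates = r[top]
        b0 = max(starts[0] - proto.baseline_dur_s, 0.0)
        base = series.epoch_values(b0, starts[0])
        baseline_rate = float(base.mean()) if len(base) else 0.0
        if baseline_rate <= 0:
            mode = "absolute"
        periods[label] = {"baseline_rate": baseline_rate,
                          "top_rates": top_rates}
    for label, d in periods.items():
        if mode == "absolute":
            vals = d["top_rates"] - d["baseline_rate"]
            d["percent"] = None
        else:
            vals = 100.0 * d["top_rates"] / d["baseline_rate"]
            d["percent"] = vals
        values[label] = vals
    if mode == "absolute":
        notes.append("zero baseline rate: absolute rate differences used")
    elif log_percent and series.window == "spontaneous":
        if all(np.all(v > 0) for v in values.values()):
            values = {k: np.log10(v) for k, v in values.items()}
            mode = "log_percent"
        else:
            notes.append("non-positive percentages: log transform skipped")
    decision = epoch_composite_decision(values, "nmda", alpha)
    decision.notes.extend(notes)
    return NmdaEnhancement(periods=periods, decision=decision,
                           percent_mode=mode, window=series.window)


# --------------------------------------------------------------------------
# latency, difference PSTH, K-S, association
# --------------------------------------------------------------------------


def first_spike_latency(spikes: pd.DataFrame, n_sweeps: int,
                        averaging_window_min: float = 5.0,
                        sweep: SweepStructure = SweepStructure()) -> pd.DataFrame:
    """Mean first-spike latency (s after tone onset) per averaging block.

    Sweeps without driven spikes contribute nothing to their block's mean.
    """
    w0, w1 = analysis_window("driven", sweep)
    d = spikes[(spikes["time_s"] >= w0) & (spikes["time_s"] < w1)]
    if len(d) == 0:
        return pd.DataFrame({"t_start_s": [], "mean_latency_s": [], "n_sweeps": []})
    first = d.groupby("sweep")["time_s"].min() - sweep.tone_on_s
    spb = max(int(round(averaging_window_min * 60.0 / sweep.sweep_s)), 1)
    block = (first.index.to_numpy() // spb).astype(int)
    g = first.groupby(block)
    return pd.DataFrame({
        "t_start_s": g.mean().index.to_numpy() * spb * sweep.sweep_s,
        "mean_latency_s": g.mean().to_numpy(),
        "n_sweeps": g.size().to_numpy(),
    })


@dataclass
class PsthDifference:
    """Baseline-vs-drug PSTH comparison on identical fine binning."""

    bin_width_ms: float
    bin_centers_s: np.ndarray
    baseline_prob: np.ndarray
    drug_prob: np.ndarray
    diff: np.ndarray  # drug - baseline spike probability per bin
    ks_d: float
    ks_p: float
    baseline_sweeps: tuple
    drug_sweeps: tuple


def _sweep_range_mask(sw: np.ndarray, first: int, last: int) -> np.ndarray:
    # 1-based inclusive sweep range -> mask over 0-based sweep indices
    return (sw >= first - 1) & (sw <= last - 1)


def psth_difference(spikes: pd.DataFrame, baseline_sweeps=(301, 900),
                    drug_sweeps=(1501, 2100), bin_ms: float = 0.2,
                    window=(0.0, 0.2)) -> PsthDifference:
    """Fine-binned PSTH difference between two sweep ranges, with a K-S test.

    Sweep ranges are 1-based inclusive (e.g. sweeps 301-900 of the
    baseline period versus 1501-2100 during the drug).  Per bin the spike
    probability (count / number of sweeps) is differenced (drug minus
    baseline); the two in-window spike-time samples are compared with a
    two-sample Kolmogorov-Smirnov test.
    """
    b0, b1 = baseline_sweeps
    d0, d1 = drug_sweeps
    if not (b1 < d0 or d1 < b0):
        raise ConfigurationError("sweep ranges must be disjoint")
    sw = spikes["sweep"].to_numpy()
    t = spikes["time_s"].to_numpy()
    w0, w1 = window
    n_bins = int(round((w1 - w0) / (bin_ms / 1000.0)))
    edges = w0 + np.arange(n_bins + 1) * (bin_ms / 1000.0)
    in_win = (t >= w0) & (t < w1)
    tb = t[in_win & _sweep_range_mask(sw, b0, b1)]
    td = t[in_win & _sweep_range_mask(sw, d0, d1)]
    if len(tb) == 0 or len(td) == 0:
        raise ConfigurationError("empty spike sample in a sweep range")
    pb = np.histogram(tb, bins=edges)[0] / (b1 - b0 + 1)
    pdg = np.histogram(td, bins=edges)[0] / (d1 - d0 + 1)
    d, p = ks_two_sample(tb, td)
    return PsthDifference(bin_width_ms=bin_ms,
                          bin_centers_s=(edges[:-1] + edges[1:]) / 2.0,
                          baseline_prob=pb, drug_prob=pdg, diff=pdg - pb,
                          ks_d=d, ks_p=p,
                          baseline_sweeps=tuple(baseline_sweeps),
                          drug_sweeps=tuple(drug_sweeps))


def ks_two_sample(x, y):
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value.

    D is the supremum of the absolute difference of the two empirical CDFs;
    the p-value uses the asymptotic Kolmogorov distribution at
    ``sqrt(n_x n_y / (n_x + n_y)) * D``.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ConfigurationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / nx
    cdf_y = np.searchsorted(y, pooled, side="right") / ny
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    en = nx * ny / (nx + ny)
    p = float(special.kolmogorov(math.sqrt(en) * d))
    return d, min(max(p, 0.0), 1.0)


def association_test(table, exact_max_total: int = 40, n_mc: int = 100000,
                     seed: int = 0):
    """Exact (or Monte-Carlo) test of independence for an R x C count table.

    Generalised Fisher's exact test: the p-value is the total probability,
    under the fixed-margin hypergeometric null, of tables no more probable
    than the observed one.  Tables with a grand total of at most
    ``exact_max_total`` are fully enumerated; larger tables use seeded
    Monte-Carlo sampling of label permutations (>= ``n_mc`` tables).
    Returns ``(p, method)``.
    """
    t = np.asarray(table)
    if t.ndim != 2 or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = np.asarray(table, dtype=float)
        if t.ndim != 2 or np.any(t < 0) or np.any(t != np.round(t)):
            raise ConfigurationError("table must be a 2-D array of counts >= 0")
        t = t.astype(np.int64)
    n = int(t.sum())
    if n < 1:
        raise ConfigurationError("table total must be >= 1")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    logp_obs = _log_table_prob(t, rows, cols, n)
    tol = 1e-9
    if n <= exact_max_total:
        total = 0.0
        for logp in _enumerate_table_probs(rows, cols, n):
            if logp <= logp_obs + tol:
                total += math.exp(logp)
        return min(total, 1.0), "exact"
    # Monte-Carlo: permute column labels against fixed row labels
    rng = np.random.default_rng(seed)
    row_lab = np.repeat(np.arange(len(rows)), rows)
    col_lab = np.repeat(np.arange(len(cols)), cols)
    stat_obs = float(special.gammaln(t + 1.0).sum())
    hits = 0
    chunk = max(1, min(n_mc, 20000))
    done = 0
    r, c = len(rows), len(cols)
    while done < n_mc:
        b = min(chunk, n_mc - done)
        perm = rng.permuted(np.tile(col_lab, (b, 1)), axis=1)
        flat = (row_lab[None, :] * c + perm) + (np.arange(b) * (r * c))[:, None]
        counts = np.bincount(flat.ravel(), minlength=b * r * c).reshape(b, r, c)
        stat = special.gammaln(counts + 1.0).sum(axis=(1, 2))
        hits += int(np.sum(stat >= stat_obs - tol))
        done += b
    return (hits + 1) / (n_mc + 1), "monte-carlo"


def _log_table_prob(t, rows, cols, n):
    return float(special.gammaln(rows + 1.0).sum() + special.gammaln(cols + 1.0).sum()
                 - special.gammaln(n + 1.0) - special.gammaln(t + 1.0).sum())


def _enumerate_table_probs(rows, cols, n):
    """Yield log-probabilities of all tables with the given margins."""
    r, c = len(rows), len(cols)
    const = (special.gammaln(rows + 1.0).sum() + special.gammaln(cols + 1.0).sum()
             - special.gammaln(n + 1.0))
    cells = np.zeros((r, c), dtype=np.int64)

    def rec_row(i, col_rem):
        if i == r - 1:
            if np.any(col_rem < 0):
                return
            cells[i] = col_rem
            yield const - special.gammaln(cells + 1.0).sum()
            return
        yield from rec_cell(i, 0, rows[i], col_rem)

    def rec_cell(i, j, row_rem, col_rem):
        if j == c - 1:
            if row_rem > col_rem[j]:
                return
            cells[i, j] = row_rem
            new_rem = col_rem.copy()
            new_rem[j] -= row_rem
            yield from rec_row(i + 1, new_rem)
            return
        for v in range(min(row_rem, col_rem[j]) + 1):
            cells[i, j] = v
            new_rem = col_rem.copy()
            new_rem[j] -= v
            yield from rec_cell(i, j + 1, row_rem - v, new_rem)

    yield from rec_row(0, cols.astype(np.int64).copy())


# --------------------------------------------------------------------------
# population summaries
# --------------------------------------------------------------------------


def percent_of_count(k: int, n: int) -> int:
    """Integer percentage of a count, rounded half away from zero."""
    if n <= 0:
        raise ConfigurationError("denominator must be > 0")
    return int(math.floor(100.0 * k / n + 0.5))


def percent_of_baseline(baseline_rate: float, effect_rate: float) -> float:
    """Rate during the effect as a percentage of the baseline rate."""
    if baseline_rate <= 0:
        raise ConfigurationError("baseline rate must be > 0 for a percentage")
    return 100.0 * effect_rate / baseline_rate


def population_summary(outcomes) -> dict:
    """Population-level report over per-unit decisions.

    ``outcomes`` is an iterable of dicts with keys ``unit``, ``decision``
    (:class:`DecisionResult`), and optionally ``baseline_rate`` and
    ``effect_rate`` (Hz).  For each direction the report gives the flagged
    count, its integer percentage of units tested, and — across flagged
    units with a non-zero baseline — the mean and SD of the per-unit
    percent-of-baseline (mean of per-unit ratios, not ratio of means).
    Units with zero baseline are excluded from percent summaries and
    counted separately.
    """
    outcomes = list(outcomes)
    n = len(outcomes)
    if n == 0:
        raise ConfigurationError("need at least one unit outcome")
    report = {"n_tested": n, "directions": {}}
    for direction in ("increase", "decrease"):
        sel = [o for o in outcomes if o["decision"].flagged
               and o["decision"].direction == direction]
        percents, excluded = [], 0
        for o in sel:
            b = o.get("baseline_rate")
            e = o.get("effect_rate")
            if b is None or e is None:
                continue
            if b <= 0:
                excluded += 1
                continue
            percents.append(percent_of_baseline(b, e))
        entry = {
            "n_flagged": len(sel),
            "pct_of_tested": percent_of_count(len(sel), n),
            "units": [o["unit"] for o in sel],
            "n_zero_baseline": excluded,
        }
        if percents:
            arr = np.asarray(percents)
            entry["percent_of_baseline_mean"] = float(arr.mean())
            entry["percent_of_baseline_sd"] = (
                float(arr.std(ddof=1)) if len(arr) > 1 else 0.0)
        report["directions"][direction] = entry
    n_any = sum(1 for o in outcomes if o["decision"].flagged)
    report["n_flagged"] = n_any
    report["pct_flagged"] = percent_of_count(n_any, n)
    return report
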
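"""Probe-, replicon- and within-replicon statistics.

Implements the coverage computation (percent of bases in a union of
same-kind features), top-quartile flags, one-sample t and exact binomial
tests of timing classes against their region, Welch two-sample comparisons
of EM vs L replicons, and the 10-interval / 5-bin within-replicon
metaprofile with exact binomial confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint
from statsmodels.stats.multitest import multipletests

from .replicons import Replicon
from .segmentation import CLASS_ORDER

__all__ = [
    "StatResult",
    "significance_code",
    "compute_coverage",
    "top_quartile_flags",
    "binomial_test_two_sided",
    "probe_class_tests",
    "replicon_compare",
    "bin_of_interval",
    "assign_bins",
    "bin_profile",
]


def significance_code(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class StatResult:
    group: str
    feature: str
    n: int
    estimate: float
    reference: float
    statistic: float
    df: float
    p_value: float

    @property
    def code(self) -> str:
        return significance_code(self.p_value)


def _merge(ivs):
    out = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return out


def compute_coverage(start: int, end: int,
                     features: list[tuple[int, int]]) -> float:
    """Percent of interval bases overlapping the union of features.

    Overlapping features are merged so coverage never exceeds 100%.
    """
    if end <= start:
        raise ValueError("zero-length interval")
    covered = 0
    for s, e in _merge(list(features)):
        covered += max(0, min(e, end) - max(s, start))
    return 100.0 * covered / (end - start)


def top_quartile_flags(values: np.ndarray) -> np.ndarray:
    """Flag values at or above the 75th percentile (linear-interpolation
    quantile) of the whole array.  With all values equal, every probe is
    flagged (every value >= the quantile)."""
    v = np.asarray(values, dtype=float)
    q = np.quantile(v, 0.75)
    return v >= q


def binomial_test_two_sided(x: int, n: int, p0: float) -> float:
    """Exact binomial p-value: doubled smaller tail, capped at 1."""
    if not 0 <= x <= n:
        raise ValueError("x must lie in [0, n]")
    lower = sps.binom.cdf(x, n, p0)
    upper = sps.binom.sf(x - 1, n, p0)
    return float(min(1.0, 2.0 * min(lower, upper)))


def probe_class_tests(
    probe_cls: list[str],
    continuous: dict[str, np.ndarray],
    binary: dict[str, np.ndarray],
    region_mask: np.ndarray | None = None,
    n_min: int = 20,
    region: str = "",
) -> list[StatResult]:
    """Per-timing-class enrichment tests against the region-wide values.

    Continuous features: two-sided one-sample t-test of the class's probe
    values against the region mean.  Binary features: exact two-sided
    binomial test of the class's positive count against the region-wide
    positive fraction.  Classes with fewer than ``n_min`` probes in the
    region are omitted; a zero-variance t-test is reported with p = NaN.
    """
    cls = np.asarray(probe_cls)
    mask = np.ones(cls.size, bool) if region_mask is None \
        else np.asarray(region_mask, bool)
    out: list[StatResult] = []
    for feature, vals in continuous.items():
        v = np.asarray(vals, float)[mask]
        mu0 = float(v.mean())
        for c in CLASS_ORDER:
            sel = v[cls[mask] == c]
            if sel.size < n_min:
                continue
            if np.std(sel, ddof=1) == 0:
                t, p = np.nan, np.nan
            else:
                t, p = sps.ttest_1samp(sel, mu0)
            out.append(StatResult(
                group=f"{region}/{c}" if region else c, feature=feature,
                n=int(sel.size), estimate=float(sel.mean()), reference=mu0,
                statistic=float(t), df=float(sel.size - 1),
                p_value=float(p)))
    for feature, flags in binary.items():
        f = np.asarray(flags, bool)[mask]
        p0 = float(f.mean())
        for c in CLASS_ORDER:
            sel = f[cls[mask] == c]
            if sel.size < n_min:
                continue
            x = int(sel.sum())
            p = binomial_test_two_sided(x, sel.size, p0)
            out.append(StatResult(
                group=f"{region}/{c}" if region else c, feature=feature,
                n=int(sel.size), estimate=100.0 * x / sel.size,
                reference=100.0 * p0, statistic=float(x), df=np.nan,
                p_value=p))
    return out


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t: (t, fractional df, p)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0:
        return 0.0, float(na + nb - 2), 1.0
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def replicon_compare(per_replicon_values: dict[str, np.ndarray],
                     groups: np.ndarray,
                     group_a: str = "EM", group_b: str = "L"
                     ) -> list[StatResult]:
    """Welch two-sample comparison of per-replicon feature values between
    two replicon classes (typically EM vs L)."""
    groups = np.asarray(groups)
    out = []
    for feature, vals in per_replicon_values.items():
        v = np.asarray(vals, float)
        a, b = v[groups == group_a], v[groups == group_b]
        if a.size < 2 or b.size < 2:
            raise ValueError(
                f"need >=2 replicons per class for {feature} "
                f"({group_a}: {a.size}, {group_b}: {b.size})")
        t, df, p = welch_t(a, b)
        out.append(StatResult(
            group=f"{group_a} vs {group_b}", feature=feature,
            n=int(a.size + b.size), estimate=float(a.mean()),
            reference=float(b.mean()), statistic=t, df=df, p_value=p))
    return out


def bin_of_interval(interval: int) -> int:
    """Map the 10 within-replicon intervals onto 5 symmetric bins:
    {5,6} -> 1 (innermost, near initiation), {4,7} -> 2, {3,8} -> 3,
    {2,9} -> 4, {1,10} -> 5 (outermost, near termination)."""
    if not 1 <= interval <= 10:
        raise ValueError("interval must be 1..10")
    return 6 - min(interval, 11 - interval)


def assign_bins(positions: np.ndarray, start: float, end: float) -> np.ndarray:
    """Bin (1..5) of each position within a replicon [start, end).

    Positions are assigned to 10 equal-length intervals by relative
    position, then folded symmetrically onto 5 bins.
    """
    rel = (np.asarray(positions, float) - start) / (end - start)
    interval = np.clip(np.floor(rel * 10).astype(int) + 1, 1, 10)
    return np.array([bin_of_interval(i) for i in interval])


def bin_profile(replicons: list[Replicon], centers: np.ndarray,
                flags: np.ndarray, min_probes: int = 10,
                mode: str = "pooled", alpha: float = 0.05):
    """Proportion of feature-positive probes in bins 1-5 across replicons.

    Probes are assigned to bins by center position within their replicon.
    ``mode='pooled'`` pools probes across replicons (each probe counts
    once); ``mode='per_replicon'`` averages per-replicon proportions.
    Returns (proportions[5], (ci_lo[5], ci_hi[5]), overall_mean); CIs are
    exact Clopper-Pearson intervals (NaN in pooled-empty bins).
    """
    centers = np.asarray(centers, float)
    flags = np.asarray(flags, bool)
    pos_cnt = np.zeros(5)
    tot_cnt = np.zeros(5)
    per_rep: list[list[list[float]]] = [[] for _ in range(5)]
    used = np.zeros(centers.size, bool)
    for r in replicons:
        idx = np.flatnonzero((centers >= r.start) & (centers < r.end))
        if idx.size < min_probes:
            continue
        bins = assign_bins(centers[idx], r.start, r.end)
        used[idx] = True
        for b in range(1, 6):
            sel = flags[idx[bins == b]]
            pos_cnt[b - 1] += sel.sum()
            tot_cnt[b - 1] += sel.size
            if sel.size:
                per_rep[b - 1].append(float(sel.mean()))
    with np.errstate(invalid="ignore", divide="ignore"):
        if mode == "pooled":
            props = np.where(tot_cnt > 0, pos_cnt / np.maximum(tot_cnt, 1),
                             np.nan)
        elif mode == "per_replicon":
            props = np.array([np.mean(v) if v else np.nan for v in per_rep])
        else:
            raise ValueError("mode must be 'pooled' or 'per_replicon'")
    lo = np.full(5, np.nan)
    hi = np.full(5, np.nan)
    for b in range(5):
        if tot_cnt[b] > 0:
            lo[b], hi[b] = proportion_confint(
                int(pos_cnt[b]), int(tot_cnt[b]), alpha=alpha, method="beta")
    overall = float(flags[used].mean()) if used.any() else np.nan
    return props, (lo, hi), overall


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (reported alongside raw p;
    significance codes always use raw p)."""
    p = np.asarray(p_values, float)
    ok = np.isfinite(p)
    out = np.full(p.shape, np.nan)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
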
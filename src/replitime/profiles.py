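"""Replicate combination, normalization and loess profile smoothing.

The smoothed per-fraction profile is the basic object of the analysis:
log2 BrdU-enrichment ratios, averaged over replicates and loess-smoothed
in a fixed genomic window (default 150 kb), one value per probe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SmoothedProfile",
    "average_replicates",
    "quantile_normalize",
    "loess_smooth",
    "profile_correlation",
    "decile_rank",
]


@dataclass(frozen=True)
class SmoothedProfile:
    """Loess-smoothed enrichment values aligned 1:1 to the probe list."""

    fraction: str
    values: np.ndarray
    window: float = 150_000.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("smoothed profile contains non-finite values")


def average_replicates(ratios: np.ndarray, centers: np.ndarray | None = None,
                       max_missing_frac: float = 0.05) -> np.ndarray:
    """Mean across replicates, ignoring missing (NaN) values.

    ``ratios`` is probes x replicates.  A probe with no finite value in
    any replicate is linearly interpolated from flanking probes in
    genomic coordinate (``centers``; index coordinate if omitted).
    Aborts if more than ``max_missing_frac`` of probes are entirely
    missing.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.ndim == 1:
        ratios = ratios[:, None]
    n = ratios.shape[0]
    finite = np.isfinite(ratios)
    counts = finite.sum(axis=1)
    sums = np.where(finite, ratios, 0.0).sum(axis=1)
    mean = np.divide(sums, counts, out=np.full(n, np.nan),
                     where=counts > 0)
    missing = ~np.isfinite(mean)
    if missing.mean() > max_missing_frac:
        raise ValueError(
            f"{missing.sum()} of {n} probes have no replicate value "
            f"(> {max_missing_frac:.0%}); aborting"
        )
    if missing.any():
        x = np.arange(n, dtype=float) if centers is None \
            else np.asarray(centers, float)
        ok = ~missing
        mean[missing] = np.interp(x[missing], x[ok], mean[ok])
    return mean


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Quantile normalization across arrays (columns).

    Every column's sorted values are replaced by the row-wise mean of the
    sorted input columns; tied values within a column receive the mean of
    the reference values their ranks span.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least two columns")
    if not np.all(np.isfinite(m)):
        raise ValueError("non-finite input to quantile normalization")
    ref = np.sort(m, axis=0).mean(axis=1)
    out = np.empty_like(m)
    for j in range(m.shape[1]):
        col = m[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty_like(ref)
        ranked[order] = ref
        # average reference values over runs of ties
        sorted_col = col[order]
        k = 0
        while k < len(sorted_col):
            k2 = k
            while k2 + 1 < len(sorted_col) and sorted_col[k2 + 1] == sorted_col[k]:
                k2 += 1
            if k2 > k:
                ranked[order[k:k2 + 1]] = ref[k:k2 + 1].mean()
            k = k2 + 1
        out[:, j] = ranked
    return out


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def loess_smooth(centers: np.ndarray, values: np.ndarray,
                 window: float = 150_000.0, fraction: str = "",
                 degree: int = 2, min_pts: int = 8) -> SmoothedProfile:
    """Locally weighted polynomial smoothing in a fixed genomic window.

    At each probe center x0 a degree-``degree`` polynomial is fitted by
    weighted least squares over probes with centers within window/2 of
    x0, with tricube weights on |x - x0| / (window/2); the fitted value
    at x0 is returned.  Windows holding fewer than ``min_pts`` probes
    fall back to the tricube-weighted mean.
    """
    x = np.asarray(centers, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("centers and values must be equal-length 1-D arrays")
    if np.any(np.diff(x) < 0):
        raise ValueError("probes must be sorted by position")
    n = x.size
    half = window / 2.0
    lo = np.searchsorted(x, x - half, side="left")
    hi = np.searchsorted(x, x + half, side="right")
    width = hi - lo
    kmax = int(width.max())
    # padded neighbor matrix: row i holds the window around probe i,
    # zero-weighted beyond the true window
    offs = lo[:, None] + np.arange(kmax)[None, :]
    valid = offs < hi[:, None]
    offs = np.minimum(offs, n - 1)
    t = (x[offs] - x[:, None]) / half
    w = _tricube(t) * valid
    ys = y[offs]
    sw = w.sum(axis=1)
    out = np.where(sw > 0, (w * ys).sum(axis=1) / np.where(sw > 0, sw, 1.0), y)
    fit = width >= min_pts
    if degree > 0 and fit.any():
        # weighted least squares via per-probe normal equations on the
        # scaled coordinate t in [-1, 1]
        p = degree + 1
        moments = [np.sum(w * t ** k, axis=1) for k in range(2 * degree + 1)]
        rhs = [np.sum(w * ys * t ** k, axis=1) for k in range(p)]
        A = np.empty((n, p, p))
        for a in range(p):
            for b in range(p):
                A[:, a, b] = moments[a + b]
        B = np.stack(rhs, axis=1)
        idx = np.flatnonzero(fit)
        try:
            out[idx] = np.linalg.solve(A[idx], B[idx][:, :, None])[:, 0, 0]
        except np.linalg.LinAlgError:
            for i in idx:  # rare singular windows: solve one by one
                try:
                    out[i] = np.linalg.solve(A[i], B[i])[0]
                except np.linalg.LinAlgError:
                    pass
    return SmoothedProfile(fraction=fraction, values=out, window=window)


def profile_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two aligned profiles.

    Returns NaN (with no exception) when either profile has zero
    variance, where the correlation is undefined.
    """
    a = np.asarray(getattr(a, "values", a), float)
    b = np.asarray(getattr(b, "values", b), float)
    if a.shape != b.shape:
        raise ValueError("profiles must be aligned and equal length")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def decile_rank(values: np.ndarray) -> np.ndarray:
    """Partition probes into 10 equal-count groups by value (1 = lowest).

    Ties are broken by genomic position (array order, leftmost first), so
    every decile holds floor(n/10) or ceil(n/10) probes.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 10:
        raise ValueError("need at least 10 probes for decile ranking")
    order = np.argsort(v, kind="stable")  # stable = positional tie-break
    ranks = np.empty(n, dtype=int)
    # equal-count groups: group g gets indices [g*n//10, (g+1)*n//10)
    for g in range(10):
        ranks[order[g * n // 10:(g + 1) * n // 10]] = g + 1
    return ranks
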
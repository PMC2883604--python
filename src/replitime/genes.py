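"""Per-gene epigenetic patterns, timing classes and expression statistics.

Genes inherit mark calls from overlapping probes (any positive probe makes
the gene positive for that mark, by default), the 4-bit mark vector maps
onto one of 16 fixed patterns ranked by gene activity, and a gene's timing
class is the overlap-length plurality over the timing segments it spans.
Association tables use exact binomial tests (activity vs the overall
activity rate) and one-sided hypergeometric tests (pattern x timing-class
representation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .feature_stats import binomial_test_two_sided, StatResult
from .segmentation import CLASS_ORDER, TimingSegment
from .simulate import GenomicFeature, GeneExpression, MarkCalls, Probe

__all__ = [
    "GeneRecord",
    "PATTERN_MAP",
    "pattern_of",
    "assign_gene_marks",
    "assign_gene_timing",
    "build_gene_records",
    "pattern_activity_table",
    "timing_enrichment_table",
    "activity_by_timing",
    "element_distribution_in_replicons",
    "intergenic_regions",
]

#: (k4, k9, k56, mc) -> pattern rank (1 = highest gene activity)
PATTERN_MAP: dict[tuple[bool, bool, bool, bool], int] = {
    (True, False, True, True): 1,
    (False, False, True, True): 2,
    (False, False, True, False): 3,
    (True, False, True, False): 4,
    (True, False, False, True): 5,
    (True, True, True, False): 6,
    (True, True, True, True): 7,
    (False, True, True, False): 8,
    (False, True, True, True): 9,
    (True, False, False, False): 10,
    (True, True, False, False): 11,
    (False, False, False, True): 12,
    (False, False, False, False): 13,
    (True, True, False, True): 14,
    (False, True, False, True): 15,
    (False, True, False, False): 16,
}


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    marks: tuple[bool, bool, bool, bool]  # (k4, k9, k56, mc)
    pattern: int
    present: bool
    level: float
    cls: str


def pattern_of(k4: bool, k9: bool, k56: bool, mc: bool) -> int:
    """Pattern rank (1-16) of a 4-bit mark vector; the map is a bijection
    over all 16 vectors."""
    return PATTERN_MAP[(bool(k4), bool(k9), bool(k56), bool(mc))]


def _overlapping(starts: np.ndarray, ends: np.ndarray,
                 s: int, e: int) -> np.ndarray:
    return np.flatnonzero((ends > s) & (starts < e))


def assign_gene_marks(gene_start: int, gene_end: int,
                      probe_starts: np.ndarray, probe_ends: np.ndarray,
                      marks: list[MarkCalls], rule: str = "any"
                      ) -> tuple[bool, bool, bool, bool] | None:
    """Mark vector of a gene from its overlapping probes.

    ``rule='any'``: positive iff any overlapping probe is positive;
    ``rule='majority'``: positive iff more than half are.  Returns None
    when the gene overlaps no probe (such genes are excluded upstream).
    """
    idx = _overlapping(np.asarray(probe_starts), np.asarray(probe_ends),
                       gene_start, gene_end)
    if idx.size == 0:
        return None
    vecs = np.array([[marks[i].k4, marks[i].k9, marks[i].k56, marks[i].mc]
                     for i in idx], dtype=bool)
    if rule == "any":
        agg = vecs.any(axis=0)
    elif rule == "majority":
        agg = vecs.mean(axis=0) > 0.5
    else:
        raise ValueError("rule must be 'any' or 'majority'")
    return tuple(bool(b) for b in agg)


def assign_gene_timing(gene_start: int, gene_end: int,
                       segments: list[TimingSegment]) -> str | None:
    """Timing class with the greatest total overlap length with the gene,
    ties broken by the fixed class order; None when there is no overlap."""
    lengths = {c: 0 for c in CLASS_ORDER}
    for seg in segments:
        ov = min(seg.end, gene_end) - max(seg.start, gene_start)
        if ov > 0:
            lengths[seg.cls] += ov
    if not any(lengths.values()):
        return None
    best = max(lengths.values())
    return next(c for c in CLASS_ORDER if lengths[c] == best)


def build_gene_records(features: list[GenomicFeature],
                       probes: list[Probe], marks: list[MarkCalls],
                       expression: list[GeneExpression],
                       segments: list[TimingSegment],
                       mark_rule: str = "any"
                       ) -> tuple[list[GeneRecord], int]:
    """Assemble per-gene records; returns (records, n_excluded) where
    excluded genes lacked overlapping probes or timing data."""
    ps = np.array([p.start for p in probes])
    pe = np.array([p.end for p in probes])
    expr = {e.gene_id: e for e in expression}
    out: list[GeneRecord] = []
    excluded = 0
    for f in features:
        if f.kind != "gene" or f.feature_id not in expr:
            continue
        vec = assign_gene_marks(f.start, f.end, ps, pe, marks, mark_rule)
        cls = assign_gene_timing(f.start, f.end, segments)
        if vec is None or cls is None:
            excluded += 1
            continue
        e = expr[f.feature_id]
        out.append(GeneRecord(
            gene_id=f.feature_id, chrom=f.chrom, start=f.start, end=f.end,
            strand=f.strand, marks=vec, pattern=pattern_of(*vec),
            present=e.present, level=e.level, cls=cls))
    return out, excluded


def pattern_activity_table(genes: list[GeneRecord]) -> list[StatResult]:
    """Per-pattern activity: n, mean level, % present, exact binomial test
    of the pattern's activity against the overall activity rate; ordered
    by descending observed activity."""
    if not genes:
        return []
    p0 = np.mean([g.present for g in genes])
    rows = []
    for pat in range(1, 17):
        grp = [g for g in genes if g.pattern == pat]
        if not grp:
            continue
        x = sum(g.present for g in grp)
        n = len(grp)
        rows.append(StatResult(
            group=f"pattern {pat}", feature="activity", n=n,
            estimate=100.0 * x / n, reference=100.0 * float(p0),
            statistic=float(np.mean([g.level for g in grp])), df=np.nan,
            p_value=binomial_test_two_sided(x, n, float(p0))))
    rows.sort(key=lambda r: -r.estimate)
    return rows


def hypergeom_one_sided(x: int, N: int, K: int, n: int
                        ) -> tuple[float, float]:
    """(over, under) one-sided hypergeometric p-values for drawing x
    class-K genes in a sample of n from a population of N."""
    over = float(sps.hypergeom.sf(x - 1, N, K, n))
    under = float(sps.hypergeom.cdf(x, N, K, n))
    return over, under


def timing_enrichment_table(genes: list[GeneRecord]) -> list[dict]:
    """Pattern x timing-class representation, hypergeometric one-sided
    tests in both directions; the reported p is the smaller, with the
    direction flagged."""
    N = len(genes)
    out = []
    for pat in range(1, 17):
        grp = [g for g in genes if g.pattern == pat]
        if not grp:
            continue
        n = len(grp)
        for c in CLASS_ORDER:
            K = sum(g.cls == c for g in genes)
            if K == 0:
                continue
            x = sum(g.cls == c for g in grp)
            over, under = hypergeom_one_sided(x, N, K, n)
            direction = "over" if over <= under else "under"
            out.append({
                "pattern": pat, "cls": c, "n": n, "x": x,
                "pct": 100.0 * x / n,
                "expected_pct": 100.0 * K / N,
                "p_over": over, "p_under": under,
                "p_value": min(over, under), "direction": direction,
            })
    return out


def activity_by_timing(genes: list[GeneRecord]) -> list[StatResult]:
    """Per-timing-class activity vs the overall activity rate, plus an
    'all genes' row reproducing the unconditional rate."""
    if not genes:
        return []
    p0 = float(np.mean([g.present for g in genes]))
    rows = [StatResult(
        group="all", feature="activity", n=len(genes),
        estimate=100.0 * p0, reference=100.0 * p0,
        statistic=float(np.mean([g.level for g in genes])), df=np.nan,
        p_value=1.0)]
    for c in CLASS_ORDER:
        grp = [g for g in genes if g.cls == c]
        if not grp:
            continue
        x = sum(g.present for g in grp)
        rows.append(StatResult(
            group=c, feature="activity", n=len(grp),
            estimate=100.0 * x / len(grp), reference=100.0 * p0,
            statistic=float(np.mean([g.level for g in grp])), df=np.nan,
            p_value=binomial_test_two_sided(x, len(grp), p0)))
    return rows


def intergenic_regions(gene_ivs: list[tuple[int, int]],
                       extent: tuple[int, int]) -> list[tuple[int, int]]:
    """Complement of the union of gene intervals within the probed extent."""
    lo, hi = extent
    merged = []
    for s, e in sorted(gene_ivs):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([max(s, lo), min(e, hi)])
    out = []
    cur = lo
    for s, e in merged:
        if s > cur:
            out.append((cur, s))
        cur = max(cur, e)
    if cur < hi:
        out.append((cur, hi))
    return [iv for iv in out if iv[1] > iv[0]]


def element_distribution_in_replicons(elements: list[tuple[int, int]],
                                      replicons, alpha: float = 0.05):
    """Bin (1-5) counts of elements by midpoint position in their replicon,
    with exact binomial CIs on the per-bin share of elements.

    Elements whose midpoint falls outside every replicon are dropped;
    elements spanning a boundary are assigned by midpoint.
    """
    from statsmodels.stats.proportion import proportion_confint
    from .feature_stats import assign_bins

    counts = np.zeros(5, dtype=int)
    for s, e in elements:
        mid = 0.5 * (s + e)
        for r in replicons:
            if r.start <= mid < r.end:
                b = assign_bins(np.array([mid]), r.start, r.end)[0]
                counts[b - 1] += 1
                break
    total = int(counts.sum())
    props = counts / total if total else np.full(5, np.nan)
    lo = np.full(5, np.nan)
    hi = np.full(5, np.nan)
    if total:
        for b in range(5):
            lo[b], hi[b] = proportion_confint(counts[b], total, alpha=alpha,
                                              method="beta")
    return counts, props, (lo, hi)
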
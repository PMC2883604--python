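"""Initiation/termination zones, replicon boundaries, replicons, domains.

Zones come from local extrema of the smoothed per-fraction profiles: in
the early and mid profiles maxima mark initiation and minima termination;
in the late profile the roles flip.  Each extremum seeds a 10-kb zone,
overlapping same-kind zones merge, and replicon boundaries are then
selected from termination zones by a three-tier precedence:

    1. late-profile termination zones confirmed (within a tolerance) by
       termination zones in both the early and the mid profile;
    2. remaining late-profile termination zones;
    3. remaining early/mid termination zones falling inside reconciled
       EM segments.

Replicons are the intervals between consecutive boundaries; runs of
adjacent replicons sharing a dominant timing class form replication
domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import CLASS_ORDER, TimingSegment

__all__ = [
    "Zone",
    "Replicon",
    "Domain",
    "find_extrema",
    "make_zones",
    "assign_zone_timing",
    "match_zones",
    "select_boundaries",
    "build_replicons",
    "cluster_domains",
]


@dataclass(frozen=True)
class Zone:
    kind: str  # "initiation" | "termination"
    chrom: str
    start: float
    end: float
    source_fractions: frozenset = frozenset()
    cls: str = "I"

    @property
    def anchor(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class Replicon:
    chrom: str
    start: float
    end: float
    composition: dict[str, float] = field(default_factory=dict)
    cls: str = "I"
    init_zones: list[Zone] = field(default_factory=list)
    term_left: object = None  # bounding Zone or "chrom_end"
    term_right: object = None
    n_probes: int = 0

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class Domain:
    chrom: str
    start: float
    end: float
    cls: str
    replicon_ids: tuple[int, ...]

    @property
    def length(self) -> float:
        return self.end - self.start


def find_extrema(values: np.ndarray) -> tuple[list[int], list[int]]:
    """Indices of local maxima and minima of a profile.

    Plateaus (runs of exactly equal values) collapse to their midpoint
    index, taking the left-of-center probe when the run has even length.
    Runs touching either chromosome end are excluded.
    """
    v = np.asarray(getattr(values, "values", values), float)
    n = v.size
    if n < 3:
        return [], []
    # run-length encode
    run_starts = [0]
    for i in range(1, n):
        if v[i] != v[i - 1]:
            run_starts.append(i)
    run_starts.append(n)
    maxima, minima = [], []
    for k in range(1, len(run_starts) - 2):
        s, e = run_starts[k], run_starts[k + 1]  # run [s, e)
        left, right = v[s - 1], v[e]
        mid = s + (e - s - 1) // 2  # left-of-center on even plateaus
        if v[s] > left and v[s] > right:
            maxima.append(mid)
        elif v[s] < left and v[s] < right:
            minima.append(mid)
    return maxima, minima


def _merge_intervals(ivs: list[tuple[float, float]]) -> list[tuple[float, float]]:
    out: list[list[float]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def make_zones(maxima: list[int], minima: list[int], centers: np.ndarray,
               fraction: str, chrom_length: float, chrom: str = "",
               width: float = 10_000.0) -> tuple[list[Zone], list[Zone]]:
    """Turn profile extrema into (initiation, termination) zone lists.

    For the early and mid fractions maxima are initiation and minima
    termination; for the late fraction the mapping flips.  Zones are
    width-bp intervals centered on the extremal probe, clipped to the
    chromosome; overlapping same-kind zones merge to their union.
    """
    centers = np.asarray(centers, float)
    if fraction in ("early", "mid"):
        init_idx, term_idx = maxima, minima
    elif fraction == "late":
        init_idx, term_idx = minima, maxima
    else:
        raise ValueError(f"unknown fraction {fraction!r}")

    def zones_of(idx: list[int], kind: str) -> list[Zone]:
        ivs = [
            (max(0.0, centers[i] - width / 2),
             min(chrom_length, centers[i] + width / 2))
            for i in idx
        ]
        return [Zone(kind=kind, chrom=chrom, start=s, end=e,
                     source_fractions=frozenset([fraction]))
                for s, e in _merge_intervals(ivs)]

    return zones_of(init_idx, "initiation"), zones_of(term_idx, "termination")


def assign_zone_timing(zone: Zone, starts: np.ndarray, ends: np.ndarray,
                       probe_cls: list[str]) -> str:
    """Timing class of a zone: overlap-length plurality over the classes
    of its constituent probes, ties broken by the fixed class order.

    A zone containing no probes is classed I.
    """
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    ov = np.minimum(ends, zone.end) - np.maximum(starts, zone.start)
    lengths = {c: 0.0 for c in CLASS_ORDER}
    for i in np.flatnonzero(ov > 0):
        lengths[probe_cls[i]] += float(ov[i])
    if not any(lengths.values()):
        return "I"
    best = max(lengths.values())
    for c in CLASS_ORDER:
        if lengths[c] == best:
            return c
    return "I"  # unreachable


def with_timing(zones: list[Zone], starts, ends, probe_cls) -> list[Zone]:
    return [
        Zone(kind=z.kind, chrom=z.chrom, start=z.start, end=z.end,
             source_fractions=z.source_fractions,
             cls=assign_zone_timing(z, starts, ends, probe_cls))
        for z in zones
    ]


def match_zones(zones_a: list[Zone], zones_b: list[Zone],
                tol: float = 20_000.0) -> tuple[list[tuple[int, int]], float]:
    """Greedy nearest-center matching of two same-kind zone lists.

    Pairs are formed in order of increasing center distance, each zone
    used at most once, distances above ``tol`` excluded.  Returns the
    matched index pairs and the matched fraction of ``zones_a``.
    """
    pairs = []
    cand = sorted(
        (abs(za.anchor - zb.anchor), i, j)
        for i, za in enumerate(zones_a)
        for j, zb in enumerate(zones_b)
        if abs(za.anchor - zb.anchor) <= tol
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    for _, i, j in cand:
        if i in used_a or j in used_b:
            continue
        pairs.append((i, j))
        used_a.add(i)
        used_b.add(j)
    frac = len(pairs) / len(zones_a) if zones_a else 0.0
    return pairs, frac


def select_boundaries(term_early: list[Zone], term_mid: list[Zone],
                      term_late: list[Zone],
                      em_segments: list[TimingSegment],
                      tol: float = 20_000.0, min_sep: float = 20_000.0,
                      tier2_require_L: bool = False,
                      init_zones: list[Zone] | None = None
                      ) -> list[tuple[float, int]]:
    """Replicon boundaries from termination zones, by tier precedence.

    Tier 1: late-profile termination zones matched (<= tol, greedy
    nearest-center) by a termination zone in *both* the early and mid
    lists; the boundary sits at the center of the merged union of the
    three zones.  Tier 2: remaining late-profile termination zones
    (optionally only those whose timing class contains L).  Tier 3:
    remaining early/mid termination zones whose centers fall inside
    reconciled EM segments.  Boundaries closer than ``min_sep`` merge to
    their midpoint, keeping the better (lower) tier.  Returns sorted
    (position, tier) tuples.

    When ``init_zones`` is given, a Tier-3 candidate that overlaps an
    initiation zone called from a different fraction is discarded: a site
    that two profiles identify as initiation is not a termination zone,
    even if the remaining profile shows a local minimum there (the mid
    fraction dips at origins because mid-S labeling probability is not
    monotone in replication time).
    """
    boundaries: list[tuple[float, int]] = []
    pairs_e, _ = match_zones(term_late, term_early, tol)
    pairs_m, _ = match_zones(term_late, term_mid, tol)
    e_of = dict(pairs_e)
    m_of = dict(pairs_m)
    used_late: set[int] = set()
    used_early: set[int] = set()
    used_mid: set[int] = set()
    for i, zl in enumerate(term_late):
        if i in e_of and i in m_of:
            ze, zm = term_early[e_of[i]], term_mid[m_of[i]]
            s = min(zl.start, ze.start, zm.start)
            e = max(zl.end, ze.end, zm.end)
            boundaries.append((0.5 * (s + e), 1))
            used_late.add(i)
            used_early.add(e_of[i])
            used_mid.add(m_of[i])
    for i, zl in enumerate(term_late):
        if i in used_late:
            continue
        if tier2_require_L and "L" not in zl.cls:
            continue
        boundaries.append((zl.anchor, 2))
        used_late.add(i)
    em_ivs = [(s.start, s.end) for s in em_segments if s.cls == "EM"]
    for zones, used in ((term_early, used_early), (term_mid, used_mid)):
        for j, z in enumerate(zones):
            if j in used:
                continue
            if not any(s <= z.anchor < e for s, e in em_ivs):
                continue
            if init_zones is not None and any(
                iz.start < z.end and z.start < iz.end
                and not (iz.source_fractions & z.source_fractions)
                for iz in init_zones
            ):
                continue
            boundaries.append((z.anchor, 3))
    boundaries.sort()
    # merge near-duplicates to their midpoint, keeping the best tier
    merged: list[tuple[float, int]] = []
    k = 0
    while k < len(boundaries):
        group = [boundaries[k]]
        while (k + 1 < len(boundaries)
               and boundaries[k + 1][0] - group[-1][0] < min_sep):
            k += 1
            group.append(boundaries[k])
        pos = sum(p for p, _ in group) / len(group)
        tier = min(t for _, t in group)
        merged.append((pos, tier))
        k += 1
    return merged


def build_replicons(boundaries: list[float], starts: np.ndarray,
                    ends: np.ndarray, probe_cls: list[str],
                    init_zones: list[Zone], chrom: str = "",
                    chrom_length: float | None = None) -> list[Replicon]:
    """Replicons between consecutive boundaries (chromosome ends close the
    terminal intervals); composition = per-class probe-length fractions;
    dominant class by plurality with the fixed tie order."""
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    positions = [p for p in sorted(b[0] if isinstance(b, tuple) else b
                                   for b in boundaries)]
    lo = float(starts[0]) if len(starts) else 0.0
    hi = float(ends[-1]) if len(ends) else 0.0
    if chrom_length is not None:
        hi = float(chrom_length)
    edges = [lo] + [p for p in positions if lo < p < hi] + [hi]
    merged_inits = _merge_intervals([(z.start, z.end) for z in init_zones])
    out: list[Replicon] = []
    for s, e in zip(edges, edges[1:]):
        ov = np.minimum(ends, e) - np.maximum(starts, s)
        idx = np.flatnonzero(ov > 0)
        lengths = {c: 0.0 for c in CLASS_ORDER}
        for i in idx:
            lengths[probe_cls[i]] += float(ov[i])
        total = sum(lengths.values())
        comp = {c: (lengths[c] / total if total else 0.0) for c in CLASS_ORDER}
        if total:
            best = max(comp.values())
            cls = next(c for c in CLASS_ORDER if comp[c] == best)
        else:
            cls = "I"
        contained = [Zone(kind="initiation", chrom=chrom, start=zs, end=ze)
                     for zs, ze in merged_inits if s <= 0.5 * (zs + ze) < e]
        out.append(Replicon(chrom=chrom, start=s, end=e, composition=comp,
                            cls=cls, init_zones=contained,
                            n_probes=int(idx.size)))
    return out


def cluster_domains(replicons: list[Replicon]) -> list[Domain]:
    """Maximal runs of adjacent replicons with identical dominant class."""
    domains: list[Domain] = []
    i = 0
    while i < len(replicons):
        j = i
        while (j + 1 < len(replicons)
               and replicons[j + 1].cls == replicons[i].cls):
            j += 1
        domains.append(Domain(
            chrom=replicons[i].chrom, start=replicons[i].start,
            end=replicons[j].end, cls=replicons[i].cls,
            replicon_ids=tuple(range(i, j + 1)),
        ))
        i = j + 1
    return domains
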
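"""Per-fraction enrichment segmentation and cross-fraction timing classes.

A fraction's enriched segments are maximal runs of probes whose smoothed
log2 ratio is positive, kept only when the run spans at least 10 kb.
Reconciling the early/mid/late segmentations assigns each probe a 3-bit
membership vector which maps onto eight timing classes:

    100 -> E, 110 -> EM, 010 -> M, 011 -> ML,
    001 -> L, 101 -> EL, 111 -> EML, 000 -> I
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TimingSegment",
    "CLASS_ORDER",
    "call_segments",
    "reconcile_segments",
    "probe_classes",
    "class_composition",
]

#: fixed class order, also the tie-break precedence used downstream
CLASS_ORDER = ("E", "EM", "M", "ML", "L", "EL", "EML", "I")

#: (early, mid, late) membership bits -> timing class
BITS_TO_CLASS = {
    (1, 0, 0): "E",
    (1, 1, 0): "EM",
    (0, 1, 0): "M",
    (0, 1, 1): "ML",
    (0, 0, 1): "L",
    (1, 0, 1): "EL",
    (1, 1, 1): "EML",
    (0, 0, 0): "I",
}


@dataclass(frozen=True)
class TimingSegment:
    chrom: str
    start: int
    end: int
    cls: str
    n_probes: int

    def __post_init__(self) -> None:
        if self.cls not in CLASS_ORDER:
            raise ValueError(f"unknown timing class {self.cls!r}")
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")


def call_segments(starts: np.ndarray, ends: np.ndarray,
                  smoothed: np.ndarray, min_len: int = 10_000
                  ) -> list[tuple[int, int]]:
    """Maximal runs of probes with smoothed value > 0 spanning >= min_len.

    Interval coordinates are the run's probe span (first probe start to
    last probe end).  Positive runs shorter than min_len are discarded;
    sub-threshold negative gaps are never bridged.
    """
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    v = np.asarray(getattr(smoothed, "values", smoothed), float)
    if not (len(starts) == len(ends) == len(v)):
        raise ValueError("probe coordinates and profile must align")
    pos = v > 0
    segs = []
    i = 0
    n = len(v)
    while i < n:
        if pos[i]:
            j = i
            while j + 1 < n and pos[j + 1]:
                j += 1
            s, e = int(starts[i]), int(ends[j])
            if e - s >= min_len:
                segs.append((s, e))
            i = j + 1
        else:
            i += 1
    return segs


def _membership(starts: np.ndarray, ends: np.ndarray,
                segs: list[tuple[int, int]]) -> np.ndarray:
    """Probe-in-segment indicator by probe start containment.

    Segments come from runs on the same probe grid, so a probe belongs to
    a segment exactly when its start lies inside it.
    """
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    m = np.zeros(len(starts), dtype=bool)
    lo, hi = int(starts.min(initial=0)), int(ends.max(initial=0))
    for s, e in segs:
        if s < lo or e > hi:
            raise ValueError("fraction segment outside probe extent")
        m |= (starts >= s) & (starts < e)
    return m


def probe_classes(starts, ends, early_segs, mid_segs, late_segs) -> list[str]:
    """Per-probe timing class from the 3-bit membership vector."""
    bits = [
        _membership(starts, ends, early_segs),
        _membership(starts, ends, mid_segs),
        _membership(starts, ends, late_segs),
    ]
    return [
        BITS_TO_CLASS[(int(bits[0][i]), int(bits[1][i]), int(bits[2][i]))]
        for i in range(len(bits[0]))
    ]


def reconcile_segments(early_segs, mid_segs, late_segs,
                       starts, ends, chrom: str = "") -> list[TimingSegment]:
    """Merge the three per-fraction segmentations into timing segments.

    Maximal runs of probes with equal class become segments; no minimum
    length applies at this step, and the segments tile the probe-covered
    extent exactly.
    """
    cls = probe_classes(starts, ends, early_segs, mid_segs, late_segs)
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    out: list[TimingSegment] = []
    i = 0
    n = len(cls)
    while i < n:
        j = i
        while j + 1 < n and cls[j + 1] == cls[i]:
            j += 1
        # extend to the next probe's start so segments tile without gaps
        end = int(starts[j + 1]) if j + 1 < n else int(ends[j])
        out.append(TimingSegment(chrom=chrom, start=int(starts[i]), end=end,
                                 cls=cls[i], n_probes=j - i + 1))
        i = j + 1
    return out


def class_composition(segments: list[TimingSegment],
                      regions: list[tuple[str, int, int]]
                      ) -> dict[str, dict[str, float]]:
    """Length-weighted class fractions per named region.

    ``regions`` is a list of (name, start, end); regions must not
    overlap.  Fractions are of the probe-covered bases falling in the
    region and sum to one.
    """
    ivs = sorted((s, e, name) for name, s, e in regions)
    for (s0, e0, _), (s1, _, _) in zip(ivs, ivs[1:]):
        if s1 < e0:
            raise ValueError("regions overlap")
    out: dict[str, dict[str, float]] = {}
    for name, rs, re_ in regions:
        lengths = {c: 0 for c in CLASS_ORDER}
        for seg in segments:
            ov = min(seg.end, re_) - max(seg.start, rs)
            if ov > 0:
                lengths[seg.cls] += ov
        total = sum(lengths.values())
        out[name] = {c: (lengths[c] / total if total else 0.0)
                     for c in CLASS_ORDER}
    return out
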
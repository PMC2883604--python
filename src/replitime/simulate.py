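"""Synthetic-chromosome simulator with full ground truth.

Generates a tiling-probe grid over a single chromosome, a stochastic
biphasic origin-firing program, per-fraction BrdU-labeling probabilities,
noisy per-replicate log2 enrichment ratios, and correlated gene/TE
annotation, epigenetic-mark calls and expression values.

The generative model
--------------------
Origins are drawn along the chromosome by a renewal process with
gamma-distributed inter-origin spacing.  Each origin belongs to one of two
firing families (early or late) and receives a mean firing time drawn
uniformly from its family's firing window.  Replication time at position x
is the first-passage time of the nearest fork,

    t(x) = min over origins o of  clip(f_o + |x - o| / fork_speed, 0, 1),

so t is piecewise linear with slope +-1/fork_speed between origins, has
local minima at origins and exactly one local maximum (a termination site)
between consecutive origins.

Cell-to-cell variability in firing time is modelled as Gaussian jitter on
f_o.  The probability that a probe is labeled in S-phase fraction w (a
half-open window [a, b) of S-phase time) then has the closed form

    p_w(x) = Phi((b - mu) / sd) - Phi((a - mu) / sd),   mu = t*(x)

applied to the nearest origin's (unclipped) contribution t*(x), with the
outermost window edges extended to +-infinity so that clipping mass at 0
and 1 is attributed to the first and last windows and the three
probabilities sum to one exactly.

Observed per-replicate ratios are
``signal_gain * log2((p_w + eps) / (1/3)) + Normal(0, noise_sd)``:
enrichment relative to the uniform 1/3 expectation, on a log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "SimConfig",
    "Probe",
    "GenomicFeature",
    "MarkCalls",
    "GeneExpression",
    "GroundTruth",
    "simulate_chromosome",
    "simulate_marks_genes",
    "labeling_probabilities",
]

FRACTIONS = ("early", "mid", "late")

#: floor inside log2 so that p_w == 0 never yields -inf
EPS = 1e-6


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic chromosome.

    Lengths are in bp, times in S-phase units (S phase spans [0, 1]),
    ratios in log2 units.
    """

    chrom_length: int = 6_000_000
    chrom: str = "chr4"
    probe_length: int = 1_000
    origin_spacing_mean: float = 107_000.0
    origin_spacing_shape: float = 12.0
    p_early_family: float = 0.5
    #: probability the next origin inherits its neighbor's family (runs of
    #: like-family origins make replication domains; the marginal family
    #: frequency stays at p_early_family)
    family_persistence: float = 0.75
    firing_window_early: tuple[float, float] = (0.28, 0.38)
    firing_window_late: tuple[float, float] = (0.72, 0.92)
    #: cell-to-cell firing-time dispersion of early-family origins; large,
    #: so a euchromatic locus is labeled in early S in some cells and mid S
    #: in others (stochastic activation)
    firing_jitter_sd: float = 0.30
    #: dispersion of late-family origins; heterochromatin replicates
    #: consistently late
    firing_jitter_sd_late: float = 0.18
    fork_speed: float = 270_000.0  # bp per S-phase unit
    fraction_windows: tuple[tuple[float, float], ...] = (
        (0.0, 1.0 / 3.0),
        (1.0 / 3.0, 2.0 / 3.0),
        (2.0 / 3.0, 1.0),
    )
    signal_gain: float = 1.5
    noise_sd: float = 0.3
    n_replicates: int = 3
    # --- marks ---------------------------------------------------------
    # P(mark | d, family) = intercept + slope * d, d = scaled distance to
    # the nearest origin within the true replicon (0 at origin, 1 at edge)
    k56_early: tuple[float, float] = (0.50, -0.20)
    k56_late: tuple[float, float] = (0.40, -0.15)
    k9_early: tuple[float, float] = (0.05, 0.0)
    k9_late: tuple[float, float] = (0.30, 0.0)
    mc_early: tuple[float, float] = (0.20, 0.15)
    mc_late: tuple[float, float] = (0.42, 0.0)
    k4_early: tuple[float, float] = (0.30, 0.12)
    k4_late: tuple[float, float] = (0.38, 0.0)
    # --- genes / TEs ---------------------------------------------------
    gene_rate: float = 200.0  # genes per Mb, chromosome-wide budget
    te_rate: float = 100.0  # TEs per Mb
    gene_length_mean: float = 2_000.0
    gene_length_sd: float = 500.0
    te_length_mean: float = 1_000.0
    te_length_sd: float = 400.0
    # gene placement intensity rises with d in early-family replicons
    gene_d_slope: float = 0.8
    # TE intensity multiplier in late-family replicons
    te_late_factor: float = 2.5
    # presence ~ logistic(b0 + b_k56 * k56_frac + b_k9 * k9_frac)
    presence_b0: float = 0.35
    presence_b_k56: float = 1.2
    presence_b_k9: float = -2.5
    level_present: tuple[float, float] = (6.0, 1.5)
    level_absent: tuple[float, float] = (3.5, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        wins = self.fraction_windows
        if len(wins) != 3:
            raise ValueError("exactly three fraction windows are required")
        if abs(wins[0][0] - 0.0) > 1e-12 or abs(wins[-1][1] - 1.0) > 1e-12:
            raise ValueError("fraction windows must span [0, 1]")
        for (a0, b0), (a1, _) in zip(wins, wins[1:]):
            if b0 <= a0 or abs(b0 - a1) > 1e-12:
                raise ValueError("fraction windows must partition [0, 1]")
        for lo, hi in (self.firing_window_early, self.firing_window_late):
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError("firing windows must lie within [0, 1]")
        if self.fork_speed <= 0:
            raise ValueError("fork_speed must be positive")
        if self.probe_length <= 0 or self.chrom_length % self.probe_length:
            raise ValueError("probe_length must divide chrom_length")
        for name in ("k56", "k9", "mc", "k4"):
            for fam in ("early", "late"):
                b, m = getattr(self, f"{name}_{fam}")
                for d in (0.0, 1.0):
                    if not 0.0 <= b + m * d <= 1.0:
                        raise ValueError(
                            f"mark probability {name}_{fam} leaves [0,1]"
                        )

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Probe:
    """One tiling-array element; coordinates 0-based half-open."""

    probe_id: str
    chrom: str
    start: int
    end: int
    gc: float
    #: ratios[fraction] -> array of per-replicate log2 enrichment values
    ratios: dict[str, np.ndarray]

    @property
    def center(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class GenomicFeature:
    feature_id: str
    kind: str  # "gene" | "TE"
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("feature end must exceed start")
        if self.kind not in ("gene", "TE"):
            raise ValueError("kind must be 'gene' or 'TE'")


@dataclass(frozen=True)
class MarkCalls:
    probe_id: str
    k4: bool
    k9: bool
    k56: bool
    mc: bool


@dataclass(frozen=True)
class GeneExpression:
    gene_id: str
    present: bool
    level: float


@dataclass(frozen=True)
class GroundTruth:
    """Simulator-side record used by recovery tests."""

    #: (position, family, mean firing time) per origin, sorted by position
    origins: list[tuple[float, str, float]]
    #: positions of the local maxima of t(x) (one between consecutive origins)
    true_boundaries: np.ndarray
    #: per probe: set of fraction names with labeling probability > 1/3
    true_probe_class: list[frozenset]
    #: per probe: expected replication time t(x) in [0, 1]
    true_reptime: np.ndarray


# ---------------------------------------------------------------------------


def _draw_origins(cfg: SimConfig, rng: np.random.Generator):
    """Renewal process with gamma inter-origin spacings covering the
    chromosome; origins outside [0, L) are kept as flanking context so
    that t(x) has no edge artifacts, but only interior origins are
    reported in the truth record."""
    shape = cfg.origin_spacing_shape
    scale = cfg.origin_spacing_mean / shape
    positions = []
    # start one spacing before the chromosome to avoid an edge effect
    x = -rng.gamma(shape, scale)
    while x < cfg.chrom_length + cfg.origin_spacing_mean:
        positions.append(x)
        x += rng.gamma(shape, scale)
    positions = np.asarray(positions)
    # Markov family chain: keep the left neighbor's family with probability
    # family_persistence, otherwise redraw Bernoulli(p_early_family); the
    # stationary early-family frequency is p_early_family and like-family
    # runs form replication domains.
    fam_early = np.empty(positions.size, dtype=bool)
    for k in range(positions.size):
        if k and rng.random() < cfg.family_persistence:
            fam_early[k] = fam_early[k - 1]
        else:
            fam_early[k] = rng.random() < cfg.p_early_family
    lo_e, hi_e = cfg.firing_window_early
    lo_l, hi_l = cfg.firing_window_late
    firing = np.where(
        fam_early,
        rng.uniform(lo_e, hi_e, positions.size),
        rng.uniform(lo_l, hi_l, positions.size),
    )
    return positions, fam_early, firing


def _nearest_origin_time(x: np.ndarray, origins: np.ndarray,
                         firing: np.ndarray, fork_speed: float):
    """Unclipped first-passage time and index of the achieving origin."""
    # pairwise is fine at simulator scales (n_probes x n_origins)
    t_all = firing[None, :] + np.abs(x[:, None] - origins[None, :]) / fork_speed
    idx = np.argmin(t_all, axis=1)
    return t_all[np.arange(x.size), idx], idx


def labeling_probabilities(mu: np.ndarray, jitter_sd: float,
                           windows: Sequence[tuple[float, float]]) -> np.ndarray:
    """P(t in w) per window for t = clip(mu + Normal(0, sd), 0, 1).

    The first window's lower edge and the last window's upper edge are
    treated as -inf/+inf so the clipped mass at 0 and 1 lands in the
    outermost windows and rows sum to one exactly.  With sd -> 0 the
    probabilities degenerate to window-membership indicators.
    """
    mu = np.asarray(mu, dtype=float)
    sd = np.broadcast_to(np.asarray(jitter_sd, dtype=float), mu.shape)
    edges = [w[0] for w in windows] + [windows[-1][1]]
    out = np.empty((mu.size, len(windows)))
    t = np.clip(mu, 0.0, 1.0)
    for j, (a, b) in enumerate(windows):
        last = j == len(windows) - 1
        out[:, j] = ((t >= a) & ((t < b) | (last & (t <= b)))).astype(float)
    pos = sd > 0
    if pos.any():
        cdfs = []
        for k, e in enumerate(edges):
            if k == 0:
                cdfs.append(np.zeros(int(pos.sum())))
            elif k == len(edges) - 1:
                cdfs.append(np.ones(int(pos.sum())))
            else:
                cdfs.append(norm.cdf((e - mu[pos]) / sd[pos]))
        for j in range(len(windows)):
            out[pos, j] = cdfs[j + 1] - cdfs[j]
    return out


def simulate_chromosome(cfg: SimConfig) -> tuple[list[Probe], GroundTruth]:
    """Simulate probes and ground truth for one chromosome.

    Fully reproducible from ``cfg.seed``.
    """
    if cfg.chrom_length < 3 * cfg.origin_spacing_mean:
        raise ValueError(
            "chrom_length must be at least 3x the mean origin spacing "
            "(too few replicons to analyze)"
        )
    rng = np.random.default_rng(cfg.seed)
    origins, fam_early, firing = _draw_origins(cfg, rng)

    n = cfg.chrom_length // cfg.probe_length
    starts = np.arange(n, dtype=np.int64) * cfg.probe_length
    centers = starts + cfg.probe_length / 2.0

    mu, nearest = _nearest_origin_time(centers, origins, firing,
                                       cfg.fork_speed)
    reptime = np.clip(mu, 0.0, 1.0)
    jit_late = (cfg.firing_jitter_sd_late
                if cfg.firing_jitter_sd_late is not None
                else cfg.firing_jitter_sd)
    sd_origin = np.where(fam_early, cfg.firing_jitter_sd, jit_late)
    probs = labeling_probabilities(mu, sd_origin[nearest],
                                   cfg.fraction_windows)

    gc = rng.normal(0.36, 0.04, n).clip(0.2, 0.6)
    clean = cfg.signal_gain * np.log2((probs + EPS) / (1.0 / 3.0))
    probes: list[Probe] = []
    for i in range(n):
        ratios = {}
        for j, frac in enumerate(FRACTIONS):
            noise = rng.normal(0.0, cfg.noise_sd, cfg.n_replicates) \
                if cfg.noise_sd > 0 else np.zeros(cfg.n_replicates)
            ratios[frac] = clean[i, j] + noise
        probes.append(Probe(
            probe_id=f"P{i:06d}", chrom=cfg.chrom,
            start=int(starts[i]), end=int(starts[i]) + cfg.probe_length,
            gc=float(gc[i]), ratios=ratios,
        ))

    # Truth covers the *active* origins only: an origin dominated at its
    # own position by another origin's fork (f_j >= f_i + |o_j - o_i| / v)
    # never fires and, by the triangle inequality, never determines t(x)
    # anywhere; t(x) has no local maximum at such passively replicated
    # origins.  Between consecutive active origins t(x) has exactly one
    # local maximum at the fork-meeting point
    #   xb = (o1 + o2) / 2 + v (f2 - f1) / 2,
    # which is also the midpoint of any clip-at-1 plateau of t(x).
    v = cfg.fork_speed
    active = []
    for j in range(len(origins)):
        others = np.delete(np.arange(len(origins)), j)
        if firing[j] < np.min(firing[others]
                              + np.abs(origins[j] - origins[others]) / v):
            active.append(j)
    boundaries = []
    for a, b in zip(active, active[1:]):
        xb = 0.5 * (origins[a] + origins[b]) + 0.5 * v * (firing[b] - firing[a])
        if 0 <= xb < cfg.chrom_length:
            boundaries.append(xb)
    kept = [j for j in active if 0 <= origins[j] < cfg.chrom_length]

    third = 1.0 / 3.0
    truth = GroundTruth(
        origins=[(float(origins[k]), "early" if fam_early[k] else "late",
                  float(firing[k])) for k in kept],
        true_boundaries=np.asarray(boundaries),
        true_probe_class=[
            frozenset(f for j, f in enumerate(FRACTIONS) if probs[i, j] > third)
            for i in range(n)
        ],
        true_reptime=reptime,
    )
    return probes, truth


# ---------------------------------------------------------------------------
# marks / genes / expression


def _true_replicon_edges(cfg: SimConfig, truth: GroundTruth) -> np.ndarray:
    b = np.asarray(truth.true_boundaries, dtype=float)
    return np.concatenate([[0.0], b, [float(cfg.chrom_length)]])


def scaled_origin_distance(cfg: SimConfig, truth: GroundTruth,
                           positions: np.ndarray):
    """For each position: (d, family) where d in [0, 1] is the distance to
    the replicon's origin scaled by the distance from that origin to the
    replicon edge on the same side."""
    edges = _true_replicon_edges(cfg, truth)
    opos = np.array([o[0] for o in truth.origins])
    ofam = np.array([o[1] == "early" for o in truth.origins])
    positions = np.asarray(positions, dtype=float)
    idx = np.clip(np.searchsorted(edges, positions, side="right") - 1,
                  0, len(edges) - 2)
    d = np.empty(positions.size)
    fam = np.empty(positions.size, dtype=bool)
    for i, (x, k) in enumerate(zip(positions, idx)):
        lo, hi = edges[k], edges[k + 1]
        cand = np.flatnonzero((opos >= lo) & (opos < hi))
        if cand.size == 0:  # flanking origin outside chromosome
            j = int(np.argmin(np.abs(opos - x)))
        else:
            j = cand[int(np.argmin(np.abs(opos[cand] - x)))]
        o = opos[j]
        half = (hi - o) if x >= o else (o - lo)
        d[i] = min(abs(x - o) / half, 1.0) if half > 0 else 1.0
        fam[i] = ofam[j]
    return d, fam


def _place_features(cfg: SimConfig, rng: np.random.Generator,
                    d_of, kind: str) -> list[tuple[int, int, str]]:
    """Thinning of a homogeneous Poisson candidate stream by a d/family
    dependent acceptance probability; returns (start, end, strand)."""
    L = cfg.chrom_length
    if kind == "gene":
        rate = cfg.gene_rate / 1e6
        lmean, lsd = cfg.gene_length_mean, cfg.gene_length_sd
    else:
        rate = cfg.te_rate / 1e6
        lmean, lsd = cfg.te_length_mean, cfg.te_length_sd
    lam_max = rate * max(1.0 + cfg.gene_d_slope, cfg.te_late_factor, 1.0)
    n_cand = rng.poisson(lam_max * L)
    xs = np.sort(rng.uniform(0, L, n_cand))
    d, fam_early = d_of(xs)
    if kind == "gene":
        # intensity rises with d (toward termination zones) in early-family
        # replicons; flat elsewhere
        lam = rate * np.where(fam_early, 1.0 + cfg.gene_d_slope * d, 1.0)
    else:
        lam = rate * np.where(fam_early, 1.0, cfg.te_late_factor)
    accept = rng.random(n_cand) < lam / lam_max
    out = []
    last_end = -1
    for x in xs[accept]:
        length = max(200, int(rng.normal(lmean, lsd)))
        s = int(x)
        e = min(s + length, L)
        if s >= e or s <= last_end:  # keep features non-overlapping
            continue
        out.append((s, e, "+" if rng.random() < 0.5 else "-"))
        last_end = e
    return out


def simulate_marks_genes(
    cfg: SimConfig, truth: GroundTruth, probes: list[Probe]
) -> tuple[list[GenomicFeature], list[MarkCalls], list[GeneExpression]]:
    """Generate annotation, per-probe mark calls and per-gene expression
    correlated with the replication program.

    Mark probabilities are linear in the scaled origin distance d with
    family-specific intercepts/slopes; genes are placed by an
    inhomogeneous point process with intensity rising with d inside
    early-family replicons, TEs with elevated intensity in late-family
    replicons; gene presence is logistic in the H3K56ac and H3K9me2
    status of the gene's overlapping probes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    centers = np.array([p.center for p in probes])
    d, fam_early = scaled_origin_distance(cfg, truth, centers)

    def p_of(name):
        be, me_ = getattr(cfg, f"{name}_early")
        bl, ml = getattr(cfg, f"{name}_late")
        return np.where(fam_early, be + me_ * d, bl + ml * d)

    marks: list[MarkCalls] = []
    draws = {name: rng.random(len(probes)) < p_of(name)
             for name in ("k4", "k9", "k56", "mc")}
    for i, p in enumerate(probes):
        marks.append(MarkCalls(
            probe_id=p.probe_id,
            k4=bool(draws["k4"][i]), k9=bool(draws["k9"][i]),
            k56=bool(draws["k56"][i]), mc=bool(draws["mc"][i]),
        ))

    d_of = lambda xs: scaled_origin_distance(cfg, truth, xs)  # noqa: E731
    genes = _place_features(cfg, rng, d_of, "gene")
    tes = _place_features(cfg, rng, d_of, "TE")
    features: list[GenomicFeature] = []
    for k, (s, e, strand) in enumerate(genes):
        features.append(GenomicFeature(f"G{k:05d}", "gene", cfg.chrom,
                                       s, e, strand))
    for k, (s, e, strand) in enumerate(tes):
        features.append(GenomicFeature(f"T{k:05d}", "TE", cfg.chrom,
                                       s, e, strand))
    features.sort(key=lambda f: (f.start, f.end))

    starts = np.array([p.start for p in probes])
    ends = np.array([p.end for p in probes])
    k56v = draws["k56"].astype(float)
    k9v = draws["k9"].astype(float)
    expression: list[GeneExpression] = []
    for f in features:
        if f.kind != "gene":
            continue
        i0 = np.searchsorted(ends, f.start, side="right")
        i1 = np.searchsorted(starts, f.end, side="left")
        if i1 <= i0:
            k56_frac = k9_frac = 0.0
        else:
            k56_frac = float(k56v[i0:i1].mean())
            k9_frac = float(k9v[i0:i1].mean())
        z = (cfg.presence_b0 + cfg.presence_b_k56 * k56_frac
             + cfg.presence_b_k9 * k9_frac)
        present = rng.random() < 1.0 / (1.0 + np.exp(-z))
        m, s = cfg.level_present if present else cfg.level_absent
        expression.append(GeneExpression(
            gene_id=f.feature_id, present=bool(present),
            level=float(rng.normal(m, s)),
        ))
    return features, marks, expression
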
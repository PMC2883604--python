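"""End-to-end pipeline driver: normalize -> smooth -> segment -> zones ->
replicons -> domains -> statistics -> genes, with a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import feature_stats as fs
from . import genes as ga
from . import io as rio
from .profiles import (average_replicates, loess_smooth, profile_correlation,
                       quantile_normalize, decile_rank)
from .replicons import (build_replicons, cluster_domains, find_extrema,
                        make_zones, select_boundaries, with_timing)
from .segmentation import (call_segments, probe_classes, reconcile_segments)
from .simulate import FRACTIONS

log = logging.getLogger("replitime")

__all__ = ["PipelineConfig", "run_pipeline", "analyze"]


@dataclass
class PipelineConfig:
    probes: str = ""
    annotation: str = ""
    marks: str = ""
    expression: str = ""
    outdir: str = "replitime_out"
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)
    window: float = 150_000.0
    min_len: int = 10_000
    zone_width: float = 10_000.0
    tol: float = 20_000.0
    min_sep: float = 20_000.0
    n_min: int = 20
    quartile: float = 0.75
    quantile_normalization: bool = True
    bin_mode: str = "pooled"
    gene_mark_rule: str = "any"
    tier2_require_L: bool = False
    close_ends: bool = True  # chromosome ends close terminal replicons
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window <= 0 or self.min_len <= 0 or self.zone_width <= 0:
            raise ValueError("lengths must be positive")
        if self.tol < self.zone_width / 2:
            raise ValueError("tol must be >= zone_width / 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def analyze(probes, cfg: PipelineConfig):
    """Run the in-memory analysis (no file IO): smoothed profiles,
    segments, zones, boundaries, replicons and domains.

    Returns a dict of intermediate and final objects keyed by stage.
    """
    starts = np.array([p.start for p in probes])
    ends = np.array([p.end for p in probes])
    centers = 0.5 * (starts + ends)
    chrom = probes[0].chrom if probes else ""
    chrom_length = float(ends[-1]) if cfg.close_ends else None

    averaged = {}
    for f in FRACTIONS:
        mat = np.stack([p.ratios[f] for p in probes])
        if cfg.quantile_normalization and mat.shape[1] >= 2 \
                and np.all(np.isfinite(mat)):
            mat = quantile_normalize(mat)
        averaged[f] = average_replicates(mat, centers)

    smoothed = {f: loess_smooth(centers, averaged[f], cfg.window, fraction=f)
                for f in FRACTIONS}
    corr = {
        "early_mid": profile_correlation(smoothed["early"], smoothed["mid"]),
        "early_late": profile_correlation(smoothed["early"], smoothed["late"]),
        "mid_late": profile_correlation(smoothed["mid"], smoothed["late"]),
    }
    deciles = {f: decile_rank(smoothed[f].values) for f in FRACTIONS}

    frac_segs = {f: call_segments(starts, ends, smoothed[f], cfg.min_len)
                 for f in FRACTIONS}
    segments = reconcile_segments(frac_segs["early"], frac_segs["mid"],
                                  frac_segs["late"], starts, ends, chrom)
    cls = probe_classes(starts, ends, frac_segs["early"], frac_segs["mid"],
                        frac_segs["late"])

    init_zones, term_zones = {}, {}
    L = float(ends[-1])
    for f in FRACTIONS:
        maxima, minima = find_extrema(smoothed[f].values)
        iz, tz = make_zones(maxima, minima, centers, f, L, chrom,
                            cfg.zone_width)
        init_zones[f] = with_timing(iz, starts, ends, cls)
        term_zones[f] = with_timing(tz, starts, ends, cls)

    all_inits = [z for f in FRACTIONS for z in init_zones[f]]
    boundaries = select_boundaries(
        term_zones["early"], term_zones["mid"], term_zones["late"],
        segments, tol=cfg.tol, min_sep=cfg.min_sep,
        tier2_require_L=cfg.tier2_require_L, init_zones=all_inits)
    replicons = build_replicons([b for b, _ in boundaries], starts, ends,
                                cls, all_inits, chrom, chrom_length)
    domains = cluster_domains(replicons)

    return {
        "starts": starts, "ends": ends, "centers": centers, "chrom": chrom,
        "averaged": averaged, "smoothed": smoothed, "correlations": corr,
        "deciles": deciles, "fraction_segments": frac_segs,
        "segments": segments, "probe_classes": cls,
        "init_zones": init_zones, "term_zones": term_zones,
        "boundaries": boundaries, "replicons": replicons, "domains": domains,
    }


def _config_hash(cfg: PipelineConfig) -> str:
    # outdir does not affect results, so it is excluded: the same inputs
    # and knobs give the same hash (and byte-identical bundles) wherever
    # the bundle is written
    d = asdict(cfg)
    d.pop("outdir", None)
    blob = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline from files to files.

    Stats and gene stages are skipped (with a notice) when marks or
    annotation/expression inputs are absent; the replicon map is always
    produced.  Output bundles are byte-identical for identical
    (config, inputs).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": _config_hash(cfg), "seed": cfg.seed,
                      "stages": {}, "row_counts": {}, "skipped": []}

    probes = rio.read_probe_table(cfg.probes)
    res = analyze(probes, cfg)

    import pandas as pd
    sm = pd.DataFrame({"probe_id": [p.probe_id for p in probes]})
    for f in FRACTIONS:
        sm[f] = res["smoothed"][f].values
    sm.to_csv(outdir / "smoothed.tsv", sep="\t", index=False,
              float_format="%.6g")

    dec = pd.DataFrame({"probe_id": [p.probe_id for p in probes]})
    for f in FRACTIONS:
        dec[f"{f}_decile"] = res["deciles"][f]
    dec.to_csv(outdir / "deciles.tsv", sep="\t", index=False)

    rio.write_segments_bed(res["segments"], outdir / "segments.bed")
    for kind, zones in (("initiation", res["init_zones"]),
                        ("termination", res["term_zones"])):
        flat = [z for f in FRACTIONS for z in zones[f]]
        rio.write_segments_bed(flat, outdir / f"zones_{kind}.bed")
    rio.write_segments_bed(res["replicons"], outdir / "replicons.bed")
    rio.write_segments_bed(res["domains"], outdir / "domains.bed")
    with open(outdir / "boundaries.tsv", "w") as fh:
        fh.write("position\ttier\n")
        for pos, tier in res["boundaries"]:
            fh.write(f"{pos:.1f}\t{tier}\n")
    with open(outdir / "correlations.json", "w") as fh:
        json.dump({k: round(v, 6) for k, v in res["correlations"].items()},
                  fh, indent=1, sort_keys=True)

    manifest["row_counts"].update({
        "probes": len(probes),
        "segments": len(res["segments"]),
        "replicons": len(res["replicons"]),
        "domains": len(res["domains"]),
        "boundaries": len(res["boundaries"]),
    })

    have_marks = bool(cfg.marks)
    have_genes = bool(cfg.annotation) and bool(cfg.expression)
    if have_marks:
        marks = rio.read_marks(cfg.marks)
        mark_arr = {m_: np.array([getattr(mk, m_) for mk in marks])
                    for m_ in ("k4", "k9", "k56", "mc")}
        features = rio.read_features(cfg.annotation) if cfg.annotation else []
        gene_ivs = [(f.start, f.end) for f in features if f.kind == "gene"]
        te_ivs = [(f.start, f.end) for f in features if f.kind == "TE"]
        cont = {"gc": np.array([p.gc for p in probes])}
        if features:
            cont["gene_coverage"] = np.array([
                fs.compute_coverage(p.start, p.end, gene_ivs) for p in probes])
            cont["te_coverage"] = np.array([
                fs.compute_coverage(p.start, p.end, te_ivs) for p in probes])
        binary = dict(mark_arr)
        binary["at_rich"] = fs.top_quartile_flags(1.0 - cont["gc"])
        if "gene_coverage" in cont:
            binary["gene_rich"] = fs.top_quartile_flags(cont["gene_coverage"])
        tests = fs.probe_class_tests(res["probe_classes"], cont, binary,
                                     n_min=cfg.n_min)
        pd.DataFrame([{
            "group": t.group, "feature": t.feature, "n": t.n,
            "estimate": t.estimate, "reference": t.reference,
            "statistic": t.statistic, "df": t.df, "p_value": t.p_value,
            "code": t.code,
        } for t in tests]).to_csv(outdir / "probe_stats.tsv", sep="\t",
                                  index=False, float_format="%.6g")
        manifest["row_counts"]["probe_stats"] = len(tests)
    else:
        manifest["skipped"].append("probe_stats (no marks input)")
        log.warning("marks input absent: probe/replicon stats skipped")

    if have_marks and have_genes:
        expression = rio.read_expression(cfg.expression)
        records, n_excl = ga.build_gene_records(
            features, probes, marks, expression, res["segments"],
            cfg.gene_mark_rule)
        act = ga.pattern_activity_table(records)
        pd.DataFrame([{
            "group": t.group, "n": t.n, "activity_pct": t.estimate,
            "overall_pct": t.reference, "mean_level": t.statistic,
            "p_value": t.p_value, "code": t.code,
        } for t in act]).to_csv(outdir / "gene_patterns.tsv", sep="\t",
                                index=False, float_format="%.6g")
        tim = ga.activity_by_timing(records)
        pd.DataFrame([{
            "group": t.group, "n": t.n, "activity_pct": t.estimate,
            "mean_level": t.statistic, "p_value": t.p_value, "code": t.code,
        } for t in tim]).to_csv(outdir / "gene_timing.tsv", sep="\t",
                                index=False, float_format="%.6g")
        manifest["row_counts"]["genes"] = len(records)
        manifest["row_counts"]["genes_excluded"] = n_excl
    else:
        manifest["skipped"].append("gene_analysis (missing inputs)")

    used = asdict(cfg)
    used.pop("outdir", None)  # keep bundles byte-identical across outdirs
    with open(outdir / "config_used.yaml", "w") as fh:
        yaml.safe_dump(used, fh, sort_keys=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
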
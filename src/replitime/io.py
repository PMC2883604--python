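"""Readers and writers for probe tables, annotation, marks and expression.

All internal coordinates are 0-based half-open.  BED is read/written
half-open; GFF3 is converted from/to 1-based inclusive on the way through.
Ratio columns follow the naming convention ``<fraction>_r<k>``; a
``_swap`` suffix marks dye-swap replicates whose sign is flipped on read.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import (FRACTIONS, GeneExpression, GenomicFeature, MarkCalls,
                       Probe)

__all__ = [
    "read_probe_table", "write_probe_table",
    "read_features", "write_features_bed", "write_features_gff3",
    "read_marks", "write_marks",
    "read_expression", "write_expression",
    "write_segments_bed", "write_truth", "read_truth",
]

_FLOAT_FMT = "%.6g"


def _ratio_columns(columns) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {f: [] for f in FRACTIONS}
    for c in columns:
        for f in FRACTIONS:
            if c == f or c.startswith(f + "_"):
                out[f].append(c)
    return out


def read_probe_table(path) -> list[Probe]:
    """Read a probe TSV; validates coordinates, sorts by start, flips the
    sign of dye-swap columns (``_swap`` suffix)."""
    df = pd.read_csv(path, sep="\t")
    required = {"probe_id", "chrom", "start", "end"}
    if not required <= set(df.columns):
        raise ValueError(f"probe table must have columns {sorted(required)}")
    rc = _ratio_columns(df.columns)
    for f in FRACTIONS:
        if not rc[f]:
            raise ValueError(f"no ratio columns found for fraction {f!r}")
        for c in rc[f]:
            if not pd.api.types.is_numeric_dtype(df[c]):
                bad = df[~df[c].apply(
                    lambda v: isinstance(v, (int, float)) or pd.isna(v))]
                line = int(bad.index[0]) + 2 if len(bad) else "?"
                raise ValueError(f"non-numeric ratio in column {c}, "
                                 f"line {line}")
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        raise ValueError(f"probe end <= start at line {int(bad[0]) + 2}")
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    for chrom, grp in df.groupby("chrom"):
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        if np.any(s[1:] < e[:-1]):
            i = int(np.flatnonzero(s[1:] < e[:-1])[0])
            raise ValueError(
                f"overlapping probes on {chrom} near line "
                f"{int(grp.index[i + 1]) + 2}")
    probes = []
    for _, row in df.iterrows():
        ratios = {}
        for f in FRACTIONS:
            vals = []
            for c in rc[f]:
                v = row[c]
                if c.endswith("_swap"):
                    v = -v
                vals.append(v)
            ratios[f] = np.asarray(vals, dtype=float)
        probes.append(Probe(
            probe_id=str(row["probe_id"]), chrom=str(row["chrom"]),
            start=int(row["start"]), end=int(row["end"]),
            gc=float(row.get("gc", np.nan)), ratios=ratios))
    return probes


def write_probe_table(probes: list[Probe], path) -> None:
    rows = []
    for p in probes:
        row = {"probe_id": p.probe_id, "chrom": p.chrom,
               "start": p.start, "end": p.end, "gc": p.gc}
        for f in FRACTIONS:
            for k, v in enumerate(p.ratios[f], start=1):
                row[f"{f}_r{k}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format=_FLOAT_FMT)


def read_features(path) -> list[GenomicFeature]:
    """Read gene/TE annotation from BED (0-based half-open) or GFF3
    (1-based inclusive), auto-detected by extension."""
    path = str(path)
    feats: list[GenomicFeature] = []
    if path.endswith((".gff", ".gff3")):
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                chrom, _, ftype, start, end, _, strand = f[:7]
                attrs = dict(kv.split("=", 1)
                             for kv in f[8].split(";") if "=" in kv)
                kind = "TE" if "transposable" in ftype.lower() \
                    or ftype.upper() == "TE" else "gene"
                feats.append(GenomicFeature(
                    feature_id=attrs.get("ID", f"{ftype}_{start}"),
                    kind=kind, chrom=chrom,
                    start=int(start) - 1, end=int(end),
                    strand=strand if strand in "+-" else "+"))
    elif path.endswith(".bed"):
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name = f[3] if len(f) > 3 else f"feat_{start}"
                strand = f[5] if len(f) > 5 and f[5] in "+-" else "+"
                kind = "TE" if name.startswith("T") else "gene"
                feats.append(GenomicFeature(feature_id=name, kind=kind,
                                            chrom=chrom, start=start,
                                            end=end, strand=strand))
    else:
        raise ValueError("annotation must be .bed, .gff or .gff3")
    feats.sort(key=lambda f: (f.chrom, f.start, f.end))
    return feats


def write_features_bed(features: list[GenomicFeature], path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.feature_id}\t0\t"
                     f"{f.strand}\n")


def write_features_gff3(features: list[GenomicFeature], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            ftype = "gene" if f.kind == "gene" else "transposable_element"
            fh.write(f"{f.chrom}\treplitime\t{ftype}\t{f.start + 1}\t"
                     f"{f.end}\t.\t{f.strand}\t.\tID={f.feature_id}\n")


def read_marks(path) -> list[MarkCalls]:
    df = pd.read_csv(path, sep="\t")
    return [MarkCalls(probe_id=str(r.probe_id), k4=bool(r.k4), k9=bool(r.k9),
                      k56=bool(r.k56), mc=bool(r.mc))
            for r in df.itertuples()]


def write_marks(marks: list[MarkCalls], path) -> None:
    pd.DataFrame([{"probe_id": m.probe_id, "k4": int(m.k4), "k9": int(m.k9),
                   "k56": int(m.k56), "mc": int(m.mc)} for m in marks]
                 ).to_csv(path, sep="\t", index=False)


def read_expression(path) -> list[GeneExpression]:
    df = pd.read_csv(path, sep="\t")
    return [GeneExpression(gene_id=str(r.gene_id), present=bool(r.present),
                           level=float(r.level)) for r in df.itertuples()]


def write_expression(expression: list[GeneExpression], path) -> None:
    pd.DataFrame([{"gene_id": e.gene_id, "present": int(e.present),
                   "level": e.level} for e in expression]
                 ).to_csv(path, sep="\t", index=False,
                          float_format=_FLOAT_FMT)


def write_segments_bed(segments, path) -> None:
    """BED4: chrom, start, end, class (works for segments, zones with a
    kind/cls name, replicons and domains)."""
    with open(path, "w") as fh:
        for s in segments:
            name = getattr(s, "cls", getattr(s, "kind", "."))
            fh.write(f"{s.chrom}\t{int(s.start)}\t{int(s.end)}\t{name}\n")


def write_truth(truth, path_origins, path_boundaries) -> None:
    pd.DataFrame(truth.origins,
                 columns=["position", "family", "firing_time"]).to_csv(
        path_origins, sep="\t", index=False, float_format="%.3f")
    pd.DataFrame({"boundary": truth.true_boundaries}).to_csv(
        path_boundaries, sep="\t", index=False, float_format="%.3f")


def read_truth(path_origins, path_boundaries):
    origins = pd.read_csv(path_origins, sep="\t")
    boundaries = pd.read_csv(path_boundaries, sep="\t")
    return ([(float(r.position), str(r.family), float(r.firing_time))
             for r in origins.itertuples()],
            boundaries["boundary"].to_numpy())
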
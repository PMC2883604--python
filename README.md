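# replitime

Replication-timing analysis for tiling-array BrdU-enrichment data, with a
synthetic-chromosome simulator for end-to-end validation.

In a Repli-chip experiment, S-phase nuclei are sorted into early, mid and
late fractions, BrdU-labeled nascent DNA is immunoprecipitated, and each
fraction is hybridized against total DNA on a tiling array. Every probe
then carries three log2(BrdU-IP/input) enrichment ratios. `replitime`
turns those ratios into a replicon map and the statistics that relate
replication time to chromatin state:

1. **Profiles** — replicate averaging, quantile normalization, and loess
   smoothing (locally weighted quadratic regression, tricube weights, in a
   fixed 150-kb genomic window).
2. **Segmentation** — per-fraction enriched segments (smoothed ratio > 0
   over ≥ 10 kb), reconciled across fractions into eight timing classes:
   E, EM, M, ML, L, EL, EML, I (no enrichment).
3. **Replicon map** — initiation/termination zones from profile extrema
   (10-kb zones, overlaps merged), replicon boundaries from termination
   zones by a three-tier precedence (consistent across all three
   fractions ≻ late-profile ≻ early/mid minima inside EM segments),
   replicons between consecutive boundaries, and replication domains as
   runs of like-classed replicons.
4. **Feature statistics** — gene/TE coverage, AT-/gene-rich top-quartile
   flags, one-sample t and exact binomial enrichment tests per timing
   class, Welch comparisons of EM vs L replicons, and a five-bin
   within-replicon metaprofile (bin 1 = innermost 20 %, near initiation;
   bin 5 = outermost, near termination) with Clopper–Pearson intervals.
5. **Gene analysis** — per-gene 4-mark epigenetic patterns (H3K4me1/2,
   H3K9me2, H3K56ac, 5mC; 16 patterns ranked by activity), timing classes
   by overlap plurality, exact binomial activity tests and hypergeometric
   pattern × timing enrichment.

The `simulate` module generates a synthetic chromosome under a stochastic
biphasic origin-firing model — gamma-spaced origins in clustered
early/late families, per-cell Gaussian firing-time dispersion, fork
elongation at constant speed, closed-form labeling probabilities per
S-phase window — together with mark calls, gene/TE annotation and
expression values correlated with the replication program, plus the full
ground truth (origins, fork-meeting boundaries, per-probe classes) so that
every pipeline stage can be validated against a known answer.

## Worked example

```python
import numpy as np
import replitime as rt

cfg = rt.SimConfig(seed=1)                      # 6-Mb chromosome
probes, truth = rt.simulate_chromosome(cfg)
res = rt.analyze(probes, rt.PipelineConfig(seed=1))

print(res["correlations"])
reps = [r for r in res["replicons"] if r.n_probes > 0]
print(len(reps), np.median([r.length for r in reps]) / 1000)
```

prints

```
{'early_mid': 0.9630..., 'early_late': -0.8971..., 'mid_late': -0.7906...}
43 108.0
```

The early and mid profiles are nearly interchangeable (r = +0.96; origin
firing in the first half of S phase is stochastic, so both fractions label
the same euchromatic sequences) while early and late are complementary
(r = −0.90). The smoothed profiles yield 43 replicons with a median length
of 108 kb, organised into 8 alternating early/late replication domains.
Longer narrative walk-throughs — boundary recovery against ground truth,
timing-class composition, the H3K56ac metaprofile, gene-pattern activity
tables — are in `examples/`; each prints the numbers it computes and a
line on what they mean.

A thin CLI mirrors the library for shell use:

```bash
replitime simulate --seed 1 --outdir sim/
replitime run --config pipeline.yaml          # files in, files out
replitime smooth|segment|replicons|stats|genes ...
```

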
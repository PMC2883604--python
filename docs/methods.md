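# Methods

## The measurement being modelled

Sorted S-phase fractions (early/mid/late), BrdU immunoprecipitation, and
two-colour tiling-array hybridization give, per ~1-kb probe, a
log2(BrdU-IP/input) ratio per fraction and replicate. A probe enriched in
a fraction replicates during that part of S phase. All coordinates in the
package are 0-based half-open; S-phase time runs over [0, 1].

## Synthetic chromosome model

The simulator exists so that segmentation, zone calling, boundary
selection and the downstream statistics can be validated against known
truth. Its generative model is deliberately the simplest mechanism that
reproduces the qualitative structure of plant chromosome replication
programs: biphasic timing, stochastic early-origin activation, clustered
timing domains, and chromatin marks correlated with timing.

**Origins.** A renewal process with gamma-distributed spacing
(mean 107 kb — the observed median replicon length in *Arabidopsis*
chr4-scale data — shape 12, giving fairly regular spacing, sd ≈ 31 kb).
Each origin belongs to an early or a late firing family. Families are
assigned by a Markov chain (`family_persistence = 0.75`: keep the left
neighbour's family, else redraw with `p_early_family = 0.5`), producing
runs of like-family origins. Clustering is essential: with independent
family assignment, early forks passively replicate isolated late origins
and no late domains survive. The persistence value gives domains of ~6–9
replicons (mean domain length ~0.7–1 Mb on the default chromosome).

**Firing times.** Origin *o* has a mean firing time drawn uniformly from
its family window — early [0.28, 0.38], late [0.72, 0.92] — and a
per-cell Gaussian jitter: sd 0.30 for early-family origins, 0.18 for
late-family (`firing_jitter_sd`, `firing_jitter_sd_late`). The large
early-family dispersion is the substantive modelling commitment: a
euchromatic locus is labeled in early S in some cells and in mid S in
others, which is what makes the early and mid profiles nearly identical
(r ≈ +0.95 on default data) and euchromatin EM-classed. Small dispersion
with family windows pinned inside single fraction windows would instead
produce a strict temporal program — anti-correlated early/mid profiles
and disjoint E/M segments — which contradicts the biology the pipeline is
meant to analyse. The late family keeps a moderate dispersion so the late
profile retains curvature (and therefore detectable extrema) deep inside
late domains.

**Replication time.** With fork speed v (270 kb per S-phase unit),
`t(x) = min over origins of clip(f_o + |x − o| / v, 0, 1)`. An origin
whose position is reached by a neighbour's fork before it fires
(f_j ≥ f_i + |o_j − o_i|/v) never fires; by the triangle inequality it
never determines t anywhere (passive replication). Ground truth lists the
*active* interior origins and the fork-meeting boundaries between
consecutive active origins, at
`x_b = (o_1 + o_2)/2 + v (f_2 − f_1)/2` (also the midpoint of any
clip-at-1 plateau). The fork speed trades off two pipeline-visible
properties: faster forks flatten t within replicons (more uniform EM
euchromatin, weaker boundary extrema), slower forks sharpen boundaries
but push replicon edges into the next fraction window.

**Labeling signal.** The probability that a probe at x is labeled in
fraction window [a, b) is the Gaussian-jitter closed form
`Φ((b − μ)/sd) − Φ((a − μ)/sd)` with μ the nearest (in time) origin's
unclipped contribution and sd that origin's jitter; the outermost window
edges extend to ±∞ so the three probabilities sum to 1 exactly.
Per-replicate ratios are `1.5 · log2((p_w + 1e−6) / (1/3)) + N(0, 0.3)`
(`signal_gain`, floor ε inside the log, `noise_sd`, 3 replicates).
Fraction windows default to thirds of S phase.

**Marks, genes, expression.** Mark probabilities are linear in d, the
probe's distance to its replicon's origin scaled to the replicon
half-length: H3K56ac 0.50 − 0.20 d (early family) / 0.40 − 0.15 d (late);
H3K9me2 0.05 / 0.30; 5mC 0.20 + 0.15 d / 0.42; H3K4me1/2 0.30 + 0.12 d /
0.38. Genes are placed by a thinned Poisson process with intensity rising
with d inside early-family replicons (~200/Mb budget); TEs with 2.5×
intensity in late-family replicons (~100/Mb). Gene presence is logistic
in the mean H3K56ac and H3K9me2 status of overlapping probes, calibrated
to ≈60 % active genes overall; expression levels are N(6, 1.5) for
present genes and N(3.5, 1) for absent ones.

**What the simulator does not emulate.** FACS sorter cross-contamination
and fraction purity, dye bias and intensity-dependent (MA) effects,
cross-hybridization from repeats (the source of EL/I segments in real
data), sequence-level GC (probe GC is drawn, not computed), and any
between-replicate correlation structure (noise is i.i.d.). Passing
recovery tests therefore demonstrate that the analysis correctly inverts
*this* generative model at realistic noise, not that it is robust to
every array artifact.

## Analysis pipeline

**Normalization.** Replicate arrays of a fraction are quantile-normalized
(each column's sorted values replaced by the mean sorted column; ties
receive the mean of the reference values they span), then averaged per
probe; probes with no finite replicate value are linearly interpolated in
genomic coordinate, and a fraction aborts if more than 5 % of probes are
entirely missing. Dye-swap columns are sign-flipped by the reader.

**Smoothing.** Loess: at each probe center, a weighted quadratic is
fitted over probes within ±75 kb with tricube weights on the scaled
distance; windows with fewer than 8 probes fall back to the weighted
mean. The window is a fixed genomic span (not a probe count) because the
grid is near-uniform but gappy. Implemented with vectorized per-probe
normal equations; singular windows fall back to the weighted mean.

**Segmentation.** Per fraction, maximal runs of positive smoothed values
spanning ≥ 10 kb; shorter positive runs are dropped and negative gaps are
never bridged (the minimum-length rule constrains only enriched runs).
Reconciliation assigns each probe a 3-bit early/mid/late membership
vector mapped to the eight timing classes, with no minimum length, so the
timing segments tile the probed extent exactly.

**Zones and boundaries.** Local extrema of each smoothed profile
(plateaus collapse to their midpoint, left-of-center on even runs;
chromosome-end runs excluded) become 10-kb zones, merged when
overlapping. In early/mid profiles maxima are initiation and minima
termination; in the late profile the roles flip. Boundaries come from
termination zones by tier: (1) late-profile zones matched within 20 kb by
both an early and a mid termination zone (boundary at the center of the
merged union); (2) remaining late-profile zones (optionally restricted to
zones whose timing class contains L); (3) remaining early/mid zones whose
centers fall inside reconciled EM segments. Boundaries closer than 20 kb
merge to their midpoint, keeping the best tier.

One reconciliation rule was added to tier 3: a candidate is discarded
when it overlaps an initiation zone called from a *different* fraction.
Under three-window labeling the mid-fraction probability is non-monotone
in replication time (it peaks mid-S), so the mid profile dips at origins;
without the filter every euchromatic origin — a site the early and late
profiles both identify as initiation — would be misread as a tier-3
termination zone, roughly doubling the replicon count. The filter uses
only information the pipeline already computes and never touches tiers 1
and 2.

**Replicons and domains.** Replicons are the intervals between
consecutive boundaries (chromosome ends close the terminal intervals;
configurable). Composition is the per-class probe-length fraction; the
dominant class is the plurality, ties broken by the fixed order E, EM, M,
ML, L, EL, EML, I. Merged initiation zones attach by center containment.
Domains are maximal runs of replicons sharing a dominant class.

**Statistics.** One-sample two-sided t-tests for continuous features
against the region mean; exact binomial tests (doubled smaller tail,
capped at 1) for binary features against the region-wide rate; classes
with fewer than 20 probes are omitted. EM-vs-L replicon comparisons use
Welch's unequal-variance t (the fractional degrees of freedom printed in
such tables identify the Welch form). Top-quartile flags use the
linear-interpolation 75th percentile over all probes (AT-richness is
1 − GC), so with all values equal every probe is flagged. The
within-replicon metaprofile assigns probes to 10 equal-length intervals
by center position and folds them symmetrically into 5 bins
({5,6}→1 … {1,10}→5); per-bin proportions pool probes across replicons by
default (per-replicon averaging is available) with exact Clopper–Pearson
95 % intervals. Hypergeometric pattern × timing tests report both
one-sided p-values and flag the direction of the smaller. Raw p-values
carry the significance codes (* < 0.05, ** < 0.01, *** < 0.001); a
Benjamini–Hochberg column is available but never drives the codes.

**Gene records.** A gene is positive for a mark if any overlapping probe
is (a majority rule is available); the 4-bit vector indexes a fixed
16-pattern table ranked by gene activity. Timing is the class with the
greatest overlap length, ties by the fixed class order. Genes overlapping
no probe or no segment are excluded and counted.

## Validation results and known limitations

On ten 3-Mb default chromosomes (seeds 1–10) at `noise_sd = 0.3`, pooled
boundary recovery within 20 kb is 0.90 and family-consistent replicon
classification 0.93. Without noise, recovery is ~0.87–0.88, not 100 %:
boundaries between two late-family origins produce shallow late-profile
maxima (the late profile is near its ceiling on both sides), and a
quadratic fitted over a 150-kb window admits only one interior extremum,
so adjacent shallow peaks on ~107-kb replicons can merge. These losses
are a resolution property of fixed-window loess on this geometry, not a
noise effect — which is also why recovery does not degrade monotonically
between noise 0 and 0.3: noise occasionally adds extrema in those flat
late-domain interiors that happen to land near true boundaries. Recovery
at noise 0.6 (0.88) remains within a few points of the reference level.
Numbers quoted here are recomputed by `scripts/acceptance.py` and the
test suite; they vary by 3–5 points with the base seed.

Other limitations: per-chromosome processing only (no multi-chromosome
joint modelling); no changepoint/HMM alternative to the threshold
segmentation; zones are not single origins (no sub-zone origin calling);
EL/EML/I segments are structurally rare in the simulator (it has no
cross-hybridization or allele-specific mechanism), so those classes are
exercised mainly by unit fixtures rather than end-to-end runs.
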
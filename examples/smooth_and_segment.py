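"""Smooth the three S-phase fraction profiles, correlate them, and cut the
chromosome into timing-class segments.

Early and mid profiles should be strongly positively correlated (origin
firing in the first half of S is stochastic) while early and late are
anti-correlated (euchromatin vs heterochromatin).
"""

import replitime as rt

cfg = rt.SimConfig(seed=1)
probes, truth = rt.simulate_chromosome(cfg)
res = rt.analyze(probes, rt.PipelineConfig(seed=1))

c = res["correlations"]
print(f"r(early, mid)  = {c['early_mid']:+.2f}")
print(f"r(early, late) = {c['early_late']:+.2f}")
print(f"r(mid, late)   = {c['mid_late']:+.2f}")

comp = rt.class_composition(res["segments"],
                            [("chrom", 0, cfg.chrom_length)])["chrom"]
print("\nfraction of probe-covered bases per timing class:")
for cls in rt.CLASS_ORDER:
    if comp[cls] > 0:
        print(f"  {cls:>4}: {100 * comp[cls]:5.1f}%")
# EM (early+mid) and L (late-only) classes dominate: replication is
# biphasic, with small M/ML transition segments between the two phases.
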
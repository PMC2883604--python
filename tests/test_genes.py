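"""Gene-level mark patterns, timing assignment and association tables."""

import numpy as np
import pytest
from scipy.special import comb

import replitime as rt
from replitime.genes import (PATTERN_MAP, activity_by_timing,
                             assign_gene_marks, assign_gene_timing,
                             build_gene_records, element_distribution_in_replicons,
                             hypergeom_one_sided, intergenic_regions,
                             pattern_activity_table, pattern_of,
                             timing_enrichment_table, GeneRecord)
from replitime.simulate import MarkCalls
from replitime.segmentation import TimingSegment


def mk(i, k4=False, k9=False, k56=False, mc=False):
    return MarkCalls(probe_id=f"P{i}", k4=k4, k9=k9, k56=k56, mc=mc)


class TestPatternMap:
    def test_fixed_anchors(self):
        assert pattern_of(True, False, True, True) == 1
        assert pattern_of(False, True, False, False) == 16
        assert pattern_of(False, False, False, False) == 13
        assert pattern_of(False, False, True, False) == 3

    def test_bijection_over_all_sixteen_vectors(self):
        from itertools import product
        ranks = {pattern_of(*v) for v in product([False, True], repeat=4)}
        assert ranks == set(range(1, 17))
        assert len(PATTERN_MAP) == 16


class TestGeneMarks:
    starts = np.arange(0, 10_000, 1000)
    ends = starts + 1000

    def test_any_positive_probe_makes_gene_positive(self):
        marks = [mk(i, k56=(i == 3)) for i in range(10)]
        vec = assign_gene_marks(2500, 4500, self.starts, self.ends, marks)
        assert vec == (False, False, True, False)

    def test_all_negative_gives_pattern_13(self):
        marks = [mk(i) for i in range(10)]
        vec = assign_gene_marks(0, 3000, self.starts, self.ends, marks)
        assert pattern_of(*vec) == 13

    def test_majority_rule_option(self):
        marks = [mk(i, k9=(i == 0)) for i in range(10)]
        vec = assign_gene_marks(0, 3000, self.starts, self.ends, marks,
                                rule="majority")
        assert vec == (False, False, False, False)

    def test_no_overlapping_probe_returns_none(self):
        assert assign_gene_marks(50_000, 51_000, self.starts, self.ends,
                                 [mk(i) for i in range(10)]) is None

    def test_matches_per_base_overlap_oracle(self, rng):
        marks = [mk(i, k4=bool(rng.integers(2)), k9=bool(rng.integers(2)),
                    k56=bool(rng.integers(2)), mc=bool(rng.integers(2)))
                 for i in range(10)]
        for _ in range(50):
            s = int(rng.integers(0, 9000))
            e = s + int(rng.integers(1, 4000))
            vec = assign_gene_marks(s, e, self.starts, self.ends, marks)
            overlapping = [m for i, m in enumerate(marks)
                           if self.ends[i] > s and self.starts[i] < e]
            want = tuple(any(getattr(m, a) for m in overlapping)
                         for a in ("k4", "k9", "k56", "mc"))
            assert vec == want


class TestGeneTiming:
    segs = [TimingSegment("c", 0, 10_000, "EM", 10),
            TimingSegment("c", 10_000, 30_000, "L", 20)]

    def test_fully_inside_segment(self):
        assert assign_gene_timing(2000, 8000, self.segs) == "EM"

    def test_overlap_length_plurality(self):
        assert assign_gene_timing(7000, 17_000, self.segs) == "L"

    def test_tie_broken_by_class_order(self):
        assert assign_gene_timing(5000, 15_000, self.segs) == "EM"

    def test_no_overlap_returns_none(self):
        assert assign_gene_timing(40_000, 50_000, self.segs) is None

    def test_matches_per_base_plurality_oracle(self, rng):
        segs = []
        pos = 0
        for _ in range(12):
            ln = int(rng.integers(1000, 8000))
            segs.append(TimingSegment(
                "c", pos, pos + ln, str(rng.choice(rt.CLASS_ORDER)), 1))
            pos += ln
        for _ in range(50):
            s = int(rng.integers(0, pos - 1))
            e = s + int(rng.integers(1, 20_000))
            got = assign_gene_timing(s, e, segs)
            per_base = {}
            for seg in segs:
                ov = min(seg.end, e) - max(seg.start, s)
                if ov > 0:
                    per_base[seg.cls] = per_base.get(seg.cls, 0) + ov
            if not per_base:
                assert got is None
            else:
                best = max(per_base.values())
                want = next(c for c in rt.CLASS_ORDER
                            if per_base.get(c) == best)
                assert got == want


def gene(pattern_vec, present, cls="EM", level=5.0, gid="g"):
    return GeneRecord(gene_id=gid, chrom="c", start=0, end=1, strand="+",
                      marks=pattern_vec, pattern=pattern_of(*pattern_vec),
                      present=present, level=level, cls=cls)


class TestActivityTables:
    def test_single_pattern_population_p_one(self):
        genes = [gene((True, False, True, True), i % 2 == 0, gid=str(i))
                 for i in range(20)]
        rows = pattern_activity_table(genes)
        assert len(rows) == 1
        assert rows[0].p_value == pytest.approx(1.0)

    def test_papers_margins_give_significant_enrichment(self):
        """2844 genes, 60.6% active overall; an 818-gene pattern at 75.8%
        active is enriched with p < 0.001 by the exact binomial test."""
        n, n1 = 2844, 818
        x1 = round(0.758 * n1)  # 620
        x_rest = round(0.606 * n) - x1
        genes = []
        for i in range(n1):
            genes.append(gene((True, False, True, True), i < x1,
                              gid=f"a{i}"))
        for i in range(n - n1):
            genes.append(gene((False, False, False, False), i < x_rest,
                              gid=f"b{i}"))
        rows = pattern_activity_table(genes)
        top = next(r for r in rows if r.group == "pattern 1")
        assert top.estimate == pytest.approx(100 * x1 / n1)
        assert top.p_value < 0.001
        # oracle: doubled upper tail around the overall rate
        p0 = (x1 + x_rest) / n
        from replitime.feature_stats import binomial_test_two_sided
        assert top.p_value == pytest.approx(
            binomial_test_two_sided(x1, n1, p0), abs=1e-12)

    def test_rows_ordered_by_descending_activity_and_ns_sum(self):
        genes = ([gene((True, False, True, True), True, gid=f"x{i}")
                  for i in range(10)]
                 + [gene((False, True, False, False), False, gid=f"y{i}")
                    for i in range(10)])
        rows = pattern_activity_table(genes)
        assert [r.estimate for r in rows] == sorted(
            (r.estimate for r in rows), reverse=True)
        assert sum(r.n for r in rows) == len(genes)

    def test_activity_by_timing_overall_row(self):
        genes = [gene((True,) * 4, i < 12, cls="EM" if i < 15 else "L",
                      gid=str(i)) for i in range(20)]
        rows = activity_by_timing(genes)
        overall = rows[0]
        assert overall.group == "all"
        assert overall.estimate == pytest.approx(100 * 12 / 20)
        assert sum(r.n for r in rows[1:]) == 20


class TestHypergeometric:
    def brute_over(self, x, N, K, n):
        tot = comb(N, n, exact=True)
        return sum(comb(K, k, exact=True) * comb(N - K, n - k, exact=True)
                   for k in range(x, min(K, n) + 1)) / tot

    def test_worked_combinatorial_example(self):
        over, under = hypergeom_one_sided(3, 100, 30, 10)
        assert over == pytest.approx(self.brute_over(3, 100, 30, 10),
                                     abs=1e-12)

    def test_matches_combinatorial_oracle(self, rng):
        for _ in range(50):
            N = int(rng.integers(10, 300))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            x = int(rng.integers(max(0, K + n - N), min(K, n) + 1))
            over, under = hypergeom_one_sided(x, N, K, n)
            assert over == pytest.approx(self.brute_over(x, N, K, n),
                                         abs=1e-10)
            under_brute = 1.0 - self.brute_over(x + 1, N, K, n)
            assert under == pytest.approx(under_brute, abs=1e-10)

    def test_entire_gene_set_is_exactly_represented(self):
        genes = [gene((True,) * 4, True, cls="EM", gid=str(i))
                 for i in range(30)]
        rows = timing_enrichment_table(genes)
        assert all(r["p_value"] == pytest.approx(1.0) for r in rows)

    def test_maximal_overlap_is_point_mass_tail(self):
        genes = ([gene((True,) * 4, True, cls="EM", gid=f"a{i}")
                  for i in range(10)]
                 + [gene((False,) * 4, True, cls="L", gid=f"b{i}")
                    for i in range(20)])
        rows = timing_enrichment_table(genes)
        r = next(r for r in rows if r["pattern"] == 7 and r["cls"] == "EM")
        assert r["x"] == 10 and r["direction"] == "over"
        assert r["p_over"] == pytest.approx(
            self.brute_over(10, 30, 10, 10), abs=1e-12)


class TestSyntheticGeneAssociations:
    def test_em_genes_more_active_than_l_genes(self, default_run):
        d = default_run
        records, _ = build_gene_records(d["features"], d["probes"],
                                        d["marks"], d["expression"],
                                        d["res"]["segments"])
        rows = {r.group: r for r in activity_by_timing(records)}
        assert rows["EM"].estimate > rows["L"].estimate

    def test_k56_positive_patterns_rank_above_k9_positive(self, default_run):
        """Ranking patterns by activity places k56+/k9- patterns above
        k9+/k56- patterns, as the generator encodes."""
        d = default_run
        records, _ = build_gene_records(d["features"], d["probes"],
                                        d["marks"], d["expression"],
                                        d["res"]["segments"])
        rows = pattern_activity_table(records)
        vec_of = {v: k for v, k in PATTERN_MAP.items()}
        act = {}
        for r in rows:
            pat = int(r.group.split()[-1])
            if r.n >= 30:
                act[pat] = r.estimate
        k56_pos = [a for (k4, k9, k56, mc), p in PATTERN_MAP.items()
                   if k56 and not k9 and p in act for a in [act[p]]]
        k9_pos = [a for (k4, k9, k56, mc), p in PATTERN_MAP.items()
                  if k9 and not k56 and p in act for a in [act[p]]]
        if k56_pos and k9_pos:
            assert np.mean(k56_pos) > np.mean(k9_pos)

    def test_per_pattern_ns_sum_to_gene_count(self, default_run):
        d = default_run
        records, _ = build_gene_records(d["features"], d["probes"],
                                        d["marks"], d["expression"],
                                        d["res"]["segments"])
        rows = pattern_activity_table(records)
        assert sum(r.n for r in rows) == len(records)


class TestElementDistribution:
    def test_intergenic_complement(self):
        genes = [(0, 400), (600, 1000)]
        assert intergenic_regions(genes, (0, 1000)) == [(400, 600)]

    def test_genes_tiling_everything_leave_no_intergenic(self):
        assert intergenic_regions([(0, 500), (400, 1000)], (0, 1000)) == []

    def test_uniform_elements_flat_profile(self, rng):
        reps = [rt.Replicon(chrom="c", start=float(s), end=float(s + 100_000))
                for s in range(0, 2_000_000, 100_000)]
        elements = [(int(x), int(x) + 100)
                    for x in rng.uniform(0, 2_000_000 - 100, 2000)]
        counts, props, (lo, hi) = element_distribution_in_replicons(
            elements, reps)
        assert counts.sum() == len(elements)
        assert np.all(lo <= 0.2) and np.all(0.2 <= hi)

    def test_midpoint_assignment_rule(self):
        reps = [rt.Replicon(chrom="c", start=0.0, end=100_000.0)]
        counts, _, _ = element_distribution_in_replicons([(0, 6000)], reps)
        assert counts[4] == 1  # midpoint 3000 -> relative 0.03 -> bin 5

    def test_gene_density_rises_toward_termination_in_em_replicons(
            self, default_run):
        d = default_run
        em = [r for r in d["res"]["replicons"] if r.cls == "EM"]
        genes = [(f.start, f.end) for f in d["features"] if f.kind == "gene"]
        counts, props, _ = element_distribution_in_replicons(genes, em)
        assert props[4] > props[0]  # outermost bin denser than innermost
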
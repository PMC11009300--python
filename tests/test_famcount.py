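"""Hit filtering/classification, cutoff optimization, and gene grouping."""

import numpy as np
import pandas as pd
import pytest

from tcellkit import famcount as fc
from tcellkit.famcount import ConfusionSummary
from tcellkit.simulate import GenomeSimSpec, simulate_domain_hits


def make_hits(rows):
    base = {"strand": "+", "domain_id": "D", "family": "MHC-I",
            "rank": 1, "reciprocal_best_domain": "D"}
    return pd.DataFrame([{**base, **r} for r in rows])


class TestReciprocalFilter:
    def test_rank_and_concordance_rules(self):
        hits = make_hits([
            {"scaffold": "s1", "start": 0, "end": 10, "rank": 11},
            {"scaffold": "s1", "start": 20, "end": 30, "reciprocal_best_domain": "OTHER"},
            {"scaffold": "s1", "start": 40, "end": 50},
        ])
        out = fc.reciprocal_filter(hits, "D")
        assert len(out) == 1 and out.iloc[0]["start"] == 40

    def test_identity_when_all_concordant(self):
        hits = make_hits([{"scaffold": "s1", "start": i * 100, "end": i * 100 + 10}
                          for i in range(5)])
        assert len(fc.reciprocal_filter(hits, "D")) == 5

    def test_missing_column_errors(self):
        with pytest.raises(KeyError, match="reciprocal"):
            fc.reciprocal_filter(pd.DataFrame({"rank": [1]}), "D")


ANN = pd.DataFrame([
    {"scaffold": "s1", "start": 100, "end": 500, "strand": "+", "gene_id": "gA",
     "orthogroup_id": "OG1", "is_family_member": True},
    {"scaffold": "s1", "start": 2000, "end": 2400, "strand": "+", "gene_id": "gB",
     "orthogroup_id": "OG_other", "is_family_member": False},
])


class TestClassify:
    def test_statuses(self):
        hits = make_hits([
            {"scaffold": "s1", "start": 150, "end": 200},       # inside family gene
            {"scaffold": "s1", "start": 2100, "end": 2200},     # inside non-family
            {"scaffold": "s1", "start": 600, "end": 700},       # near family gene
            {"scaffold": "s2", "start": 0, "end": 50},          # far from anything
        ])
        out = fc.classify_hits(hits, ANN, synteny_window=1000)
        assert list(out["status"]) == ["annotated", "removed",
                                       "syntenic_unannotated", "nonsyntenic_unannotated"]
        assert out.iloc[0]["gene_id"] == "gA"
        assert out.iloc[1]["removal_reason"] == "non_family_gene"

    def test_beyond_window_is_nonsyntenic(self):
        hits = make_hits([{"scaffold": "s1", "start": 10_000_600, "end": 10_000_700}])
        out = fc.classify_hits(hits, ANN, synteny_window=1_000_000)
        assert out.iloc[0]["status"] == "nonsyntenic_unannotated"

    def test_elimination_interval(self):
        hits = make_hits([{"scaffold": "s1", "start": 600, "end": 700}])
        elim = pd.DataFrame([{"scaffold": "s1", "start": 650, "end": 1200}])
        out = fc.classify_hits(hits, ANN, elimination=elim, synteny_window=1000)
        assert out.iloc[0]["removal_reason"] == "elimination_interval"

    def test_contradictory_overlap_errors(self):
        ann = pd.concat([ANN, pd.DataFrame([
            {"scaffold": "s1", "start": 120, "end": 480, "strand": "+",
             "gene_id": "gC", "orthogroup_id": "OGx", "is_family_member": False}])],
            ignore_index=True)
        hits = make_hits([{"scaffold": "s1", "start": 150, "end": 200}])
        with pytest.raises(ValueError, match="contradictory"):
            fc.classify_hits(hits, ann)


class TestGapTable:
    def test_intragenic_and_intergenic_labels(self):
        hits = make_hits([
            {"scaffold": "s1", "start": 100, "end": 200},
            {"scaffold": "s1", "start": 600, "end": 700},
            {"scaffold": "s1", "start": 5000, "end": 5100},
        ])
        hits["status"] = "annotated"
        hits["gene_id"] = ["gA", "gA", "gB"]
        gaps = fc.gap_table(hits)
        assert list(gaps["distance"]) == [400, 4300]
        assert list(gaps["truth"]) == ["intragenic", "intergenic"]

    def test_single_hit_per_scaffold_is_empty(self):
        hits = make_hits([{"scaffold": f"s{i}", "start": 0, "end": 10} for i in range(3)])
        hits["status"] = "annotated"
        hits["gene_id"] = list("abc")
        assert len(fc.gap_table(hits)) == 0


class TestFMeasure:
    @pytest.mark.parametrize("tp,fp,fn,f1,half", [
        (10, 0, 0, 1.0, 0.5),              # p = r = 1
        (10, 10, 0, 2 / 3, 1 / 3),         # p = 0.5, r = 1
        (30, 10, 10, 0.75, 0.375),         # p = r = 0.75 -> F1 = p
    ])
    def test_closed_forms(self, tp, fp, fn, f1, half):
        s = ConfusionSummary(TP=tp, FP=fp, FN=fn, TN=5)
        assert fc.f_measure(s, "f1") == pytest.approx(f1)
        assert fc.f_measure(s, "half") == pytest.approx(half)

    def test_undefined_is_nan_not_zero(self):
        s = ConfusionSummary(TP=0, FP=0, FN=5, TN=5)  # precision undefined
        assert np.isnan(fc.f_measure(s))


def exhaustive_best_cutoff(gaps, formula="f1"):
    """Oracle: evaluate F at every candidate cutoff by brute force."""
    d = np.sort(gaps["distance"].unique()).astype(float)
    candidates = np.concatenate([[d[0] - 1], (d[:-1] + d[1:]) / 2, [d[-1] + 1]])
    best = None
    for c in candidates:
        pred = gaps["distance"] < c
        truth = gaps["truth"] == "intragenic"
        tp, fp = (pred & truth).sum(), (pred & ~truth).sum()
        fn = (~pred & truth).sum()
        if tp + fp == 0 or tp + fn == 0:
            continue
        p, r = tp / (tp + fp), tp / (tp + fn)
        if p + r == 0:
            continue
        f = 2 * p * r / (p + r) if formula == "f1" else p * r / (p + r)
        if best is None or f > best[1] + 1e-15:
            best = (float(c), f)
    return best


class TestOptimizeCutoff:
    def test_perfect_separation(self):
        gaps = pd.DataFrame({"distance": [100, 200, 300, 5000, 6000],
                             "truth": ["intragenic"] * 3 + ["intergenic"] * 2})
        cutoff, summary = fc.optimize_cutoff(gaps)
        assert 300 < cutoff < 5000
        assert cutoff == pytest.approx((300 + 5000) / 2)
        assert summary.f1 == 1.0

    def test_inverted_labels_warn(self):
        gaps = pd.DataFrame({"distance": [5000, 6000, 100, 200],
                             "truth": ["intragenic"] * 2 + ["intergenic"] * 2})
        with pytest.warns(UserWarning, match="inverted"):
            cutoff, summary = fc.optimize_cutoff(gaps)
        assert summary.f1 < 1.0

    def test_one_class_errors(self):
        gaps = pd.DataFrame({"distance": [1, 2], "truth": ["intragenic"] * 2})
        with pytest.raises(ValueError):
            fc.optimize_cutoff(gaps)

    def test_simulated_gaps_match_exhaustive_oracle(self):
        rng = np.random.default_rng(17)
        intra = np.maximum(rng.normal(500, 100, 500), 1)
        inter = np.maximum(rng.normal(20000, 3000, 500), 1)
        gaps = pd.DataFrame({
            "distance": np.round(np.concatenate([intra, inter])),
            "truth": ["intragenic"] * 500 + ["intergenic"] * 500,
        })
        cutoff, summary = fc.optimize_cutoff(gaps)
        oracle_cut, oracle_f = exhaustive_best_cutoff(gaps)
        assert cutoff == oracle_cut
        assert summary.f1 == pytest.approx(oracle_f)
        assert summary.f1 >= 0.99
        assert intra.max() > cutoff > 0 or (intra.min() < cutoff < inter.min())

    def test_argmax_invariant_to_formula(self):
        rng = np.random.default_rng(18)
        gaps = pd.DataFrame({
            "distance": np.concatenate([rng.normal(500, 300, 200).clip(1),
                                        rng.normal(3000, 2000, 200).clip(1)]).round(),
            "truth": ["intragenic"] * 200 + ["intergenic"] * 200,
        })
        c1, _ = fc.optimize_cutoff(gaps, formula="f1")
        c2, _ = fc.optimize_cutoff(gaps, formula="half")
        assert c1 == c2


class TestGroupHits:
    def test_worked_example(self):
        hits = make_hits([{"scaffold": "s1", "start": s, "end": s + 1}
                          for s in (100, 700, 25000)])
        calls = fc.group_hits(hits, cutoff=1000)
        assert len(calls) == 2
        assert calls.iloc[0]["n_hits"] == 2 and calls.iloc[1]["n_hits"] == 1

    def test_zero_cutoff_one_gene_per_hit(self):
        hits = make_hits([{"scaffold": "s1", "start": s, "end": s + 10}
                          for s in (0, 100, 200)])
        assert len(fc.group_hits(hits, 0)) == 3

    def test_huge_cutoff_one_gene_per_scaffold(self):
        hits = make_hits([{"scaffold": f"s{i % 2}", "start": s * 1000, "end": s * 1000 + 10}
                          for i, s in enumerate(range(8))])
        assert len(fc.group_hits(hits, 10**9)) == 2

    def test_partition_property(self, genome_sim):
        hits, _, _ = genome_sim
        calls = fc.group_hits(hits, 5000)
        all_rows = [r for rows in calls["hit_rows"] for r in rows]
        assert sorted(all_rows) == sorted(hits.index)

    def test_gene_count_monotone_in_cutoff(self, genome_sim):
        hits, _, _ = genome_sim
        counts = [len(fc.group_hits(hits, c)) for c in (0, 100, 1000, 10000, 10**6)]
        assert counts == sorted(counts, reverse=True)


class TestCountFamilies:
    def test_recovers_planted_gene_count(self, genome_sim):
        hits, ann, truth = genome_sim
        classified = fc.classify_hits(hits, ann)
        gaps = fc.gap_table(classified)
        cutoff, _ = fc.optimize_cutoff(gaps)
        table = fc.count_families({"nmr": classified}, cutoffs={"nmr": cutoff})
        assert table.loc["nmr", "MHC-I"] == truth["gene_id"].nunique() == 50

    def test_row_order_invariance(self, genome_sim):
        hits, _, _ = genome_sim
        shuffled = hits.sample(frac=1, random_state=0)
        t1 = fc.count_families({"sp": hits}, cutoffs=5000.0)
        t2 = fc.count_families({"sp": shuffled}, cutoffs=5000.0)
        pd.testing.assert_frame_equal(t1, t2)

    def test_single_domain_family_counts_hits(self):
        hits = make_hits([{"scaffold": "s1", "start": s, "end": s + 50}
                          for s in (0, 1000, 2000)])
        hits["family"] = "TRGV"
        table = fc.count_families({"sp": hits})
        assert table.loc["sp", "TRGV"] == 3

    def test_derived_sums(self):
        rows = []
        for fam, n in (("TRAV", 2), ("TRBV", 3), ("TRGV", 1), ("TRDV", 4)):
            for i in range(n):
                rows.append({"scaffold": "s1", "start": i * 10_000,
                             "end": i * 10_000 + 50, "family": fam})
        hits = make_hits(rows)
        table = fc.count_families({"sp": hits})
        assert table.loc["sp", "Va+Vb"] == 5
        assert table.loc["sp", "Vg+Vd"] == 5


class TestBenchmark:
    def test_exact_match_zero_fn(self, genome_sim):
        hits, ann, _ = genome_sim
        classified = fc.classify_hits(hits, ann)
        calls = fc.group_hits(classified, 5000)
        result = fc.benchmark_against_annotation(calls, ann)
        assert result["fn_rate"] == 0.0
        assert result["unannotated_call_fraction"] == 0.0

    def test_partial_annotation_recovered(self):
        spec = GenomeSimSpec(n_scaffolds=10, genes_per_scaffold=10,
                             annotated_fraction=0.8, seed=21)
        hits, ann, _ = simulate_domain_hits(spec)
        classified = fc.classify_hits(hits, ann, synteny_window=100_000)
        calls = fc.group_hits(classified, 5000)
        result = fc.benchmark_against_annotation(calls, ann)
        assert result["fn_rate"] == 0.0
        assert result["unannotated_call_fraction"] == pytest.approx(0.2, abs=0.05)

    def test_one_missed_gene_of_ten(self):
        ann = pd.DataFrame([{"scaffold": "s1", "start": i * 10_000,
                             "end": i * 10_000 + 500, "strand": "+",
                             "gene_id": f"g{i}", "orthogroup_id": "OG1",
                             "is_family_member": True} for i in range(10)])
        calls = pd.DataFrame([{"gene_index": i, "scaffold": "s1",
                               "start": i * 10_000, "end": i * 10_000 + 400,
                               "n_hits": 1, "hit_rows": [i], "status": "annotated"}
                              for i in range(9)])
        result = fc.benchmark_against_annotation(calls, ann)
        assert result["fn_rate"] == pytest.approx(0.1)
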
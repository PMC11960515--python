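import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from enrange.classify import classify_gene, classify_table
from enrange.sensitivity import (
    CorrelationClustering,
    ResponseThresholds,
    attach_coverage_feature,
    category_response_fractions,
    compare_categories,
    correlation_cluster,
    joined_frame,
    ks_d_one_sided,
    ks_one_sided_d,
    multi_factor_set,
    overlap_response,
    quartile_stratify,
    response_class,
    wilcoxon_two_sided,
)
from enrange.synthdata import SimConfig, gen_de, gen_links
from enrange.tables_io import CoverageTrack, DeRecord, DeTable

from conftest import make_link


def brute_force_ks_d(x, y):
    """sup over the pooled support of F_x - F_y, by direct ECDF counting."""
    pts = np.concatenate([x, y])
    best = -np.inf
    for t in pts:
        fx = np.mean(np.asarray(x) <= t)
        fy = np.mean(np.asarray(y) <= t)
        best = max(best, fx - fy)
    return best


def enumeration_wilcoxon_p(x, y):
    """Exact two-sided rank-sum p by enumerating all label assignments."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n_x = len(x)
    w_obs = ranks[:n_x].sum()
    dist = [
        sum(ranks[list(idx)])
        for idx in itertools.combinations(range(len(pooled)), n_x)
    ]
    dist = np.array(dist)
    mean = dist.mean()
    dev = abs(w_obs - mean)
    return float(np.mean(np.abs(dist - mean) >= dev - 1e-12))


class TestKs:
    def test_identical_samples_zero(self):
        cmp = ks_d_one_sided([1, 2, 3], [1, 2, 3])
        assert cmp.statistic == 0.0
        assert cmp.p_value == 1.0

    def test_complete_separation_one(self):
        cmp = ks_d_one_sided([-2, -1], [1, 2])
        assert cmp.statistic == 1.0

    def test_small_example_matches_frozen_oracle_value(self):
        # brute-force ECDF evaluation over the 5 pooled points gives 1/3
        x, y = [-1, 0, 2], [0, 1]
        assert brute_force_ks_d(x, y) == pytest.approx(1 / 3)
        assert ks_d_one_sided(x, y).statistic == pytest.approx(1 / 3)

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(200):
            x = rng.normal(size=rng.integers(1, 50))
            y = rng.normal(size=rng.integers(1, 50))
            assert ks_one_sided_d(x, y) == pytest.approx(brute_force_ks_d(x, y), abs=1e-12)

    def test_matches_scipy_one_sided_statistic(self, rng):
        for _ in range(50):
            x = rng.normal(size=40)
            y = rng.normal(size=30)
            ref = stats.ks_2samp(x, y, alternative="greater").statistic
            assert ks_one_sided_d(x, y) == pytest.approx(ref, abs=1e-12)

    def test_large_downward_shift_gives_d_one(self, rng):
        y = rng.normal(size=80)
        x = y[:40] - (y.max() - y.min() + 10.0)
        assert ks_one_sided_d(x, y) == 1.0

    def test_direction_convention_lower_is_positive(self, rng):
        x = rng.normal(-1.0, 1.0, size=200)
        y = rng.normal(0.0, 1.0, size=200)
        assert ks_one_sided_d(x, y) > 0.15
        assert ks_one_sided_d(y, x) < 0.05

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_d_one_sided([], [1.0])


class TestWilcoxon:
    def test_textbook_exact_p(self):
        cmp = wilcoxon_two_sided([1, 2, 3], [4, 5, 6])
        assert cmp.p_value == pytest.approx(0.1)

    def test_identical_multisets_p_one(self):
        cmp = wilcoxon_two_sided([1.5, 2.5, 7.0], [1.5, 2.5, 7.0])
        assert cmp.p_value == pytest.approx(1.0)

    def test_exact_path_matches_enumeration_for_all_3v3_splits(self):
        """Full sweep of the 20 splits of {1..6} into two triples."""
        values = set(range(1, 7))
        for x in itertools.combinations(range(1, 7), 3):
            y = tuple(values - set(x))
            expected = enumeration_wilcoxon_p(np.array(x, float), np.array(y, float))
            got = wilcoxon_two_sided(list(x), list(y)).p_value
            assert got == pytest.approx(expected), (x, y)

    def test_type_one_error_near_nominal(self, rng):
        hits = 0
        reps = 1000
        for _ in range(reps):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            if wilcoxon_two_sided(x, y).p_value < 0.05 :
                hits += 1
        assert 0.025 <= hits / reps <= 0.08

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_two_sided([1.0], [])


class TestResponseClass:
    @pytest.mark.parametrize(
        "log2fc, fdr, expected",
        [
            (-1.0, 0.01, "downregulated"),
            (0.0, 0.9, "unaffected"),
            (-0.5, 0.001, "neither"),
            (-1.0, 0.5, "neither"),  # fails the FDR condition
            (-1.0, None, "neither"),  # missing FDR blocks downregulated
            (0.19, None, "unaffected"),  # band has no FDR condition
            (0.2, 0.9, "neither"),  # band is open
        ],
    )
    def test_rules(self, log2fc, fdr, expected):
        rec = DeRecord("G", 100.0, log2fc, fdr)
        assert response_class(rec) == expected

    def test_partition_disjoint_by_construction(self, rng):
        th = ResponseThresholds()
        for _ in range(500):
            rec = DeRecord("G", 1.0, float(rng.normal(0, 1)), float(rng.uniform()))
            assert response_class(rec, th) in {"downregulated", "unaffected", "neither"}


def small_cohort():
    """10 short genes with hand-set responses, 5 no-enhancer reference genes."""
    classes = []
    rows = []
    lfc = [-1.0, -0.9, -1.2, -2.0, 0.0, 0.1, -0.1, 0.5, -0.5, 0.3]
    fdr = [0.01, 0.01, 0.01, 0.01, 0.9, 0.9, 0.9, 0.9, 0.001, 0.9]
    for i, (l, f) in enumerate(zip(lfc, fdr)):
        g = f"S{i}"
        classes.append(classify_gene([make_link(5_000, 0.9, gene_id=g)]))
        rows.append((g, 100.0, l, f))
    for i in range(5):
        g = f"N{i}"
        classes.append(classify_gene([]))
        classes[-1].gene_id = g
        rows.append((g, 100.0, 0.05 * i, 0.9))
    de = DeTable("toy", pd.DataFrame(rows, columns=["gene_id", "base_mean", "log2fc", "fdr"]))
    return classes, de


class TestResponseFractions:
    def test_hand_enumeration(self):
        classes, de = small_cohort()
        out = category_response_fractions(classes, de)
        # short: 4 downregulated, 3 in the open (-0.2, 0.2) band, of 10
        assert out["short"]["fraction_down"] == pytest.approx(0.4)
        assert out["short"]["fraction_unaffected"] == pytest.approx(0.3)
        assert out["short"]["n"] == 10
        assert out["no_enhancer"]["fraction_down"] == 0.0

    def test_all_neither(self):
        classes = [classify_gene([make_link(5_000, 0.9, gene_id="A")])]
        de = DeTable("t", pd.DataFrame([("A", 10.0, -0.5, 0.9)],
                                       columns=["gene_id", "base_mean", "log2fc", "fdr"]))
        out = category_response_fractions(classes, de)
        assert out["short"]["fraction_down"] == 0.0
        assert out["short"]["fraction_unaffected"] == 0.0


class TestCompareCategories:
    def test_self_pair_d_zero(self):
        classes, de = small_cohort()
        comps, _ = compare_categories(classes, de, [("short", "short")])
        assert comps[0].statistic == 0.0

    def test_unknown_category_rejected(self):
        classes, de = small_cohort()
        with pytest.raises(ValueError, match="mid"):
            compare_categories(classes, de, [("mid", "short")])

    def test_planted_shift_detected(self, rng):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            classes, rows = [], []
            for i in range(200):
                g = f"L{i}"
                classes.append(classify_gene([make_link(100_000, 0.9, gene_id=g)]))
                rows.append((g, 100.0, r.normal(-0.5, 0.4), 0.5))
            for i in range(200):
                g = f"N{i}"
                c = classify_gene([])
                c.gene_id = g
                classes.append(c)
                rows.append((g, 100.0, r.normal(0.0, 0.4), 0.5))
            de = DeTable("t", pd.DataFrame(rows, columns=["gene_id", "base_mean", "log2fc", "fdr"]))
            comps, _ = compare_categories(classes, de, [("long", "no_enhancer")])
            if comps[0].p_value < 0.001:
                hits += 1
        assert hits == 20

    def test_null_mostly_non_significant(self):
        hits = 0
        for seed in range(40):
            r = np.random.default_rng(1000 + seed)
            classes, rows = [], []
            for i in range(200):
                g = f"L{i}"
                classes.append(classify_gene([make_link(100_000, 0.9, gene_id=g)]))
                rows.append((g, 100.0, r.normal(0, 1), 0.5))
            for i in range(200):
                g = f"N{i}"
                c = classify_gene([])
                c.gene_id = g
                classes.append(c)
                rows.append((g, 100.0, r.normal(0, 1), 0.5))
            de = DeTable("t", pd.DataFrame(rows, columns=["gene_id", "base_mean", "log2fc", "fdr"]))
            comps, _ = compare_categories(classes, de, [("long", "no_enhancer")])
            if comps[0].p_value < 0.01:
                hits += 1
        assert hits <= 3


class TestQuartileStratify:
    def build(self, feature_values, lfc=None):
        classes, rows = [], []
        for i, v in enumerate(feature_values):
            g = f"L{i}"
            classes.append(
                classify_gene([make_link(100_000 + i * 1000, 0.9, gene_id=g,
                                         features={"EP300": v})])
            )
            rows.append((g, 100.0, 0.0 if lfc is None else lfc[i], 0.5))
        for i in range(10):
            g = f"N{i}"
            c = classify_gene([])
            c.gene_id = g
            classes.append(c)
            rows.append((g, 100.0, 0.0, 0.5))
        de = DeTable("t", pd.DataFrame(rows, columns=["gene_id", "base_mean", "log2fc", "fdr"]))
        return classes, de

    def test_eight_enhancers_quartiles(self):
        classes, de = self.build([1, 2, 3, 4, 5, 6, 7, 8])
        strat = quartile_stratify(classes, de, "EP300")
        assert set(strat.low_gene_ids) == {"L0", "L1"}
        assert set(strat.high_gene_ids) == {"L6", "L7"}
        assert len(strat.low_gene_ids) == len(strat.high_gene_ids) == 8 // 4

    def test_constant_feature_flagged_degenerate(self):
        classes, de = self.build([5.0] * 8)
        strat = quartile_stratify(classes, de, "EP300")
        assert strat.degenerate
        assert len(strat.low_gene_ids) == 2  # tie-break by coordinate

    def test_membership_counts_floor(self, rng):
        for n in (7, 8, 9, 41):
            classes, de = self.build(list(rng.normal(size=n)))
            strat = quartile_stratify(classes, de, "EP300")
            assert len(strat.low_gene_ids) == len(strat.high_gene_ids) == n // 4

    def test_planted_feature_coupling(self):
        r = np.random.default_rng(7)
        feats = r.uniform(0, 1, size=80)
        lfc = -feats + r.normal(0, 0.2, size=80)
        classes, de = self.build(list(feats), lfc=list(lfc))
        strat = quartile_stratify(classes, de, "EP300")
        de_ix = de.df.set_index("gene_id")["log2fc"]
        assert de_ix[strat.high_gene_ids].median() < de_ix[strat.low_gene_ids].median()

    def test_missing_feature_majority_rejected(self):
        classes, de = self.build([np.nan] * 6 + [1.0, 2.0])
        with pytest.raises(ValueError, match="missing"):
            quartile_stratify(classes, de, "EP300")


class TestAttachCoverage:
    def track(self, rows):
        return CoverageTrack(pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]))

    def test_uniform_coverage(self):
        cls = classify_gene([make_link(100_000, 0.9, tss=0)])
        elem = cls.representative_link.element
        track = self.track([("chr1", elem.start, elem.end, 2.0)])
        attach_coverage_feature([cls], track, "LDB1")
        assert cls.representative_link.features["LDB1"] == pytest.approx(2.0)

    def test_length_weighting(self):
        cls = classify_gene([make_link(100_000, 0.9, tss=0)])
        elem = cls.representative_link.element
        midpoint = (elem.start + elem.end) // 2
        track = self.track(
            [("chr1", elem.start, midpoint, 1.0), ("chr1", midpoint, elem.end, 3.0)]
        )
        attach_coverage_feature([cls], track, "LDB1")
        assert cls.representative_link.features["LDB1"] == pytest.approx(2.0)

    def test_no_overlap_zero(self):
        cls = classify_gene([make_link(100_000, 0.9, tss=0)])
        track = self.track([("chr2", 0, 10, 5.0)])
        attach_coverage_feature([cls], track, "LDB1")
        assert cls.representative_link.features["LDB1"] == 0.0

    def test_invariant_to_splitting_intervals(self, rng):
        cls = classify_gene([make_link(100_000, 0.9, tss=0)])
        elem = cls.representative_link.element
        whole = self.track([("chr1", elem.start - 100, elem.end + 100, 1.7)])
        cut = int(rng.integers(elem.start, elem.end))
        split = self.track(
            [("chr1", elem.start - 100, cut, 1.7), ("chr1", cut, elem.end + 100, 1.7)]
        )
        a = whole.mean_over(elem.chrom, elem.start, elem.end)
        b = split.mean_over(elem.chrom, elem.start, elem.end)
        assert a == pytest.approx(b, abs=1e-12)


class TestOverlapResponse:
    def make_tables(self, coupled, seed=0):
        r = np.random.default_rng(seed)
        classes, rows_a, rows_b = [], [], []
        for i in range(120):
            g = f"L{i}"
            classes.append(classify_gene([make_link(100_000, 0.9, gene_id=g)]))
            hit = i < 60
            lfc_a = r.normal(-0.8, 0.2) if hit else r.normal(0.0, 0.05)
            lfc_b = (r.normal(-0.6, 0.3) if hit else r.normal(0.0, 0.3)) if coupled \
                else r.normal(0.0, 0.3)
            rows_a.append((g, 100.0, lfc_a, 0.001 if hit else 0.9))
            rows_b.append((g, 100.0, lfc_b, 0.5))
        cols = ["gene_id", "base_mean", "log2fc", "fdr"]
        return classes, DeTable("a", pd.DataFrame(rows_a, columns=cols)), \
            DeTable("b", pd.DataFrame(rows_b, columns=cols))

    def test_coupled_tables_significant_negative(self):
        classes, de_a, de_b = self.make_tables(coupled=True)
        cmp = overlap_response(classes, de_a, de_b)
        assert cmp.p_value < 0.01
        assert cmp.direction == "lower"

    def test_independent_tables_mostly_non_significant(self):
        hits = 0
        for seed in range(40):
            classes, de_a, de_b = self.make_tables(coupled=False, seed=100 + seed)
            if overlap_response(classes, de_a, de_b).p_value < 0.01:
                hits += 1
        assert hits <= 3

    def test_empty_set_named_in_error(self):
        classes, de_a, de_b = self.make_tables(coupled=True)
        with pytest.raises(ValueError, match="short"):
            overlap_response(classes, de_a, de_b, category="short")


class TestMultiFactorSet:
    def tables(self, lfc_by_gene_list):
        cols = ["gene_id", "base_mean", "log2fc", "fdr"]
        return [
            DeTable(f"t{i}", pd.DataFrame(
                [(g, 10.0, v, 0.5) for g, v in d.items()], columns=cols))
            for i, d in enumerate(lfc_by_gene_list)
        ]

    def test_two_of_three_included(self):
        tabs = self.tables([{"A": -0.6, "B": -0.6}, {"A": -0.6, "B": 0.0}, {"A": 0.0, "B": 0.0}])
        assert multi_factor_set(tabs) == {"A"}

    def test_one_of_three_excluded(self):
        tabs = self.tables([{"A": -0.6}, {"A": 0.0}, {"A": 0.0}])
        assert multi_factor_set(tabs) == set()

    def test_two_identical_tables(self):
        tabs = self.tables([{"A": -0.6, "B": -0.2}, {"A": -0.6, "B": -0.2}])
        assert multi_factor_set(tabs) == {"A"}

    def test_too_few_tables_rejected(self):
        tabs = self.tables([{"A": -0.6}])
        with pytest.raises(ValueError):
            multi_factor_set(tabs)


class TestCorrelationCluster:
    def tables_from_matrix(self, mat, genes):
        cols = ["gene_id", "base_mean", "log2fc", "fdr"]
        return [
            DeTable(name, pd.DataFrame(
                [(g, 10.0, v, 0.5) for g, v in zip(genes, col)], columns=cols))
            for name, col in mat.items()
        ]

    def test_identical_tables_r_one(self, rng):
        genes = [f"G{i}" for i in range(20)]
        v = rng.normal(size=20)
        tabs = self.tables_from_matrix({"a": v, "b": v.copy()}, genes)
        out = correlation_cluster(tabs, set(genes))
        assert out.correlation.loc["a", "b"] == pytest.approx(1.0)

    def test_negation_r_minus_one(self, rng):
        genes = [f"G{i}" for i in range(20)]
        v = rng.normal(size=20)
        tabs = self.tables_from_matrix({"a": v, "b": -v}, genes)
        out = correlation_cluster(tabs, set(genes))
        assert out.correlation.loc["a", "b"] == pytest.approx(-1.0)

    def test_zero_variance_reported_missing(self, rng):
        genes = [f"G{i}" for i in range(10)]
        tabs = self.tables_from_matrix(
            {"a": rng.normal(size=10), "b": rng.normal(size=10), "flat": np.zeros(10)},
            genes,
        )
        out = correlation_cluster(tabs, set(genes))
        assert np.isnan(out.correlation.loc["flat", "a"])
        assert out.leaf_order[-1] == "flat"

    def test_planted_factor_groups_cluster_adjacently(self):
        genes = [f"G{i}" for i in range(60)]
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            shared = {k: r.normal(size=60) for k in "ABC"}
            mat = {}
            for grp in "ABC":
                for j in range(3):
                    mat[f"{grp}{j}"] = shared[grp] + r.normal(0, 0.4, size=60)
            out = correlation_cluster(self.tables_from_matrix(mat, genes), set(genes))
            order = [name[0] for name in out.leaf_order]
            runs = sum(1 for i in range(1, len(order)) if order[i] != order[i - 1])
            if runs == 2:  # three contiguous blocks
                hits += 1
        assert hits >= 19

    def test_requires_two_tables_and_three_genes(self, rng):
        genes = [f"G{i}" for i in range(5)]
        tabs = self.tables_from_matrix({"a": rng.normal(size=5)}, genes)
        with pytest.raises(ValueError):
            correlation_cluster(tabs, set(genes))
        tabs2 = self.tables_from_matrix({"a": rng.normal(size=5), "b": rng.normal(size=5)}, genes)
        with pytest.raises(ValueError):
            correlation_cluster(tabs2, {"G0", "G1"})
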
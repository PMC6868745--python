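from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reosig import (
    GenePair,
    enumerate_pairs,
    fisher_one_sided,
    pair_apparent_accuracy,
    rank_diff_stat,
    reo_counts,
    screen_pairs,
)
from reosig.pair_screen import write_pair_stats
from reosig.subtype_opposite import OppositeGeneSet
from _oracles import hypergeom_one_sided_p, random_monotone_transform
from conftest import make_matrix


def _two_class_matrix(scc_pairs, adc_pairs, extra_rows=None):
    """Matrix with genes (gA, gB) and per-sample (Ea, Eb) tuples per class."""
    cols = list(scc_pairs) + list(adc_pairs)
    labels = ["SCC"] * len(scc_pairs) + ["ADC"] * len(adc_pairs)
    values = np.array(cols, dtype=float).T
    if extra_rows is not None:
        values = np.vstack([values, extra_rows])
    genes = ["gA", "gB"] + [f"x{i}" for i in range(values.shape[0] - 2)]
    return make_matrix(values, gene_ids=genes, labels=labels)


class TestReoCounts:
    def test_direct_count(self):
        m = _two_class_matrix([(5, 1), (3, 2)], [(1, 5), (2, 3)])
        assert reo_counts(m, GenePair("gA", "gB")) == (2, 2, 0, 2)

    def test_tie_not_counted(self):
        m = _two_class_matrix([(4, 4)], [(1, 2)])
        assert reo_counts(m, GenePair("gA", "gB")) == (0, 1, 0, 1)

    def test_missing_gene_named(self):
        m = _two_class_matrix([(5, 1)], [(1, 5)])
        with pytest.raises(KeyError, match="nope"):
            reo_counts(m, GenePair("nope", "gB"))

    def test_invariant_under_per_sample_monotone_transform(self, rng):
        m = _two_class_matrix(
            [(5, 1), (3, 2), (2, 6)], [(1, 5), (2, 3)], extra_rows=rng.normal(size=(3, 5))
        )
        base = reo_counts(m, GenePair("gA", "gB"))
        for _ in range(25):
            vals = m.values.copy()
            for j in range(m.n_samples):
                vals[:, j] = random_monotone_transform(rng)(vals[:, j])
            m2 = make_matrix(vals, gene_ids=m.gene_ids, labels=m.labels)
            assert reo_counts(m2, GenePair("gA", "gB")) == base


class TestFisherOneSided:
    def test_equal_frequencies_null_direction(self):
        assert fisher_one_sided(5, 10, 5, 10) >= 0.5

    def test_2_2_0_2_is_one_sixth(self):
        # oracle: enumerate all C(4,2) assignments under fixed margins
        assert hypergeom_one_sided_p(2, 2, 0, 2) == pytest.approx(1 / 6)
        assert fisher_one_sided(2, 2, 0, 2) == pytest.approx(1 / 6)

    def test_tail_identity(self):
        # p(greater) + p(less) - p(observed) == 1
        from scipy.stats import fisher_exact, hypergeom

        a, n1, b, n2 = 7, 9, 2, 8
        p_greater = fisher_one_sided(a, n1, b, n2)
        p_less = float(
            fisher_exact([[a, n1 - a], [b, n2 - b]], alternative="less")[1]
        )
        p_obs = float(hypergeom.pmf(a, n1 + n2, a + b, n1))
        assert p_greater + p_less - p_obs == pytest.approx(1.0)

    def test_swapping_roles_gives_opposite_tail(self):
        from scipy.stats import fisher_exact

        a, n1, b, n2 = 6, 8, 1, 7
        assert fisher_one_sided(b, n2, a, n1) == pytest.approx(
            float(fisher_exact([[a, n1 - a], [b, n2 - b]], alternative="less")[1])
        )

    def test_zero_group_is_error(self):
        with pytest.raises(ValueError):
            fisher_one_sided(0, 0, 1, 2)

    def test_agrees_with_enumeration_oracle_small_margins(self):
        for n1 in range(1, 8):
            for n2 in range(1, 8):
                for a in range(n1 + 1):
                    for b in range(n2 + 1):
                        assert fisher_one_sided(a, n1, b, n2) == pytest.approx(
                            hypergeom_one_sided_p(a, n1, b, n2), abs=1e-12
                        )


class TestEnumeratePairs:
    @settings(max_examples=25, deadline=None)
    @given(n=st.integers(2, 40))
    def test_pair_count_formula(self, n):
        genes = [f"g{i}" for i in range(n)]
        assert len(enumerate_pairs(genes)) == n * (n - 1) // 2

    def test_two_genes_one_pair(self):
        assert enumerate_pairs(["a", "b"]) == [GenePair("a", "b")]

    def test_duplicate_rejected(self):
        with pytest.raises(ValueError):
            enumerate_pairs(["a", "a"])

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError):
            GenePair("a", "a")


class TestApparentAccuracy:
    def test_98_43_example(self):
        from reosig import percent, two_gene_cohort

        m = two_gene_cohort(99, 92, miscalled_adc=0, miscalled_scc=3)
        rep = pair_apparent_accuracy(m, GenePair("KRT5", "AGR2"))
        assert (rep.C, rep.M) == (188, 191)
        assert percent(rep.C, rep.M) == 98.43

    def test_94_44_example(self):
        from reosig import percent, two_gene_cohort

        m = two_gene_cohort(45, 27, miscalled_adc=3, miscalled_scc=1)
        rep = pair_apparent_accuracy(m, GenePair("KRT5", "AGR2"))
        assert (rep.C, rep.M) == (68, 72)
        assert percent(rep.C, rep.M) == 94.44

    def test_perfect_agreement(self):
        m = _two_class_matrix([(5, 1), (4, 2)], [(1, 5), (2, 4)])
        rep = pair_apparent_accuracy(m, GenePair("gA", "gB"))
        assert rep.accuracy == 1.0
        assert rep.reclassified_to_scc == [] and rep.reclassified_to_adc == []

    def test_unlabeled_excluded(self):
        m = make_matrix(
            [[5.0, 1.0, 3.0], [1.0, 5.0, 2.0]],
            gene_ids=["gA", "gB"],
            labels=["SCC", "ADC", "UNKNOWN"],
        )
        rep = pair_apparent_accuracy(m, GenePair("gA", "gB"))
        assert rep.M == 2 and rep.C == 2

    def test_reorientation_complements_accuracy_on_tie_free_data(self, rng):
        vals = rng.normal(size=(2, 30))
        labels = ["SCC"] * 15 + ["ADC"] * 15
        m = make_matrix(vals, gene_ids=["gA", "gB"], labels=labels)
        a = pair_apparent_accuracy(m, GenePair("gA", "gB")).accuracy
        b = pair_apparent_accuracy(m, GenePair("gB", "gA")).accuracy
        assert a + b == pytest.approx(1.0)

    def test_sens_spec_decomposition(self):
        m = _two_class_matrix([(5, 1), (1, 5), (4, 2)], [(1, 5), (5, 1)])
        rep = pair_apparent_accuracy(m, GenePair("gA", "gB"))
        assert rep.C == pytest.approx(
            rep.sensitivity * rep.n_adc + rep.specificity * rep.n_scc
        )


class TestRankDiffStat:
    def test_geometric_mean_of_class_means(self):
        # one sample per class; rank diffs 9 (SCC) and 4 (ADC) -> sqrt(36) = 6
        scc = [10, 1, 2, 3, 4, 5, 6, 7, 8, 9]  # gA rank 10, gB rank 1 -> diff 9
        adc = [5, 1, 2, 3, 4, 10, 9, 8, 7, 6]  # gA rank 5, gB rank 1 -> diff 4
        values = np.array([scc, adc], dtype=float).T
        m = make_matrix(values, gene_ids=["gA", "gB"] + [f"x{i}" for i in range(8)],
                        labels=["SCC", "ADC"])
        assert rank_diff_stat(m, GenePair("gA", "gB")) == pytest.approx(6.0)

    def test_constant_rank_diff(self):
        # gA always ranks 3, gB always ranks 1 among 3 genes -> R = 2 everywhere
        values = np.array([[9, 9, 9, 9], [1, 1, 1, 1], [5, 5, 5, 5]], dtype=float)
        m = make_matrix(values, gene_ids=["gA", "gB", "gC"],
                        labels=["SCC", "SCC", "ADC", "ADC"])
        assert rank_diff_stat(m, GenePair("gA", "gB")) == pytest.approx(2.0)

    def test_hand_computed_nested_geometric_means(self):
        # 5-gene toy, 3 samples per class, ranks assigned by construction
        ranks_per_sample = {
            "SCC": [(5, 1), (4, 2), (5, 2)],  # diffs 4, 2, 3
            "ADC": [(1, 5), (2, 4), (1, 4)],  # diffs 4, 2, 3
        }
        cols, labels = [], []
        for label, pairs in ranks_per_sample.items():
            for ra, rb in pairs:
                others = [r for r in (1, 2, 3, 4, 5) if r not in (ra, rb)]
                cols.append([ra, rb] + others)
                labels.append(label)
        values = np.array(cols, dtype=float).T
        m = make_matrix(values, gene_ids=["gA", "gB", "c1", "c2", "c3"], labels=labels)
        gm = (4 * 2 * 3) ** (1 / 3)
        assert rank_diff_stat(m, GenePair("gA", "gB")) == pytest.approx(math.sqrt(gm * gm))

    def test_zero_diff_floored_at_one(self):
        values = np.array([[5.0, 5.0], [5.0, 5.0], [1.0, 9.0]], dtype=float)
        m = make_matrix(values, gene_ids=["gA", "gB", "gC"], labels=["SCC", "ADC"])
        assert rank_diff_stat(m, GenePair("gA", "gB")) == pytest.approx(1.0)

    def test_invariant_under_per_sample_monotone_transform(self, rng):
        vals = rng.normal(size=(6, 10))
        labels = ["SCC"] * 5 + ["ADC"] * 5
        m = make_matrix(vals, labels=labels)
        base = rank_diff_stat(m, GenePair("g1", "g2"))
        for _ in range(25):
            v2 = vals.copy()
            for j in range(10):
                v2[:, j] = random_monotone_transform(rng)(v2[:, j])
            m2 = make_matrix(v2, labels=labels)
            assert rank_diff_stat(m2, GenePair("g1", "g2")) == pytest.approx(base)


class TestScreenPairs:
    def test_planted_pair_attains_minimum_p(self, rng):
        # 10 genes, 20 samples; g1/g2 separate perfectly, the rest are noise
        n = 20
        labels = ["SCC"] * 10 + ["ADC"] * 10
        vals = rng.normal(8, 1, size=(10, n))
        vals[0, :10] = rng.normal(12, 0.5, size=10)  # g1 high in SCC
        vals[1, :10] = rng.normal(4, 0.5, size=10)   # g2 low in SCC
        vals[0, 10:] = rng.normal(4, 0.5, size=10)
        vals[1, 10:] = rng.normal(12, 0.5, size=10)
        m = make_matrix(vals, labels=labels)
        stats = screen_pairs(m, [f"g{i + 1}" for i in range(10)], keep_all=True)
        # brute-force oracle: every pair's p via direct enumeration
        oracle_ps = {}
        for s in stats:
            oracle_ps[s.pair.unordered] = hypergeom_one_sided_p(
                s.n_scc_pattern, s.n_scc, s.n_adc_pattern, s.n_adc
            )
            assert s.p == pytest.approx(oracle_ps[s.pair.unordered], abs=1e-10)
        planted = frozenset({"g1", "g2"})
        best_p = min(oracle_ps.values())
        assert oracle_ps[planted] == pytest.approx(best_p)
        planted_stats = next(s for s in stats if s.pair.unordered == planted)
        assert planted_stats.p == pytest.approx(best_p)
        assert planted_stats.apparent_accuracy == 1.0

    def test_pair_count_and_orientation(self, rng):
        labels = ["SCC"] * 6 + ["ADC"] * 6
        m = make_matrix(rng.normal(size=(5, 12)), labels=labels)
        stats = screen_pairs(m, [f"g{i + 1}" for i in range(5)], keep_all=True)
        assert len(stats) == 10
        for s in stats:
            # SCC pattern frequency must not be below the ADC pattern frequency
            assert s.n_scc_pattern * s.n_adc >= s.n_adc_pattern * s.n_scc

    def test_opposite_gene_set_input(self, rng):
        labels = ["SCC"] * 4 + ["ADC"] * 4
        m = make_matrix(rng.normal(size=(3, 8)), labels=labels)
        genes = OppositeGeneSet("d", [("g1", "UP", "DOWN"), ("g2", "DOWN", "UP")])
        stats = screen_pairs(m, genes, keep_all=True)
        assert len(stats) == 1

    def test_single_gene_is_error(self, rng):
        m = make_matrix(rng.normal(size=(2, 4)), labels=["SCC", "SCC", "ADC", "ADC"])
        with pytest.raises(ValueError, match="2 candidate"):
            screen_pairs(m, ["g1"])

    def test_fdr_filters(self):
        # perfectly separating pair among 2 genes, tiny cohort: p = 1/C(8,4)... but
        # with one pair the BH fdr equals p; just check the filter is applied
        scc = [(5.0, 1.0)] * 6
        adc = [(1.0, 5.0)] * 6
        m = _two_class_matrix(scc, adc)
        sig = screen_pairs(m, ["gA", "gB"], fdr_alpha=0.05)
        assert len(sig) == 1 and sig[0].fdr < 0.05
        none = screen_pairs(m, ["gA", "gB"], fdr_alpha=1e-6)
        assert none == []

    def test_write_pair_stats_sorted(self, tmp_path, rng):
        labels = ["SCC"] * 6 + ["ADC"] * 6
        m = make_matrix(rng.normal(size=(4, 12)), labels=labels)
        stats = screen_pairs(m, [f"g{i + 1}" for i in range(4)], keep_all=True)
        path = tmp_path / "pairs.tsv"
        write_pair_stats(stats, path)
        lines = path.read_text().splitlines()
        accs = [float(l.split("\t")[8]) for l in lines[1:]]
        assert accs == sorted(accs, reverse=True)
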
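"""Nucleotide diversity (exact and approximate), concordance, evaluation stats."""

import numpy as np
import pytest

from allelekde import (
    KernelSpec,
    build_distance_space,
    concordance_rate,
    counting_diversity,
    estimate_frequencies,
    evaluation_stats,
    expected_distance_beyond,
    nucleotide_diversity_approx,
    nucleotide_diversity_exact,
    tally_alleles,
)
from allelekde.io import Alignment
from conftest import oracle_pi, random_detected


def table_of(seqs):
    return tally_alleles(
        Alignment(ids=tuple(map(str, range(len(seqs)))), sequences=tuple(seqs))
    )


class TestExactDiversity:
    def test_two_alleles_half_half(self):
        res = nucleotide_diversity_exact({"AA": 0.5, "AT": 0.5})
        assert res.pi == pytest.approx(0.25)

    def test_monomorphic_is_zero(self):
        assert nucleotide_diversity_exact({"ACGT": 1.0}).pi == 0.0

    def test_counting_equals_exact_on_sample_frequencies(self):
        table = table_of(["AAT", "AAA", "AAT", "GAT", "GAT", "GAT"])
        res = counting_diversity(table)
        assert res.pi == pytest.approx(oracle_pi(table.frequencies, 3))

    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValueError):
            nucleotide_diversity_exact({"AA": 0.5, "AT": 0.4})

    def test_bounded_by_jukes_cantor_ceiling(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            alleles = random_detected(rng, 4, 4)
            p = rng.dirichlet(np.ones(4))
            res = nucleotide_diversity_exact(dict(zip(alleles, p)))
            assert 0.0 <= res.pi <= 0.75


class TestApproxDiversity:
    def test_m_zero_equals_counting(self):
        table = table_of(["AAT", "AAA", "AAT", "GAT"])
        space = build_distance_space(table.alleles, 0)
        est = estimate_frequencies(table, KernelSpec(P=0.0, l=3, m=0), space)
        got = nucleotide_diversity_approx(est)
        assert got.pi == pytest.approx(counting_diversity(table).pi)

    @pytest.mark.parametrize("l,k,m", [(2, 2, 2), (3, 3, 3), (4, 2, 4)])
    def test_all_terms_match_sequence_space_exact(self, l, k, m):
        """With undetected-undetected pairs included, the approximation is exact."""
        rng = np.random.default_rng(13 * l + k)
        seqs = list(random_detected(rng, l, k)) * 2
        table = table_of(seqs)
        space = build_distance_space(table.alleles, m, keep_members=True)
        est = estimate_frequencies(table, KernelSpec(P=0.09, l=l, m=m), space)
        full = nucleotide_diversity_approx(est, include_undetected_pairs=True)
        freqs = {
            seq: est.sequence_mass(seq)
            for members in space.members
            for seq in members
        }
        assert full.pi == pytest.approx(oracle_pi(freqs, l), abs=1e-10)

    @pytest.mark.parametrize("m", [1, 2])
    def test_truncation_only_drops_nonnegative_terms(self, m):
        rng = np.random.default_rng(m)
        seqs = list(random_detected(rng, 4, 3)) * 2
        table = table_of(seqs)
        space = build_distance_space(table.alleles, m, keep_members=True)
        est = estimate_frequencies(table, KernelSpec(P=0.12, l=4, m=m), space)
        approx = nucleotide_diversity_approx(est)
        full = nucleotide_diversity_approx(est, include_undetected_pairs=True)
        assert approx.pi <= full.pi + 1e-12

    def test_censored_distance_recovery_against_enumeration(self):
        """The INF-entry distance term equals the enumerated conditional mean."""
        from conftest import all_sequences, oracle_hamming

        A, B = "AAAA", "ATTA"  # d = 2
        l, m, x = 4, 1, 1
        dists = [
            oracle_hamming(s, B)
            for s in all_sequences(l)
            if oracle_hamming(s, A) == x and oracle_hamming(s, B) > m
        ]
        assert expected_distance_beyond(2, l, x, m) == pytest.approx(np.mean(dists))

    def test_impossible_censoring_is_nan(self):
        assert np.isnan(expected_distance_beyond(0, 4, 1, 2))


class TestConcordance:
    def test_identical_distributions_score_one(self):
        table = table_of(["AA", "AT", "AA", "AT"])
        space = build_distance_space(table.alleles, 1)
        est = estimate_frequencies(table, KernelSpec(P=0.0, l=2, m=1), space)
        assert concordance_rate({"AA": 0.5, "AT": 0.5}, est) == pytest.approx(1.0)

    def test_disjoint_supports_score_minus_one(self):
        table = table_of(["AA", "AA"])
        space = build_distance_space(table.alleles, 0)
        est = estimate_frequencies(table, KernelSpec(P=0.0, l=2, m=0), space)
        assert concordance_rate({"GG": 0.7, "GC": 0.3}, est) == pytest.approx(-1.0)

    def test_counting_sample_against_population(self, aa_at_table):
        space = build_distance_space(aa_at_table.alleles, 0)
        est = estimate_frequencies(aa_at_table, KernelSpec(P=0.0, l=2, m=0), space)
        got = concordance_rate({"AA": 0.6, "AT": 0.4}, est)
        assert got == pytest.approx(1 - (0.1 + 0.1))

    def test_population_alleles_map_onto_undetected_coordinates(self, aa_at_table):
        space = build_distance_space(aa_at_table.alleles, 2)
        est = estimate_frequencies(aa_at_table, KernelSpec(P=0.1, l=2, m=2), space)
        truth = {"AA": 0.4, "AT": 0.4, "AG": 0.1, "AC": 0.1}
        # AG and AC share coordinate (1,1): their true mass adds there
        idx = space.index_of((1, 1))
        expected = 1 - (
            abs(0.4 - est.mass[0])
            + abs(0.4 - est.mass[1])
            + abs(0.2 - est.mass[idx])
            + (est.mass.sum() - est.mass[0] - est.mass[1] - est.mass[idx])
        )
        assert concordance_rate(truth, est) == pytest.approx(expected)


class TestEvaluationStats:
    def test_perfect_estimates(self):
        s = evaluation_stats([2.0, 2.0, 2.0], 2.0)
        assert s.relative_bias == 0.0 and s.accuracy == 0.0 and s.squared_accuracy == 0.0

    def test_symmetric_errors_cancel_bias_not_accuracy(self):
        s = evaluation_stats([0.9, 1.1], 1.0)
        assert s.relative_bias == pytest.approx(0.0)
        assert s.accuracy == pytest.approx(0.1)
        assert s.squared_accuracy == pytest.approx(0.01)

    def test_accuracy_dominates_bias(self):
        rng = np.random.default_rng(11)
        x = rng.lognormal(0, 0.4, size=20)
        s = evaluation_stats(x, 1.0)
        assert s.accuracy >= abs(s.relative_bias)
        assert s.n_replicates == 20

    def test_truth_zero_rejected(self):
        with pytest.raises(ValueError):
            evaluation_stats([1.0], 0.0)

    def test_per_replicate_truth_vector(self):
        s = evaluation_stats([1.0, 4.0], [2.0, 2.0])
        assert s.relative_bias == pytest.approx((-0.5 + 1.0) / 2)
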
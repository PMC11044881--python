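"""KDE on sequence and distance spaces, CV criteria and bandwidth selection."""

import math

import numpy as np
import pytest

from allelekde import (
    AlleleFrequencyKDE,
    ConfigurationError,
    KernelSpec,
    build_distance_space,
    build_sequence_space,
    default_bandwidth_grid,
    estimate_frequencies,
    lcv_score,
    loo_density,
    lscv_score,
    select_bandwidth,
    tally_alleles,
)
from allelekde.io import Alignment
from conftest import (
    oracle_lcv,
    oracle_loo,
    oracle_lscv,
    oracle_sequence_space_estimate,
    random_detected,
)


def table_of(seqs):
    return tally_alleles(
        Alignment(ids=tuple(map(str, range(len(seqs)))), sequences=tuple(seqs))
    )


AA_AT = ["AA"] * 3 + ["AT"] * 3


class TestEstimate:
    def test_zero_bandwidth_is_counting(self, aa_at_table):
        space = build_distance_space(aa_at_table.alleles, 2)
        est = estimate_frequencies(aa_at_table, KernelSpec(P=0.0, l=2, m=2), space)
        np.testing.assert_allclose(est.mass, [0.5, 0.5, 0, 0, 0, 0], atol=0)

    def test_mutation_number_zero_is_counting(self, aa_at_table):
        space = build_distance_space(aa_at_table.alleles, 0)
        est = estimate_frequencies(aa_at_table, KernelSpec(P=0.2, l=2, m=0), space)
        np.testing.assert_allclose(est.mass, [0.5, 0.5], atol=0)

    def test_doubly_adjacent_alleles_get_extra_mass(self, aa_at_table):
        """AG and AC sit one step from both detected alleles; GG sits two away."""
        space = build_sequence_space(2)
        est = estimate_frequencies(aa_at_table, KernelSpec(P=0.05, l=2, m=2), space)
        ag, ac, gg = (est.sequence_mass(s) for s in ("AG", "AC", "GG"))
        assert ag == ac > gg > 0

    def test_total_mass_is_one_renormalized(self):
        rng = np.random.default_rng(5)
        for l, k, m in [(6, 3, 2), (10, 4, 1), (4, 2, 4)]:
            seqs = list(random_detected(rng, l, k)) * 2
            table = table_of(seqs)
            space = build_distance_space(table.alleles, m)
            for P in (0.0, 0.01, 0.2):
                est = estimate_frequencies(
                    table, KernelSpec(P=P, l=l, m=m, renormalize=True), space
                )
                assert est.total_mass == pytest.approx(1.0, abs=1e-9)
                assert (est.mass >= 0).all()

    def test_unnormalized_truncated_mass_below_one(self):
        table = table_of(AA_AT)
        space = build_distance_space(table.alleles, 1)
        est = estimate_frequencies(
            table, KernelSpec(P=0.1, l=2, m=1, renormalize=False), space
        )
        assert est.total_mass < 1.0

    @pytest.mark.parametrize("l,k,m", [(2, 2, 2), (3, 3, 3), (4, 2, 4), (5, 3, 5)])
    def test_distance_space_equals_sequence_space(self, l, k, m):
        """Per-sequence masses agree with full 4^l enumeration to 1e-12."""
        rng = np.random.default_rng(l + k)
        seqs = list(random_detected(rng, l, k)) + list(random_detected(rng, l, k))
        table = table_of(seqs)
        space = build_distance_space(table.alleles, m)
        P = 0.11
        est = estimate_frequencies(table, KernelSpec(P=P, l=l, m=m), space)
        oracle = oracle_sequence_space_estimate(list(table_expand(table)), P, m, True)
        for seq, mass in oracle.items():
            assert est.sequence_mass(seq) == pytest.approx(mass, abs=1e-12)

    def test_detected_mass_shrinks_as_bandwidth_grows(self, aa_at_table):
        space = build_distance_space(aa_at_table.alleles, 2)
        detected_mass = []
        for P in np.linspace(0.0, 0.24, 13):
            est = estimate_frequencies(aa_at_table, KernelSpec(P=P, l=2, m=2), space)
            detected_mass.append(est.mass[:2].sum())
        assert all(b <= a + 1e-12 for a, b in zip(detected_mass, detected_mass[1:]))

    def test_incompatible_space_rejected(self, aa_at_table):
        other = build_distance_space(("AA", "AG"), 2)
        with pytest.raises(ConfigurationError):
            estimate_frequencies(aa_at_table, KernelSpec(P=0.1, l=2, m=2), other)
        space = build_distance_space(aa_at_table.alleles, 1)
        with pytest.raises(ConfigurationError):
            estimate_frequencies(aa_at_table, KernelSpec(P=0.1, l=2, m=2), space)


def table_expand(table):
    for allele, count in zip(table.alleles, table.counts):
        yield from [allele] * count


class TestLeaveOneOut:
    def test_counting_closed_form(self, aa_at_table):
        spec = KernelSpec(P=0.0, l=2, m=2)
        for i in range(6):
            assert loo_density(aa_at_table, spec, i) == pytest.approx(2 / 5)

    def test_unseen_heldout_allele_gives_zero(self):
        table = table_of(["AA", "AT"])
        assert loo_density(table, KernelSpec(P=0.0, l=2, m=2), 0) == 0.0

    def test_kernel_value_at_distance_one(self):
        table = table_of(["AA", "AT"])
        spec = KernelSpec(P=0.1, l=2, m=2)
        assert loo_density(table, spec, 0) == pytest.approx((1 - 3 * 0.1) * 0.1)
        assert loo_density(table, spec, 0) == pytest.approx(
            oracle_loo(["AA", "AT"], 0.1, 2, True, 0)
        )

    def test_requires_two_individuals(self):
        table = table_of(["AA"])
        with pytest.raises(ValueError):
            loo_density(table, KernelSpec(P=0.1, l=2, m=2), 0)


class TestCVScores:
    def test_lscv_counting_closed_form(self, aa_at_table):
        space = build_distance_space(aa_at_table.alleles, 2)
        got = lscv_score(aa_at_table, KernelSpec(P=0.0, l=2, m=2), space)
        expected = 2 * 0.5**2 - (2 / 6) * 6 * (2 / 5)
        assert got == pytest.approx(expected)

    @pytest.mark.parametrize("l,k,m", [(2, 2, 2), (3, 2, 3), (4, 3, 4), (4, 3, 2)])
    @pytest.mark.parametrize("P", [0.0, 0.05, 0.2])
    def test_lscv_matches_sequence_space_oracle(self, l, k, m, P):
        rng = np.random.default_rng(41 * l + k)
        seqs = list(random_detected(rng, l, k)) * 2 + list(random_detected(rng, l, 1))
        table = table_of(seqs)
        space = build_distance_space(table.alleles, m)
        got = lscv_score(table, KernelSpec(P=P, l=l, m=m), space)
        assert got == pytest.approx(
            oracle_lscv(list(table_expand(table)), P, m, True), abs=1e-10
        )

    def test_lscv_finite_over_bandwidth_range(self, aa_at_table):
        space = build_distance_space(aa_at_table.alleles, 2)
        for P in np.linspace(0, 0.2499, 20):
            assert math.isfinite(
                lscv_score(aa_at_table, KernelSpec(P=P, l=2, m=2), space)
            )

    def test_lcv_counting_closed_form(self, aa_at_table):
        got = lcv_score(aa_at_table, KernelSpec(P=0.0, l=2, m=2))
        assert got == pytest.approx(6 * math.log(2 / 5))

    def test_lcv_minus_inf_for_distinct_pair_at_zero(self):
        table = table_of(["AA", "AT"])
        assert lcv_score(table, KernelSpec(P=0.0, l=2, m=2)) == -math.inf

    def test_lcv_singletons_finite_iff_within_reach(self):
        near = table_of(["AA", "AT", "AG"])  # all within distance 1 of each other
        far = table_of(["AAAA", "TTTT", "CCGG"])  # all beyond m=1
        spec1 = KernelSpec(P=0.05, l=2, m=1)
        assert math.isfinite(lcv_score(near, spec1))
        assert lcv_score(far, KernelSpec(P=0.05, l=4, m=1)) == -math.inf

    @pytest.mark.parametrize("P", [0.02, 0.15])
    def test_lcv_matches_oracle(self, P):
        sample = ["AAT", "AAA", "AAT", "GAT"]
        table = table_of(sample)
        got = lcv_score(table, KernelSpec(P=P, l=3, m=3))
        assert got == pytest.approx(
            oracle_lcv(list(table_expand(table)), P, 3, True), abs=1e-10
        )


class TestSelectBandwidth:
    def test_deterministic(self, aa_at_table):
        a = select_bandwidth(aa_at_table, 2, "lscv")
        b = select_bandwidth(aa_at_table, 2, "lscv")
        assert a.selected_P == b.selected_P
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_lcv_prefers_no_smoothing_when_sample_is_whole_population(self):
        # a concentrated sample: counting already fits the held-out alleles
        table = table_of(["AA"] * 10 + ["AT"] * 10)
        cv = select_bandwidth(table, 2, "lcv")
        assert not cv.fallback
        assert cv.selected_P <= 1e-6

    def test_lcv_all_minus_inf_falls_back_to_zero(self):
        table = table_of(["AAAA", "TTTT"])  # beyond m of each other
        cv = select_bandwidth(table, 1, "lcv")
        assert cv.fallback and cv.selected_P == 0.0

    def test_lscv_refined_optimum_matches_exhaustive_grid(self, aa_at_table):
        space = build_distance_space(aa_at_table.alleles, 2)
        fine = np.arange(0.0, 0.2499, 1e-4)
        scores = [
            lscv_score(aa_at_table, KernelSpec(P=P, l=2, m=2), space) for P in fine
        ]
        exhaustive = fine[int(np.argmin(scores))]
        cv = select_bandwidth(aa_at_table, 2, "lscv", space=space)
        assert abs(cv.selected_P - exhaustive) < 1e-3

    def test_selected_score_is_grid_optimum(self, aa_at_table):
        cv = select_bandwidth(aa_at_table, 2, "lscv", refine=False)
        assert cv.selected_score == cv.scores.min()
        assert cv.selected_P == cv.grid[int(np.argmin(cv.scores))]

    def test_default_grid_shape(self):
        grid = default_bandwidth_grid()
        assert grid[0] == 0.0 and len(grid) == 65 and grid.max() < 0.25


class TestModelAPI:
    def test_fit_summary_and_frame(self, aa_at_alignment):
        model = AlleleFrequencyKDE(aa_at_alignment, mutation_number=2)
        res = model.fit(method="lscv")
        text = res.summary()
        assert "LSCV" in text and "Bandwidth" in text
        df = res.to_frame()
        assert df["frequency"].sum() == pytest.approx(1.0)
        assert len(df) == 6

    def test_from_fasta_roundtrip(self, tmp_path, aa_at_alignment):
        from allelekde import write_alignment

        path = tmp_path / "sample.fa"
        write_alignment(aa_at_alignment, path)
        model = AlleleFrequencyKDE.from_fasta(path, mutation_number=1)
        res = model.fit(bandwidth=0.0)
        assert res.estimate.mass[:2].sum() == pytest.approx(1.0)

    def test_mutation_number_zero_ignores_method(self, aa_at_alignment):
        model = AlleleFrequencyKDE(aa_at_alignment, mutation_number=0)
        res = model.fit(method="lcv")
        assert res.bandwidth == 0.0 and res.cv is None

    def test_fixed_bandwidth_requires_value(self, aa_at_alignment):
        model = AlleleFrequencyKDE(aa_at_alignment, mutation_number=1)
        with pytest.raises(ValueError):
            model.fit(method="none")
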
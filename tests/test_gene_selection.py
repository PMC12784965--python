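"""Gene-level statistics: tallies, C_N/C_S, H and the chi-square tests."""

import numpy as np
import pandas as pd
import pytest

import selscape as ss
from selscape.gene_selection import SelectionMode


def _records(gene, entries):
    """entries: list of (sample, cds_position, consequence)."""
    return pd.DataFrame(
        {
            "sample_id": [e[0] for e in entries],
            "gene_id": gene,
            "transcript_id": "T",
            "cds_position": [e[1] for e in entries],
            "codon_index": [(e[1] - 1) // 3 + 1 for e in entries],
            "ref_base": "A",
            "alt_base": "C",
            "consequence": [e[2] for e in entries],
            "context_class": None,
        }
    )


class TestTallyGene:
    tx = ss.CodingTranscript("G", "T", "ATG" * 12 + "TAA")

    def test_empty_input_gives_zero_counts(self):
        counts = ss.tally_gene(_records("G", []), self.tx)
        assert (counts.N, counts.S, counts.S_N, counts.S_S) == (0, 0, 0, 0)
        assert counts.z.sum() == 0 and len(counts.z) == 12

    def test_recurrent_codon_counted_per_mutation(self):
        entries = [
            ("s1", 19, "missense"),  # codon 7
            ("s2", 20, "missense"),  # codon 7 again, other sample
            ("s3", 25, "missense"),  # codon 9
        ]
        counts = ss.tally_gene(_records("G", entries), self.tx)
        assert counts.N == 3 and counts.S_N == 2
        assert counts.z[6] == 2 and counts.z[8] == 1

    def test_manual_tally_of_mixed_fixture(self):
        entries = (
            [("s%d" % i, 3 * i + 1, "missense") for i in range(5)]
            + [("t%d" % i, 6, "synonymous") for i in range(3)]
            + [("u0", 9, "synonymous"), ("u1", 12, "other")]
        )
        counts = ss.tally_gene(_records("G", entries), self.tx)
        assert counts.N == 5
        assert counts.S == 4
        assert counts.S_N == 5
        assert counts.S_S == 2  # positions 6 and 9
        assert counts.z.sum() == counts.N

    def test_foreign_gene_records_rejected(self):
        with pytest.raises(ValueError):
            ss.tally_gene(_records("OTHER", [("s", 1, "missense")]), self.tx)


class TestComputeCncs:
    def test_zero_numerator(self):
        assert ss.compute_cncs(0, 5, 300.0, 100.0)[0] == 0.0

    def test_balanced_counts_give_unity(self):
        assert ss.compute_cncs(30, 10, 300.0, 100.0)[0] == pytest.approx(1.0)

    def test_zero_s_policy_flags_gene(self):
        value, flags = ss.compute_cncs(10, 0, 300.0, 100.0)
        assert value == pytest.approx((10 / 300) / (0.5 / 100))
        assert "S0_pseudocount" in flags

    def test_no_mutations_at_all_rejected(self):
        with pytest.raises(ValueError):
            ss.compute_cncs(0, 0, 300.0, 100.0)

    def test_scale_invariance_in_opportunities(self):
        a = ss.compute_cncs(17, 5, 321.0, 98.0)[0]
        b = ss.compute_cncs(17, 5, 3210.0, 980.0)[0]
        assert a == pytest.approx(b, rel=1e-12)


class TestComputeH:
    def test_single_hot_site_among_four(self):
        assert ss.compute_H(np.array([0, 0, 0, 4])) == pytest.approx(2 / 3)

    def test_single_hot_site_among_five(self):
        assert ss.compute_H(np.array([5, 0, 0, 0, 0])) == pytest.approx(0.75)

    def test_underdispersed_counts_clamp_to_zero(self):
        assert ss.compute_H(np.array([0, 2, 1, 1])) == 0.0

    def test_equal_counts_give_zero(self):
        assert ss.compute_H(np.array([2, 2, 2, 2])) == 0.0

    def test_no_missense_is_undefined(self):
        assert np.isnan(ss.compute_H(np.zeros(10)))

    def test_concentration_drives_h_toward_one(self):
        n = 10_000
        z = np.zeros(n)
        z[0] = 500
        assert ss.compute_H(z) > 0.99


class TestChisqTest:
    def test_exact_null_fit(self):
        stat, p, _ = ss.cncs_chisq_test(150, 50, 300.0, 100.0, 1.0)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        stat, p, _ = ss.cncs_chisq_test(200, 50, 300.0, 100.0, 1.0, "two-sided")
        assert stat == pytest.approx(3.3333, abs=1e-3)
        assert p == pytest.approx(0.0679, abs=1e-3)

    def test_h_zero_makes_both_nulls_identical(self):
        a = ss.cncs_chisq_test(80, 30, 300.0, 100.0, 1.0, "greater")
        b = ss.cncs_chisq_test(80, 30, 300.0, 100.0, 1.0 - 0.0, "greater")
        assert a == b

    def test_one_sided_wrong_direction_never_significant(self):
        _, p, _ = ss.cncs_chisq_test(10, 50, 300.0, 100.0, 1.0, "greater")
        assert p >= 0.5

    def test_small_expected_cell_flagged(self):
        _, _, flags = ss.cncs_chisq_test(1, 1, 1000.0, 1.0, 1.0)
        assert "small_expected_cell" in flags


class TestSelectionMode:
    def test_dominant_positive(self):
        mode = ss.selection_mode(12.4, 0.9, 1e-30, 0.5)
        assert mode is SelectionMode.DOMINANT_POSITIVE

    def test_weak_positive_band(self):
        mode = ss.selection_mode(0.9, 0.4, 0.5, 0.01)
        assert mode is SelectionMode.WEAK_POSITIVE

    def test_negative(self):
        mode = ss.selection_mode(0.3, 0.4, 0.9, 0.001)
        assert mode is SelectionMode.NEGATIVE

    def test_boundary_unity_is_undetermined(self):
        mode = ss.selection_mode(1.0, 0.2, 1.0, 1.0)
        assert mode is SelectionMode.NEUTRAL_OR_UNDETERMINED


class TestHEstimatorCalibration:
    def test_mean_h_small_under_equal_rates(self, rng):
        """Equal-rate genes should show essentially no heterogeneity."""
        hs = [ss.compute_H(rng.poisson(1.0, 500)) for _ in range(300)]
        assert np.nanmean(hs) < 0.05

    def test_h_converges_to_analytic_two_class_value(self, rng):
        """Two-point rate mixture: H -> 1 - E[r]^2/E[r^2]."""
        n = 10_000
        hot = rng.random(n) < 0.1
        z = np.where(hot, rng.poisson(5.0, n), rng.poisson(1.0, n))
        analytic = 1 - (0.9 * 1 + 0.1 * 5) ** 2 / (0.9 * 1 + 0.1 * 25)
        assert abs(ss.compute_H(z) - analytic) < 0.05

    def test_chi2_type_i_error_near_nominal(self, rng):
        """One-sided test vs null ratio 1 on neutral count pairs."""
        n_rep, rej = 1000, 0
        for _ in range(n_rep):
            N = rng.poisson(50)
            S = rng.poisson(50 / 3)
            if N + S == 0:
                continue
            _, p, _ = ss.cncs_chisq_test(N, S, 300.0, 100.0, 1.0, "greater")
            rej += p < 0.05
        assert rej / n_rep < 0.08
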
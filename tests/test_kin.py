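"""Kinship likelihood-ratio model, calibration, and classification."""

import numpy as np
import pytest

from skatekin.matrix import MISSING, GenotypeMatrix
from skatekin import kin


def _enumerated_hs_table(p: float) -> np.ndarray:
    """Independent oracle: P(g1, g2 | HS) by enumerating alleles.

    g1's alleles are drawn from the population; with probability 1/2 the
    pair shares one IBD allele (a uniformly chosen allele of g1 copied
    into g2, whose other allele is a fresh population draw), otherwise
    g2 is an independent Hardy-Weinberg draw.
    """
    q = 1.0 - p
    allele_p = {0: q, 1: p}
    out = np.zeros((3, 3))
    for a1 in (0, 1):
        for a2 in (0, 1):
            pg1 = allele_p[a1] * allele_p[a2]
            g1 = a1 + a2
            for pick, w_pick in ((a1, 0.5), (a2, 0.5)):
                for b in (0, 1):            # g2's non-IBD allele
                    out[g1, pick + b] += 0.5 * pg1 * w_pick * allele_p[b]
            for b1 in (0, 1):               # unlinked branch (kappa0)
                for b2 in (0, 1):
                    out[g1, b1 + b2] += 0.5 * pg1 * allele_p[b1] * allele_p[b2]
    return out


class TestPairProbabilityModel:
    @pytest.mark.parametrize("hyp", list(kin.KAPPA))
    @pytest.mark.parametrize("error", [0.0, 0.005, 0.05])
    def test_tables_sum_to_one_over_nine_genotype_pairs(self, hyp, error):
        tables = kin.pair_prob_tables([0.1, 0.3, 0.5], kin.KAPPA[hyp], error)
        assert np.allclose(tables.sum(axis=(1, 2)), 1.0, atol=1e-12)

    def test_unrelated_factorises(self):
        t = kin.pair_prob_tables([0.3], kin.KAPPA["U"], 0.0)[0]
        hw = np.array([0.49, 0.42, 0.09])
        assert np.allclose(t, np.outer(hw, hw))

    def test_po_opposing_homozygotes_impossible(self):
        t = kin.pair_prob_tables([0.3], kin.KAPPA["PO"], 0.0)[0]
        assert t[0, 2] == 0.0 and t[2, 0] == 0.0

    def test_hs_table_matches_allele_enumeration(self):
        for p in (0.1, 0.3, 0.5):
            t = kin.pair_prob_tables([p], kin.KAPPA["HS"], 0.0)[0]
            assert np.allclose(t, _enumerated_hs_table(p), atol=1e-12)

    def test_both_het_at_half_frequency_is_uninformative(self):
        # p = 0.5, both heterozygous: P is 1/4 under both HS and U
        lam = (kin.genotype_pair_loglik(1, 1, 0.5, kin.KAPPA["HS"])
               - kin.genotype_pair_loglik(1, 1, 0.5, kin.KAPPA["U"]))
        assert lam == pytest.approx(0.0, abs=1e-12)

    def test_missing_call_contributes_zero(self):
        assert kin.genotype_pair_loglik(MISSING, 1, 0.3,
                                        kin.KAPPA["HS"]) == 0.0


@pytest.fixture(scope="module")
def matrix():
    rng = np.random.default_rng(2)
    p = rng.uniform(0.05, 0.5, 40)
    calls = rng.binomial(2, p, (8, 40)).astype(np.int8)
    calls[rng.random(calls.shape) < 0.1] = MISSING
    return GenotypeMatrix(
        calls, np.array([f"s{i}" for i in range(8)], dtype=object),
        np.array([f"l{j}" for j in range(40)], dtype=object))


@pytest.fixture(scope="module")
def calib():
    rng = np.random.default_rng(4)
    freqs = rng.uniform(0.05, 0.5, 100)
    return kin.simulate_lr_distributions(freqs, "HS", "U", n_sim=20_000,
                                         error_rate=0.005, rng=9)


class TestPairScores:
    def test_antisymmetric_under_hypothesis_swap(self, matrix):
        a = kin.pair_lr(matrix, ("s0", "s1"), "HS", "U", error_rate=0.01)
        b = kin.pair_lr(matrix, ("s0", "s1"), "U", "HS", error_rate=0.01)
        assert a == pytest.approx(-b, rel=1e-12)

    def test_matrix_route_matches_per_pair_loop(self, matrix):
        freqs = matrix.allele_freq()
        lam = kin.all_pairs_lambda(matrix, "HS", "U", freqs, 0.01)
        for i in range(8):
            for j in range(i + 1, 8):
                direct = kin.pair_lr(matrix,
                                     (matrix.samples[i], matrix.samples[j]),
                                     "HS", "U", freqs, 0.01)
                assert lam[i, j] == pytest.approx(direct, abs=1e-9)

    def test_uninformative_locus_leaves_lambda_unchanged(self, matrix):
        lam0 = kin.pair_lr(matrix, ("s2", "s3"), "HS", "U", error_rate=0.01)
        calls = np.hstack([matrix.calls,
                           np.full((8, 1), MISSING, dtype=np.int8)])
        bigger = GenotypeMatrix(
            calls, matrix.samples,
            np.append(matrix.loci, "extra").astype(object))
        freqs = np.append(matrix.allele_freq(), 0.5)
        lam1 = kin.pair_lr(bigger, ("s2", "s3"), "HS", "U", freqs, 0.01)
        assert lam1 == pytest.approx(lam0, abs=1e-12)

    def test_pair_count_combinatorics(self):
        assert kin.n_pairs(662) == 218_791
        assert kin.n_pairs(4) == 6


class TestCalibration:
    def test_degenerate_frequencies_rejected(self):
        with pytest.raises(ValueError):
            kin.simulate_lr_distributions(np.ones(5), "HS", "U", rng=0)

    def test_threshold_limits(self, calib):
        assert calib.fnr(-1e9) == 0.0
        assert calib.fpr_naive(-1e9) == 1.0

    def test_importance_sampling_agrees_with_naive_mc(self, calib):
        """At a moderate threshold both tail estimators see the same FPR."""
        thr = np.quantile(calib.lam_h0, 0.98)
        naive = calib.fpr_naive(thr)
        via_is = calib.fpr(thr)
        se = np.sqrt(naive * (1 - naive) / calib.lam_h0.size)
        assert abs(via_is - naive) < 3 * se + 1e-4

    def test_choose_threshold_meets_false_positive_budget(self, calib):
        choice = kin.choose_threshold(calib, n_comparisons=200_000,
                                      target_expected_fp=0.1)
        assert choice["expected_fp"] <= 0.1
        assert 0.0 <= choice["fnr"] <= 1.0

    def test_large_panel_separates_hs_from_unrelated(self):
        """1500 loci at MAF ~ U(0.05, 0.5): misclassification < 1e-3 at the
        midpoint threshold."""
        rng = np.random.default_rng(6)
        freqs = rng.uniform(0.05, 0.5, 1500)
        calib = kin.simulate_lr_distributions(freqs, "HS", "U", n_sim=5000,
                                              error_rate=0.005, rng=8)
        mid = 0.5 * (calib.lam_h1.mean() + calib.lam_h0.mean())
        assert calib.fnr(mid) < 1e-3
        assert calib.fpr(mid) < 1e-3


class TestClassification:
    def test_detected_kin_are_truly_related(self, small_dataset):
        gm = small_dataset.genotypes
        thr, info = kin.calibrate_thresholds(
            gm.allele_freq(), kin.n_pairs(gm.n_samples), error_rate=0.005,
            n_sim=10_000, rng=5)
        table = kin.classify_pairs(gm, thr, metadata=small_dataset.metadata,
                                   error_rate=0.005)
        related = set(map(frozenset,
                          small_dataset.truth[["id1", "id2"]].values))
        flagged = set(map(frozenset, table[["id1", "id2"]].values))
        unrelated_hits = [p for p in flagged if p not in related]
        # expected false positives were budgeted at 0.1 pairs
        assert len(unrelated_hits) <= 1
        assert {"year1", "year2", "distance_km"} <= set(table.columns)

    def test_frequency_vector_must_match_locus_set(self, small_dataset):
        gm = small_dataset.genotypes
        with pytest.raises(ValueError, match="locus"):
            kin.classify_pairs(gm, kin.KinThresholds(hs_u=10.0),
                               freqs=np.full(3, 0.2))
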
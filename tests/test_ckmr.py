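"""HSP pseudo-likelihood, comparison aggregation, and the MH sampler."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import small_config
from skatekin import ckmr
from skatekin.simulate import simulate_dataset


def _meta(births, years=None):
    n = len(births)
    years = years or [b + 5 for b in births]
    return pd.DataFrame({"id": [f"i{k}" for k in range(n)],
                         "year": years, "birth_year": births})


EMPTY_KIN = pd.DataFrame(columns=["id1", "id2", "category"])


class TestHspProb:
    def test_boundary_probability_one(self):
        p = ckmr.hsp_prob(2000, 2003, ckmr.DemographicParams(4, 0.0, 1.0),
                          year0=2000)
        assert p == pytest.approx(1.0)

    def test_hand_evaluated_value(self):
        p = ckmr.hsp_prob(2002, 2005,
                          ckmr.DemographicParams(25_000, 0.0, 0.828),
                          year0=2002)
        assert p == pytest.approx(4 / 25_000 * 0.828 ** 3, rel=1e-12)
        assert p == pytest.approx(9.08e-5, rel=2e-3)

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            ckmr.hsp_prob(2005, 2005, ckmr.DemographicParams(100, 0, 0.8),
                          year0=2000)

    def test_monotone_in_abundance_and_gap(self):
        base = ckmr.hsp_prob(2000, 2003,
                             ckmr.DemographicParams(1000, 0, 0.8), 2000)
        bigger_n = ckmr.hsp_prob(2000, 2003,
                                 ckmr.DemographicParams(2000, 0, 0.8), 2000)
        longer_gap = ckmr.hsp_prob(2000, 2006,
                                   ckmr.DemographicParams(1000, 0, 0.8), 2000)
        assert bigger_n < base and longer_gap < base


class TestBuildComparisons:
    def test_hand_enumerated_cross_cohort_pairs(self):
        counts = ckmr.build_comparisons(_meta([2000, 2000, 2001, 2002]),
                                        EMPTY_KIN)
        assert counts.total_comparisons == 5
        cells = dict(zip(zip(counts.b_i, counts.b_j), counts.n_comparisons))
        assert cells == {(2000, 2001): 2, (2000, 2002): 2, (2001, 2002): 1}

    def test_all_same_cohort_gives_no_comparisons(self):
        counts = ckmr.build_comparisons(_meta([2000] * 5), EMPTY_KIN)
        assert counts.total_comparisons == 0

    def test_age_cap_removes_individuals(self):
        meta = _meta([1980, 2000, 2001], years=[2010, 2010, 2010])
        counts = ckmr.build_comparisons(meta, EMPTY_KIN, age_cap=15)
        assert counts.total_comparisons == 1      # only the 2000-2001 pair

    def test_excluded_categories_leave_both_pools(self):
        meta = _meta([2000, 2001, 2002])
        kin = pd.DataFrame({"id1": ["i0"], "id2": ["i1"],
                            "category": ["FS"]})
        counts = ckmr.build_comparisons(meta, kin)
        assert counts.total_comparisons == 2      # 3 cross-cohort minus FS
        assert counts.total_hsp == 0

    def test_hsp_missing_from_metadata_errors(self):
        kin = pd.DataFrame({"id1": ["ghost"], "id2": ["i0"],
                            "category": ["HS"]})
        with pytest.raises(ValueError, match="ghost"):
            ckmr.build_comparisons(_meta([2000, 2001]), kin)

    def test_same_cohort_hsp_dropped(self):
        meta = _meta([2000, 2000, 2001])
        kin = pd.DataFrame({"id1": ["i0", "i0"], "id2": ["i1", "i2"],
                            "category": ["HS", "HS"]})
        counts = ckmr.build_comparisons(meta, kin)
        assert counts.total_hsp == 1              # only the cross-cohort HSP


class TestPseudoLikelihood:
    def test_aggregated_equals_per_pair_product(self):
        """The cell-aggregated log likelihood must equal the naive product
        over every retained pair of a 200-individual synthetic set."""
        rng = np.random.default_rng(33)
        births = rng.integers(1996, 2012, size=200)
        meta = _meta(births.tolist(), years=(births + 4).tolist())
        hs_rows = []
        ids = meta["id"].to_numpy()
        for k in range(12):   # plant HSPs on distinct cross-cohort pairs
            i, j = 2 * k, 2 * k + 1
            if births[i] != births[j]:
                hs_rows.append({"id1": ids[i], "id2": ids[j],
                                "category": "HS"})
        kin = pd.DataFrame(hs_rows)
        counts = ckmr.build_comparisons(meta, kin)
        params = ckmr.DemographicParams(5000, 0.05, 0.85)

        hs_set = set(map(frozenset, kin[["id1", "id2"]].values))
        ll = 0.0
        for a in range(200):
            for b in range(a + 1, 200):
                bi, bj = sorted((births[a], births[b]))
                if bi == bj:
                    continue
                p = ckmr.hsp_prob(bi, bj, params, counts.year0)
                if frozenset((ids[a], ids[b])) in hs_set:
                    ll += math.log(p)
                else:
                    ll += math.log1p(-p)
        agg = ckmr.log_pseudo_likelihood(counts, params)
        assert agg == pytest.approx(ll, abs=1e-8)

    def test_zero_hsp_limit_approaches_zero_from_below(self):
        counts = ckmr.build_comparisons(_meta([2000, 2001, 2002]), EMPTY_KIN)
        ll = ckmr.log_pseudo_likelihood(
            counts, ckmr.DemographicParams(1e9, 0.0, 0.9))
        assert -1e-6 < ll < 0.0

    def test_single_cell_maximised_at_binomial_mle(self):
        counts = ckmr.CohortComparisonCounts(
            b_i=np.array([2000]), b_j=np.array([2003]),
            n_hsp=np.array([7]), n_comparisons=np.array([1000]),
            year0=2000)
        phi = 0.9
        p_hat = 7 / 1000
        n0_star = 4.0 * phi ** 3 / p_hat
        best = ckmr.log_pseudo_likelihood(
            counts, ckmr.DemographicParams(n0_star, 0.0, phi))
        for factor in (0.9, 1.1):
            other = ckmr.log_pseudo_likelihood(
                counts, ckmr.DemographicParams(n0_star * factor, 0.0, phi))
            assert other < best

    def test_impossible_probability_is_minus_infinity(self):
        counts = ckmr.CohortComparisonCounts(
            b_i=np.array([2000]), b_j=np.array([2001]),
            n_hsp=np.array([1]), n_comparisons=np.array([10]), year0=2000)
        ll = ckmr.log_pseudo_likelihood(
            counts, ckmr.DemographicParams(2, 0.0, 1.0))   # p = 2 > 1
        assert ll == -math.inf


class TestExpectedHspCount:
    def test_quadratic_scaling_with_sample_size(self):
        params = ckmr.DemographicParams(5000, 0.05, 0.85)
        sizes = {2000: 30, 2002: 40, 2005: 50}
        e1 = ckmr.expected_hsp_count(params, sizes, year0=1996)
        e2 = ckmr.expected_hsp_count(params,
                                     {y: 2 * n for y, n in sizes.items()},
                                     year0=1996)
        assert e2 == pytest.approx(4 * e1, rel=1e-12)

    def test_zero_samples_zero_expectation(self):
        params = ckmr.DemographicParams(5000, 0.05, 0.85)
        assert ckmr.expected_hsp_count(params, {}) == 0.0
        assert ckmr.expected_hsp_count(params, {2000: 100}) == 0.0

    def test_survey_scale_expectation_order_of_magnitude(self):
        """A ~656-sample, 20-cohort design around N0 ~ 25k, phi ~ 0.83
        predicts on the order of ten to twenty HSPs."""
        params = ckmr.DemographicParams(25_000, 0.071, 0.828)
        sizes = {y: 33 for y in range(1996, 2016)}    # ~660 total
        e = ckmr.expected_hsp_count(params, sizes, year0=1996)
        assert 3.0 < e < 40.0


class TestSampler:
    def test_flat_likelihood_recovers_prior(self):
        cells = ckmr.CohortComparisonCounts(
            b_i=np.array([2000]), b_j=np.array([2001]),
            n_hsp=np.array([0]), n_comparisons=np.array([0]), year0=2000)
        chain = ckmr.run_mh(
            cells, ckmr.Priors(),
            ckmr.MCMCConfig(iterations=40_000, thin=10, burnin=5_000),
            seed=3)
        from scipy import stats
        r = chain.draws["r"].to_numpy()
        phi = chain.draws["phi"].to_numpy()
        assert stats.kstest(r, stats.uniform(-1, 2).cdf).statistic < 0.05
        assert stats.kstest(phi, stats.uniform(0, 1).cdf).statistic < 0.05

    def test_zero_hsp_pushes_n0_against_upper_prior_bound(self):
        """With no recaptures the likelihood only rules out small N0, so
        posterior mass piles into the top decade of the log-uniform prior
        (prior share of that decade: 1/5) and the upper quantile hugs the
        bound."""
        meta = _meta(list(range(2000, 2010)) * 20)
        counts = ckmr.build_comparisons(meta, EMPTY_KIN)
        chain = ckmr.run_mh(
            counts, ckmr.Priors(n0_bounds=(1e2, 1e7)),
            ckmr.MCMCConfig(iterations=30_000, thin=10, burnin=5_000),
            seed=4)
        n0 = chain.draws["n0"].to_numpy()
        assert (n0 > 1e6).mean() > 0.2
        assert np.quantile(n0, 0.975) > 5e6

    def test_more_hsps_shift_abundance_downward(self):
        def fit(n_hsp, seed):
            counts = ckmr.CohortComparisonCounts(
                b_i=np.array([2000, 2001]), b_j=np.array([2003, 2004]),
                n_hsp=np.array([n_hsp, n_hsp]),
                n_comparisons=np.array([20_000, 20_000]), year0=2000)
            chain = ckmr.run_mh(
                counts, ckmr.Priors(),
                ckmr.MCMCConfig(iterations=30_000, thin=10, burnin=5_000),
                seed=seed)
            return chain.draws["n0"].median()
        for seed in (1, 2, 3):
            assert fit(16, seed) < fit(4, seed)

    def test_chains_agree_across_seeds_within_mc_error(self):
        ds = simulate_dataset(small_config(seed=77), genotypes=False)
        counts = ckmr.build_comparisons(ds.metadata, ds.truth, age_cap=12)
        chains = [ckmr.run_mh(counts, ckmr.Priors(),
                              ckmr.MCMCConfig(iterations=80_000, thin=10,
                                              burnin=10_000), seed=s)
                  for s in (11, 22)]
        for c in ("n0", "r", "phi"):
            means = [ch.draws[c].mean() for ch in chains]
            mcse = [ch.draws[c].std() / math.sqrt(ch.ess[c])
                    for ch in chains]
            assert abs(means[0] - means[1]) < 2 * (mcse[0] + mcse[1])

    def test_summary_contains_trajectory(self):
        cells = ckmr.CohortComparisonCounts(
            b_i=np.array([2000]), b_j=np.array([2003]),
            n_hsp=np.array([5]), n_comparisons=np.array([10_000]),
            year0=2000)
        chain = ckmr.run_mh(cells, ckmr.Priors(),
                            ckmr.MCMCConfig(iterations=20_000, thin=10,
                                            burnin=4_000), seed=6)
        summ = ckmr.summarize_posterior(chain, years=[2000, 2005])
        assert {"n0", "r", "phi", "N_2000", "N_2005"} <= \
            set(summ["quantity"])
        assert (summ["lo2.5"] <= summ["hi97.5"]).all()


class TestSensitivityRefit:
    def test_age_reassignment_spread_is_reported(self):
        ds = simulate_dataset(small_config(seed=88), genotypes=False)
        kin_table = ds.truth[ds.truth["category"] == "HS"]
        out = ckmr.sensitivity_refit(ds.metadata, kin_table,
                                     length_noise_sd=3.0, n_reps=5,
                                     age_cap=12, seed=9)
        assert len(out) == 5
        assert np.isfinite(out[["n0", "r", "phi"]].to_numpy()).all()
        assert out["n_hsp"].between(0, len(kin_table)).all()
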
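"""Forward simulator: demography, pedigree structure, Mendelian genotypes."""

import math

import numpy as np
import pytest

from conftest import small_config
from skatekin.simulate import (ExtinctionError, SimulationConfig,
                               simulate_dataset, simulate_demography,
                               simulate_genotypes, simulate_pedigree)


class TestDemography:
    def test_constant_when_r_zero(self):
        cfg = small_config(r=0.0)
        traj = simulate_demography(cfg)
        assert set(traj.values()) == {400}

    def test_exponential_growth_value(self):
        cfg = small_config(n0=1000, r=0.071, cohort_years=(2000, 2010),
                           survey_years=(2010,), samples_per_year=(10,))
        traj = simulate_demography(cfg)
        assert traj[2010] == round(1000 * math.exp(0.71))  # 2034

    def test_ln2_doubles_yearly(self):
        cfg = small_config(n0=100, r=math.log(2.0), cohort_years=(2000, 2005),
                           survey_years=(2005,), samples_per_year=(5,))
        traj = simulate_demography(cfg)
        for y in range(2001, 2006):
            assert traj[y] == 2 * traj[y - 1]


class TestPedigree:
    def test_reproducible_under_seed(self):
        cfg = small_config(seed=9)
        p1 = simulate_pedigree(cfg)
        p2 = simulate_pedigree(cfg)
        assert np.array_equal(p1.mother, p2.mother)
        assert np.array_equal(p1.father, p2.father)
        assert np.array_equal(p1.death_year, p2.death_year)

    def test_single_pair_founders_give_full_sibs(self):
        cfg = SimulationConfig(n0=2, r=0.0, phi=1.0, age_maturity=3,
                               cohort_years=(2000, 2004),
                               survey_years=(2004,), samples_per_year=(5,),
                               sample_age_range=(0, 4), n_loci=10,
                               offspring_per_year=10, seed=1)
        ped = simulate_pedigree(cfg)
        off = np.concatenate(list(ped.cohort_members.values()))
        assert len(set(ped.mother[off])) == 1
        assert len(set(ped.father[off])) == 1

    def test_extinction_raises_with_year(self):
        cfg = SimulationConfig(n0=2, r=0.0, phi=0.01, age_maturity=1,
                               cohort_years=(2000, 2010),
                               survey_years=(2010,), samples_per_year=(1,),
                               n_loci=10, offspring_per_year=1, seed=1)
        with pytest.raises(ExtinctionError, match=r"year 20\d\d"):
            simulate_pedigree(cfg)

    def test_parents_are_adults_born_earlier(self):
        ped = simulate_pedigree(small_config())
        for b, members in ped.cohort_members.items():
            for which in (ped.mother, ped.father):
                par = which[members]
                assert np.all(par >= 0)
                assert np.all(ped.birth_year[par] < b)
                assert np.all(ped.is_adult[par])

    def test_cross_cohort_half_sib_rate_matches_kin_probability(self):
        """Realized parent-sharing between two cohorts matches
        4/N_bj * phi^gap within 3 Monte-Carlo SE over 200 populations."""
        n0, phi, gap = 60, 0.8, 3
        fracs = []
        for rep in range(200):
            cfg = SimulationConfig(
                n0=n0, r=0.0, phi=phi, age_maturity=3,
                cohort_years=(2000, 2003), survey_years=(2003,),
                samples_per_year=(5,), sample_age_range=(0, 3),
                n_loci=2, offspring_per_year=40, seed=5000 + rep)
            ped = simulate_pedigree(cfg)
            a = ped.cohort_members[2000]
            b = ped.cohort_members[2003]
            share = ((ped.mother[a][:, None] == ped.mother[b][None, :])
                     | (ped.father[a][:, None] == ped.father[b][None, :]))
            fracs.append(share.mean())
        expected = 4.0 / n0 * phi ** gap
        fracs = np.asarray(fracs)
        se = fracs.std(ddof=1) / math.sqrt(len(fracs))
        assert abs(fracs.mean() - expected) < 3 * se + 1e-12


class TestGenotypes:
    def test_reproducible_and_mendelian_without_error(self):
        cfg = small_config(genotyping_error=0.0, seed=21)
        ped = simulate_pedigree(cfg)
        off = ped.cohort_members[2010][:20]
        gm1 = simulate_genotypes(ped, cfg, off, rng=7)
        gm2 = simulate_genotypes(ped, cfg, off, rng=7)
        assert np.array_equal(gm1.calls, gm2.calls)
        # parent-offspring pairs share an allele at every locus
        trio = np.concatenate([off[:5], ped.mother[off[:5]]])
        gm = simulate_genotypes(ped, cfg, trio, rng=3)
        child = gm.calls[:5]
        parent = gm.calls[5:]
        opposing = ((child == 0) & (parent == 2)) | \
                   ((child == 2) & (parent == 0))
        assert not opposing.any()

    def test_founder_frequencies_match_configuration(self):
        cfg = small_config(n_loci=200, maf_range=(0.3, 0.3),
                           genotyping_error=0.0)
        ped = simulate_pedigree(cfg)
        founders = np.where(ped.mother < 0)[0][:300]
        gm = simulate_genotypes(ped, cfg, founders, rng=11)
        freq = gm.allele_freq()
        se = math.sqrt(0.3 * 0.7 / (2 * founders.size))
        assert abs(freq.mean() - 0.3) < 3 * se


class TestSurveyAndTruth:
    def test_dataset_reproducible(self):
        cfg = small_config(seed=31)
        d1 = simulate_dataset(cfg)
        d2 = simulate_dataset(cfg)
        assert d1.metadata.equals(d2.metadata)
        assert np.array_equal(d1.genotypes.calls, d2.genotypes.calls)
        assert d1.truth.equals(d2.truth)

    def test_lengths_track_growth_curve(self, small_dataset):
        from skatekin.growth import length_at_age
        meta = small_dataset.metadata
        resid = meta["length"] - length_at_age(meta["true_age"].to_numpy())
        assert abs(resid.mean()) < 1.0
        assert 1.5 < resid.std() < 4.5      # configured noise sd = 3

    def test_oversampling_raises(self):
        cfg = small_config(samples_per_year=(10_000, 10, 10),
                           offspring_per_year=100)
        with pytest.raises(ValueError, match="survey year"):
            simulate_dataset(cfg, genotypes=False)

    def test_truth_labels_are_symmetric_first_and_second_order(self,
                                                               small_dataset):
        truth = small_dataset.truth
        assert set(truth["category"]) <= {"PO", "FS", "HS", "GG", "AV", "HAV"}
        pairs = set(map(frozenset, truth[["id1", "id2"]].values))
        assert len(pairs) == len(truth)      # no duplicated pairs

    def test_site_fidelity_shrinks_sibling_distances(self):
        from skatekin.survey import haversine_km
        cfg = small_config(site_fidelity=True, site_fidelity_sd=5.0, seed=41)
        ds = simulate_dataset(cfg, genotypes=False)
        pos = ds.metadata.set_index("id")
        sib = ds.truth[ds.truth["category"].isin(["HS", "FS"])]
        d_sib = haversine_km(pos.loc[sib["id1"], "lat"].to_numpy(),
                             pos.loc[sib["id1"], "lon"].to_numpy(),
                             pos.loc[sib["id2"], "lat"].to_numpy(),
                             pos.loc[sib["id2"], "lon"].to_numpy())
        rng = np.random.default_rng(0)
        i = rng.integers(0, len(pos), 2000)
        j = rng.integers(0, len(pos), 2000)
        d_all = haversine_km(pos["lat"].to_numpy()[i], pos["lon"].to_numpy()[i],
                             pos["lat"].to_numpy()[j], pos["lon"].to_numpy()[j])
        assert np.median(d_sib) < np.median(d_all[i != j])
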
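"""Forward simulator for close-kin mark-recapture studies.

Generates an age-structured population with overlapping generations whose
adult segment follows the deterministic trajectory N_t = N_0 * exp(r t):
adults survive year to year with probability ``phi`` and the shortfall is
recruited from the cohort reaching maturity (or, in the earliest years,
from parentless immigrant-free founders).  Every mature adult is a
candidate parent every year, so for two offspring of cohorts b_i < b_j
the probability of sharing a parent is 4 / N_{b_j} * phi^(b_j - b_i) —
the generative truth the half-sibling CKMR model estimates.

Genotypes are transmitted Mendelian from parents at unlinked biallelic
loci with founder frequencies drawn uniformly from a configurable MAF
band, then passed through a symmetric per-call error channel and
optional missingness.  Surveys draw individuals without replacement from
the cohorts alive in each survey year, with lengths from the von
Bertalanffy curve plus Gaussian noise, capture positions optionally
clustered around the mother's home site (site fidelity), and true
pairwise kin labels emitted for validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .growth import GrowthParams, DEFAULT_GROWTH, length_at_age
from .matrix import MISSING, GenotypeMatrix


class ExtinctionError(RuntimeError):
    """Raised when a simulated population loses all adults of one sex."""


@dataclass
class SimulationConfig:
    """Generative truth for a synthetic CKMR study.

    The defaults are a desk-scale scenario (N0 = 5000, r = 0.05,
    phi = 0.85, four survey years, ~660 samples, 1500 post-QC-like loci)
    sized to yield a few tens of half-sibling pairs in minutes.
    """

    n0: int = 5000                      # adults in the first cohort year
    r: float = 0.05                     # annual adult growth rate
    phi: float = 0.85                   # annual adult survival
    age_maturity: int = 10              # years to recruitment
    max_age: int = 40
    cohort_years: tuple[int, int] = (1996, 2015)
    n_loci: int = 1500
    maf_range: tuple[float, float] = (0.05, 0.5)
    genotyping_error: float = 0.005     # per-call symmetric flip rate
    missing_rate: float = 0.0
    survey_years: tuple[int, ...] = (2011, 2014, 2015, 2017)
    samples_per_year: tuple[int, ...] = (165, 165, 165, 165)
    sample_age_range: tuple[int, int] = (2, 15)
    offspring_per_year: int | None = None   # None: sized automatically
    length_noise_sd: float = 3.0        # cm
    site_fidelity: bool = False
    site_fidelity_sd: float = 15.0      # km dispersal around natal site
    growth: GrowthParams = field(default_factory=GrowthParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.phi <= 1.0:
            raise ValueError("phi must be in (0, 1]")
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("r must be in [-1, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if len(self.survey_years) != len(self.samples_per_year):
            raise ValueError("survey_years and samples_per_year differ "
                             "in length")


@dataclass
class Pedigree:
    """Columnar pedigree: parents are row indices, -1 = unknown (founder)."""

    birth_year: np.ndarray       # int; founders get a nominal pre-model year
    mother: np.ndarray           # int index or -1
    father: np.ndarray
    sex: np.ndarray              # 0 = female, 1 = male
    is_adult: np.ndarray         # ever recruited to the adult pool
    death_year: np.ndarray       # year adult died; large sentinel if alive
    cohort_members: dict[int, np.ndarray]   # birth year -> offspring indices

    @property
    def n(self) -> int:
        return self.birth_year.size


def simulate_demography(config: SimulationConfig) -> dict[int, int]:
    """Deterministic adult trajectory N_t = round(N0 * exp(r t))."""
    y0, y_last = config.cohort_years
    y_end = max(y_last, max(config.survey_years))
    return {y: int(round(config.n0 * math.exp(config.r * (y - y0))))
            for y in range(y0, y_end + 1)}


def _auto_pool(config: SimulationConfig, traj: dict[int, int]) -> int:
    need = max(max(0, traj[y] - int(config.phi * traj[y - 1]))
               for y in list(traj)[1:]) if len(traj) > 1 else 0
    want = max(config.samples_per_year) * 3
    return max(2 * need, want, 50)


def simulate_pedigree(config: SimulationConfig, rng=None) -> Pedigree:
    """Overlapping-generation pedigree whose adult counts track Eq. N_t.

    Each cohort's offspring draw a mother uniformly from the living adult
    females of that year and a father uniformly from the living adult
    males (post-survival, post-recruitment pool).
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    traj = simulate_demography(config)
    y0, y_last = config.cohort_years
    years = sorted(traj)
    pool = config.offspring_per_year or _auto_pool(config, traj)

    ALIVE = 10 ** 9
    birth, mother, father, sex, is_adult, death = ([] for _ in range(6))

    def add(n, by, mo, fa, sx, adult):
        start = len(birth)
        birth.extend([by] * n if np.isscalar(by) else list(by))
        mother.extend(mo if not np.isscalar(mo) else [mo] * n)
        father.extend(fa if not np.isscalar(fa) else [fa] * n)
        sex.extend(sx)
        is_adult.extend([adult] * n)
        death.extend([ALIVE] * n)
        return np.arange(start, start + n)

    # founders: exactly balanced sexes to avoid spurious early extinction
    n0 = traj[y0]
    sx = np.zeros(n0, dtype=np.int8)
    sx[n0 // 2:] = 1
    rng.shuffle(sx)
    adults = list(add(n0, y0 - config.age_maturity, -1, -1, sx, True))
    cohort_members: dict[int, np.ndarray] = {}

    for y in years:
        if y > y0:
            # survival
            adults_arr = np.array(adults)
            alive = rng.random(adults_arr.size) < config.phi
            for idx in adults_arr[~alive]:
                death[idx] = y
            adults = list(adults_arr[alive])
            # recruitment back to the deterministic trajectory
            need = traj[y] - len(adults)
            if need > 0:
                src_year = y - config.age_maturity
                cand = cohort_members.get(src_year, np.empty(0, dtype=int))
                cand = cand[~np.array([is_adult[i] for i in cand], bool)] \
                    if cand.size else cand
                take = min(need, cand.size)
                if take > 0:
                    picked = rng.choice(cand, size=take, replace=False)
                    for idx in picked:
                        is_adult[idx] = True
                    adults.extend(picked.tolist())
                extra = need - take
                if extra > 0 and src_year < y0:
                    # recruits born before the modelled cohorts exist:
                    # parentless founders stand in for them
                    sx = (rng.random(extra) < 0.5).astype(np.int8)
                    adults.extend(add(extra, src_year, -1, -1, sx, True))
        # breeding
        if y0 <= y <= y_last:
            adults_arr = np.array(adults)
            fem = adults_arr[np.array([sex[i] for i in adults_arr]) == 0]
            mal = adults_arr[np.array([sex[i] for i in adults_arr]) == 1]
            if fem.size == 0 or mal.size == 0:
                missing_sex = "females" if fem.size == 0 else "males"
                raise ExtinctionError(
                    f"no adult {missing_sex} alive in year {y}")
            mo = rng.choice(fem, size=pool, replace=True)
            fa = rng.choice(mal, size=pool, replace=True)
            sx = (rng.random(pool) < 0.5).astype(np.int8)
            cohort_members[y] = add(pool, y, list(mo), list(fa), sx, False)

    return Pedigree(np.array(birth), np.array(mother), np.array(father),
                    np.array(sex, dtype=np.int8), np.array(is_adult, bool),
                    np.array(death), cohort_members)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _ancestor_closure(ped: Pedigree, ids: np.ndarray) -> np.ndarray:
    need = set(int(i) for i in ids)
    stack = list(need)
    while stack:
        i = stack.pop()
        for par in (ped.mother[i], ped.father[i]):
            if par >= 0 and par not in need:
                need.add(int(par))
                stack.append(int(par))
    return np.array(sorted(need))


def simulate_genotypes(ped: Pedigree, config: SimulationConfig,
                       for_individuals=None, rng=None) -> GenotypeMatrix:
    """Mendelian genotypes for the requested individuals (+ ancestors).

    Founders are drawn from Hardy-Weinberg at per-locus frequencies
    uniform on ``maf_range``; each offspring receives one allele per
    parent.  The error channel flips a call to one of the two other
    genotypes with total probability ``genotyping_error``.
    """
    rng = np.random.default_rng(rng)
    ids = (np.arange(ped.n) if for_individuals is None
           else np.asarray(for_individuals, dtype=int))
    closure = _ancestor_closure(ped, ids)
    row = {int(i): k for k, i in enumerate(closure)}
    L = config.n_loci
    freqs = rng.uniform(*config.maf_range, size=L)
    G = np.empty((closure.size, L), dtype=np.int8)

    order = closure[np.argsort(ped.birth_year[closure], kind="stable")]
    for i in order:
        k = row[int(i)]
        mo, fa = int(ped.mother[i]), int(ped.father[i])
        if mo < 0 or fa < 0:
            G[k] = rng.binomial(2, freqs).astype(np.int8)
        else:
            am = rng.random(L) < G[row[mo]] / 2.0
            af = rng.random(L) < G[row[fa]] / 2.0
            G[k] = am.astype(np.int8) + af.astype(np.int8)

    keep = np.array([row[int(i)] for i in ids])
    calls = G[keep]
    if config.genotyping_error > 0:
        flip = rng.random(calls.shape) < config.genotyping_error
        shift = rng.integers(1, 3, size=calls.shape).astype(np.int8)
        calls = np.where(flip, (calls + shift) % 3, calls).astype(np.int8)
    if config.missing_rate > 0:
        calls = np.where(rng.random(calls.shape) < config.missing_rate,
                         MISSING, calls).astype(np.int8)
    samples = np.array([f"ind_{i}" for i in ids], dtype=object)
    loci = np.array([f"locus_{j}" for j in range(L)], dtype=object)
    return GenotypeMatrix(calls, samples, loci)


# ---------------------------------------------------------------------------
# survey
# ---------------------------------------------------------------------------

_REGION = {"lat": (49.1, 50.3), "lon": (-8.0, -6.3)}
_KM_PER_DEG = 111.2


def _stations() -> pd.DataFrame:
    lats = np.linspace(*_REGION["lat"], 5)
    lons = np.linspace(*_REGION["lon"], 5)
    rows = [{"station": f"S{i * 5 + j:02d}", "lat": la, "lon": lo}
            for i, la in enumerate(lats) for j, lo in enumerate(lons)]
    return pd.DataFrame(rows)


def simulate_survey(ped: Pedigree, config: SimulationConfig, rng=None
                    ) -> pd.DataFrame:
    """Sample individuals per survey year; returns the metadata table.

    Columns: id, year, sex, length, lat, lon, station, true_age,
    birth_year, pedigree_index.  Lengths are von Bertalanffy expectations
    plus Gaussian noise, truncated into (0, l_inf).  With
    ``site_fidelity`` on, capture positions scatter around the mother's
    home site so siblings cluster in space.
    """
    rng = np.random.default_rng(rng)
    lo_age, hi_age = config.sample_age_range
    stations = _stations()
    home_lat = rng.uniform(*_REGION["lat"], size=ped.n)
    home_lon = rng.uniform(*_REGION["lon"], size=ped.n)

    rows = []
    taken: set[int] = set()
    for y, n_want in zip(config.survey_years, config.samples_per_year):
        eligible = []
        for b, members in ped.cohort_members.items():
            age = y - b
            if lo_age <= age <= hi_age:
                alive = ped.death_year[members] > y
                eligible.append(members[alive])
        eligible = np.concatenate(eligible) if eligible else np.empty(0, int)
        eligible = eligible[~np.isin(eligible, list(taken))]
        if eligible.size < n_want:
            raise ValueError(
                f"survey year {y}: requested {n_want} samples but only "
                f"{eligible.size} eligible individuals are alive")
        picked = rng.choice(eligible, size=n_want, replace=False)
        taken.update(int(i) for i in picked)
        age = y - ped.birth_year[picked]
        length = length_at_age(age, config.growth) + \
            rng.normal(0.0, config.length_noise_sd, size=n_want)
        length = np.clip(length, 1.0, config.growth.l_inf - 0.01)
        if config.site_fidelity:
            base_lat = np.where(ped.mother[picked] >= 0,
                                home_lat[np.maximum(ped.mother[picked], 0)],
                                home_lat[picked])
            base_lon = np.where(ped.mother[picked] >= 0,
                                home_lon[np.maximum(ped.mother[picked], 0)],
                                home_lon[picked])
            sd_deg = config.site_fidelity_sd / _KM_PER_DEG
            lat = base_lat + rng.normal(0, sd_deg, n_want)
            lon = base_lon + rng.normal(0, sd_deg, n_want)
        else:
            lat = rng.uniform(*_REGION["lat"], size=n_want)
            lon = rng.uniform(*_REGION["lon"], size=n_want)
        st_idx = np.argmin(
            (lat[:, None] - stations["lat"].to_numpy()) ** 2
            + (lon[:, None] - stations["lon"].to_numpy()) ** 2, axis=1)
        for k, i in enumerate(picked):
            rows.append({"id": f"ind_{int(i)}", "year": int(y),
                         "sex": "F" if ped.sex[i] == 0 else "M",
                         "length": float(length[k]), "lat": float(lat[k]),
                         "lon": float(lon[k]),
                         "station": stations["station"].iloc[st_idx[k]],
                         "true_age": int(age[k]),
                         "birth_year": int(ped.birth_year[i]),
                         "pedigree_index": int(i)})
    return pd.DataFrame(rows)


def _parent_of(ped: Pedigree, ids: np.ndarray, which: str) -> np.ndarray:
    """Parent index of each id (-1 propagates for unknowns)."""
    arr = ped.mother if which == "m" else ped.father
    out = np.full(ids.shape, -1, dtype=int)
    ok = ids >= 0
    out[ok] = arr[ids[ok]]
    return out


def true_kin_labels(ped: Pedigree, metadata: pd.DataFrame) -> pd.DataFrame:
    """True relationship for every sampled pair that is related.

    Categories: PO, FS, HS (first/second order via shared parents), GG
    (grandparent-grandchild), AV (full avuncular — same IBD-sharing
    class as HS), HAV (half avuncular — same class as first cousins).
    Unrelated-at-these-orders pairs are omitted.
    """
    idx = metadata["pedigree_index"].to_numpy()
    ids = metadata["id"].to_numpy()
    mo, fa = ped.mother[idx], ped.father[idx]
    # grandparents via each parent (sex-matched slots: a shared mother can
    # only be a mother on both sides)
    mm, mf = _parent_of(ped, mo, "m"), _parent_of(ped, mo, "f")
    fm, ff = _parent_of(ped, fa, "m"), _parent_of(ped, fa, "f")

    def eq(a, b):
        return (a[:, None] == b[None, :]) & (a[:, None] >= 0)

    n_share = eq(mo, mo).astype(int) + eq(fa, fa).astype(int)
    is_par = eq(mo, idx) | eq(fa, idx)
    grand = eq(mm, idx) | eq(mf, idx) | eq(fm, idx) | eq(ff, idx)
    # avuncular: a parent of i is a (half/full) sibling of j
    via_mo = eq(mm, mo).astype(int) + eq(mf, fa).astype(int)
    via_fa = eq(fm, mo).astype(int) + eq(ff, fa).astype(int)
    av = np.maximum(via_mo, via_fa)

    iu, ju = np.triu_indices(idx.size, k=1)
    cat = np.full(iu.size, "U", dtype=object)
    av_pair = np.maximum(av[iu, ju], av.T[iu, ju])
    cat[av_pair == 1] = "HAV"
    cat[av_pair == 2] = "AV"
    cat[grand[iu, ju] | grand.T[iu, ju]] = "GG"
    cat[n_share[iu, ju] == 1] = "HS"
    cat[n_share[iu, ju] == 2] = "FS"
    cat[is_par[iu, ju] | is_par.T[iu, ju]] = "PO"
    keep = cat != "U"
    return pd.DataFrame({"id1": ids[iu[keep]], "id2": ids[ju[keep]],
                         "category": cat[keep]})


def simulate_effort(config: SimulationConfig, metadata: pd.DataFrame,
                    rng=None) -> pd.DataFrame:
    """Survey-effort table consistent with the sampled catches.

    Per station-year: net length (km), soak time (h) and the lengths of
    the individuals captured there (from the survey metadata), suitable
    for CPUE summaries.
    """
    rng = np.random.default_rng(rng)
    rows = []
    for (year, station), grp in metadata.groupby(["year", "station"]):
        rows.append({"station": station, "year": int(year),
                     "net_length_km": float(rng.uniform(0.8, 2.5)),
                     "soak_time_h": float(rng.uniform(12.0, 48.0)),
                     "lengths_cm": tuple(np.round(grp["length"], 1))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# one-call dataset
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    pedigree: Pedigree
    metadata: pd.DataFrame
    genotypes: GenotypeMatrix | None
    truth: pd.DataFrame
    demography: dict[int, int]
    effort: pd.DataFrame


def simulate_dataset(config: SimulationConfig,
                     genotypes: bool = True) -> SimulatedDataset:
    """Pedigree + survey (+ genotypes) under one seed; fully reproducible."""
    rng = np.random.default_rng(config.seed)
    ped = simulate_pedigree(config, rng)
    meta = simulate_survey(ped, config, rng)
    gm = None
    if genotypes:
        gm = simulate_genotypes(ped, config,
                                meta["pedigree_index"].to_numpy(), rng)
    truth = true_kin_labels(ped, meta)
    effort = simulate_effort(config, meta, rng)
    return SimulatedDataset(config, ped, meta, gm, truth,
                            simulate_demography(config), effort)
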
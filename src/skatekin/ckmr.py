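"""Half-sibling-pair close-kin mark-recapture model.

The recapture unit is the cross-cohort half-sibling pair.  For two
individuals with birth years b_i < b_j, the probability that they are
half-siblings is

    P(HSP | b_i, b_j) = 4 / N_{b_j} * phi^(b_j - b_i)

where N_{b_j} is the number of breeding adults in j's birth year and phi
the annual adult survival: i's parent must survive the gap (phi^gap) and
then be one of j's two parents among N/2 candidates of each sex (factor
4/N).  Adult abundance follows the exponential demographic model
N_t = N_0 * exp(r t), with model year 0 the birth year of the earliest
retained cohort.

The pairwise relationship outcomes are combined into a pseudo-likelihood
(a product over non-independent pairs): each cross-cohort pair
contributes p if it is an HSP and 1 - p otherwise, so the per-cohort-pair
comparison counts are the sufficient statistic.  Posterior sampling is a
component-wise Gaussian random-walk Metropolis-Hastings on
(log N_0, r, phi), with uniform priors on r in (-1, 1) and phi in (0, 1)
and a log-uniform prior on N_0 whose bounds are configurable and, with
few kin pairs, load-bearing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .growth import GrowthParams, DEFAULT_GROWTH, age_from_length, assign_cohort

_LOG4 = math.log(4.0)


@dataclass(frozen=True)
class DemographicParams:
    """(N_0, r, phi): initial adult abundance, growth rate, adult survival."""

    n0: float
    r: float
    phi: float

    def __post_init__(self) -> None:
        if self.n0 <= 0:
            raise ValueError("n0 must be > 0")
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("r must be in [-1, 1]")
        if not 0.0 < self.phi <= 1.0:
            raise ValueError("phi must be in (0, 1]")


@dataclass
class CohortComparisonCounts:
    """Per ordered birth-year pair (b_i < b_j): HSPs and total comparisons."""

    b_i: np.ndarray
    b_j: np.ndarray
    n_hsp: np.ndarray
    n_comparisons: np.ndarray
    year0: int                   # calendar year mapped to model t = 0

    def __post_init__(self) -> None:
        if np.any(self.b_i >= self.b_j):
            raise ValueError("cells must satisfy b_i < b_j")
        if np.any(self.n_hsp > self.n_comparisons):
            raise ValueError("n_hsp cannot exceed n_comparisons")

    @property
    def total_comparisons(self) -> int:
        return int(self.n_comparisons.sum())

    @property
    def total_hsp(self) -> int:
        return int(self.n_hsp.sum())


def build_comparisons(metadata: pd.DataFrame, kin_table: pd.DataFrame,
                      age_cap: int = 15,
                      exclude_categories: tuple = ("FS", "FC", "PO"),
                      ) -> CohortComparisonCounts:
    """Aggregate the pairwise data into per-cohort-pair counts.

    Individuals older than ``age_cap`` are dropped (age-at-length is
    unreliable near the growth asymptote), all same-birth-year pairs are
    dropped (litter mates violate independent sampling), and pairs in
    ``exclude_categories`` are removed from both the HSP and the
    comparison pools.  ``metadata`` needs columns id, year, birth_year
    (age is year - birth_year).
    """
    meta = metadata.copy()
    meta["age"] = meta["year"] - meta["birth_year"]
    known = set(meta["id"])
    for _, row in kin_table.iterrows():
        if row["category"] == "HS" and not {row["id1"], row["id2"]} <= known:
            raise ValueError(f"HSP pair ({row['id1']}, {row['id2']}) not "
                             "present in metadata")
    meta = meta[meta["age"] <= age_cap]
    ids = meta["id"].to_numpy()
    birth = meta["birth_year"].to_numpy()
    by_id = dict(zip(ids, birth))

    def pair_key(a, b):
        ba, bb = by_id[a], by_id[b]
        return (ba, bb, a, b) if ba <= bb else (bb, ba, b, a)

    hsp_pairs, excluded_pairs = set(), set()
    for _, row in kin_table.iterrows():
        a, b = row["id1"], row["id2"]
        if a not in by_id or b not in by_id:
            continue  # removed by the age cap
        if row["category"] == "HS":
            hsp_pairs.add(pair_key(a, b))
        elif row["category"] in exclude_categories:
            excluded_pairs.add(pair_key(a, b))

    cohorts, counts = np.unique(birth, return_counts=True)
    size = dict(zip(cohorts, counts))
    cells: dict[tuple[int, int], list[int]] = {}
    for bi, bj in combinations(sorted(cohorts), 2):
        cells[(bi, bj)] = [0, size[bi] * size[bj]]
    for bi, bj, *_ in excluded_pairs:
        if bi < bj:
            cells[(bi, bj)][1] -= 1
    for bi, bj, *_ in hsp_pairs:
        if bi < bj:                      # same-cohort HSPs are excluded
            cells[(bi, bj)][0] += 1

    keys = sorted(cells)
    return CohortComparisonCounts(
        b_i=np.array([k[0] for k in keys]),
        b_j=np.array([k[1] for k in keys]),
        n_hsp=np.array([cells[k][0] for k in keys]),
        n_comparisons=np.array([cells[k][1] for k in keys]),
        year0=int(cohorts.min()))


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def abundance_at(params: DemographicParams, t) -> np.ndarray:
    """N_t = N_0 exp(r t) for model year(s) t."""
    return params.n0 * np.exp(params.r * np.asarray(t, dtype=float))


def hsp_prob(b_i: int, b_j: int, params: DemographicParams,
             year0: int) -> float:
    """4 / N_{b_j} * phi^(b_j - b_i); may exceed 1 for absurd parameters
    (the likelihood treats that as impossible)."""
    if b_i >= b_j:
        raise ValueError("requires b_i < b_j")
    n_bj = float(abundance_at(params, b_j - year0))
    return 4.0 / n_bj * params.phi ** (b_j - b_i)


def _cell_log_lik(log_n0: float, r: float, phi: float, t_bj: np.ndarray,
                  gap: np.ndarray, n_hsp: np.ndarray,
                  n_comp: np.ndarray) -> float:
    log_p = _LOG4 - log_n0 - r * t_bj + gap * math.log(phi)
    if np.any(log_p >= 0.0):
        return -math.inf
    p = np.exp(log_p)
    return float((n_hsp * log_p + (n_comp - n_hsp) * np.log1p(-p)).sum())


def log_pseudo_likelihood(counts: CohortComparisonCounts,
                          params: DemographicParams) -> float:
    """Aggregated log pseudo-likelihood over cohort-pair cells."""
    return _cell_log_lik(math.log(params.n0), params.r, params.phi,
                         (counts.b_j - counts.year0).astype(float),
                         (counts.b_j - counts.b_i).astype(float),
                         counts.n_hsp.astype(float),
                         counts.n_comparisons.astype(float))


def expected_hsp_count(params: DemographicParams,
                       cohort_sizes: dict[int, int],
                       year0: int | None = None,
                       count_any_shared_parent: bool = True) -> float:
    """Expected cross-cohort HSP count for a sampling design.

    ``cohort_sizes`` maps birth year to the number sampled from that
    cohort; the expectation sums the pair probability over all retained
    cross-cohort pairs and therefore scales quadratically with sample
    size.  ``count_any_shared_parent`` is kept for symmetry with the
    pedigree truth (the model probability already counts either parent).
    """
    years = sorted(cohort_sizes)
    if year0 is None:
        year0 = years[0] if years else 0
    total = 0.0
    for bi, bj in combinations(years, 2):
        p = hsp_prob(bi, bj, params, year0)
        total += cohort_sizes[bi] * cohort_sizes[bj] * min(p, 1.0)
    return total


# ---------------------------------------------------------------------------
# priors and MCMC
# ---------------------------------------------------------------------------

@dataclass
class Priors:
    """Log-uniform N_0 within bounds; uniform r and phi within bounds."""

    n0_bounds: tuple[float, float] = (1e2, 1e7)
    r_bounds: tuple[float, float] = (-1.0, 1.0)
    phi_bounds: tuple[float, float] = (0.0, 1.0)

    def log_prior(self, log_n0: float, r: float, phi: float) -> float:
        lo, hi = self.n0_bounds
        if not (math.log(lo) <= log_n0 <= math.log(hi)):
            return -math.inf
        if not (self.r_bounds[0] <= r <= self.r_bounds[1]):
            return -math.inf
        if not (self.phi_bounds[0] < phi <= self.phi_bounds[1]):
            return -math.inf
        return 0.0           # flat in (log N_0, r, phi) within bounds


@dataclass
class MCMCConfig:
    iterations: int = 1_000_000
    thin: int = 100
    burnin: int = 100_000
    adapt_interval: int = 500
    target_accept: float = 0.3
    initial_step: tuple[float, float, float] = (0.5, 0.05, 0.05)


@dataclass
class PosteriorChain:
    """Thinned post-burn-in draws plus sampler diagnostics."""

    draws: pd.DataFrame          # columns n0, r, phi
    acceptance: dict[str, float]
    step_sizes: dict[str, float]
    year0: int
    ess: dict[str, float] = field(default_factory=dict)

    def compute_ess(self) -> dict[str, float]:
        import arviz as az
        self.ess = {c: float(az.ess(self.draws[c].to_numpy()[None, :]))
                    for c in ("n0", "r", "phi")}
        return self.ess


def _initial_state(counts: CohortComparisonCounts, priors: Priors
                   ) -> np.ndarray:
    lo, hi = (math.log(b) for b in priors.n0_bounds)
    if counts.total_hsp > 0:
        crude = 4.0 * counts.total_comparisons / counts.total_hsp * 0.5
        log_n0 = min(max(math.log(crude), lo), hi)
    else:
        log_n0 = 0.5 * (lo + hi)
    return np.array([log_n0, 0.0, 0.8])


def run_mh(counts: CohortComparisonCounts, priors: Priors | None = None,
           mcmc: MCMCConfig | None = None, seed=None) -> PosteriorChain:
    """Component-wise Gaussian random-walk Metropolis-Hastings.

    Step sizes adapt toward the target acceptance rate during burn-in
    only, then freeze, so the retained draws come from a fixed kernel
    that preserves detailed balance.
    """
    if counts.n_comparisons.size == 0:
        raise ValueError("no comparison cells")
    priors = priors or Priors()
    mcmc = mcmc or MCMCConfig()
    rng = np.random.default_rng(seed)

    t_bj = (counts.b_j - counts.year0).astype(float)
    gap = (counts.b_j - counts.b_i).astype(float)
    nh = counts.n_hsp.astype(float)
    nc = counts.n_comparisons.astype(float)

    def log_post(x):
        lp = priors.log_prior(*x)
        if not math.isfinite(lp):
            return -math.inf
        return lp + _cell_log_lik(x[0], x[1], x[2], t_bj, gap, nh, nc)

    x = _initial_state(counts, priors)
    lp = log_post(x)
    step = np.array(mcmc.initial_step, dtype=float)
    accepted = np.zeros(3)
    proposed = np.zeros(3)
    window_acc = np.zeros(3)
    window_n = np.zeros(3)
    kept = []
    names = ("n0", "r", "phi")

    for it in range(mcmc.iterations):
        for k in range(3):
            prop = x.copy()
            prop[k] += rng.normal(0.0, step[k])
            lp_prop = log_post(prop)
            proposed[k] += 1
            window_n[k] += 1
            if math.log(rng.random()) < lp_prop - lp:
                x, lp = prop, lp_prop
                accepted[k] += 1
                window_acc[k] += 1
        if it < mcmc.burnin and (it + 1) % mcmc.adapt_interval == 0:
            rate = window_acc / np.maximum(window_n, 1)
            step *= np.exp(rate - mcmc.target_accept)
            window_acc[:] = 0
            window_n[:] = 0
        if it >= mcmc.burnin and (it - mcmc.burnin) % mcmc.thin == 0:
            kept.append([math.exp(x[0]), x[1], x[2]])

    draws = pd.DataFrame(kept, columns=names)
    acc = dict(zip(names, (accepted / np.maximum(proposed, 1)).tolist()))
    chain = PosteriorChain(draws, acc, dict(zip(names, step.tolist())),
                           counts.year0)
    chain.compute_ess()
    return chain


def summarize_posterior(chain: PosteriorChain,
                        years=None) -> pd.DataFrame:
    """Mean and central 95% interval for each parameter and for the
    derived abundance trajectory N_t per calendar year."""
    rows = []
    for c in ("n0", "r", "phi"):
        v = chain.draws[c].to_numpy()
        rows.append({"quantity": c, "mean": v.mean(),
                     "lo2.5": np.quantile(v, 0.025),
                     "hi97.5": np.quantile(v, 0.975),
                     "ess": chain.ess.get(c, np.nan)})
    if years is not None:
        n0 = chain.draws["n0"].to_numpy()
        r = chain.draws["r"].to_numpy()
        for y in years:
            nt = n0 * np.exp(r * (y - chain.year0))
            rows.append({"quantity": f"N_{y}", "mean": nt.mean(),
                         "lo2.5": np.quantile(nt, 0.025),
                         "hi97.5": np.quantile(nt, 0.975),
                         "ess": np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# age-reassignment sensitivity (maximum pseudo-likelihood refits)
# ---------------------------------------------------------------------------

def max_pseudo_likelihood(counts: CohortComparisonCounts,
                          priors: Priors | None = None) -> DemographicParams:
    """Maximum of the pseudo-likelihood within the prior bounds."""
    from scipy.optimize import minimize
    priors = priors or Priors()

    t_bj = (counts.b_j - counts.year0).astype(float)
    gap = (counts.b_j - counts.b_i).astype(float)
    nh = counts.n_hsp.astype(float)
    nc = counts.n_comparisons.astype(float)

    def neg(x):
        val = _cell_log_lik(x[0], x[1], x[2], t_bj, gap, nh, nc)
        return -val if math.isfinite(val) else 1e12

    x0 = _initial_state(counts, priors)
    bounds = [(math.log(priors.n0_bounds[0]), math.log(priors.n0_bounds[1])),
              priors.r_bounds, (1e-6, priors.phi_bounds[1] - 1e-9)]
    res = minimize(neg, x0, method="L-BFGS-B", bounds=bounds)
    return DemographicParams(math.exp(res.x[0]), float(res.x[1]),
                             float(res.x[2]))


def sensitivity_refit(metadata: pd.DataFrame, kin_table: pd.DataFrame,
                      length_noise_sd: float = 3.0, n_reps: int = 20,
                      age_cap: int = 15,
                      growth: GrowthParams = DEFAULT_GROWTH,
                      seed=None) -> pd.DataFrame:
    """Refit after re-assigning ages from length perturbed within its
    noise model; returns one maximum-pseudo-likelihood estimate per
    replicate, whose spread shows the sensitivity to age error.

    ``metadata`` needs id, year, length.
    """
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(n_reps):
        meta = metadata.copy()
        jitter = rng.normal(0.0, length_noise_sd, size=len(meta))
        lengths = np.clip(meta["length"] + jitter, 1.0, growth.l_inf - 0.01)
        ages = [age_from_length(L, growth) for L in lengths]
        meta["birth_year"] = [assign_cohort(y, a)
                              for y, a in zip(meta["year"], ages)]
        counts = build_comparisons(meta, kin_table, age_cap=age_cap)
        est = max_pseudo_likelihood(counts)
        out.append({"replicate": rep, "n0": est.n0, "r": est.r,
                    "phi": est.phi, "n_hsp": counts.total_hsp,
                    "n_comparisons": counts.total_comparisons})
    return pd.DataFrame(out)
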
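"""Genetic diversity and linkage-disequilibrium effective population size.

Diversity follows the conventional per-locus summaries: observed
heterozygosity H_o (fraction of called genotypes that are heterozygous),
expected heterozygosity H_e = 2p(1-p) (sample-size-uncorrected), and the
fixation index F = 1 - H_o / H_e, averaged over loci with standard
errors across loci.

The LD method estimates contemporary N_e from the background
between-locus association that genetic drift generates in a finite
population.  The mean squared genotype-dosage correlation across locus
pairs, r^2, is decomposed into a sampling component expected even in an
infinite population plus a drift component ~ 1/(3 N_e) for unlinked loci
under random mating; the published bias-corrected formulas (the
S >= 30 coefficient set, with the small-sample variant below that) then
invert the drift component to N_e.  When the drift signal is <= 0 the
estimate is reported as infinite.  Confidence intervals jackknife over
individuals.

Caveat surfaced in the returned result: estimates from a mixed-age
sample do not measure N_e per generation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def _group_stats(gm: GenotypeMatrix) -> dict:
    called = gm.called()
    n_called = called.sum(axis=0)
    ok = n_called > 0
    het = ((gm.calls == 1) & called).sum(axis=0)
    ho = het[ok] / n_called[ok]
    p = gm.allele_freq()[ok]
    he = 2.0 * p * (1.0 - p)
    poly = he > 0
    f = 1.0 - ho[poly] / he[poly]

    def mse(x):
        if x.size < 2:
            return float(np.mean(x)), float("nan")
        return float(np.mean(x)), float(np.std(x, ddof=1) / np.sqrt(x.size))

    ho_m, ho_se = mse(ho)
    he_m, he_se = mse(he)
    f_m, f_se = mse(f)
    return {"n": gm.n_samples, "Ho": ho_m, "Ho_se": ho_se,
            "He": he_m, "He_se": he_se, "F": f_m, "F_se": f_se,
            "n_loci": int(ok.sum())}


def diversity(gm: GenotypeMatrix, grouping=None) -> pd.DataFrame:
    """Mean H_o, H_e and F (+/- SE over loci) per group and overall.

    ``grouping`` maps sample id to a group label (dict or Series);
    ``None`` gives the overall row only.
    """
    rows = []
    if grouping is not None:
        grouping = pd.Series(grouping)
        for g in sorted(grouping.unique()):
            ids = grouping[grouping == g].index
            sub = gm.take_samples(gm.sample_index(ids))
            rows.append({"group": g, **_group_stats(sub)})
    rows.append({"group": "overall", **_group_stats(gm)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# LD Ne
# ---------------------------------------------------------------------------

def pairwise_dosage_corr(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(r^2, n) over locus pairs, on pairwise-complete observations."""
    X = calls.astype(np.float64)
    C = (calls != MISSING).astype(np.float64)
    X0 = np.where(C > 0, X, 0.0)
    n = C.T @ C
    sx = X0.T @ C
    sxx = (X0 ** 2).T @ C
    sxy = X0.T @ X0
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        var = n * sxx - sx ** 2
        r2 = cov ** 2 / (var * var.T)
    r2[~np.isfinite(r2)] = np.nan
    return r2, n


def _expected_sampling_r2(S: float) -> float:
    if S >= 30:
        return 1.0 / S + 3.19 / S ** 2
    return 0.0018 + 0.907 / S + 4.44 / S ** 2


def _ne_from_drift(r2_drift: float, S: float) -> float:
    """Invert the drift r^2 ~ f(1/Ne) relation (random mating)."""
    if r2_drift <= 0:
        return math.inf
    if S >= 30:
        disc = 1.0 / 9.0 - 2.76 * r2_drift
        num = 1.0 / 3.0 + math.sqrt(disc) if disc > 0 else 1.0 / 3.0
    else:
        disc = 0.308 ** 2 - 2.08 * r2_drift
        num = 0.308 + math.sqrt(disc) if disc > 0 else 0.308
    ne = num / (2.0 * r2_drift)
    return ne if ne > 0 else math.inf


@dataclass
class LdNeResult:
    ne: float
    ci: tuple[float, float]
    mean_r2: float
    drift_r2: float
    harmonic_mean_s: float
    n_locus_pairs: int
    crit_maf: float
    warnings: list[str] = field(default_factory=list)


def _mean_r2_and_s(calls: np.ndarray) -> tuple[float, float, int]:
    r2, n = pairwise_dosage_corr(calls)
    iu, ju = np.triu_indices(calls.shape[1], k=1)
    vals = r2[iu, ju]
    ns = n[iu, ju]
    ok = np.isfinite(vals) & (ns >= 2)
    vals, ns = vals[ok], ns[ok]
    S = ns.size / np.sum(1.0 / ns)        # harmonic mean sample size
    return float(vals.mean()), float(S), int(vals.size)


def ld_ne(gm: GenotypeMatrix, crit_maf: float = 0.05,
          jackknife: bool = True) -> LdNeResult:
    """LD effective population size with jackknife-over-individuals CI."""
    keep = np.where(np.nan_to_num(gm.maf()) >= crit_maf)[0]
    if keep.size < 2:
        raise ValueError("fewer than 2 loci pass the critical MAF")
    sub = gm.take_loci(keep)
    warnings = []
    if sub.n_samples < 30:
        warnings.append(f"only {sub.n_samples} individuals; the LD method "
                        "is unreliable below ~30")
    warnings.append("mixed-age sample: estimate does not correspond to "
                    "Ne per generation")

    mean_r2, S, n_pairs_used = _mean_r2_and_s(sub.calls)
    drift = mean_r2 - _expected_sampling_r2(S)
    ne = _ne_from_drift(drift, S)

    ci = (math.nan, math.nan)
    if jackknife and sub.n_samples > 2:
        loo = np.empty(sub.n_samples)
        for i in range(sub.n_samples):
            calls_i = np.delete(sub.calls, i, axis=0)
            loo[i], _, _ = _mean_r2_and_s(calls_i)
        n = sub.n_samples
        var = (n - 1) / n * np.sum((loo - loo.mean()) ** 2)
        sd = math.sqrt(var)
        lo_drift = drift - 1.96 * sd
        hi_drift = drift + 1.96 * sd
        # smaller drift signal -> larger Ne (infinite when signal <= 0)
        ci = (_ne_from_drift(hi_drift, S), _ne_from_drift(lo_drift, S))
    return LdNeResult(ne=ne, ci=ci, mean_r2=mean_r2, drift_r2=drift,
                      harmonic_mean_s=S, n_locus_pairs=n_pairs_used,
                      crit_maf=crit_maf, warnings=warnings)
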
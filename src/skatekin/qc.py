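"""SNP and sample quality-control cascade for kin-finding panels.

The cascade mirrors standard practice for reduced-representation SNP
panels destined for kinship inference: locus call-rate filtering,
collapsing duplicate assays of the same marker, minor-allele-frequency
filtering, a Hardy-Weinberg exact test (Monte-Carlo permutation of
alleles, two-sided by conditional-probability ordering) with
Benjamini-Hochberg false-discovery-rate control, linkage-disequilibrium
pruning on genotype-dosage r^2, and duplicate-sample detection by
pairwise mismatch rate.

Because removing duplicate samples changes per-locus summaries, the
pipeline re-applies the locus filters until a fixed point is reached, so
a second pass over its own output removes nothing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .matrix import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# call rate / MAF
# ---------------------------------------------------------------------------

def filter_call_rate(gm: GenotypeMatrix, threshold: float = 0.95
                     ) -> tuple[GenotypeMatrix, dict]:
    """Drop loci with call rate < threshold; flag samples below 0.90.

    Samples are flagged, not removed (low-score samples are a data-entry
    warning, and surveys typically retain all samples at >= 90%).
    """
    keep = gm.locus_call_rate() >= threshold
    out = gm.take_loci(np.where(keep)[0])
    if out.n_loci == 0:
        raise ValueError("no loci survive the call-rate filter")
    flagged = out.samples[out.sample_call_rate() < 0.90]
    return out, {"removed_loci": int((~keep).sum()),
                 "flagged_samples": list(flagged)}


def filter_maf(gm: GenotypeMatrix, min_maf: float = 0.05
               ) -> tuple[GenotypeMatrix, dict]:
    """Drop monomorphic loci and those with MAF < min_maf (strict)."""
    maf = gm.maf()
    keep = np.nan_to_num(maf) >= min_maf
    return gm.take_loci(np.where(keep)[0]), {"removed_loci": int((~keep).sum())}


def drop_duplicate_loci(gm: GenotypeMatrix, clone_ids: dict | None
                        ) -> tuple[GenotypeMatrix, dict]:
    """Collapse duplicate assays of one marker, keeping the best call rate.

    ``clone_ids`` maps locus id -> marker (clone) id; duplicates are not
    inferable from genotypes alone.  ``None`` is a no-op.
    """
    if clone_ids is None:
        return gm, {"removed_loci": 0}
    call = gm.locus_call_rate()
    best: dict = {}
    for i, locus in enumerate(gm.loci):
        key = clone_ids.get(locus, locus)
        if key not in best or call[i] > call[best[key]]:
            best[key] = i
    keep = np.array(sorted(best.values()))
    return gm.take_loci(keep), {"removed_loci": gm.n_loci - keep.size}


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Monte Carlo permutation of alleles)
# ---------------------------------------------------------------------------

def hwe_het_log_pmf(n_het: np.ndarray, n: int, n_minor: int) -> np.ndarray:
    """Log conditional probability of a heterozygote count given allele counts.

    Levene's distribution: the probability of ``n_het`` heterozygotes in a
    sample of ``n`` diploids carrying ``n_minor`` copies of one allele,
    conditional on the allele counts, under random union of gametes.
    """
    n_het = np.asarray(n_het)
    n_major = 2 * n - n_minor
    n_aa = (n_minor - n_het) // 2
    n_bb = (n_major - n_het) // 2
    out = (gammaln(n + 1) - gammaln(n_aa + 1) - gammaln(n_het + 1)
           - gammaln(n_bb + 1) + n_het * np.log(2.0)
           + gammaln(n_minor + 1) + gammaln(n_major + 1) - gammaln(2 * n + 1))
    # parity / range violations have probability zero
    bad = ((n_minor - n_het) % 2 != 0) | (n_aa < 0) | (n_bb < 0)
    return np.where(bad, -np.inf, out)


def hwe_exact_mc(n_hom_ref: int, n_het: int, n_hom_alt: int,
                 n_perm: int = 1000, rng=None) -> float:
    """Monte-Carlo exact Hardy-Weinberg p-value for one locus.

    Alleles are permuted and re-paired into genotypes ``n_perm`` times; the
    p-value is the fraction of replicates whose heterozygote count is at
    least as extreme as observed, where extremeness is ordered by the
    conditional probability of the outcome (two-sided exact-test
    convention).  Replicates tied with the observed outcome count half
    (mid-p), which keeps null p-values calibrated despite the discrete
    support; a +1/2 correction keeps p strictly positive.
    """
    rng = np.random.default_rng(rng)
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return 1.0  # fewer than 2 distinct alleles observed
    alleles = np.zeros(2 * n, dtype=np.int8)
    alleles[:n_minor] = 1
    # vectorised permutations: one argsort of random keys per replicate
    keys = rng.random((n_perm, 2 * n))
    order = np.argsort(keys, axis=1)
    perm = alleles[order]
    het_rep = (perm[:, 0::2] != perm[:, 1::2]).sum(axis=1)
    lp_obs = hwe_het_log_pmf(np.array([n_het]), n, n_minor)[0]
    lp_rep = hwe_het_log_pmf(het_rep, n, n_minor)
    lower = int((lp_rep < lp_obs - 1e-9).sum())
    tied = int((np.abs(lp_rep - lp_obs) <= 1e-9).sum())
    return min(1.0, (lower + 0.5 * tied + 0.5) / (n_perm + 1))


def hwe_test(gm: GenotypeMatrix, n_perm: int = 1000, rng=None) -> np.ndarray:
    """Per-locus Monte-Carlo Hardy-Weinberg p-values."""
    rng = np.random.default_rng(rng)
    pvals = np.empty(gm.n_loci)
    for j in range(gm.n_loci):
        col = gm.calls[:, j]
        counts = [(col == g).sum() for g in (0, 1, 2)]
        pvals[j] = hwe_exact_mc(*counts, n_perm=n_perm, rng=rng)
    return pvals


def bh_adjust(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level alpha."""
    reject, *_ = multipletests(np.asarray(pvalues, float), alpha=alpha,
                               method="fdr_bh")
    return reject


def filter_hwe(gm: GenotypeMatrix, alpha: float = 0.05, n_perm: int = 1000,
               rng=None) -> tuple[GenotypeMatrix, dict]:
    pvals = hwe_test(gm, n_perm=n_perm, rng=rng)
    reject = bh_adjust(pvals, alpha=alpha)
    out = gm.take_loci(np.where(~reject)[0])
    return out, {"removed_loci": int(reject.sum())}


# ---------------------------------------------------------------------------
# LD pruning on dosage r^2
# ---------------------------------------------------------------------------

def dosage_r2(gm: GenotypeMatrix) -> np.ndarray:
    """Pairwise squared genotype-dosage correlation, pairwise-complete."""
    X = gm.calls.astype(np.float64)
    C = (gm.calls != MISSING).astype(np.float64)
    X0 = np.where(C > 0, X, 0.0)
    n = C.T @ C
    sx = X0.T @ C
    sy = sx.T
    sxx = (X0 ** 2).T @ C
    syy = sxx.T
    sxy = X0.T @ X0
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx ** 2
        vary = n * syy - sy ** 2
        r2 = cov ** 2 / (varx * vary)
    r2[~np.isfinite(r2)] = 0.0
    np.fill_diagonal(r2, 0.0)
    return r2


def ld_prune(gm: GenotypeMatrix, r2_max: float = 0.80
             ) -> tuple[GenotypeMatrix, dict]:
    """Remove one locus from each pair with dosage r^2 > r2_max.

    Victim rule (deterministic): the member with the lower call rate,
    ties broken by dropping the later-indexed locus.  Offending pairs are
    visited in index order; by construction no surviving pair exceeds the
    threshold, so re-running is a no-op.
    """
    if gm.n_loci < 2:
        return gm, {"removed_loci": 0}
    r2 = dosage_r2(gm)
    call = gm.locus_call_rate()
    ii, jj = np.where(np.triu(r2 > r2_max, k=1))
    removed: set[int] = set()
    for i, j in zip(ii, jj):
        if i in removed or j in removed:
            continue
        if call[i] < call[j]:
            removed.add(int(i))
        else:
            removed.add(int(j))  # equal call rates: drop the later index
    keep = [k for k in range(gm.n_loci) if k not in removed]
    return gm.take_loci(keep), {"removed_loci": len(removed)}


# ---------------------------------------------------------------------------
# duplicate samples
# ---------------------------------------------------------------------------

def find_duplicate_samples(gm: GenotypeMatrix,
                           max_mismatch_fraction: float = 0.10) -> list[list]:
    """Group samples whose pairwise mismatch rate over co-called loci is
    below the threshold (likely resamples or contamination); each group is
    ordered by descending call rate so the first member is the keeper."""
    C = (gm.calls != MISSING).astype(np.float64)
    agree = np.zeros((gm.n_samples, gm.n_samples))
    for g in (0, 1, 2):
        Xg = (gm.calls == g).astype(np.float64)
        agree += Xg @ Xg.T
    cocalled = C @ C.T
    with np.errstate(invalid="ignore", divide="ignore"):
        mismatch = 1.0 - agree / cocalled
    dup = (mismatch < max_mismatch_fraction) & (cocalled > 0)
    np.fill_diagonal(dup, False)
    # union-find over duplicate edges
    parent = list(range(gm.n_samples))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in zip(*np.where(np.triu(dup, k=1))):
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[rj] = ri
    groups: dict[int, list[int]] = {}
    for i in range(gm.n_samples):
        groups.setdefault(find(i), []).append(i)
    call = gm.sample_call_rate()
    out = []
    for members in groups.values():
        if len(members) > 1:
            members = sorted(members, key=lambda i: (-call[i], i))
            out.append([gm.samples[i] for i in members])
    return out


def remove_duplicate_samples(gm: GenotypeMatrix,
                             max_mismatch_fraction: float = 0.10
                             ) -> tuple[GenotypeMatrix, dict]:
    groups = find_duplicate_samples(gm, max_mismatch_fraction)
    drop = {s for grp in groups for s in grp[1:]}
    keep = [i for i, s in enumerate(gm.samples) if s not in drop]
    return gm.take_samples(keep), {"removed_samples": len(drop),
                                   "groups": groups}


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def qc_pipeline(gm: GenotypeMatrix, *, call_rate: float = 0.95,
                min_maf: float = 0.05, hwe_alpha: float = 0.05,
                hwe_n_perm: int = 1000, ld_r2_max: float = 0.80,
                dup_mismatch: float = 0.10, clone_ids: dict | None = None,
                seed=None, max_rounds: int = 3
                ) -> tuple[GenotypeMatrix, dict]:
    """Full cascade: call rate -> duplicate loci -> MAF -> HWE+BH -> LD
    prune -> duplicate samples, with per-stage counts.

    Locus filters are re-applied after any duplicate-sample removal (up
    to ``max_rounds``) so the output is a fixed point of the cascade.
    """
    rng = np.random.default_rng(seed)
    report: dict = {"stages": [], "initial": {"n_samples": gm.n_samples,
                                              "n_loci": gm.n_loci}}

    def log(stage, info):
        report["stages"].append({"stage": stage, **info,
                                 "n_samples": gm.n_samples,
                                 "n_loci": gm.n_loci})

    gm, info = drop_duplicate_loci(gm, clone_ids)
    log("duplicate_loci", info)
    for round_ in range(max_rounds):
        changed = False
        gm2, info = filter_call_rate(gm, call_rate)
        changed |= info["removed_loci"] > 0
        gm = gm2
        log("call_rate", info)
        gm, info = filter_maf(gm, min_maf)
        changed |= info["removed_loci"] > 0
        log("maf", info)
        gm, info = filter_hwe(gm, alpha=hwe_alpha, n_perm=hwe_n_perm, rng=rng)
        changed |= info["removed_loci"] > 0
        log("hwe", info)
        gm, info = ld_prune(gm, ld_r2_max)
        changed |= info["removed_loci"] > 0
        log("ld_prune", info)
        gm, info = remove_duplicate_samples(gm, dup_mismatch)
        log("duplicate_samples", info)
        if info["removed_samples"] == 0 and (round_ > 0 or not changed):
            break
        if info["removed_samples"] == 0:
            break
    report["final"] = {"n_samples": gm.n_samples, "n_loci": gm.n_loci}
    return gm, report


def locus_summary(gm: GenotypeMatrix, hwe_pvals=None) -> pd.DataFrame:
    """Per-locus QC summary table (call rate, MAF, optional HWE p)."""
    df = pd.DataFrame({"locus": gm.loci, "call_rate": gm.locus_call_rate(),
                       "maf": gm.maf()})
    if hwe_pvals is not None:
        df["hwe_p"] = hwe_pvals
    return df
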
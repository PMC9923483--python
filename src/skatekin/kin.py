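"""Pairwise kinship classification from SNP genotypes.

Each relationship hypothesis is a triple of IBD-sharing probabilities
kappa = (k0, k1, k2): the chance a pair shares 0, 1 or 2 alleles
identical by descent at a locus.  The joint probability of an observed
genotype pair is the kappa-mixture of the 0/1/2-IBD joint distributions
under Hardy-Weinberg at the observed allele frequency, pushed through a
symmetric per-genotype error channel (rate ``error_rate``, mass split
evenly over the two wrong calls) applied independently to each member.

Pairs are scored by the summed per-locus log-likelihood ratio
lambda = sum_l [log P(g1, g2 | H1) - log P(g1, g2 | H0)]; thresholds for
the sequential hypothesis tests (HS vs U first, then FS vs HS, PO vs FS,
HS vs FC) are calibrated per dataset by simulating genotype pairs from
the observed allele frequencies.  False-positive rates at far-tail
thresholds are estimated by importance sampling: simulating under H1 and
weighting by exp(-lambda) re-expresses the H0 tail probability without
needing astronomically many H0 draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix

KAPPA: dict[str, tuple[float, float, float]] = {
    "PO": (0.0, 1.0, 0.0),
    "FS": (0.25, 0.5, 0.25),
    "HS": (0.5, 0.5, 0.0),
    "FC": (0.75, 0.25, 0.0),
    "U": (1.0, 0.0, 0.0),
}

_LOG_FLOOR = np.log(1e-300)  # keeps impossible pairs finite for matrix algebra


def n_pairs(n: int) -> int:
    """Number of unordered pairs among n samples."""
    return n * (n - 1) // 2


# ---------------------------------------------------------------------------
# per-locus genotype-pair probability tables
# ---------------------------------------------------------------------------

def _hw_probs(freqs: np.ndarray) -> np.ndarray:
    """(L, 3) Hardy-Weinberg genotype probabilities at alt frequency p."""
    p = np.asarray(freqs, dtype=float)
    q = 1.0 - p
    return np.stack([q * q, 2 * p * q, p * p], axis=-1)


def _one_ibd_transition(freqs: np.ndarray) -> np.ndarray:
    """(L, 3, 3) P(g2 | g1) when the pair shares exactly one IBD allele.

    A uniformly chosen allele of g1 is copied; g2's other allele is an
    independent draw from the population.
    """
    p = np.asarray(freqs, dtype=float)
    q = 1.0 - p
    z = np.zeros_like(p)
    T = np.stack([
        np.stack([q, p, z], axis=-1),                  # g1 = 0 (IBD allele ref)
        np.stack([0.5 * q, 0.5 * np.ones_like(p), 0.5 * p], axis=-1),
        np.stack([z, q, p], axis=-1),                  # g1 = 2 (IBD allele alt)
    ], axis=-2)
    return T


def _error_channel(error_rate: float) -> np.ndarray:
    """3x3 symmetric misclassification matrix E[true, observed]."""
    e = float(error_rate)
    if not 0.0 <= e < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    E = np.full((3, 3), e / 2.0)
    np.fill_diagonal(E, 1.0 - e)
    return E


def pair_prob_tables(freqs, kappa, error_rate: float = 0.0) -> np.ndarray:
    """(L, 3, 3) joint probability of an observed genotype pair per locus."""
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    k0, k1, k2 = kappa
    hw = _hw_probs(freqs)                                  # (L, 3)
    P0 = hw[:, :, None] * hw[:, None, :]
    P1 = hw[:, :, None] * _one_ibd_transition(freqs)
    P2 = hw[:, :, None] * np.eye(3)[None, :, :]
    P = k0 * P0 + k1 * P1 + k2 * P2
    E = _error_channel(error_rate)
    return np.einsum("lab,ax,by->lxy", P, E, E)


def pair_log_tables(freqs, kappa, error_rate: float = 0.0) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.maximum(np.log(pair_prob_tables(freqs, kappa, error_rate)),
                          _LOG_FLOOR)


def genotype_pair_loglik(g1: int, g2: int, freq: float, kappa,
                         error_rate: float = 0.0) -> float:
    """Log P(g1, g2) at a single locus; missing calls contribute 0."""
    if g1 == MISSING or g2 == MISSING:
        return 0.0
    return float(pair_log_tables([freq], kappa, error_rate)[0, g1, g2])


# ---------------------------------------------------------------------------
# pair scoring
# ---------------------------------------------------------------------------

def pair_loglik(calls1: np.ndarray, calls2: np.ndarray,
                log_tables: np.ndarray) -> float:
    """Sum of per-locus log probabilities, skipping missing calls."""
    ok = (calls1 != MISSING) & (calls2 != MISSING)
    return float(log_tables[np.where(ok)[0], calls1[ok], calls2[ok]].sum())


def _informative(freqs: np.ndarray) -> np.ndarray:
    """Mask of segregating loci; fixed loci carry no kinship signal."""
    freqs = np.asarray(freqs, dtype=float)
    return np.isfinite(freqs) & (freqs > 0.0) & (freqs < 1.0)


def pair_lr(gm: GenotypeMatrix, pair, h1: str, h0: str, freqs=None,
            error_rate: float = 0.005) -> float:
    """Log-likelihood ratio lambda_{H1/H0} for one sample pair."""
    if freqs is None:
        freqs = gm.allele_freq()
    ok = _informative(freqs)
    i, j = gm.sample_index(pair)
    t1 = pair_log_tables(freqs[ok], KAPPA[h1], error_rate)
    t0 = pair_log_tables(freqs[ok], KAPPA[h0], error_rate)
    return (pair_loglik(gm.calls[i][ok], gm.calls[j][ok], t1)
            - pair_loglik(gm.calls[i][ok], gm.calls[j][ok], t0))


def all_pairs_lambda(gm: GenotypeMatrix, h1: str, h0: str, freqs=None,
                     error_rate: float = 0.005) -> np.ndarray:
    """(n, n) matrix of lambda_{H1/H0} for every ordered sample pair.

    Computed as nine indicator-matrix products (one per genotype-pair
    class), which evaluates all n(n-1)/2 scores in a handful of BLAS
    calls; missing calls drop out because their indicators are zero, and
    fixed loci are skipped as uninformative.
    """
    if freqs is None:
        freqs = gm.allele_freq()
    ok = _informative(freqs)
    calls = gm.calls[:, ok]
    delta = (pair_log_tables(freqs[ok], KAPPA[h1], error_rate)
             - pair_log_tables(freqs[ok], KAPPA[h0], error_rate))  # (L,3,3)
    X = [(calls == g).astype(np.float64) for g in (0, 1, 2)]
    lam = np.zeros((gm.n_samples, gm.n_samples))
    for a in range(3):
        for b in range(3):
            lam += (X[a] * delta[:, a, b]) @ X[b].T
    return lam


# ---------------------------------------------------------------------------
# Monte-Carlo calibration
# ---------------------------------------------------------------------------

def simulate_genotype_pairs(freqs, kappa, n_sim: int, error_rate: float = 0.0,
                            rng=None) -> tuple[np.ndarray, np.ndarray]:
    """Simulate (n_sim, L) observed genotype-pair calls under one hypothesis."""
    rng = np.random.default_rng(rng)
    freqs = np.asarray(freqs, dtype=float)
    L = freqs.size
    hw = _hw_probs(freqs)                      # (L, 3)
    cum1 = hw.cumsum(axis=1)
    u = rng.random((n_sim, L))
    g1 = (u[..., None] > cum1[None, :, :]).sum(axis=2).astype(np.int8)
    k0, k1, k2 = kappa
    cond = (k0 * hw[:, None, :] + k1 * _one_ibd_transition(freqs)
            + k2 * np.eye(3)[None, :, :])      # (L, g1, g2)
    cum2 = cond.cumsum(axis=2)
    u = rng.random((n_sim, L))
    g2 = (u[..., None] > cum2[np.arange(L)[None, :], g1, :]).sum(axis=2)
    g2 = g2.astype(np.int8)

    def _err(g):
        if error_rate <= 0:
            return g
        flip = rng.random(g.shape) < error_rate
        shift = rng.integers(1, 3, size=g.shape)
        return np.where(flip, (g + shift) % 3, g).astype(np.int8)

    return _err(g1), _err(g2)


@dataclass
class LambdaCalibration:
    """Simulated log-likelihood-ratio distributions for one hypothesis pair."""

    h1: str
    h0: str
    lam_h1: np.ndarray          # lambda of pairs simulated under H1
    lam_h0: np.ndarray          # lambda of pairs simulated under H0

    def fpr(self, threshold: float) -> float:
        """P(lambda >= threshold | H0), importance-sampled from H1 draws."""
        sel = self.lam_h1 >= threshold
        return float(np.mean(np.exp(-self.lam_h1[sel])) * sel.mean()) if sel.any() else 0.0

    def fpr_naive(self, threshold: float) -> float:
        return float(np.mean(self.lam_h0 >= threshold))

    def fnr(self, threshold: float) -> float:
        return float(np.mean(self.lam_h1 < threshold))


def simulate_lr_distributions(freqs, h1: str, h0: str, n_sim: int = 20000,
                              error_rate: float = 0.005, rng=None
                              ) -> LambdaCalibration:
    """Simulate lambda under both hypotheses from observed frequencies."""
    rng = np.random.default_rng(rng)
    freqs = np.asarray(freqs, dtype=float)
    if np.all((freqs <= 0) | (freqs >= 1)):
        raise ValueError("allele frequency set is degenerate (all fixed)")
    freqs = freqs[(freqs > 0) & (freqs < 1)]
    delta = (pair_log_tables(freqs, KAPPA[h1], error_rate)
             - pair_log_tables(freqs, KAPPA[h0], error_rate))
    flat = delta.reshape(-1, 9)
    L = freqs.size

    def lam(g1, g2):
        idx = g1.astype(np.int64) * 3 + g2
        return flat[np.arange(L)[None, :], idx].sum(axis=1)

    a1, b1 = simulate_genotype_pairs(freqs, KAPPA[h1], n_sim, error_rate, rng)
    a0, b0 = simulate_genotype_pairs(freqs, KAPPA[h0], n_sim, error_rate, rng)
    return LambdaCalibration(h1, h0, lam(a1, b1), lam(a0, b0))


def choose_threshold(calib: LambdaCalibration, n_comparisons: int,
                     target_expected_fp: float = 0.1) -> dict:
    """Smallest lambda* whose expected false positives over all
    comparisons stay at or below the target; reports the implied FNR."""
    lam_sorted = np.sort(calib.lam_h1)
    w = np.exp(-lam_sorted)
    # suffix means: FPR estimate at threshold = lam_sorted[i]
    suffix = np.cumsum(w[::-1])[::-1] / lam_sorted.size
    ok = suffix * n_comparisons <= target_expected_fp
    if not ok.any():
        raise ValueError("target expected false positives unreachable; "
                         "increase n_sim or relax the target")
    i = int(np.argmax(ok))
    thr = float(lam_sorted[i])
    return {"threshold": thr, "fpr": float(suffix[i]),
            "expected_fp": float(suffix[i] * n_comparisons),
            "fnr": calib.fnr(thr)}


@dataclass
class KinThresholds:
    """Decision thresholds for the sequential hypothesis tests."""

    hs_u: float
    fs_hs: float = 0.0
    po_fs: float = 0.0
    hs_fc: float = 0.0


def calibrate_thresholds(freqs, n_comparisons: int, error_rate: float = 0.005,
                         n_sim: int = 20000, target_expected_fp: float = 0.1,
                         rng=None) -> tuple[KinThresholds, dict]:
    """Dataset-specific thresholds from simulated lambda distributions."""
    rng = np.random.default_rng(rng)
    calib = simulate_lr_distributions(freqs, "HS", "U", n_sim, error_rate, rng)
    choice = choose_threshold(calib, n_comparisons, target_expected_fp)
    return KinThresholds(hs_u=choice["threshold"]), {"hs_u": choice,
                                                     "calibration": calib}


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_pairs(gm: GenotypeMatrix, thresholds: KinThresholds,
                   metadata: pd.DataFrame | None = None,
                   error_rate: float = 0.005, freqs=None) -> pd.DataFrame:
    """Score every unordered pair and assign relationship categories.

    All pairs are first screened with lambda(HS vs U); pairs above the
    calibrated threshold are then tested FS vs HS and PO vs FS, and pairs
    that remain HS but fail HS vs FC are labelled FC (likely distant
    relatives) — conservatively excluded from the HSP list downstream.
    Allele frequencies default to the full post-QC sample, matching the
    calibration simulations; a supplied vector must have one entry per
    locus.
    """
    if freqs is None:
        freqs = gm.allele_freq()
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size != gm.n_loci:
        raise ValueError("allele-frequency vector does not match the "
                         "post-QC locus set")
    lam_hsu = all_pairs_lambda(gm, "HS", "U", freqs, error_rate)
    iu, ju = np.triu_indices(gm.n_samples, k=1)
    lam_vals = lam_hsu[iu, ju]
    hit = lam_vals >= thresholds.hs_u

    ok = _informative(freqs)
    calls = gm.calls[:, ok]
    tables = {h: pair_log_tables(freqs[ok], KAPPA[h], error_rate)
              for h in ("PO", "FS", "HS", "FC")}
    rows = []
    for i, j, lam in zip(iu[hit], ju[hit], lam_vals[hit]):
        c1, c2 = calls[i], calls[j]
        ll = {h: pair_loglik(c1, c2, t) for h, t in tables.items()}
        lam_fs_hs = ll["FS"] - ll["HS"]
        lam_po_fs = ll["PO"] - ll["FS"]
        lam_hs_fc = ll["HS"] - ll["FC"]
        if lam_fs_hs >= thresholds.fs_hs:
            category = "PO" if lam_po_fs >= thresholds.po_fs else "FS"
        elif lam_hs_fc >= thresholds.hs_fc:
            category = "HS"
        else:
            category = "FC"
        rows.append({"id1": gm.samples[i], "id2": gm.samples[j],
                     "category": category, "lambda_hs_u": lam,
                     "lambda_fs_hs": lam_fs_hs, "lambda_po_fs": lam_po_fs,
                     "lambda_hs_fc": lam_hs_fc})
    out = pd.DataFrame(rows, columns=["id1", "id2", "category", "lambda_hs_u",
                                      "lambda_fs_hs", "lambda_po_fs",
                                      "lambda_hs_fc"])
    if metadata is not None and len(out):
        meta = metadata.set_index("id")
        for side in ("1", "2"):
            out[f"year{side}"] = meta.loc[out[f"id{side}"], "year"].to_numpy()
        if {"lat", "lon"}.issubset(meta.columns):
            from .survey import haversine_km
            out["distance_km"] = haversine_km(
                meta.loc[out["id1"], "lat"].to_numpy(),
                meta.loc[out["id1"], "lon"].to_numpy(),
                meta.loc[out["id2"], "lat"].to_numpy(),
                meta.loc[out["id2"], "lon"].to_numpy())
    return out
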
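"""Genotype matrix container.

Biallelic SNP calls are stored as alternate-allele dosages (0, 1, 2) in an
``int8`` array of shape (n_samples, n_loci); ``-1`` marks a missing call.
All QC, kin-inference and population-genetic routines operate on this
container.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci, dosage-coded with missing = -1."""

    calls: np.ndarray
    samples: np.ndarray
    loci: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.samples = np.asarray(self.samples, dtype=object)
        self.loci = np.asarray(self.loci, dtype=object)
        n, L = self.calls.shape
        if n != self.samples.size or L != self.loci.size:
            raise ValueError(
                f"shape mismatch: calls {self.calls.shape}, "
                f"{self.samples.size} samples, {self.loci.size} loci"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls must be 0, 1, 2 or -1 (missing)")
        if len(set(self.samples)) != self.samples.size:
            raise ValueError("duplicate sample ids")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.calls != MISSING

    # -- per-locus / per-sample summaries --------------------------------
    def locus_call_rate(self) -> np.ndarray:
        return self.called().mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return self.called().mean(axis=1)

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per locus from non-missing calls."""
        called = self.called()
        n_called = called.sum(axis=0)
        alt = np.where(called, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n_called > 0, alt / (2.0 * n_called), np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    # -- subsetting ------------------------------------------------------
    def take_loci(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.calls[:, idx], self.samples, self.loci[idx])

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.calls[idx], self.samples[idx], self.loci)

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"sample id {e.args[0]!r} not in matrix") from None

    # -- round trips -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.calls.astype(float), index=self.samples,
                          columns=self.loci)
        return df.where(df >= 0)  # missing -> NaN

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        calls = df.to_numpy(dtype=float)
        calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
        return cls(calls, df.index.to_numpy(object), df.columns.to_numpy(object))
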
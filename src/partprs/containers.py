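"""Core in-memory containers shared across the pipeline.

Summary statistics are held as a plain :class:`pandas.DataFrame` with the
canonical column set in :data:`SUMSTATS_COLUMNS`; genotypes are held in
:class:`GenotypeMatrix`, a thin wrapper around a participants x variants
dosage array plus its variant map.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical summary-statistics columns (one row per variant).
SUMSTATS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "P", "FREQ", "N"]

#: Single-nucleotide alleles accepted in v1 (no indels).
VALID_ALLELES = frozenset("ACGT")

#: Strand-ambiguous (palindromic) allele pairs.
PALINDROMIC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})


def validate_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    """Check a summary-statistics frame against the container invariants.

    Raises ``ValueError`` on a missing column, a p-value outside (0, 1],
    a non-ACGT allele, or duplicated variant ids. Returns the input frame.
    """
    for col in SUMSTATS_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"summary statistics missing required column {col!r}")
    p = df["P"].to_numpy(dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    for col in ("A1", "A2"):
        bad = ~df[col].astype(str).isin(list(VALID_ALLELES))
        if bad.any():
            raise ValueError(f"column {col} contains non-ACGT alleles")
    if df["SNP"].duplicated().any():
        raise ValueError("duplicate variant ids in summary statistics")
    return df


@dataclass
class GenotypeMatrix:
    """Participants x variants additive dosage matrix with its variant map.

    Parameters
    ----------
    samples:
        Participant identifiers, length ``n_samples``.
    variants:
        One row per variant with at least columns ``id, chrom, pos, ref, alt``
        (``pos`` is 1-based). Positions must be non-decreasing within each
        chromosome.
    dosages:
        ``(n_samples, n_variants)`` array counting the alt allele; hard calls
        are 0/1/2, mean-imputed entries may be fractional.
    n_imputed:
        Per-variant count of mean-imputed genotypes (0 if fully observed).
    """

    samples: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray
    n_imputed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-dimensional")
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                "dosage shape "
                f"{self.dosages.shape} does not match {len(self.samples)} samples "
                f"x {len(self.variants)} variants"
            )
        if self.n_imputed is None:
            self.n_imputed = np.zeros(len(self.variants), dtype=int)
        self.variants = self.variants.reset_index(drop=True)
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions not sorted within chromosome {chrom}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def alt_freq(self, cols: np.ndarray | None = None) -> np.ndarray:
        """Alt-allele frequency per variant (mean dosage / 2)."""
        d = self.dosages if cols is None else self.dosages[:, cols]
        return d.mean(axis=0) / 2.0

    def maf(self, cols: np.ndarray | None = None) -> np.ndarray:
        f = self.alt_freq(cols)
        return np.minimum(f, 1.0 - f)

    def standardized(self, cols: np.ndarray | None = None) -> np.ndarray:
        """Column-standardized dosages (mean 0, SD 1; ddof=0).

        Raises ``ValueError`` if any requested column is monomorphic.
        """
        d = self.dosages if cols is None else self.dosages[:, cols]
        mu = d.mean(axis=0)
        sd = d.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("cannot standardize monomorphic variant columns")
        return (d - mu) / sd
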
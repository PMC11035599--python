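"""Greedy p-value-ordered LD clumping against target-cohort genotypes.

LD is the squared Pearson correlation of dosage columns computed in the
target cohort itself (no external reference panel). Clumping repeatedly takes
the unremoved variant with the smallest ranking p-value as an index and
removes every unprocessed same-chromosome variant within the distance window
whose r-squared with the index strictly exceeds the threshold; pairs at
exactly the threshold are kept. Ties in p are broken by genomic order so the
output is deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import GenotypeMatrix


@dataclass(frozen=True)
class ClumpParams:
    """r2_max: removal beyond this r-squared (default 0.1); window_bp: maximum
    index-to-neighbour distance considered (default 1 Mb, inclusive)."""

    r2_max: float = 0.1
    window_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if not (0 < self.r2_max <= 1):
            raise ValueError("r2_max must lie in (0, 1]")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")


@dataclass
class ClumpResult:
    """Retained index variants plus, for each removed variant, the index that
    absorbed it. ``retained`` and ``absorbed_by`` keys partition the input."""

    retained: list[str]
    absorbed_by: dict[str, str] = field(default_factory=dict)

    @property
    def removed(self) -> list[str]:
        return list(self.absorbed_by)


def ld_r2(gm: GenotypeMatrix, i: int, j: int) -> float:
    """Squared Pearson correlation between dosage columns ``i`` and ``j``.

    Raises ``ValueError`` on a monomorphic column (QC should run first).
    """
    x = gm.dosages[:, i]
    y = gm.dosages[:, j]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("monomorphic variant column; run QC before LD")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def clump(
    variant_cols: np.ndarray,
    pvalues: np.ndarray,
    gm: GenotypeMatrix,
    params: ClumpParams = ClumpParams(),
) -> ClumpResult:
    """Greedy clumping of a variant set.

    Parameters
    ----------
    variant_cols:
        Dosage-column indices of the (compartment-restricted) candidate set.
    pvalues:
        Ranking p-values aligned with ``variant_cols``.
    gm:
        Target genotypes supplying positions and LD.
    """
    variant_cols = np.asarray(variant_cols, dtype=int)
    pvalues = np.asarray(pvalues, dtype=float)
    if len(variant_cols) != len(pvalues):
        raise ValueError("pvalues must align with variant_cols")
    if len(variant_cols) == 0:
        return ClumpResult(retained=[])

    ids = gm.variants["id"].to_numpy()[variant_cols]
    chrom = gm.variants["chrom"].to_numpy()[variant_cols]
    pos = gm.variants["pos"].to_numpy()[variant_cols]

    # standardize candidate columns once; r = z_i . z_j / n
    X = gm.dosages[:, variant_cols]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("monomorphic variant in clumping set; run QC first")
    Z = (X - mu) / sd
    n = Z.shape[0]

    order = np.lexsort((pos, chrom, pvalues))  # p, then chrom, then pos
    removed = np.zeros(len(variant_cols), dtype=bool)
    processed = np.zeros(len(variant_cols), dtype=bool)
    retained: list[str] = []
    absorbed: dict[str, str] = {}

    for k in order:
        if removed[k]:
            processed[k] = True
            continue
        processed[k] = True
        retained.append(ids[k])
        cand = np.flatnonzero(
            (~processed)
            & (~removed)
            & (chrom == chrom[k])
            & (np.abs(pos - pos[k]) <= params.window_bp)
        )
        if len(cand) == 0:
            continue
        r = Z[:, cand].T @ Z[:, k] / n
        hit = cand[r * r > params.r2_max]
        removed[hit] = True
        for h in hit:
            absorbed[ids[h]] = ids[k]
    return ClumpResult(retained=retained, absorbed_by=absorbed)
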
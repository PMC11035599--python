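"""Polygenic-score construction: compartment x p-threshold series, few-SNP
added-risk scores and per-gene scores, plus covariate adjustment and
standardization.

A raw score is the weighted sum of alt-allele dosages over the clumped,
p-thresholded variant selection, with weights taken from harmonized discovery
summary statistics. Adjusted scores are residuals of an OLS regression on
ancestry principal components and a genotyping-array indicator, then z-scored.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clump import ClumpParams, clump
from .containers import GenotypeMatrix
from .partition import VariantPartition, annotate_genic

log = logging.getLogger(__name__)

#: Discovery p-value thresholds used for the score series.
DEFAULT_THRESHOLDS = (1e-5, 1e-4, 1e-3, 0.01, 0.1)


def compute_prs(
    harmonized: pd.DataFrame,
    gm: GenotypeMatrix,
    retained_ids: set[str] | None = None,
    p_threshold: float = 1.0,
) -> tuple[np.ndarray, int]:
    """Weighted-dosage score over retained variants with p <= threshold.

    Returns ``(scores, n_snps)``; an empty selection yields an all-NaN vector
    with ``n_snps == 0`` and a logged message.
    """
    sel = harmonized["P"].to_numpy() <= p_threshold
    if retained_ids is not None:
        sel &= harmonized["SNP"].isin(retained_ids).to_numpy()
    sub = harmonized[sel]
    if sub.empty:
        log.info("compute_prs: empty selection at threshold %g", p_threshold)
        return np.full(gm.n_samples, np.nan), 0
    cols = sub["col"].to_numpy(dtype=int)
    w = sub["weight"].to_numpy(dtype=float)
    return gm.dosages[:, cols] @ w, int(len(sub))


def _drop_constant(cov: pd.DataFrame) -> pd.DataFrame:
    const = [c for c in cov.columns if cov[c].nunique() <= 1]
    if const:
        log.info("adjust_and_standardize: dropping constant covariates %s", const)
    return cov.drop(columns=const)


def adjust_and_standardize(raw: np.ndarray, covariates: pd.DataFrame | None = None) -> np.ndarray:
    """Residualize a raw score on covariates (PCs + array indicator) and
    z-score the residual (population SD).

    Constant covariate columns are dropped; remaining collinear columns raise
    ``ValueError`` naming them, as does a zero-variance residual.
    """
    raw = np.asarray(raw, dtype=float)
    if covariates is not None and len(covariates.columns):
        cov = _drop_constant(covariates)
        X = np.column_stack([np.ones(len(raw)), cov.to_numpy(dtype=float)])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            bad = []
            for k in range(1, X.shape[1]):
                if np.linalg.matrix_rank(X[:, : k + 1]) == np.linalg.matrix_rank(X[:, :k]):
                    bad.append(cov.columns[k - 1])
            raise ValueError(f"collinear covariate columns: {bad}")
        beta, *_ = np.linalg.lstsq(X, raw, rcond=None)
        resid = raw - X @ beta
    else:
        resid = raw - raw.mean()
    sd = resid.std()
    if sd < 1e-12 * max(1.0, np.abs(raw).max()):
        raise ValueError("score has zero residual variance after adjustment")
    return (resid - resid.mean()) / resid.std()


def snp_set_score(
    harmonized: pd.DataFrame,
    gm: GenotypeMatrix,
    snp_ids: list[str],
    mode: str = "weighted",
) -> np.ndarray:
    """Few-SNP added-risk score.

    ``weighted`` sums oriented weight x dosage over the listed SNPs (equal to
    :func:`compute_prs` restricted to them at threshold 1). ``allele_count``
    counts risk alleles: the dosage itself when the oriented weight is
    positive, ``2 - dosage`` when negative (so the counted allele always
    carries positive discovery effect). Missing ids raise ``KeyError``.
    """
    idx = harmonized.set_index("SNP")
    missing = [s for s in snp_ids if s not in idx.index]
    if missing:
        raise KeyError(f"SNPs absent after harmonization: {missing}")
    sub = idx.loc[snp_ids]
    cols = np.atleast_1d(sub["col"].to_numpy(dtype=int))
    w = np.atleast_1d(sub["weight"].to_numpy(dtype=float))
    d = gm.dosages[:, cols]
    if mode == "weighted":
        return d @ w
    if mode == "allele_count":
        risk = np.where(w >= 0, d, 2.0 - d)
        return risk.sum(axis=1)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class ScoreMatrix:
    """Participants x score-column container.

    One column per (compartment, mask-state, p-threshold) triple, named
    ``<compartment>[-<mask>]@<threshold>``. ``raw`` holds weighted-dosage
    sums, ``adjusted`` the PC/array-residualized z-scores, ``snp_counts`` the
    per-column number of SNPs entering the sum.
    """

    raw: pd.DataFrame
    adjusted: pd.DataFrame
    snp_counts: dict[str, int]
    params: dict = field(default_factory=dict)

    def counts_json(self) -> dict:
        return {"snp_counts": self.snp_counts, "params": self.params}


def column_name(compartment: str, mask: str | None, threshold: float) -> str:
    tag = compartment if mask is None else f"{compartment}-{mask}"
    return f"{tag}@{threshold:g}"


def build_score_series(
    gm: GenotypeMatrix,
    harmonized: pd.DataFrame,
    partition: VariantPartition,
    compartments: tuple[str, ...] = ("genomewide", "genic", "intergenic"),
    masks: tuple[str | None, ...] = (None,),
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    clump_params: ClumpParams = ClumpParams(),
    covariates: pd.DataFrame | None = None,
) -> ScoreMatrix:
    """Build the full score series.

    For every (compartment, mask-state) the candidate set is restricted to
    QC-passing harmonized variants of that compartment (mask-excluded for
    masked states), clumped within the set, then thresholded. Masks beyond
    ``None`` name region masks loaded in the partition.
    """
    by_id = harmonized.set_index("SNP")
    raw_cols: dict[str, np.ndarray] = {}
    adj_cols: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for comp in compartments:
        for mask in masks:
            cols = partition.indices(comp, exclude_mask=mask)
            ids = gm.variants["id"].to_numpy()[cols]
            present = by_id.index.intersection(ids)
            sub = by_id.loc[present]
            cand_cols = sub["col"].to_numpy(dtype=int)
            res = clump(cand_cols, sub["P"].to_numpy(), gm, clump_params)
            retained = set(res.retained)
            for thr in thresholds:
                name = column_name(comp, mask, thr)
                score, n_snp = compute_prs(harmonized, gm, retained, thr)
                raw_cols[name] = score
                counts[name] = n_snp
                if n_snp == 0:
                    adj_cols[name] = score
                else:
                    adj_cols[name] = adjust_and_standardize(score, covariates)
    index = pd.Index(gm.samples, name="IID")
    return ScoreMatrix(
        raw=pd.DataFrame(raw_cols, index=index),
        adjusted=pd.DataFrame(adj_cols, index=index),
        snp_counts=counts,
        params={
            "thresholds": list(thresholds),
            "compartments": list(compartments),
            "masks": [m for m in masks],
            "clump_r2": clump_params.r2_max,
            "clump_bp": clump_params.window_bp,
        },
    )


def gene_score(
    gm: GenotypeMatrix,
    harmonized: pd.DataFrame,
    genes: pd.DataFrame,
    gene_id: str,
    p_threshold: float = 0.1,
    clump_params: ClumpParams = ClumpParams(),
    up_kb: float = 35,
    down_kb: float = 10,
    strand_aware: bool = True,
) -> tuple[np.ndarray, int]:
    """Single-gene score: clump within the gene's extended window, then sum
    weighted dosages at the given threshold (most inclusive by default)."""
    sub_genes = genes[genes["gene_id"] == gene_id]
    if sub_genes.empty:
        raise KeyError(f"unknown gene {gene_id!r}")
    in_win = annotate_genic(gm.variants, sub_genes, up_kb, down_kb, strand_aware)
    ids = set(gm.variants["id"].to_numpy()[in_win])
    sub = harmonized[harmonized["SNP"].isin(ids)]
    res = clump(sub["col"].to_numpy(dtype=int), sub["P"].to_numpy(), gm, clump_params)
    return compute_prs(harmonized, gm, set(res.retained), p_threshold)
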
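"""Covariate-adjusted association of scores with tract phenotypes.

Each model is an OLS regression of a standardized tract phenotype on one or
more standardized scores plus sex, age and scan-site covariates (site entered
as categorical dummies). Reported effect sizes are the standardized betas
with two-tailed t-distribution p-values. Multiple testing is handled with
Bonferroni families mirroring the analysis tables (e.g. 5 thresholds x 4
tracts = 20 tests).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .clump import ClumpParams, clump
from .containers import GenotypeMatrix
from .partition import VariantPartition
from .scoring import adjust_and_standardize, compute_prs

log = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    score: str
    phenotype: str
    beta: float
    se: float
    p: float
    n: int
    family: str | None = None
    family_m: int | None = None
    significant: bool | None = None


@dataclass
class TestFamily:
    """A Bonferroni family: per-test threshold is ``alpha / m``."""

    __test__ = False  # not a pytest collection target

    family_id: str
    members: list[AssociationResult] = field(default_factory=list)
    alpha: float = 0.05

    @property
    def m(self) -> int:
        return len(self.members)

    @property
    def threshold(self) -> float:
        if self.m < 1:
            raise ValueError("family must contain at least one test")
        return self.alpha / self.m


def bonferroni(family: TestFamily) -> float:
    """Apply the family's Bonferroni threshold, flagging members in place.

    A member is significant when ``p < alpha / m`` (strict). Returns the
    threshold.
    """
    thr = family.threshold
    for r in family.members:
        r.family = family.family_id
        r.family_m = family.m
        r.significant = r.p < thr
    return thr


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance column cannot be standardized")
    return (x - x.mean()) / sd


def _covariate_design(cov: pd.DataFrame) -> pd.DataFrame:
    """Numeric design columns: site expanded to dummies, rest passed through."""
    parts = []
    for c in cov.columns:
        if c == "site":
            parts.append(pd.get_dummies(cov[c], prefix="site", drop_first=True, dtype=float))
        else:
            parts.append(cov[[c]].astype(float))
    return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=cov.index)


def fit_association(
    phenotype: pd.Series,
    scores: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> list[AssociationResult]:
    """OLS of a standardized phenotype on standardized score(s) + covariates.

    Rows with any missing value across phenotype, scores and covariates are
    dropped (listwise deletion); standardization is computed on the analysis
    sample. With several score columns each beta is conditional on the others
    (joint model). Returns one result per score column.
    """
    if isinstance(scores, pd.Series):
        scores = scores.to_frame()
    frames = [phenotype.rename("_y"), scores]
    if covariates is not None:
        frames.append(covariates)
    data = pd.concat(frames, axis=1, join="inner").dropna()
    n = len(data)
    cov_design = (
        _covariate_design(data[covariates.columns]) if covariates is not None else
        pd.DataFrame(index=data.index)
    )
    n_params = 1 + len(scores.columns) + cov_design.shape[1]
    if n <= n_params + 1:
        raise ValueError(f"too few complete cases (n={n}) for {n_params} parameters")

    y = _standardize(data["_y"].to_numpy(dtype=float))
    Xs = np.column_stack(
        [_standardize(data[c].to_numpy(dtype=float)) for c in scores.columns]
    )
    X = pd.DataFrame(Xs, columns=list(scores.columns), index=data.index)
    X = pd.concat([X, cov_design], axis=1)
    model = sm.OLS(y, sm.add_constant(X.to_numpy(dtype=float))).fit()
    names = ["const"] + list(X.columns)
    results = []
    for c in scores.columns:
        k = names.index(c)
        results.append(
            AssociationResult(
                score=str(c),
                phenotype=str(phenotype.name),
                beta=float(model.params[k]),
                se=float(model.bse[k]),
                p=float(model.pvalues[k]),
                n=n,
            )
        )
    return results


def associate_series(
    score_table: pd.DataFrame,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame | None,
    family_id: str,
) -> tuple[list[AssociationResult], TestFamily]:
    """Test every (score column, phenotype column) pair as one Bonferroni
    family. All-missing score columns are skipped with a log message."""
    results: list[AssociationResult] = []
    for s in score_table.columns:
        if score_table[s].isna().all():
            log.info("associate_series: skipping empty score column %s", s)
            continue
        for ph in phenotypes.columns:
            results.extend(
                fit_association(phenotypes[ph], score_table[[s]], covariates)
            )
    family = TestFamily(family_id, members=results)
    if results:
        bonferroni(family)
    return results, family


def per_chromosome_scan(
    gm: GenotypeMatrix,
    harmonized: pd.DataFrame,
    partition: VariantPartition,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame | None,
    mask: str | None = None,
    p_threshold: float = 1e-4,
    clump_params: ClumpParams = ClumpParams(),
    adjust_covariates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, list[AssociationResult], TestFamily]:
    """Intergenic score per chromosome at a fixed threshold, tested against
    every phenotype as a single Bonferroni family.

    The chromosome carrying the mask region additionally gets a
    ``<chrom>-<mask>`` column with masked variants excluded. Chromosomes with
    no qualifying SNPs are skipped with a log message.
    """
    by_id = harmonized.set_index("SNP")
    chroms = list(dict.fromkeys(gm.variants["chrom"]))
    mask_chrom = None
    if mask is not None:
        mask_chrom = str(partition.params.get("regions", {}).get(mask, (None,))[0])
    score_cols: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for chrom in chroms:
        states: list[tuple[str, str | None]] = [(str(chrom), None)]
        if mask is not None and str(chrom) == mask_chrom:
            states.append((f"{chrom}-{mask}", mask))
        for name, mstate in states:
            cols = partition.indices("intergenic", exclude_mask=mstate)
            cols = cols[gm.variants["chrom"].to_numpy()[cols] == chrom]
            ids = gm.variants["id"].to_numpy()[cols]
            sub = by_id.loc[by_id.index.intersection(ids)]
            sub = sub[sub["P"] <= p_threshold]
            if sub.empty:
                log.info("per_chromosome_scan: no qualifying SNPs for %s", name)
                continue
            res = clump(sub["col"].to_numpy(dtype=int), sub["P"].to_numpy(), gm, clump_params)
            raw, n_snp = compute_prs(harmonized, gm, set(res.retained), p_threshold)
            score_cols[name] = adjust_and_standardize(raw, adjust_covariates)
            counts[name] = n_snp
    score_table = pd.DataFrame(score_cols, index=pd.Index(gm.samples, name="IID"))
    results, family = associate_series(
        score_table, phenotypes, covariates, family_id="per_chromosome"
    )
    return score_table, results, family
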
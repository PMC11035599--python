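"""Variant QC and compartment labelling (genic / intergenic / gene-set / masked).

QC removes variants with MAF below 5% or Hardy-Weinberg exact-test p below
1e-6 (defaults). Genic status uses asymmetric, strand-aware windows around
gene bodies: 35 kb upstream and 10 kb downstream by default, so a variant
near a minus-strand gene is genic when it lies within 10 kb before the start
or 35 kb past the end. Named region masks (e.g. an MHC-like interval) are
half-open ``[start, end)`` on position.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import GenotypeMatrix

log = logging.getLogger(__name__)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided Hardy-Weinberg exact test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed the
    observed one. Monomorphic samples have a single attainable configuration
    and return 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if n_minor == 0:
        return 1.0
    # heterozygote counts share the parity of the minor-allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_min = (n_minor - hets) // 2
    hom_maj = n - hets - hom_min
    ok = hom_maj >= 0
    hets, hom_min, hom_maj = hets[ok], hom_min[ok], hom_maj[ok]
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_min + 1)
        - gammaln(hets + 1)
        - gammaln(hom_maj + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[hets == n_Aa][0]
    p = float(prob[prob <= obs * (1 + 1e-12)].sum())
    return min(p, 1.0)


def genotype_counts(gm: GenotypeMatrix) -> np.ndarray:
    """Hard-call genotype counts per variant as an ``(n_variants, 3)`` array
    of (hom-ref, het, hom-alt). Imputed fractional dosages are rounded."""
    d = np.rint(gm.dosages).astype(int)
    counts = np.empty((gm.n_variants, 3), dtype=int)
    for g in (0, 1, 2):
        counts[:, g] = (d == g).sum(axis=0)
    return counts


def qc_filter(
    gm: GenotypeMatrix, maf_min: float = 0.05, hwe_p_min: float = 1e-6
) -> np.ndarray:
    """Boolean pass flag per variant: fails when MAF < ``maf_min`` (strict)
    or the HWE exact p-value < ``hwe_p_min`` (strict)."""
    counts = genotype_counts(gm)
    n_alt = counts[:, 1] + 2 * counts[:, 2]
    n_tot = 2 * counts.sum(axis=1)
    f = n_alt / n_tot
    maf = np.minimum(f, 1 - f)
    passes = maf >= maf_min
    for j in np.flatnonzero(passes):
        if hwe_exact_test(*counts[j]) < hwe_p_min:
            passes[j] = False
    n_fail = int((~passes).sum())
    if n_fail:
        log.info("qc_filter: %d of %d variants fail QC", n_fail, len(passes))
    return passes


def _gene_windows(
    genes: pd.DataFrame, up_kb: float, down_kb: float, strand_aware: bool
) -> pd.DataFrame:
    up = int(up_kb * 1000)
    down = int(down_kb * 1000)
    minus = (genes["strand"] == "-") & strand_aware
    lo = np.where(minus, genes["start"] - down, genes["start"] - up)
    hi = np.where(minus, genes["end"] + up, genes["end"] + down)
    return pd.DataFrame({"chrom": genes["chrom"], "lo": lo, "hi": hi})


def annotate_genic(
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    up_kb: float = 35,
    down_kb: float = 10,
    strand_aware: bool = True,
) -> np.ndarray:
    """Boolean flag per variant: inside the extended window of any gene.

    A plus-strand gene covers ``[start - up, end + down]`` (inclusive); a
    minus-strand gene ``[start - down, end + up]``. With
    ``strand_aware=False`` every gene is windowed as if on the plus strand.
    Variants on chromosomes without genes are intergenic.
    """
    flags = np.zeros(len(variants), dtype=bool)
    if genes.empty:
        return flags
    win = _gene_windows(genes, up_kb, down_kb, strand_aware)
    for chrom, sub in win.groupby("chrom", sort=False):
        vmask = (variants["chrom"] == chrom).to_numpy()
        if not vmask.any():
            continue
        pos = variants.loc[vmask, "pos"].to_numpy()
        hit = np.zeros(len(pos), dtype=bool)
        for lo, hi in zip(sub["lo"].to_numpy(), sub["hi"].to_numpy()):
            hit |= (pos >= lo) & (pos <= hi)
        flags[np.flatnonzero(vmask)] |= hit
    return flags


def apply_region_mask(
    variants: pd.DataFrame, region: tuple[str, int, int]
) -> np.ndarray:
    """Flag variants inside ``(chrom, start, end)``, half-open on position."""
    chrom, start, end = region
    if end <= start:
        raise ValueError("mask region end must exceed start")
    return (
        (variants["chrom"].astype(str) == str(chrom))
        & (variants["pos"] >= start)
        & (variants["pos"] < end)
    ).to_numpy()


def parse_region(spec: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` into a region tuple."""
    chrom, _, span = spec.partition(":")
    start, _, end = span.partition("-")
    return chrom, int(start), int(end)


@dataclass
class VariantPartition:
    """Per-variant QC and compartment labels aligned to a genotype matrix.

    ``table`` holds, per variant: ``qc_pass``, ``genic`` (window hit on any
    gene), one ``set_<name>`` column per loaded gene set (window hit on set
    genes only, hence implying genic) and one ``mask_<name>`` column per
    named region.
    """

    table: pd.DataFrame
    params: dict = field(default_factory=dict)

    def indices(
        self,
        compartment: str = "genomewide",
        exclude_mask: str | None = None,
        qc_only: bool = True,
    ) -> np.ndarray:
        """Variant column indices for a compartment, optionally mask-excluded.

        ``compartment`` is ``genomewide``, ``genic``, ``intergenic`` or a
        loaded gene-set name.
        """
        t = self.table
        # copy: to_numpy() can alias the column's backing array, and we &= below
        sel = t["qc_pass"].to_numpy().copy() if qc_only else np.ones(len(t), dtype=bool)
        if compartment == "genomewide":
            pass
        elif compartment == "genic":
            sel &= t["genic"].to_numpy()
        elif compartment == "intergenic":
            sel &= ~t["genic"].to_numpy()
        elif f"set_{compartment}" in t.columns:
            sel &= t[f"set_{compartment}"].to_numpy()
        else:
            raise KeyError(f"unknown compartment {compartment!r}")
        if exclude_mask is not None:
            sel &= ~t[f"mask_{exclude_mask}"].to_numpy()
        return np.flatnonzero(sel)


def build_partition(
    gm: GenotypeMatrix,
    genes: pd.DataFrame,
    gene_sets: dict[str, list[str]] | None = None,
    regions: dict[str, tuple[str, int, int]] | None = None,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-6,
    up_kb: float = 35,
    down_kb: float = 10,
    strand_aware: bool = True,
) -> VariantPartition:
    """QC-filter and label every variant of a genotype matrix."""
    gene_sets = gene_sets or {}
    regions = regions or {}
    t = pd.DataFrame(index=gm.variants.index)
    t["id"] = gm.variants["id"]
    t["chrom"] = gm.variants["chrom"]
    t["qc_pass"] = qc_filter(gm, maf_min, hwe_p_min)
    t["genic"] = annotate_genic(gm.variants, genes, up_kb, down_kb, strand_aware)
    known = set(genes["gene_id"])
    for name, members in gene_sets.items():
        missing = set(members) - known
        if missing:
            log.warning("gene set %s: %d ids not in gene models", name, len(missing))
        sub = genes[genes["gene_id"].isin(members)]
        t[f"set_{name}"] = annotate_genic(gm.variants, sub, up_kb, down_kb, strand_aware)
    for name, region in regions.items():
        t[f"mask_{name}"] = apply_region_mask(gm.variants, region)
    params = {
        "maf_min": maf_min,
        "hwe_p_min": hwe_p_min,
        "up_kb": up_kb,
        "down_kb": down_kb,
        "strand_aware": strand_aware,
        "regions": {k: tuple(v) for k, v in regions.items()},
    }
    return VariantPartition(t, params)
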
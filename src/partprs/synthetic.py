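"""Synthetic cohort generator with planted genetic architecture.

Generates everything the downstream analysis consumes: biallelic SNP dosages
with block-wise LD (elevated inside one designated high-LD region), stranded
gene models with a nested gene set, a discovery-GWAS summary-statistics file
whose marginal effects are the LD-convolution of a point-normal joint
architecture plus sampling noise, and per-participant covariates plus
left/right tract phenotypes carrying the planted regional signal.

Genotypes come from a latent-Gaussian copula: per block, two latent haplotype
chains with a non-stationary AR(1) correlation are thresholded at each
variant's allele-frequency quantile. The adjacent-pair latent correlation is
calibrated (tetrachoric inversion) so the *dosage* correlation hits the
requested target r-squared; correlation decays multiplicatively with
distance and is zero across blocks.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import GenotypeMatrix
from .partition import annotate_genic, apply_region_mask

log = logging.getLogger(__name__)

#: Tract naming follows the four frontal association tracts analysed.
TRACT_NAMES = ("CG", "iFO", "sL", "Unc")

_ALLELE_PAIRS = [
    ("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
    ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T"),
]


@dataclass(frozen=True)
class GenomeSpec:
    """Geometry of the synthetic genome.

    ``special_region`` designates the high-LD interval (an MHC-like region)
    on one chromosome; ``r2_adjacent`` / ``r2_adjacent_special`` are the
    target dosage r-squared between neighbouring SNPs outside / inside it.
    """

    n_chromosomes: int = 4
    chrom_length_bp: int = 20_000_000
    block_length_bp: int = 1_000_000
    snps_per_block: int = 8
    maf_range: tuple[float, float] = (0.05, 0.5)
    special_region: tuple[str, int, int] = ("2", 5_000_000, 15_000_000)
    r2_adjacent: float = 0.4
    r2_adjacent_special: float = 0.8
    seed: int = 0

    def chromosomes(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chromosomes)]

    def validate(self) -> None:
        for fname in ("n_chromosomes", "chrom_length_bp", "block_length_bp", "snps_per_block"):
            if getattr(self, fname) <= 0:
                raise ValueError(f"{fname} must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < min <= max <= 0.5")
        chrom, start, end = self.special_region
        if str(chrom) not in self.chromosomes():
            raise ValueError(f"special_region chromosome {chrom!r} not in genome")
        if not (0 <= start < end <= self.chrom_length_bp):
            raise ValueError("special_region must lie within its chromosome")
        for fname in ("r2_adjacent", "r2_adjacent_special"):
            if not (0 <= getattr(self, fname) < 1):
                raise ValueError(f"{fname} must lie in [0, 1)")


@dataclass(frozen=True)
class EffectSpec:
    """Planted genetic architecture shared by the discovery trait and tracts.

    ``h2_region`` / ``h2_background`` are the phenotype variance fractions
    contributed by causal variants inside / outside the special region.
    Causal status is point-normal: probability ``prop_causal`` per variant,
    multiplied by ``set_enrichment`` (capped at 1) for gene-set variants.
    ``rho_traits`` correlates each tract's causal effects with the discovery
    trait's. ``n_discovery`` scales the summary-statistics sampling noise
    (variance 1/n per standardized variant).
    """

    h2_background: float = 0.10
    h2_region: float = 0.02
    prop_causal: float = 0.05
    set_enrichment: float = 20.0
    covariate_betas: tuple[tuple[str, float], ...] = (
        ("sex", 0.10), ("age", 0.01), ("site", 0.05),
    )
    n_discovery: int = 100_000
    rho_traits: float = -0.9

    def validate(self) -> None:
        if self.h2_background < 0 or self.h2_region < 0:
            raise ValueError("h2_background and h2_region must be non-negative")
        if self.h2_background + self.h2_region > 1:
            raise ValueError("h2_background + h2_region must not exceed 1")
        if not (0 < self.prop_causal <= 1):
            raise ValueError("prop_causal must lie in (0, 1]")
        if self.set_enrichment < 0:
            raise ValueError("set_enrichment must be non-negative")
        if not (-1 <= self.rho_traits <= 1):
            raise ValueError("rho_traits must lie in [-1, 1]")
        if self.n_discovery < 10:
            raise ValueError("n_discovery must be at least 10")

    @property
    def covariates(self) -> dict[str, float]:
        return dict(self.covariate_betas)


@lru_cache(maxsize=4096)
def _latent_rho(p1: float, p2: float, r_target: float) -> float:
    """Latent bivariate-normal correlation giving Bernoulli(p1), Bernoulli(p2)
    threshold indicators a Pearson correlation of ``r_target`` (capped at the
    maximum attainable for the margins)."""
    if r_target <= 0:
        return 0.0
    z1, z2 = stats.norm.ppf(p1), stats.norm.ppf(p2)
    target_p11 = p1 * p2 + r_target * np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))

    def gap(rho: float) -> float:
        cov = [[1.0, rho], [rho, 1.0]]
        return stats.multivariate_normal.cdf([z1, z2], mean=[0, 0], cov=cov) - target_p11

    hi = 0.9999
    if gap(hi) <= 0:
        return hi
    return float(optimize.brentq(gap, 0.0, hi, xtol=1e-5))


def _block_in_region(chrom: str, b_start: int, b_end: int, region: tuple[str, int, int]) -> bool:
    rc, rs, re = region
    return str(chrom) == str(rc) and b_start >= rs and b_end <= re


def simulate_genotypes(spec: GenomeSpec, n_samples: int) -> GenotypeMatrix:
    """Generate hard-call dosages with the block LD structure of ``spec``.

    Reproducible given ``spec.seed``; alt is always the minor allele with the
    drawn MAF (in expectation), ref/alt letters avoid palindromic pairs.
    """
    spec.validate()
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    rng = np.random.default_rng(spec.seed)
    L = spec.block_length_bp
    m_b = spec.snps_per_block
    rows = []
    dose_cols = []
    for chrom in spec.chromosomes():
        n_blocks = max(1, spec.chrom_length_bp // L)
        for b in range(n_blocks):
            b_start = b * L
            special = _block_in_region(chrom, b_start, b_start + L, spec.special_region)
            r2 = spec.r2_adjacent_special if special else spec.r2_adjacent
            r_t = np.sqrt(r2)
            center = rng.uniform(*spec.maf_range)
            mafs = np.clip(center + rng.uniform(-0.02, 0.02, size=m_b), 0.01, 0.5)
            rhos = np.array(
                [
                    _latent_rho(round(mafs[j], 3), round(mafs[j + 1], 3), round(r_t, 3))
                    for j in range(m_b - 1)
                ]
            )
            # two latent haplotype chains, thresholded at the MAF quantile
            haps = []
            for _ in range(2):
                x = np.empty((n_samples, m_b))
                x[:, 0] = rng.standard_normal(n_samples)
                for j in range(1, m_b):
                    eps = rng.standard_normal(n_samples)
                    x[:, j] = rhos[j - 1] * x[:, j - 1] + np.sqrt(1 - rhos[j - 1] ** 2) * eps
                haps.append(x < stats.norm.ppf(mafs))
            dose_cols.append((haps[0].astype(float) + haps[1]).astype(float))
            for j in range(m_b):
                pos = b_start + int((j + 1) * L / (m_b + 1))
                ref, alt = _ALLELE_PAIRS[rng.integers(len(_ALLELE_PAIRS))]
                rows.append(
                    (f"v{chrom}_{b * m_b + j}", chrom, pos, ref, alt, f"{chrom}:{b}",
                     float(mafs[j]))
                )
    variants = pd.DataFrame(
        rows, columns=["id", "chrom", "pos", "ref", "alt", "block", "target_maf"]
    )
    samples = np.array([f"S{i:06d}" for i in range(n_samples)])
    return GenotypeMatrix(samples, variants, np.hstack(dose_cols))


def simulate_annotation(spec: GenomeSpec) -> tuple[pd.DataFrame, list[str]]:
    """Gene models plus the designated gene set.

    One gene per even-indexed block, occupying the 30-55% span of the block,
    with alternating strand. The gene set holds the first three genes whose
    blocks lie fully inside the special region plus the first gene of the
    next chromosome, so the set is nested in the region but not confined to
    it. Raises if the region hosts fewer than two genes.
    """
    spec.validate()
    L = spec.block_length_bp
    rows = []
    gi = 0
    for chrom in spec.chromosomes():
        n_blocks = max(1, spec.chrom_length_bp // L)
        for b in range(0, n_blocks, 2):
            start = b * L + int(0.30 * L)
            end = b * L + int(0.55 * L)
            rows.append((f"G{chrom}_{b}", chrom, start, end, "+" if gi % 2 == 0 else "-"))
            gi += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])

    in_region = [
        g["gene_id"]
        for _, g in genes.iterrows()
        if _block_in_region(g["chrom"], (g["start"] // L) * L, (g["start"] // L) * L + L,
                            spec.special_region)
    ]
    if len(in_region) < 2:
        raise ValueError("special_region too small to host the required >=2 set genes")
    outside = genes[~genes["gene_id"].isin(in_region)]
    # prefer an off-chromosome gene so the out-of-region set member is LD-free
    off_chrom = outside[outside["chrom"] != str(spec.special_region[0])]
    pick = off_chrom if not off_chrom.empty else outside
    if pick.empty:
        raise ValueError("genome too small to place a set gene outside the region")
    gene_set = list(in_region[:3]) + [pick["gene_id"].iloc[0]]
    return genes, gene_set


@dataclass
class TrueEffects:
    """Planted joint effects on the standardized-dosage scale."""

    causal: np.ndarray            # bool per variant
    beta_disorder: np.ndarray     # (m,)
    beta_tracts: np.ndarray       # (m, n_tracts)
    in_region: np.ndarray         # bool per variant
    in_set: np.ndarray            # bool per variant


def draw_effects(
    gm: GenotypeMatrix,
    genes: pd.DataFrame,
    gene_set: list[str],
    region: tuple[str, int, int],
    effects: EffectSpec,
    n_tracts: int = 4,
    seed: int | None = None,
) -> TrueEffects:
    """Draw the shared point-normal architecture.

    Causal effects for the discovery trait and each tract are bivariate
    normal with correlation ``rho_traits`` per variant, then rescaled so the
    realized variance of the regional and background genetic components
    match ``h2_region`` and ``h2_background`` exactly in this sample.
    """
    effects.validate()
    rng = np.random.default_rng(seed)
    m = gm.n_variants
    set_genes = genes[genes["gene_id"].isin(gene_set)]
    in_set = annotate_genic(gm.variants, set_genes)
    in_region = apply_region_mask(gm.variants, region)
    p_causal = np.where(
        in_set, np.minimum(1.0, effects.prop_causal * effects.set_enrichment),
        effects.prop_causal,
    )
    causal = rng.random(m) < p_causal

    d = rng.standard_normal(m)
    resid = rng.standard_normal((m, n_tracts))
    t = effects.rho_traits * d[:, None] + np.sqrt(1 - effects.rho_traits**2) * resid
    d[~causal] = 0.0
    t[~causal] = 0.0

    sd = gm.dosages.std(axis=0)
    ok = sd > 0
    Z = np.zeros_like(gm.dosages)
    Z[:, ok] = (gm.dosages[:, ok] - gm.dosages[:, ok].mean(axis=0)) / sd[ok]

    def rescale(beta: np.ndarray, mask: np.ndarray, h2: float) -> None:
        sel = causal & mask & ok
        if not sel.any():
            return
        g = Z[:, sel] @ beta[sel]
        v = g.var()
        beta[sel] *= np.sqrt(h2 / v) if v > 0 else 0.0

    rescale(d, in_region, effects.h2_region)
    rescale(d, ~in_region, effects.h2_background)
    for k in range(n_tracts):
        rescale(t[:, k], in_region, effects.h2_region)
        rescale(t[:, k], ~in_region, effects.h2_background)
    return TrueEffects(causal, d, t, in_region, in_set)


def simulate_discovery_sumstats(
    gm: GenotypeMatrix,
    effects: EffectSpec,
    true_effects: TrueEffects,
    seed: int | None = None,
) -> pd.DataFrame:
    """Analytic discovery-GWAS summary statistics.

    Per block, marginal standardized effects are ``R beta + e`` with ``R`` the
    empirical block LD matrix and ``e ~ N(0, R / n_discovery)``; effects are
    then rescaled to the per-allele scale and a random 30% of rows report the
    ref allele as effect allele (sign and frequency flipped accordingly).
    """
    effects.validate()
    rng = np.random.default_rng(seed)
    n = gm.n_samples
    n_disc = effects.n_discovery
    sd = gm.dosages.std(axis=0)
    b_std = np.zeros(gm.n_variants)
    blocks = gm.variants["block"] if "block" in gm.variants else gm.variants["chrom"]
    for _, idx in gm.variants.groupby(blocks, sort=False).groups.items():
        cols = np.asarray(idx, dtype=int)
        ok = sd[cols] > 0
        Z = np.zeros((n, len(cols)))
        Z[:, ok] = (
            gm.dosages[:, cols[ok]] - gm.dosages[:, cols[ok]].mean(axis=0)
        ) / sd[cols[ok]]
        R = Z.T @ Z / n
        chol = np.linalg.cholesky(R + 1e-8 * np.eye(len(cols)))
        noise = chol @ rng.standard_normal(len(cols)) / np.sqrt(n_disc)
        b_std[cols] = R @ true_effects.beta_disorder[cols] + noise

    z = b_std * np.sqrt(n_disc)
    p = np.maximum(2 * stats.norm.sf(np.abs(z)), 1e-300)
    beta_allele = np.where(sd > 0, b_std / np.where(sd > 0, sd, 1.0), b_std)
    alt_freq = gm.alt_freq()

    flip = rng.random(gm.n_variants) < 0.30
    a1 = np.where(flip, gm.variants["ref"], gm.variants["alt"])
    a2 = np.where(flip, gm.variants["alt"], gm.variants["ref"])
    beta_out = np.where(flip, -beta_allele, beta_allele)
    freq_out = np.where(flip, 1 - alt_freq, alt_freq)
    return pd.DataFrame(
        {
            "SNP": gm.variants["id"],
            "CHR": gm.variants["chrom"],
            "BP": gm.variants["pos"],
            "A1": a1,
            "A2": a2,
            "BETA": beta_out,
            "P": p,
            "FREQ": freq_out,
            "N": n_disc,
        }
    )


def simulate_phenotypes(
    gm: GenotypeMatrix,
    effects: EffectSpec,
    true_effects: TrueEffects,
    n_tracts: int = 4,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant covariates and left/right tract phenotypes.

    Axonal density carries the planted genetic signal plus sex/age/site
    effects; orientation dispersion carries covariate effects and noise only.
    Hemisphere values share 95% of the tract-level variance, so left/right
    correlate at ~0.95. Ancestry PCs and the array indicator are pure noise
    columns (no population structure is modelled) kept to exercise the score
    adjustment.
    """
    if n_tracts < 1:
        raise ValueError("n_tracts must be at least 1")
    effects.validate()
    rng = np.random.default_rng(seed)
    n = gm.n_samples
    betas = effects.covariates

    sex = rng.integers(0, 2, size=n)
    age = rng.uniform(45, 81, size=n)
    site = rng.integers(0, 3, size=n)
    array = rng.integers(0, 2, size=n)
    covar = pd.DataFrame(
        {"sex": sex, "age": age, "site": site, "array": array},
        index=pd.Index(gm.samples, name="IID"),
    )
    for k in range(1, 16):
        covar[f"PC{k}"] = rng.standard_normal(n)

    sd = gm.dosages.std(axis=0)
    ok = sd > 0
    Z = np.zeros_like(gm.dosages)
    Z[:, ok] = (gm.dosages[:, ok] - gm.dosages[:, ok].mean(axis=0)) / sd[ok]
    cov_effect = (
        betas.get("sex", 0) * sex
        + betas.get("age", 0) * (age - age.mean())
        + betas.get("site", 0) * site
    )
    h2_tot = effects.h2_region + effects.h2_background
    e_sd = np.sqrt(max(1.0 - h2_tot, 0.05))

    tract_names = [
        TRACT_NAMES[k] if k < len(TRACT_NAMES) else f"T{k + 1}" for k in range(n_tracts)
    ]
    pheno = pd.DataFrame(index=pd.Index(gm.samples, name="IID"))
    for k, tract in enumerate(tract_names):
        g = Z @ true_effects.beta_tracts[:, k]
        latent_ax = g + cov_effect + e_sd * rng.standard_normal(n)
        latent_od = betas.get("sex", 0) * sex + rng.standard_normal(n)
        for measure, latent in (
            ("axonal_density", latent_ax),
            ("orientation_dispersion", latent_od),
        ):
            hemi_sd = np.sqrt(latent.var() / 19.0)  # hemisphere corr ~0.95
            pheno[f"{tract}_{measure}_L"] = latent + hemi_sd * rng.standard_normal(n)
            pheno[f"{tract}_{measure}_R"] = latent + hemi_sd * rng.standard_normal(n)
    return pheno, covar


def simulate_sumstats_pair(
    gm: GenotypeMatrix,
    h2_a: float,
    h2_b: float,
    rho: float,
    n_a: int,
    n_b: int,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Marginal summary statistics for two traits with correlated joint
    effects over the *whole* given genotype panel.

    Per-variant standardized joint effects are bivariate normal with
    correlation ``rho``, rescaled so each trait's genetic variance equals its
    ``h2``; marginal effects are the per-block LD convolution plus
    independent ``N(0, R/n)`` sampling noise (non-overlapping samples).
    Intended for calibration studies of the local genetic-correlation
    estimator.
    """
    rng = np.random.default_rng(seed)
    m = gm.n_variants
    ba = rng.standard_normal(m)
    bb = rho * ba + np.sqrt(1 - rho**2) * rng.standard_normal(m)
    sd = gm.dosages.std(axis=0)
    ok = sd > 0
    Z = np.zeros_like(gm.dosages)
    Z[:, ok] = (gm.dosages[:, ok] - gm.dosages[:, ok].mean(axis=0)) / sd[ok]
    for beta, h2 in ((ba, h2_a), (bb, h2_b)):
        v = (Z @ beta).var()
        beta *= np.sqrt(h2 / v) if v > 0 else 0.0

    out = []
    blocks = gm.variants["block"] if "block" in gm.variants else gm.variants["chrom"]
    for beta, n in ((ba, n_a), (bb, n_b)):
        marg = np.zeros(m)
        for _, idx in gm.variants.groupby(blocks, sort=False).groups.items():
            cols = np.asarray(idx, dtype=int)
            Zb = Z[:, cols]
            R = Zb.T @ Zb / gm.n_samples
            chol = np.linalg.cholesky(R + 1e-8 * np.eye(len(cols)))
            marg[cols] = R @ beta[cols] + chol @ rng.standard_normal(len(cols)) / np.sqrt(n)
        z = marg * np.sqrt(n)
        p = np.maximum(2 * stats.norm.sf(np.abs(z)), 1e-300)
        out.append(
            pd.DataFrame(
                {
                    "SNP": gm.variants["id"], "CHR": gm.variants["chrom"],
                    "BP": gm.variants["pos"], "A1": gm.variants["alt"],
                    "A2": gm.variants["ref"],
                    "BETA": np.where(ok, marg / np.where(ok, sd, 1.0), marg),
                    "P": p, "FREQ": gm.alt_freq(), "N": n,
                }
            )
        )
    return out[0], out[1]


@dataclass
class Cohort:
    """Bundle of everything one synthetic study provides."""

    genome: GenomeSpec
    effects: EffectSpec
    genotypes: GenotypeMatrix
    genes: pd.DataFrame
    gene_set: list[str]
    sumstats: pd.DataFrame
    phenotypes: pd.DataFrame
    covariates: pd.DataFrame
    true_effects: TrueEffects
    tract_names: list[str] = field(default_factory=lambda: list(TRACT_NAMES))


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def simulate_cohort(
    genome: GenomeSpec,
    effects: EffectSpec,
    n_samples: int,
    n_tracts: int = 4,
    seed: int | None = None,
) -> Cohort:
    """Generate the full cohort deterministically from one seed."""
    base = genome.seed if seed is None else seed
    s_geno, s_eff, s_ss, s_ph = _child_seeds(base, 4)
    genome = replace(genome, seed=s_geno)
    gm = simulate_genotypes(genome, n_samples)
    genes, gene_set = simulate_annotation(genome)
    te = draw_effects(gm, genes, gene_set, genome.special_region, effects, n_tracts, s_eff)
    ss = simulate_discovery_sumstats(gm, effects, te, s_ss)
    pheno, covar = simulate_phenotypes(gm, effects, te, n_tracts, s_ph)
    tracts = [TRACT_NAMES[k] if k < len(TRACT_NAMES) else f"T{k + 1}" for k in range(n_tracts)]
    return Cohort(genome, effects, gm, genes, gene_set, ss, pheno, covar, te, tracts)


def write_cohort(cohort: Cohort, outdir: str) -> dict[str, str]:
    """Serialize a cohort to its on-disk formats; returns the path map."""
    from pathlib import Path

    from . import io as pio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sumstats": str(out / "sumstats.tsv"),
        "vcf": str(out / "genotypes.vcf"),
        "dosage": str(out / "dosages.tsv"),
        "genes": str(out / "genes.bed"),
        "gene_set": str(out / "gene_set.txt"),
        "covariates": str(out / "covariates.tsv"),
        "phenotypes": str(out / "phenotypes.tsv"),
    }
    pio.write_sumstats(cohort.sumstats, paths["sumstats"])
    pio.write_vcf(cohort.genotypes, paths["vcf"])
    pio.write_dosage_text(cohort.genotypes, paths["dosage"])
    pio.write_genes_bed(cohort.genes, paths["genes"])
    pio.write_gene_set(cohort.gene_set, paths["gene_set"])
    pio.write_table(cohort.covariates, paths["covariates"])
    pio.write_table(cohort.phenotypes, paths["phenotypes"])
    return paths
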
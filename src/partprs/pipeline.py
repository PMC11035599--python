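"""End-to-end orchestration from a single YAML/JSON config.

Stages: read inputs (optionally generating them with the synthetic cohort
module first), harmonize, QC + partition, clump + score, phenotype prep,
association tables, optional per-chromosome scan and local genetic
correlation. Emits analysis tables shaped rows = threshold (or chromosome) x
columns = tracts with ``beta (p)`` cells, machine-readable JSON results, and
a provenance record (version, seed, parameter hash).
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from . import io as pio
from .association import associate_series, per_chromosome_scan
from .clump import ClumpParams
from .containers import GenotypeMatrix
from .local_rg import define_blocks, merge_blocks, run_local_rg, write_blocks
from .partition import build_partition, parse_region
from .phenotypes import prepare_phenotypes
from .scoring import DEFAULT_THRESHOLDS, build_score_series
from .synthetic import EffectSpec, GenomeSpec, simulate_cohort, write_cohort

log = logging.getLogger(__name__)

_KNOWN_COMPARTMENTS = {"genomewide", "genic", "intergenic"}


@dataclass
class RunConfig:
    """Validated run configuration; see ``validate_config`` for the rules."""

    seed: int = 0
    simulate: dict | None = None
    paths: dict = field(default_factory=dict)
    qc: dict = field(default_factory=lambda: {"maf_min": 0.05, "hwe_p_min": 1e-6})
    windows: dict = field(default_factory=lambda: {"up_kb": 35, "down_kb": 10, "strand_aware": True})
    clump: dict = field(default_factory=lambda: {"r2_max": 0.1, "window_bp": 1_000_000})
    thresholds: list = field(default_factory=lambda: list(DEFAULT_THRESHOLDS))
    masks: dict = field(default_factory=dict)
    compartments: list = field(default_factory=lambda: ["genomewide", "genic", "intergenic"])
    tracts: list = field(default_factory=lambda: ["CG", "iFO", "sL", "Unc"])
    measures: list = field(default_factory=lambda: ["axonal_density"])
    scan: dict = field(default_factory=dict)
    local_rg: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def validate_config(config: RunConfig) -> list[str]:
    """Collect every validation error (empty list means the config is ok)."""
    errors: list[str] = []
    thr = list(config.thresholds)
    if thr != sorted(thr):
        errors.append("thresholds must be sorted ascending")
    if any(not (0 < t <= 1) for t in thr):
        errors.append("thresholds must lie in (0, 1]")
    r2 = config.clump.get("r2_max", 0.1)
    if not (0 < r2 <= 1):
        errors.append(f"clump r2_max {r2} outside (0, 1]")
    if config.clump.get("window_bp", 1) <= 0:
        errors.append("clump window_bp must be positive")
    gene_sets = set(config.paths.get("gene_sets", {}) or {})
    if config.simulate is not None:
        gene_sets.add(config.simulate.get("gene_set_name", "complement"))
    for comp in config.compartments:
        if comp not in _KNOWN_COMPARTMENTS and comp not in gene_sets:
            errors.append(f"unknown compartment {comp!r}")
    for name, region in config.masks.items():
        try:
            parse_region(region) if isinstance(region, str) else tuple(region)
        except Exception:
            errors.append(f"mask {name!r} is not a chrom:start-end region")
    if config.simulate is None:
        for key in ("sumstats", "genotypes", "genes", "covariates", "phenotypes"):
            p = config.paths.get(key)
            if not p or not Path(p).exists():
                errors.append(f"paths.{key} missing or does not exist")
        for name, p in (config.paths.get("gene_sets", {}) or {}).items():
            if not Path(p).exists():
                errors.append(f"gene set {name!r} path does not exist")
    return errors


def _param_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _beta_p_table(results, row_key, col_key) -> pd.DataFrame:
    rows = sorted({row_key(r) for r in results}, key=str)
    cols = sorted({col_key(r) for r in results}, key=str)
    table = pd.DataFrame(index=rows, columns=cols, dtype=object)
    for r in results:
        cell = f"{r.beta:.4f} ({r.p:.3g})" + ("*" if r.significant else "")
        table.loc[row_key(r), col_key(r)] = cell
    return table


def _results_records(results) -> list[dict]:
    return [
        {
            "score": r.score, "phenotype": r.phenotype, "beta": r.beta,
            "se": r.se, "p": r.p, "n": r.n, "family": r.family,
            "family_m": r.family_m, "significant": r.significant,
        }
        for r in results
    ]


def marginal_gwas(gm: GenotypeMatrix, y: np.ndarray) -> pd.DataFrame:
    """Single-variant GWAS of a quantitative trait on the cohort itself,
    emitting canonical summary statistics (per-allele betas, normal p)."""
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    ys = (y[ok] - y[ok].mean()) / y[ok].std()
    d = gm.dosages[ok]
    sd = d.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = (d - d.mean(axis=0)) / sd_safe
    n = int(ok.sum())
    b_std = Z.T @ ys / n
    z = b_std * np.sqrt(n)
    b = b_std / sd_safe
    p = np.maximum(2 * stats.norm.sf(np.abs(z)), 1e-300)
    return pd.DataFrame(
        {
            "SNP": gm.variants["id"], "CHR": gm.variants["chrom"],
            "BP": gm.variants["pos"], "A1": gm.variants["alt"],
            "A2": gm.variants["ref"], "BETA": b, "P": p,
            "FREQ": gm.alt_freq(), "N": n,
        }
    )


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full analysis; returns the report bundle as a dict.

    Any stage error aborts with a ``PipelineError`` naming the stage.
    """
    errors = validate_config(config)
    if errors:
        raise PipelineError("validate", "; ".join(errors))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    bundle: dict = {}

    def stage(name):
        log.info("stage %-12s at %6.1fs", name, time.time() - t0)

    try:
        stage("inputs")
        set_name = "complement"
        if config.simulate is not None:
            sim = dict(config.simulate)
            set_name = sim.pop("gene_set_name", "complement")
            genome = GenomeSpec(**sim.get("genome", {}), seed=config.seed)
            effspec = EffectSpec(**sim.get("effects", {}))
            cohort = simulate_cohort(
                genome, effspec, n_samples=sim.get("n_samples", 2000),
                n_tracts=sim.get("n_tracts", 4), seed=config.seed,
            )
            paths = write_cohort(cohort, out / "inputs")
            config.paths = {
                **paths, "genotypes": paths["vcf"], "genotype_format": "vcf",
                "gene_sets": {set_name: paths["gene_set"]},
            }
            if not config.masks:
                c, s, e = genome.special_region
                config.masks = {"MHC": f"{c}:{s}-{e}"}
        sumstats = pio.read_sumstats(config.paths["sumstats"], config.paths.get("dialect", "default"))
        gm = pio.read_genotypes(config.paths["genotypes"], config.paths.get("genotype_format", "vcf"))
        genes = pio.read_genes_bed(config.paths["genes"])
        gene_sets = {
            name: pio.read_gene_set(p)
            for name, p in (config.paths.get("gene_sets", {}) or {}).items()
        }
        covar = pio.read_table(config.paths["covariates"])
        pheno_raw = pio.read_table(config.paths["phenotypes"])
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError("inputs", str(err)) from err

    try:
        stage("harmonize")
        harm = pio.harmonize(sumstats, gm)
        stage("partition")
        regions = {
            k: parse_region(v) if isinstance(v, str) else tuple(v)
            for k, v in config.masks.items()
        }
        part = build_partition(
            gm, genes, gene_sets, regions,
            maf_min=config.qc.get("maf_min", 0.05),
            hwe_p_min=config.qc.get("hwe_p_min", 1e-6),
            up_kb=config.windows.get("up_kb", 35),
            down_kb=config.windows.get("down_kb", 10),
            strand_aware=config.windows.get("strand_aware", True),
        )
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError("partition", str(err)) from err

    try:
        stage("scoring")
        cp = ClumpParams(config.clump.get("r2_max", 0.1), config.clump.get("window_bp", 1_000_000))
        pc_cols = [c for c in covar.columns if c.startswith("PC")][:15]
        adj_cov = covar[pc_cols + (["array"] if "array" in covar else [])]
        adj_cov = adj_cov.loc[pd.Index(gm.samples)]
        scores = build_score_series(
            gm, harm, part,
            compartments=tuple(config.compartments),
            masks=(None, *regions.keys()),
            thresholds=tuple(config.thresholds),
            clump_params=cp,
            covariates=adj_cov,
        )
        scores.adjusted.to_csv(out / "scores.tsv", sep="\t", float_format="%.8g")
        (out / "score_counts.json").write_text(json.dumps(scores.counts_json(), indent=2))
    except Exception as err:
        raise PipelineError("scoring", str(err)) from err

    try:
        stage("phenotypes")
        wide, tidy = prepare_phenotypes(pheno_raw, tuple(config.tracts))
        keep = [f"{t}_{m}" for t in config.tracts for m in config.measures]
        pheno = wide[keep]
    except Exception as err:
        raise PipelineError("phenotypes", str(err)) from err

    try:
        stage("association")
        model_cov = covar[[c for c in ("sex", "age", "site") if c in covar.columns]]
        model_cov = model_cov.loc[pd.Index(gm.samples)]
        all_results = []
        for mask_state in (None, *regions.keys()):
            for comp in config.compartments:
                tag = comp if mask_state is None else f"{comp}-{mask_state}"
                cols = [
                    c for c in scores.adjusted.columns
                    if c.rsplit("@", 1)[0] == tag
                ]
                res, fam = associate_series(
                    scores.adjusted[cols], pheno, model_cov, family_id=tag
                )
                all_results.extend(res)
                table = _beta_p_table(
                    res,
                    row_key=lambda r: r.score.rsplit("@", 1)[1],
                    col_key=lambda r: r.phenotype,
                )
                table.to_csv(out / f"table_{tag}.tsv", sep="\t")
        bundle["association"] = _results_records(all_results)
    except Exception as err:
        raise PipelineError("association", str(err)) from err

    if config.scan.get("enable", True):
        try:
            stage("scan")
            mask_name = next(iter(regions), None)
            _, scan_res, _ = per_chromosome_scan(
                gm, harm, part, pheno, model_cov,
                mask=mask_name,
                p_threshold=config.scan.get("p_threshold", 1e-4),
                clump_params=cp, adjust_covariates=adj_cov,
            )
            bundle["scan"] = _results_records(scan_res)
            _beta_p_table(
                scan_res, row_key=lambda r: r.score, col_key=lambda r: r.phenotype
            ).to_csv(out / "table_scan.tsv", sep="\t")
        except Exception as err:
            raise PipelineError("scan", str(err)) from err

    if config.local_rg.get("enable", False):
        try:
            stage("local_rg")
            blocks = define_blocks(
                gm.variants, config.local_rg.get("block_source", "uniform:1000000")
            )
            if config.local_rg.get("merge_region_blocks", False) and regions:
                name, (rc, rs, re) = next(iter(regions.items()))
                inside = [
                    b.block_id for b in blocks
                    if b.chrom == str(rc) and b.start >= rs and b.end <= re
                ]
                if len(inside) >= 2:
                    blocks = merge_blocks(blocks, inside, new_id=name)
            write_blocks(blocks, str(out / "blocks.tsv"))
            tract_col = f"{config.tracts[0]}_{config.measures[0]}"
            tract_ss = marginal_gwas(gm, pheno[tract_col].to_numpy())
            rg = run_local_rg(
                blocks, sumstats, tract_ss, gm,
                n_a=int(sumstats["N"].iloc[0]),
                n_b=int(tract_ss["N"].iloc[0]),
                n_sim=config.local_rg.get("n_sim", 2000),
                seed=config.seed,
            )
            rg.to_csv(out / "local_rg.tsv", sep="\t", index=False, float_format="%.6g")
            bundle["local_rg"] = rg.to_dict(orient="records")
        except Exception as err:
            raise PipelineError("local_rg", str(err)) from err

    stage("done")
    provenance = {
        "version": __version__,
        "seed": config.seed,
        "param_hash": _param_hash(config),
        "n_samples": int(gm.n_samples),
        "n_variants": int(gm.n_variants),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    (out / "results.json").write_text(json.dumps(bundle, indent=2, default=str))
    bundle["provenance"] = provenance
    return bundle


class PipelineError(RuntimeError):
    """Stage failure; carries the stage name for the CLI exit message."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
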
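"""On-disk formats and summary-statistics/genotype harmonization.

Supported formats: tab-separated GWAS summary statistics (dialect-mapped
column names), VCF v4.2 with GT genotypes (read through :mod:`cyvcf2`),
a plain-text dosage dialect, BED6 gene models, one-id-per-line gene sets,
and participant-keyed TSV covariate/phenotype tables.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    PALINDROMIC_PAIRS,
    SUMSTATS_COLUMNS,
    VALID_ALLELES,
    GenotypeMatrix,
    validate_sumstats,
)

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# summary statistics

#: Registry of column-name dialects. ``columns`` maps canonical -> on-disk
#: name; ``transform`` optionally names a per-column transform applied after
#: reading ("log" is used for odds-ratio effect columns).
SUMSTAT_DIALECTS: dict[str, dict] = {
    "default": {"columns": {c: c for c in SUMSTATS_COLUMNS}, "transform": {}},
    "or": {
        "columns": {**{c: c for c in SUMSTATS_COLUMNS}, "BETA": "OR"},
        "transform": {"BETA": "log"},
    },
}

_TRANSFORMS = {"log": np.log}


def read_sumstats(path: str | Path, dialect: str | dict = "default") -> pd.DataFrame:
    """Read a summary-statistics TSV into the canonical column layout.

    Rows with unparseable or out-of-domain required fields (p outside (0,1],
    non-ACGT alleles, missing values) are dropped with a logged count, as are
    duplicate variant ids. A missing required column raises ``ValueError``.
    """
    if isinstance(dialect, str):
        dialect = SUMSTAT_DIALECTS[dialect]
    colmap: dict[str, str] = dialect["columns"]
    transform: dict[str, str] = dialect.get("transform", {})

    df = pd.read_csv(path, sep="\t", dtype=str)
    for canonical, ondisk in colmap.items():
        if ondisk not in df.columns:
            raise ValueError(f"summary statistics file missing column {ondisk!r}")
    out = pd.DataFrame({c: df[colmap[c]] for c in SUMSTATS_COLUMNS})

    n0 = len(out)
    for col, typ in [("BP", "Int64"), ("N", "Int64")]:
        out[col] = pd.to_numeric(out[col], errors="coerce").astype(typ)
    for col in ("BETA", "P", "FREQ"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    for col, fn in transform.items():
        out[col] = _TRANSFORMS[fn](out[col])
    out["CHR"] = out["CHR"].astype(str)
    for col in ("A1", "A2"):
        out[col] = out[col].astype(str).str.upper()

    ok = (
        out[SUMSTATS_COLUMNS].notna().all(axis=1)
        & (out["P"] > 0)
        & (out["P"] <= 1)
        & out["A1"].isin(list(VALID_ALLELES))
        & out["A2"].isin(list(VALID_ALLELES))
    )
    ok &= ~out["SNP"].duplicated(keep="first")
    dropped = int(n0 - ok.sum())
    if dropped:
        log.info("read_sumstats: dropped %d of %d rows failing field checks", dropped, n0)
    out = out[ok].reset_index(drop=True)
    out["BP"] = out["BP"].astype(int)
    out["N"] = out["N"].astype(int)
    return validate_sumstats(out)


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    """Write canonical summary statistics as TSV (deterministic formatting)."""
    validate_sumstats(df)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# genotypes

def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write hard-call genotypes as a minimal VCF v4.2 with GT only."""
    d = gm.dosages
    if not np.all(np.isin(d, (0.0, 1.0, 2.0))):
        raise ValueError("VCF output requires hard-call dosages in {0,1,2}")
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, sub in gm.variants.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, gm.samples)) + "\n")
        for j, v in gm.variants.iterrows():
            gts = "\t".join(gt_code[g] for g in d[:, j])
            fh.write(
                f"{v['chrom']}\t{int(v['pos'])}\t{v['id']}\t{v['ref']}\t{v['alt']}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def _read_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.array(vcf.samples)
    rows, cols, n_imp = [], [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        gts = np.asarray(rec.genotype.array())
        alleles = gts[:, :-1]  # last entry is phasing
        if alleles.shape[1] != 2:
            raise ValueError(f"ploidy {alleles.shape[1]} != 2 at {rec.CHROM}:{rec.POS}")
        missing = (alleles < 0).any(axis=1)
        dose = (alleles > 0).sum(axis=1).astype(float)
        if missing.any():
            obs = dose[~missing]
            dose[missing] = obs.mean() if len(obs) else 0.0
        cols.append(dose)
        n_imp.append(int(missing.sum()))
        rows.append((rec.ID, rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
    if n_multi:
        log.info("read_genotypes: skipped %d multiallelic records", n_multi)
    variants = pd.DataFrame(rows, columns=["id", "chrom", "pos", "ref", "alt"])
    dosages = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypeMatrix(samples, variants, dosages, np.array(n_imp, dtype=int))


def write_dosage_text(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the text dosage dialect: header of variant ids, one row per
    participant, plus a ``<path>.variants.tsv`` sidecar with the variant map."""
    path = Path(path)
    df = pd.DataFrame(gm.dosages, columns=gm.variants["id"])
    df.insert(0, "IID", gm.samples)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    gm.variants.to_csv(path.with_suffix(path.suffix + ".variants.tsv"), sep="\t", index=False)


def _read_dosage_text(path: str | Path) -> GenotypeMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".variants.tsv")
    if not sidecar.exists():
        raise FileNotFoundError(f"dosage-text variant map sidecar not found: {sidecar}")
    variants = pd.read_csv(sidecar, sep="\t", dtype={"chrom": str})
    samples = df["IID"].to_numpy()
    dosages = df.drop(columns="IID").to_numpy(dtype=float)
    if list(df.columns[1:]) != list(variants["id"].astype(str)):
        raise ValueError("dosage header does not match variant map sidecar")
    return GenotypeMatrix(samples, variants, dosages)


def read_genotypes(path: str | Path, format: str = "vcf") -> GenotypeMatrix:
    """Read target genotypes from ``vcf`` or ``dosage-text`` files.

    Missing diploid genotypes (``./.``) are mean-imputed per variant with the
    imputation count recorded; multiallelic VCF records are skipped with a
    logged count; non-diploid records raise ``ValueError``.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format in ("dosage", "dosage-text"):
        return _read_dosage_text(path)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# annotation / tables

def write_genes_bed(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene models as BED6 (0-based half-open, strand in column 6)."""
    bed = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"].astype(int),
            "end": genes["end"].astype(int),
            "name": genes["gene_id"],
            "score": 0,
            "strand": genes["strand"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_genes_bed(path: str | Path) -> pd.DataFrame:
    """Read BED6 gene models into columns gene_id, chrom, start, end, strand."""
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str},
    )
    if not bed["strand"].isin(["+", "-"]).all():
        raise ValueError("BED strand column must be + or -")
    if (bed["start"] >= bed["end"]).any():
        raise ValueError("gene intervals must satisfy start < end")
    return pd.DataFrame(
        {
            "gene_id": bed["name"],
            "chrom": bed["chrom"],
            "start": bed["start"],
            "end": bed["end"],
            "strand": bed["strand"],
        }
    )


def read_gene_set(path: str | Path) -> list[str]:
    """Read a plain-text gene set, one gene id per line."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_set(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("".join(g + "\n" for g in genes))


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a participant-keyed TSV (covariates or phenotypes)."""
    return pd.read_csv(path, sep="\t").set_index("IID")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="IID", float_format="%.8g")


# ---------------------------------------------------------------------------
# harmonization

def harmonize(sumstats: pd.DataFrame, genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Align summary-statistics effect alleles to genotype alt dosages.

    Variants are matched on (chromosome, position). When the effect allele
    equals alt the weight is the reported effect; when it equals ref the sign
    is flipped; allele pairs not matching {ref, alt} are dropped. Palindromic
    (A/T, C/G) pairs are dropped when the effect-allele frequency lies in
    (0.4, 0.6) and otherwise oriented by comparing the reported frequency with
    the target alt frequency.

    Returns a frame with columns ``SNP`` (genotype variant id), ``CHR``,
    ``BP``, ``col`` (dosage column index), ``weight`` (oriented per-allele
    effect) and ``P``. Raises ``ValueError`` when no variants overlap.
    """
    gvar = genotypes.variants.copy()
    gvar["col"] = np.arange(len(gvar))
    gvar["alt_freq"] = genotypes.alt_freq()
    merged = sumstats.merge(
        gvar,
        left_on=["CHR", "BP"],
        right_on=["chrom", "pos"],
        how="inner",
        suffixes=("", "_g"),
    )
    if merged.empty:
        raise ValueError("no variants overlap between summary statistics and genotypes")

    a1 = merged["A1"].to_numpy()
    a2 = merged["A2"].to_numpy()
    ref = merged["ref"].to_numpy()
    alt = merged["alt"].to_numpy()
    direct = (a1 == alt) & (a2 == ref)
    flipped = (a1 == ref) & (a2 == alt)
    matched = direct | flipped

    palindromic = np.array([(x, y) in PALINDROMIC_PAIRS for x, y in zip(a1, a2)])
    freq = merged["FREQ"].to_numpy(dtype=float)
    ambiguous = palindromic & (freq > 0.4) & (freq < 0.6)
    keep = matched & ~ambiguous

    # Palindromic but frequency-resolvable: orientation chosen so the reported
    # effect-allele frequency is closest to the matching target allele frequency.
    alt_freq = merged["alt_freq"].to_numpy(dtype=float)
    res = palindromic & keep
    as_alt = np.abs(freq - alt_freq) <= np.abs(freq - (1.0 - alt_freq))
    sign = np.where(direct, 1.0, -1.0)
    sign = np.where(res, np.where(as_alt, 1.0, -1.0), sign)

    n_drop = int((~keep).sum())
    if n_drop:
        log.info(
            "harmonize: dropped %d variants (%d allele mismatch, %d ambiguous palindromic)",
            n_drop, int((~matched).sum()), int((matched & ambiguous).sum()),
        )
    out = pd.DataFrame(
        {
            "SNP": merged["id"].to_numpy(),
            "CHR": merged["CHR"].to_numpy(),
            "BP": merged["BP"].to_numpy(),
            "col": merged["col"].to_numpy(),
            "weight": sign * merged["BETA"].to_numpy(dtype=float),
            "P": merged["P"].to_numpy(dtype=float),
        }
    )[keep].reset_index(drop=True)
    return out
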
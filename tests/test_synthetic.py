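"""Generator checks: LD calibration, determinism, architecture of the
planted signal, and serialization round trips."""
import dataclasses

import numpy as np
import pandas as pd
import pytest

from partprs import io as pio
from partprs.synthetic import (
    EffectSpec,
    GenomeSpec,
    draw_effects,
    simulate_annotation,
    simulate_cohort,
    simulate_discovery_sumstats,
    simulate_genotypes,
    simulate_phenotypes,
)


def _flat_genome(**kw) -> GenomeSpec:
    """Single-chromosome genome with LD-free blocks unless overridden."""
    defaults = dict(
        n_chromosomes=1,
        chrom_length_bp=2_000_000,
        block_length_bp=1_000_000,
        snps_per_block=2,
        special_region=("1", 0, 1_000_000),
        r2_adjacent=0.0,
        r2_adjacent_special=0.0,
        seed=5,
    )
    defaults.update(kw)
    return GenomeSpec(**defaults)


class TestGenotypes:
    def test_independent_variants_have_near_zero_r2(self):
        gm = simulate_genotypes(_flat_genome(), 5000)
        r = np.corrcoef(gm.dosages[:, 0], gm.dosages[:, 1])[0, 1]
        assert r**2 < 0.05

    def test_same_seed_reproduces_matrix(self):
        spec = _flat_genome(snps_per_block=5, r2_adjacent=0.3)
        a = simulate_genotypes(spec, 300)
        b = simulate_genotypes(spec, 300)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        pd.testing.assert_frame_equal(a.variants, b.variants)

    def test_adjacent_r2_calibrated_to_target(self):
        spec = _flat_genome(
            chrom_length_bp=4_000_000, snps_per_block=6,
            r2_adjacent=0.8, r2_adjacent_special=0.8, seed=2,
        )
        gm = simulate_genotypes(spec, 5000)
        r2 = []
        for b, sub in gm.variants.groupby("block"):
            cols = sub.index.to_numpy()
            for j in range(len(cols) - 1):
                r2.append(
                    np.corrcoef(gm.dosages[:, cols[j]], gm.dosages[:, cols[j + 1]])[0, 1] ** 2
                )
        assert abs(np.mean(r2) - 0.8) < 0.05

    def test_allele_frequency_matches_spec_maf(self):
        spec = _flat_genome(chrom_length_bp=10_000_000, snps_per_block=6, seed=9)
        gm = simulate_genotypes(spec, 5000)
        err = np.abs(gm.maf() - gm.variants["target_maf"].to_numpy())
        assert err.max() < 0.02

    def test_dosages_are_hard_calls(self):
        gm = simulate_genotypes(_flat_genome(), 200)
        assert set(np.unique(gm.dosages)) <= {0.0, 1.0, 2.0}

    @pytest.mark.parametrize(
        "field,value,message",
        [
            ("snps_per_block", 0, "snps_per_block"),
            ("maf_range", (0.0, 0.5), "maf_range"),
            ("maf_range", (0.1, 0.6), "maf_range"),
            ("special_region", ("9", 0, 1000), "special_region"),
            ("special_region", ("1", 0, 99_000_000), "special_region"),
        ],
    )
    def test_invalid_spec_names_offending_field(self, field, value, message):
        spec = dataclasses.replace(_flat_genome(), **{field: value})
        with pytest.raises(ValueError, match=message):
            simulate_genotypes(spec, 100)


class TestAnnotation:
    def test_genes_lie_within_chromosome_bounds(self, small_genome):
        genes, _ = simulate_annotation(small_genome)
        assert (genes["start"] >= 0).all()
        assert (genes["end"] <= small_genome.chrom_length_bp).all()
        assert (genes["start"] < genes["end"]).all()
        assert genes["strand"].isin(["+", "-"]).all()

    def test_gene_set_nested_in_region_plus_outside(self, small_genome):
        genes, gene_set = simulate_annotation(small_genome)
        chrom, start, end = small_genome.special_region
        sub = genes[genes["gene_id"].isin(gene_set)]
        inside = sub[(sub["chrom"] == chrom) & (sub["start"] >= start) & (sub["end"] <= end)]
        outside = sub[sub["chrom"] != chrom]
        assert len(inside) >= 2
        assert len(outside) >= 1

    def test_gene_set_round_trips_through_reader(self, small_genome, tmp_path):
        genes, gene_set = simulate_annotation(small_genome)
        pio.write_gene_set(gene_set, tmp_path / "set.txt")
        assert pio.read_gene_set(tmp_path / "set.txt") == gene_set
        pio.write_genes_bed(genes, tmp_path / "genes.bed")
        back = pio.read_genes_bed(tmp_path / "genes.bed")
        pd.testing.assert_frame_equal(back, genes.reset_index(drop=True), check_dtype=False)

    def test_region_too_small_for_set_genes_errors(self):
        spec = _flat_genome(chrom_length_bp=8_000_000, special_region=("1", 0, 1_000_000))
        with pytest.raises(ValueError, match="special_region too small"):
            simulate_annotation(spec)


class TestDiscoverySumstats:
    def _null_setup(self, n=2000, seed=7):
        spec = _flat_genome(chrom_length_bp=20_000_000, snps_per_block=6, seed=seed)
        gm = simulate_genotypes(spec, n)
        genes, gene_set = simulate_annotation(
            dataclasses.replace(spec, special_region=("1", 0, 4_000_000))
        )
        eff = EffectSpec(h2_background=0.0, h2_region=0.0)
        te = draw_effects(gm, genes, gene_set, ("1", 0, 4_000_000), eff, seed=seed)
        return gm, eff, te

    def test_null_pvalues_uniform(self):
        gm, eff, te = self._null_setup()
        ss = simulate_discovery_sumstats(gm, eff, te, seed=3)
        frac = (ss["P"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(ss))
        assert abs(frac - 0.05) < 2 * se + 0.02  # LD-free genome, ~120 variants

    def test_single_causal_variant_dominates(self):
        gm, eff, te = self._null_setup()
        te.beta_disorder[:] = 0.0
        te.beta_disorder[17] = 0.3
        ss = simulate_discovery_sumstats(
            gm, dataclasses.replace(eff, n_discovery=10_000_000), te, seed=4
        )
        b_std = np.abs(ss["BETA"].to_numpy() * gm.dosages.std(0))
        assert b_std.argmax() == 17
        assert ss["P"].iloc[17] <= ss["P"].min() * (1 + 1e-12)

    def test_same_seed_gives_byte_identical_tsv(self, tmp_path):
        gm, eff, te = self._null_setup()
        for name in ("a.tsv", "b.tsv"):
            ss = simulate_discovery_sumstats(gm, eff, te, seed=12)
            pio.write_sumstats(ss, tmp_path / name)
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_tiny_discovery_sample_rejected(self):
        gm, eff, te = self._null_setup(n=200)
        with pytest.raises(ValueError, match="n_discovery"):
            simulate_discovery_sumstats(gm, dataclasses.replace(eff, n_discovery=5), te)


class TestPhenotypes:
    def test_null_architecture_orthogonal_to_genotypes(self):
        spec = _flat_genome(chrom_length_bp=10_000_000, snps_per_block=6, seed=21)
        gm = simulate_genotypes(spec, 3000)
        genes, gene_set = simulate_annotation(
            dataclasses.replace(spec, special_region=("1", 0, 4_000_000))
        )
        eff = EffectSpec(h2_background=0.0, h2_region=0.0, covariate_betas=())
        te = draw_effects(gm, genes, gene_set, ("1", 0, 4_000_000), eff, seed=21)
        pheno, _ = simulate_phenotypes(gm, eff, te, n_tracts=1, seed=21)
        y = pheno["CG_axonal_density_L"].to_numpy()
        y = (y - y.mean()) / y.std()
        Z = (gm.dosages - gm.dosages.mean(0)) / gm.dosages.std(0)
        z = (Z.T @ y) / np.sqrt(len(y))
        from scipy import stats

        p = 2 * stats.norm.sf(np.abs(z))
        se = np.sqrt(0.05 * 0.95 / len(p))
        assert abs((p < 0.05).mean() - 0.05) < 2 * se + 0.04

    def test_realized_region_variance_matches_h2(self, small_cohort):
        c = small_cohort
        gm = c.genotypes
        sd = gm.dosages.std(0)
        Z = (gm.dosages - gm.dosages.mean(0)) / np.where(sd > 0, sd, 1.0)
        sel = c.true_effects.causal & c.true_effects.in_region
        g = Z[:, sel] @ c.true_effects.beta_tracts[sel, 0]
        assert abs(g.var() - c.effects.h2_region) < 0.01

    def test_hemispheres_strongly_correlated(self, small_cohort):
        ph = small_cohort.phenotypes
        r = np.corrcoef(ph["CG_axonal_density_L"], ph["CG_axonal_density_R"])[0, 1]
        assert r > 0.9

    def test_invalid_tract_count_rejected(self, small_cohort):
        c = small_cohort
        with pytest.raises(ValueError, match="n_tracts"):
            simulate_phenotypes(c.genotypes, c.effects, c.true_effects, n_tracts=0)


def test_cohort_is_deterministic(small_genome):
    a = simulate_cohort(small_genome, EffectSpec(), n_samples=300, seed=4)
    b = simulate_cohort(small_genome, EffectSpec(), n_samples=300, seed=4)
    np.testing.assert_array_equal(a.genotypes.dosages, b.genotypes.dosages)
    pd.testing.assert_frame_equal(a.sumstats, b.sumstats)
    pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
    pd.testing.assert_frame_equal(a.covariates, b.covariates)
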
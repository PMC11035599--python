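"""Score construction, adjustment/standardization, and series invariants."""
import numpy as np
import pandas as pd
import pytest

from partprs import io as pio
from partprs.clump import ClumpParams
from partprs.containers import GenotypeMatrix
from partprs.partition import build_partition
from partprs.scoring import (
    adjust_and_standardize,
    build_score_series,
    compute_prs,
    gene_score,
    snp_set_score,
)

from conftest import make_genotypes


def _harm(gm, weights, pvals):
    return pd.DataFrame(
        {
            "SNP": gm.variants["id"],
            "CHR": gm.variants["chrom"],
            "BP": gm.variants["pos"],
            "col": np.arange(gm.n_variants),
            "weight": weights,
            "P": pvals,
        }
    )


class TestComputePrs:
    def test_zero_weights_give_zero_scores(self):
        d = np.random.default_rng(0).integers(0, 3, (20, 5)).astype(float)
        gm = make_genotypes(d)
        score, n = compute_prs(_harm(gm, np.zeros(5), np.full(5, 0.5)), gm)
        np.testing.assert_array_equal(score, 0.0)
        assert n == 5

    def test_two_variant_arithmetic(self):
        gm = make_genotypes(np.array([[1.0, 2.0]]))
        score, _ = compute_prs(_harm(gm, np.array([0.1, -0.2]), np.array([0.5, 0.5])), gm)
        assert score[0] == pytest.approx(-0.3)

    def test_threshold_selection_matches_bruteforce_sum(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, (50, 10)).astype(float)
        gm = make_genotypes(d)
        w = rng.normal(size=10)
        p = np.array([1e-5, 1e-4, 5e-4, 9e-4, 2e-3, 0.01, 0.02, 0.1, 0.5, 1.0])
        score, n = compute_prs(_harm(gm, w, p), gm, p_threshold=1e-3)
        keep = p <= 1e-3
        assert n == 4
        np.testing.assert_allclose(score, d[:, keep] @ w[keep])

    def test_empty_selection_yields_missing_column(self):
        gm = make_genotypes(np.ones((10, 2)) * [0, 1])
        score, n = compute_prs(_harm(gm, np.ones(2), np.full(2, 0.5)), gm, p_threshold=1e-9)
        assert n == 0
        assert np.isnan(score).all()


class TestAdjustStandardize:
    def test_zero_covariates_reduce_to_zscore(self):
        rng = np.random.default_rng(2)
        raw = rng.normal(5, 3, size=200)
        cov = pd.DataFrame({"PC1": np.zeros(200)})
        adj = adjust_and_standardize(raw, cov)
        np.testing.assert_allclose(adj, (raw - raw.mean()) / raw.std(), atol=1e-10)

    def test_score_collinear_with_pc_raises_zero_variance(self):
        pc1 = np.random.default_rng(3).normal(size=100)
        cov = pd.DataFrame({"PC1": pc1})
        with pytest.raises(ValueError, match="zero residual variance"):
            adjust_and_standardize(2.0 * pc1 + 1.0, cov)

    def test_collinear_covariates_named(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=100)
        cov = pd.DataFrame({"PC1": x, "PC2": 2 * x})
        with pytest.raises(ValueError, match="PC2"):
            adjust_and_standardize(rng.normal(size=100), cov)

    def test_residuals_match_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        raw = rng.normal(size=150)
        cov = pd.DataFrame(rng.normal(size=(150, 3)), columns=["PC1", "PC2", "array"])
        X = np.column_stack([np.ones(150), cov.to_numpy()])
        beta = np.linalg.solve(X.T @ X, X.T @ raw)
        resid = raw - X @ beta
        expected = (resid - resid.mean()) / resid.std()
        np.testing.assert_allclose(adjust_and_standardize(raw, cov), expected, atol=1e-10)

    def test_adjusted_columns_have_unit_moments(self, small_cohort):
        c = small_cohort
        harm = pio.harmonize(c.sumstats, c.genotypes)
        part = build_partition(c.genotypes, c.genes, {"complement": c.gene_set}, {})
        pcs = c.covariates[[f"PC{k}" for k in range(1, 16)] + ["array"]]
        sm = build_score_series(
            c.genotypes, harm, part, compartments=("genomewide",), covariates=pcs
        )
        for col in sm.adjusted:
            assert sm.adjusted[col].mean() == pytest.approx(0.0, abs=1e-8)
            assert sm.adjusted[col].std(ddof=0) == pytest.approx(1.0, abs=1e-8)


class TestSnpSetScore:
    def _setup(self):
        rng = np.random.default_rng(6)
        d = rng.integers(0, 3, (40, 4)).astype(float)
        gm = make_genotypes(d)
        w = np.array([0.2, -0.3, 0.1, 0.4])
        return gm, _harm(gm, w, np.full(4, 1e-4)), d, w

    def test_allele_count_recodes_negative_weight(self):
        gm, harm, d, _ = self._setup()
        out = snp_set_score(harm, gm, ["s1"], mode="allele_count")
        np.testing.assert_allclose(out, 2.0 - d[:, 1])

    def test_weighted_equals_prs_restricted_to_ids(self):
        gm, harm, d, w = self._setup()
        out = snp_set_score(harm, gm, ["s0", "s2"], mode="weighted")
        np.testing.assert_allclose(out, d[:, [0, 2]] @ w[[0, 2]])

    def test_missing_snp_listed_in_error(self):
        gm, harm, *_ = self._setup()
        with pytest.raises(KeyError, match="nope"):
            snp_set_score(harm, gm, ["s0", "nope"])

    def test_per_gene_scores_add_over_disjoint_genes(self):
        rng = np.random.default_rng(7)
        d = rng.integers(0, 3, (60, 4)).astype(float)
        gm = make_genotypes(d, pos=[100_000, 102_000, 400_000, 402_000])
        genes = pd.DataFrame(
            {
                "gene_id": ["gA", "gB"],
                "chrom": ["1", "1"],
                "start": [95_000, 395_000],
                "end": [105_000, 405_000],
                "strand": ["+", "+"],
            }
        )
        harm = _harm(gm, rng.normal(size=4), np.full(4, 1e-3))
        # genes far enough apart that windows (and clumps) are disjoint
        sa, na = gene_score(gm, harm, genes, "gA", clump_params=ClumpParams(r2_max=1.0))
        sb, nb = gene_score(gm, harm, genes, "gB", clump_params=ClumpParams(r2_max=1.0))
        union_ids = ["s0", "s1", "s2", "s3"]
        total = snp_set_score(harm, gm, union_ids, mode="weighted")
        np.testing.assert_allclose(sa + sb, total)
        assert na == nb == 2


@pytest.fixture(scope="module")
def series(small_cohort):
    c = small_cohort
    harm = pio.harmonize(c.sumstats, c.genotypes)
    part = build_partition(
        c.genotypes, c.genes, {"complement": c.gene_set},
        {"MHC": c.genome.special_region},
    )
    sm = build_score_series(
        c.genotypes, harm, part,
        compartments=("genomewide", "genic", "intergenic", "complement"),
        masks=(None, "MHC"),
    )
    return c, harm, part, sm


class TestScoreSeries:
    def test_snp_counts_monotone_in_threshold(self, series):
        *_, sm = series
        for comp in ("genomewide", "genic", "intergenic", "complement"):
            counts = [sm.snp_counts[f"{comp}@{t:g}"] for t in (1e-5, 1e-4, 1e-3, 0.01, 0.1)]
            assert counts == sorted(counts)

    def test_complement_counts_bounded_by_genic(self, series):
        *_, sm = series
        for t in (1e-5, 1e-4, 1e-3, 0.01, 0.1):
            assert sm.snp_counts[f"complement@{t:g}"] <= sm.snp_counts[f"genic@{t:g}"]

    def test_masking_drops_complement_snps_at_strict_threshold(self, series):
        *_, sm = series
        assert sm.snp_counts["complement-MHC@1e-05"] < sm.snp_counts["complement@1e-05"]

    def test_noop_mask_leaves_column_identical(self, small_cohort):
        c = small_cohort
        harm = pio.harmonize(c.sumstats, c.genotypes)
        part = build_partition(
            c.genotypes, c.genes, {}, {"empty": ("1", 0, 10)}
        )
        sm = build_score_series(
            c.genotypes, harm, part, compartments=("genomewide",), masks=(None, "empty")
        )
        np.testing.assert_allclose(
            sm.raw["genomewide@0.1"], sm.raw["genomewide-empty@0.1"]
        )

    def test_preclump_genic_plus_intergenic_equals_genomewide(self, series):
        c, harm, part, _ = series
        ids = c.genotypes.variants["id"]
        in_harm = set(harm["SNP"])
        n_gw = sum(1 for i in part.indices("genomewide") if ids.iloc[i] in in_harm)
        n_gen = sum(1 for i in part.indices("genic") if ids.iloc[i] in in_harm)
        n_int = sum(1 for i in part.indices("intergenic") if ids.iloc[i] in in_harm)
        assert n_gen + n_int == n_gw

    def test_score_invariant_to_allele_relabelling(self, small_cohort):
        """Swapping ref/alt with dosage recoding 2-g only shifts the raw score
        by a constant, so the standardized score is unchanged."""
        c = small_cohort
        gm = c.genotypes
        flipped = GenotypeMatrix(
            gm.samples,
            gm.variants.assign(ref=gm.variants["alt"], alt=gm.variants["ref"]),
            2.0 - gm.dosages,
        )
        h1 = pio.harmonize(c.sumstats, gm)
        h2 = pio.harmonize(c.sumstats, flipped)
        s1, n1 = compute_prs(h1, gm)
        s2, n2 = compute_prs(h2, flipped)
        assert n1 == n2
        np.testing.assert_allclose(
            adjust_and_standardize(s1), adjust_and_standardize(s2), atol=1e-8
        )
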
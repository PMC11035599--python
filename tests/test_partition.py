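"""QC filters, the Hardy-Weinberg exact test, and compartment labelling."""
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from partprs.partition import (
    annotate_genic,
    apply_region_mask,
    build_partition,
    hwe_exact_test,
    parse_region,
    qc_filter,
)

from conftest import make_genotypes


def hwe_enumeration_oracle(n_AA: int, n_Aa: int, n_aa: int) -> Fraction:
    """Exact-rational HWE p-value by enumerating every genotype configuration
    compatible with the observed allele counts."""
    n = n_AA + n_Aa + n_aa
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if n_minor == 0:
        return Fraction(1)
    configs = []
    for het in range(n_minor % 2, n_minor + 1, 2):
        hom_min = (n_minor - het) // 2
        hom_maj = n - het - hom_min
        if hom_maj < 0:
            continue
        # multinomial arrangements x 2^het haplotype pairings
        weight = Fraction(
            comb(n, hom_min) * comb(n - hom_min, het) * 2**het
        )
        configs.append((het, weight))
    total = sum(w for _, w in configs)
    probs = {h: w / total for h, w in configs}
    obs = probs[n_Aa]
    return sum(p for p in probs.values() if p <= obs)


class TestHWE:
    def test_exact_equilibrium_has_p_one(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0)

    def test_two_individual_case_matches_enumeration(self):
        # n=2, minor count 2: het configs {0, 2} with probs 1/3 and 2/3
        assert hwe_exact_test(1, 0, 1) == pytest.approx(1 / 3)

    def test_monomorphic_returns_one(self):
        assert hwe_exact_test(42, 0, 0) == 1.0

    def test_extreme_heterozygote_excess_fails_threshold(self):
        assert hwe_exact_test(0, 100, 0) < 1e-6

    @given(
        st.integers(0, 15), st.integers(0, 15), st.integers(0, 15)
    )
    @settings(max_examples=200, deadline=None)
    def test_p_in_unit_interval_and_matches_oracle(self, a, h, b):
        if a + h + b == 0:
            return
        p = hwe_exact_test(a, h, b)
        assert 0 < p <= 1
        assert p == pytest.approx(float(hwe_enumeration_oracle(a, h, b)), rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 0, 1)


class TestQC:
    def _gm_with_freq(self, n_AA, n_Aa, n_aa):
        d = np.repeat([0.0, 1.0, 2.0], [n_AA, n_Aa, n_aa])[:, None]
        return make_genotypes(d)

    def test_maf_below_five_percent_fails(self):
        # MAF 0.04 at n=100
        gm = self._gm_with_freq(92, 8, 0)
        assert not qc_filter(gm)[0]

    def test_maf_exactly_five_percent_passes(self):
        gm = self._gm_with_freq(90, 10, 0)
        assert qc_filter(gm)[0]

    def test_monomorphic_fails_without_division_error(self):
        gm = self._gm_with_freq(100, 0, 0)
        assert not qc_filter(gm)[0]

    def test_hwe_violation_fails(self):
        gm = self._gm_with_freq(0, 100, 0)
        assert not qc_filter(gm)[0]


class TestGenicWindows:
    GENES_PLUS = pd.DataFrame(
        {"gene_id": ["g"], "chrom": ["1"], "start": [100_000], "end": [110_000], "strand": ["+"]}
    )
    GENES_MINUS = GENES_PLUS.assign(strand="-")

    def _variants(self, positions):
        return pd.DataFrame(
            {"id": [f"v{i}" for i in range(len(positions))], "chrom": "1", "pos": positions}
        )

    def test_plus_strand_upstream_window(self):
        v = self._variants([65_001, 64_999, 120_000, 120_001])
        flags = annotate_genic(v, self.GENES_PLUS)
        # 34,999 bp upstream in; 35,001 out; 10 kb downstream in; 10,001 out
        assert flags.tolist() == [True, False, True, False]

    def test_minus_strand_flips_window(self):
        v = self._variants([144_999, 145_001, 90_000, 89_999])
        flags = annotate_genic(v, self.GENES_MINUS)
        assert flags.tolist() == [True, False, True, False]

    def test_strand_agnostic_mode_treats_all_as_plus(self):
        v = self._variants([144_999])
        assert not annotate_genic(v, self.GENES_MINUS, strand_aware=False)[0]

    def test_window_enlargement_is_monotone(self, small_cohort):
        v = small_cohort.genotypes.variants
        g = small_cohort.genes
        narrow = annotate_genic(v, g, 35, 10)
        wide = annotate_genic(v, g, 50, 20)
        assert (wide | ~narrow).all()  # narrow set is a subset of wide

    def test_chromosome_without_genes_is_intergenic(self):
        v = pd.DataFrame({"id": ["v0"], "chrom": ["7"], "pos": [100_000]})
        assert not annotate_genic(v, self.GENES_PLUS)[0]


class TestRegionMask:
    def test_half_open_boundaries(self):
        v = pd.DataFrame(
            {"id": ["a", "b"], "chrom": ["6", "6"], "pos": [25_000_000, 35_000_000]}
        )
        flags = apply_region_mask(v, ("6", 25_000_000, 35_000_000))
        assert flags.tolist() == [True, False]

    def test_count_on_fixture(self):
        rng = np.random.default_rng(3)
        pos = np.sort(rng.choice(10_000_000, size=100, replace=False))
        v = pd.DataFrame({"id": [f"v{i}" for i in range(100)], "chrom": "6", "pos": pos})
        region = ("6", 2_000_000, 3_000_000)
        expected = int(((pos >= 2_000_000) & (pos < 3_000_000)).sum())
        assert apply_region_mask(v, region).sum() == expected

    def test_parse_region(self):
        assert parse_region("6:25000000-35000000") == ("6", 25_000_000, 35_000_000)


class TestPartition:
    def test_compartments_partition_qc_passing_variants(self, small_cohort):
        c = small_cohort
        part = build_partition(
            c.genotypes, c.genes, {"complement": c.gene_set},
            {"MHC": c.genome.special_region},
        )
        genic = set(part.indices("genic"))
        intergenic = set(part.indices("intergenic"))
        genomewide = set(part.indices("genomewide"))
        assert genic | intergenic == genomewide
        assert not genic & intergenic

    def test_set_membership_implies_genic(self, small_cohort):
        c = small_cohort
        part = build_partition(c.genotypes, c.genes, {"complement": c.gene_set}, {})
        assert set(part.indices("complement")) <= set(part.indices("genic"))

    def test_mask_exclusion_removes_region_variants(self, small_cohort):
        c = small_cohort
        part = build_partition(
            c.genotypes, c.genes, {}, {"MHC": c.genome.special_region}
        )
        masked = apply_region_mask(c.genotypes.variants, c.genome.special_region)
        kept = part.indices("genomewide", exclude_mask="MHC")
        assert not masked[kept].any()
        assert masked.sum() > 0

    def test_indices_calls_do_not_mutate_state(self, small_cohort):
        c = small_cohort
        part = build_partition(c.genotypes, c.genes, {"complement": c.gene_set}, {})
        before = part.table["qc_pass"].sum()
        part.indices("genic")
        part.indices("intergenic")
        part.indices("complement")
        assert part.table["qc_pass"].sum() == before
        assert len(part.indices("intergenic")) > 0
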
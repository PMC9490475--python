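"""Shared fixtures: small hand-built panels and simulated datasets."""

import numpy as np
import pytest

from haploloop.core_io import GenomicInterval, HaplotypePanel, VariantRecord
from haploloop.haplotype_dosage import load_blk_cs11, load_blk_regions


@pytest.fixture(scope="session")
def blk_cs11():
    return load_blk_cs11()


@pytest.fixture(scope="session")
def blk_regions():
    return load_blk_regions()


@pytest.fixture
def tiny_panel():
    """Three samples, five SNVs, phased by hand (variant maf recomputed)."""
    variants = [
        VariantRecord("v1", "chr8", 100, "A", "G", 0.5),
        VariantRecord("v2", "chr8", 200, "C", "T", 1 / 3),
        VariantRecord("v3", "chr8", 300, "G", "A", 1 / 6),
        VariantRecord("v4", "chr8", 400, "T", "C", 0.5),
        VariantRecord("v5", "chr8", 500, "A", "C", 1 / 3),
    ]
    alleles = np.array(
        [
            [[0, 0, 0, 1, 0], [1, 1, 0, 0, 1]],
            [[1, 0, 1, 1, 0], [0, 0, 0, 0, 0]],
            [[1, 1, 0, 1, 1], [0, 0, 0, 0, 0]],
        ],
        dtype=np.int8,
    )
    return HaplotypePanel(variants, ["s1", "s2", "s3"], alleles)


def build_promoter_panel(credible_set, n_nonrisk, n_risk, n_idio):
    """Deterministic panel whose chromosomes spell exact promoter class counts.

    Chromosome haplotypes are laid out N..N R..R I..I and paired into
    samples in order; the total must be even.  Used as the independent
    construction against which classification counts are checked.
    """
    total = n_nonrisk + n_risk + n_idio
    assert total % 2 == 0
    n_snps = len(credible_set.snps)
    variants = [
        VariantRecord(
            credible_set.snps[k],
            "chr8",
            11_349_000 + 1_000 * k,
            credible_set.nonrisk_haplotype[k],
            credible_set.risk_haplotype[k],
            0.5,
        )
        for k in range(n_snps)
    ]
    chroms = np.zeros((total, n_snps), dtype=np.int8)
    chroms[n_nonrisk : n_nonrisk + n_risk, :] = 1
    for k in range(n_idio):
        # idiosyncratic: non-risk string with one substitution
        chroms[n_nonrisk + n_risk + k, k % n_snps] = 1
    alleles = chroms.reshape(total // 2, 2, n_snps)
    samples = [f"ind{i + 1:04d}" for i in range(total // 2)]
    # recompute per-variant maf for validity
    variants = [
        VariantRecord(
            v.id, v.chrom, v.pos, v.ref, v.alt,
            min(float(alleles[:, :, k].mean()), 1 - float(alleles[:, :, k].mean())),
        )
        for k, v in enumerate(variants)
    ]
    return HaplotypePanel(variants, samples, alleles)


@pytest.fixture(scope="session")
def frequency_panel(blk_cs11):
    """Panel with the reference-cohort promoter class counts 725/243/38."""
    return build_promoter_panel(blk_cs11, 725, 243, 38)
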
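"""Promoter-haplotype classification, enhancer conditioning and risk dosage.

The promoter of *BLK* carries a credible set of tightly linked SNPs over
which essentially all European chromosomes spell one of two haplotypes:
the non-risk string (prom-N) or the risk string (prom-R); the rare
remainder is "idiosyncratic" and dropped from downstream analyses.

Conditioning on the promoter class defines local enhancer haplotypes:
for each enhancer, the modal local string among prom-R chromosomes is
that enhancer's R haplotype and the modal string among prom-N
chromosomes its N haplotype; every other string is labeled A.  Composite
per-chromosome labels over (P, E1, E2, E3) such as "RNRN" combine into
unordered multilocus genotypes per individual ("NNNN/RNRN"), and an
individual's risk dosage is the total count of R labels over both
chromosomes.  Expression is compared between genotype groups with
one-sided t-tests (lower-dosage group expected higher).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GenomicInterval, HaplotypePanel, RegionSet, log_kv, read_regions


class PromoterClass(str, Enum):
    RISK = "Risk"
    NONRISK = "NonRisk"
    IDIOSYNCRATIC = "Idiosyncratic"


@dataclass(frozen=True)
class CredibleSet:
    """An ordered credible-set SNP list with its two reference haplotypes."""

    name: str
    snps: tuple[str, ...]
    risk_haplotype: str
    nonrisk_haplotype: str

    def __post_init__(self) -> None:
        if len(self.risk_haplotype) != len(self.snps) or len(
            self.nonrisk_haplotype
        ) != len(self.snps):
            raise ValueError("haplotype string length must equal the SNP count")
        if self.risk_haplotype == self.nonrisk_haplotype:
            raise ValueError("risk and non-risk haplotypes are identical")


def load_blk_regions() -> RegionSet:
    """Packaged P/E1/E2/E3/REST/R143k region fixture (hg19)."""
    with resources.as_file(
        resources.files("haploloop.data") / "blk_regions.bed"
    ) as path:
        return read_regions(path)


def load_blk_cs11() -> CredibleSet:
    """Packaged BLK-CS-11 credible-set fixture (synthetic SNP ids)."""
    with resources.as_file(
        resources.files("haploloop.data") / "blk_cs11.tsv"
    ) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    df = df.sort_values("order")
    return CredibleSet(
        name="BLK-CS-11",
        snps=tuple(df["snp_id"]),
        risk_haplotype="".join(df["risk_allele"]),
        nonrisk_haplotype="".join(df["nonrisk_allele"]),
    )


def read_credible_set(path, name: str = "credible-set") -> CredibleSet:
    """Read a credible-set TSV (order, snp_id, nonrisk_allele, risk_allele)."""
    df = pd.read_csv(path, sep="\t", comment="#").sort_values("order")
    return CredibleSet(
        name=name,
        snps=tuple(df["snp_id"]),
        risk_haplotype="".join(df["risk_allele"]),
        nonrisk_haplotype="".join(df["nonrisk_allele"]),
    )


def classify_promoter(haplotype: str, credible_set: CredibleSet) -> PromoterClass:
    """Exact-match classification of one promoter haplotype string."""
    if len(haplotype) != len(credible_set.snps):
        raise ValueError(
            f"haplotype length {len(haplotype)} != credible-set size "
            f"{len(credible_set.snps)}"
        )
    if haplotype == credible_set.risk_haplotype:
        return PromoterClass.RISK
    if haplotype == credible_set.nonrisk_haplotype:
        return PromoterClass.NONRISK
    return PromoterClass.IDIOSYNCRATIC


def promoter_classes(
    panel: HaplotypePanel, credible_set: CredibleSet
) -> dict[tuple[int, int], PromoterClass]:
    """Classify every chromosome (sample index, hap index) of a panel."""
    missing = [s for s in credible_set.snps if s not in panel.variant_ids]
    if missing:
        raise ValueError(f"panel is missing credible-set SNPs: {missing}")
    sub = panel.subset(variant_ids=list(credible_set.snps))
    return {
        (s, h): classify_promoter(sub.haplotype_string(s, h), credible_set)
        for s, h in sub.chromosomes()
    }


def haplotype_frequencies(
    panel: HaplotypePanel, credible_set: CredibleSet
) -> pd.DataFrame:
    """Count promoter classes over all 2n chromosomes.

    Returns a table with raw counts, fractions, and integer percentages
    (nearest-integer rounding, the convention used for reporting).
    """
    classes = promoter_classes(panel, credible_set)
    counts = Counter(classes.values())
    total = 2 * panel.n_samples
    rows = []
    for cls in PromoterClass:
        c = counts.get(cls, 0)
        rows.append((cls.value, c, c / total, round(100 * c / total)))
    df = pd.DataFrame(rows, columns=["class", "count", "fraction", "percent"])
    log_kv(
        "promoter_frequencies",
        **{r["class"]: int(r["count"]) for _, r in df.iterrows()},
    )
    return df


def _modal_string(strings: Sequence[str], context: str) -> str:
    """Most frequent string; ties broken lexicographically (logged)."""
    if not strings:
        raise ValueError(f"empty conditioning class for {context}")
    counts = Counter(strings)
    best = max(counts.values())
    tied = sorted(s for s, c in counts.items() if c == best)
    if len(tied) > 1:
        log_kv("modal_haplotype_tie", context=context, tied=len(tied), chosen=tied[0])
    return tied[0]


def condition_enhancer_labels(
    panel: HaplotypePanel,
    prom_classes: Mapping[tuple[int, int], PromoterClass],
    enhancer_regions: Sequence[GenomicInterval],
) -> tuple[pd.DataFrame, dict[str, dict[str, str]]]:
    """Define per-enhancer N/R strings by promoter conditioning and label chromosomes.

    Idiosyncratic-promoter chromosomes are excluded.  For each enhancer
    region the modal local string among prom-R chromosomes defines that
    enhancer's R haplotype and the modal string among prom-N chromosomes
    its N haplotype; a degenerate conditioning (identical modal strings)
    is a hard error.  Returns the per-chromosome label table and the
    defining strings per enhancer.
    """
    kept = [
        ch
        for ch, cls in prom_classes.items()
        if cls is not PromoterClass.IDIOSYNCRATIC
    ]
    r_chroms = [ch for ch in kept if prom_classes[ch] is PromoterClass.RISK]
    n_chroms = [ch for ch in kept if prom_classes[ch] is PromoterClass.NONRISK]
    definitions: dict[str, dict[str, str]] = {}
    rows = []
    for region in enhancer_regions:
        sub = panel.subset(region=region)
        if sub.n_variants == 0:
            raise ValueError(f"no panel SNPs in enhancer region {region.name}")
        strings = {ch: sub.haplotype_string(*ch) for ch in kept}
        r_def = _modal_string([strings[ch] for ch in r_chroms], f"{region.name}-R")
        n_def = _modal_string([strings[ch] for ch in n_chroms], f"{region.name}-N")
        if r_def == n_def:
            raise ValueError(
                f"degenerate conditioning at {region.name}: "
                "modal R and N haplotypes coincide"
            )
        definitions[region.name] = {"N": n_def, "R": r_def}
        for (s, h), string in strings.items():
            label = "R" if string == r_def else "N" if string == n_def else "A"
            rows.append((s, h, region.name, label))
    labels = pd.DataFrame(rows, columns=["sample", "hap", "region", "label"])
    return labels, definitions


def composite_haplotypes(
    prom_classes: Mapping[tuple[int, int], PromoterClass],
    enhancer_labels: pd.DataFrame,
    region_order: Sequence[str],
) -> dict[tuple[int, int], str]:
    """Per-chromosome composite label strings, e.g. "RNRN" over (P, E1, E2, E3).

    The first region in ``region_order`` is the promoter (label R or N);
    idiosyncratic-promoter chromosomes are excluded.
    """
    prom_label = {
        PromoterClass.RISK: "R",
        PromoterClass.NONRISK: "N",
    }
    by_chrom = {
        (s, h): dict(zip(grp["region"], grp["label"]))
        for (s, h), grp in enhancer_labels.groupby(["sample", "hap"])
    }
    out = {}
    for ch, cls in prom_classes.items():
        if cls is PromoterClass.IDIOSYNCRATIC:
            continue
        labels = [prom_label[cls]]
        for region in region_order[1:]:
            labels.append(by_chrom.get(ch, {}).get(region, "A"))
        out[ch] = "".join(labels)
    return out


def multilocus_genotypes(
    composite: Mapping[tuple[int, int], str],
    n_samples: int,
    projection: Sequence[int] | None = None,
) -> dict[int, str]:
    """Canonical unordered genotype per sample, e.g. "NNNN/RNRN".

    ``projection`` selects label positions (e.g. (0, 3) for the
    promoter-E3 pair).  Samples with either chromosome excluded upstream
    (idiosyncratic promoter) are omitted.
    """
    out = {}
    for s in range(n_samples):
        if (s, 0) not in composite or (s, 1) not in composite:
            continue
        h0, h1 = composite[(s, 0)], composite[(s, 1)]
        if projection is not None:
            h0 = "".join(h0[k] for k in projection)
            h1 = "".join(h1[k] for k in projection)
        out[s] = "/".join(sorted([h0, h1]))
    return out


@dataclass
class DosageResult:
    """Group summaries, contrast tests and per-sample risk dosage."""

    groups: pd.DataFrame
    contrasts: pd.DataFrame
    risk_dosage: pd.Series
    dosage_groups: pd.DataFrame
    group_of: pd.Series = field(repr=False, default=None)


def risk_dosage_analysis(
    genotypes: Mapping[str, str],
    expression: Mapping[str, float] | pd.Series,
    contrasts: Sequence[tuple[str, str]] = (),
    equal_var: bool = False,
) -> DosageResult:
    """Compare expression between multilocus genotype groups.

    ``genotypes`` maps sample id -> canonical genotype string;
    ``contrasts`` lists (lower-dosage group, higher-dosage group) pairs,
    tested one-sided with the alternative that the lower-dosage group has
    the higher mean (risk haplotypes lower expression).  Welch's t-test
    by default; set ``equal_var`` for the classical pooled test.
    Contrasts with a group of fewer than two samples are skipped with a
    warning.
    """
    expr = pd.Series(expression, dtype=float)
    common = [s for s in genotypes if s in expr.index]
    group_of = pd.Series({s: genotypes[s] for s in common})
    dosage = pd.Series({s: genotypes[s].count("R") for s in common})

    rows = []
    for group, members in sorted(group_of.groupby(group_of).groups.items()):
        vals = expr.loc[list(members)]
        rows.append(
            (
                group,
                len(vals),
                float(vals.mean()),
                float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                float(vals.median()),
            )
        )
    groups = pd.DataFrame(rows, columns=["group", "n", "mean", "sd", "median"])

    crows = []
    for low, high in contrasts:
        a = expr.loc[group_of.index[group_of == low]]
        b = expr.loc[group_of.index[group_of == high]]
        if len(a) < 2 or len(b) < 2:
            log_kv("contrast_skipped", low=low, high=high, n_low=len(a), n_high=len(b))
            continue
        t, p = stats.ttest_ind(
            a, b, equal_var=equal_var, alternative="greater"
        )
        crows.append((low, high, len(a), len(b), float(t), float(p)))
    contrasts_df = pd.DataFrame(
        crows, columns=["group_low", "group_high", "n_low", "n_high", "t", "p_one_sided"]
    )

    drows = []
    for level in sorted(dosage.unique()):
        vals = expr.loc[dosage.index[dosage == level]]
        drows.append((int(level), len(vals), float(vals.mean()), float(vals.median())))
    dosage_groups = pd.DataFrame(drows, columns=["risk_dosage", "n", "mean", "median"])

    return DosageResult(groups, contrasts_df, dosage, dosage_groups, group_of)


def relabel_a_as_n(genotypes: Mapping[str, str]) -> dict[str, str]:
    """Robustness re-labeling: treat alternative (A) local haplotypes as N."""
    out = {}
    for s, g in genotypes.items():
        h0, h1 = g.split("/")
        out[s] = "/".join(sorted([h0.replace("A", "N"), h1.replace("A", "N")]))
    return out
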
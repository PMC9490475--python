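"""Seeded generators emulating the inputs of the locus analyses.

Four generators cover the four data modalities the pipeline consumes:

* :func:`simulate_panel` — a diploid phased SNP panel dominated by two
  promoter haplotypes ("N" non-risk, "R" risk) with local enhancer
  haplotypes in tunable LD with the promoter, plus a per-chromosome truth
  table of region labels.
* :func:`simulate_expression` — per-sample expression with additive
  per-region effects of each R haplotype copy and optional pairwise
  SNP x SNP interaction terms.
* :func:`simulate_hic` — replicate allelic contact matrices with a
  power-law distance decay and planted haplotype-specific loops,
  optionally expanded into allele-labeled read-pair records.
* :func:`simulate_qpcr` — a TaqMan-style allelic standard curve (known
  mixes of the two homozygous genotypes) plus input/ChIP measurements at
  planted true allelic fractions.

Every generator takes an explicit integer seed and is fully deterministic
given its spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .core_io import (
    GenomicInterval,
    HaplotypePanel,
    PairRecord,
    VariantRecord,
    log_kv,
)
from .allelic_hic import PARENT1, PARENT2, AllelicContactSet

# Published promoter haplotype strings over the 11 credible-set SNPs;
# used to spell ref/alt bases of a simulated 11-SNP promoter region so
# that synthetic panels are classifiable against the real credible set.
PROMOTER_NONRISK = "TGTACCGGGTG"
PROMOTER_RISK = "CCCCTTAAACA"

#: hg19 windows used to place simulated SNPs (1-based inclusive).
#: X1/X2 are intergenic filler windows inside the 143 kb scan region,
#: outside every regulatory element, for simulating non-GRE variants.
DEFAULT_REGION_COORDS = {
    "P": ("chr8", 11_348_001, 11_361_000),
    "E1": ("chr8", 11_387_781, 11_392_710),
    "E2": ("chr8", 11_393_832, 11_397_791),
    "E3": ("chr8", 11_402_260, 11_405_263),
    "X1": ("chr8", 11_362_000, 11_386_000),
    "X2": ("chr8", 11_406_000, 11_460_000),
}

_BASES = ("A", "C", "G", "T")


# ---------------------------------------------------------------------------
# Phased panel
# ---------------------------------------------------------------------------

@dataclass
class PanelSpec:
    """Layout and haplotype-frequency structure of a simulated panel.

    Defaults emulate the European reference panel the locus analyses used:
    503 diploid individuals; 11 promoter SNPs plus 24/13/8 enhancer SNPs;
    promoter haplotype frequencies 72% N / 24% R with the remaining 4%
    idiosyncratic; enhancer haplotypes partially coupled to the promoter
    so that the R-conditional enhancer frequencies land near the observed
    87% / 85% / 54%.
    """

    seed: int
    n_individuals: int = 503
    region_layout: tuple[tuple[str, int], ...] = (
        ("P", 11),
        ("E1", 24),
        ("E2", 13),
        ("E3", 8),
    )
    main_haplotype_freqs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "P": {"N": 0.72, "R": 0.24},
            "E1": {"N": 0.55, "R": 0.40},
            "E2": {"N": 0.60, "R": 0.35},
            "E3": {"N": 0.55, "R": 0.25},
        }
    )
    ld_coupling: float = 0.55

    def __post_init__(self) -> None:
        if not 0.0 <= self.ld_coupling <= 1.0:
            raise ValueError("ld_coupling must be in [0, 1]")
        for name, n_snps in self.region_layout:
            if n_snps <= 0:
                raise ValueError(f"region {name} has no SNPs")
        for name, freqs in self.main_haplotype_freqs.items():
            fn, fr = freqs.get("N", 0.0), freqs.get("R", 0.0)
            if not (0 <= fn <= 1 and 0 <= fr <= 1 and fn + fr <= 1):
                raise ValueError(f"invalid N/R frequencies for region {name}")


def _region_positions(name: str, n_snps: int, cursor: int) -> tuple[str, list[int], int]:
    """Deterministic, evenly spaced SNP positions for one region."""
    if name in DEFAULT_REGION_COORDS:
        chrom, start, end = DEFAULT_REGION_COORDS[name]
    else:
        chrom, start, end = "chr8", cursor, cursor + 5_000 * max(n_snps, 1) - 1
        cursor = end + 5_000
    step = max((end - start) // (n_snps + 1), 1)
    positions = [start + (k + 1) * step for k in range(n_snps)]
    return chrom, positions, cursor


def simulate_panel(spec: PanelSpec) -> tuple[HaplotypePanel, pd.DataFrame]:
    """Draw a phased diploid panel plus its per-chromosome truth table.

    For each chromosome the promoter local haplotype is drawn from
    {N, R, idiosyncratic}; each enhancer copies the promoter's N/R label
    with probability ``ld_coupling`` and is otherwise drawn independently
    from its own frequencies.  Idiosyncratic local haplotypes are the N
    string with one random substitution (label "A" in the truth table).
    """
    rng = np.random.default_rng(spec.seed)
    n_chrom = 2 * spec.n_individuals

    # per-region reference strings (allele codes): R is the complement of N
    region_n_string: dict[str, np.ndarray] = {}
    variants: list[VariantRecord] = []
    region_slices: dict[str, slice] = {}
    cursor = 11_480_000
    col = 0
    for name, n_snps in spec.region_layout:
        chrom, positions, cursor = _region_positions(name, n_snps, cursor)
        n_vec = rng.integers(0, 2, size=n_snps).astype(np.int8)
        region_n_string[name] = n_vec
        for k, pos in enumerate(positions):
            if name == "P" and n_snps == len(PROMOTER_NONRISK):
                # spell ref/alt (and ids) so code strings map onto the
                # published credible-set promoter haplotype spellings
                n_base = PROMOTER_NONRISK[k]
                r_base = PROMOTER_RISK[k]
                vid = f"cs11_{k + 1:02d}"
            else:
                n_base, r_base = rng.choice(_BASES, size=2, replace=False)
                vid = f"{name.lower()}_snp{k + 1:02d}"
            ref, alt = (n_base, r_base) if n_vec[k] == 0 else (r_base, n_base)
            variants.append(VariantRecord(vid, chrom, pos, ref, alt, 0.5))
        region_slices[name] = slice(col, col + n_snps)
        col += n_snps

    region_names = [name for name, _ in spec.region_layout]
    n_variants = col
    alleles = np.zeros((spec.n_individuals, 2, n_variants), dtype=np.int8)
    truth_rows: list[tuple[int, int, str, str]] = []

    def draw_label(region: str) -> str:
        freqs = spec.main_haplotype_freqs.get(region, {"N": 1.0, "R": 0.0})
        u = rng.random()
        if u < freqs.get("N", 0.0):
            return "N"
        if u < freqs.get("N", 0.0) + freqs.get("R", 0.0):
            return "R"
        return "A"

    def local_codes(region: str, label: str) -> np.ndarray:
        n_vec = region_n_string[region]
        if label == "N":
            return n_vec
        if label == "R":
            return 1 - n_vec
        idio = n_vec.copy()
        flip = rng.integers(0, len(idio))
        idio[flip] = 1 - idio[flip]
        return idio

    promoter = region_names[0]
    for s in range(spec.n_individuals):
        for h in (0, 1):
            prom_label = draw_label(promoter)
            labels = {promoter: prom_label}
            for region in region_names[1:]:
                if prom_label in ("N", "R") and rng.random() < spec.ld_coupling:
                    labels[region] = prom_label
                else:
                    labels[region] = draw_label(region)
            for region in region_names:
                alleles[s, h, region_slices[region]] = local_codes(
                    region, labels[region]
                )
                truth_rows.append((s, h, region, labels[region]))

    samples = [f"sim{s + 1:04d}" for s in range(spec.n_individuals)]
    # recompute per-variant MAF from the realized panel
    final_variants = []
    for i, v in enumerate(variants):
        p_alt = float(alleles[:, :, i].mean())
        final_variants.append(
            VariantRecord(v.id, v.chrom, v.pos, v.ref, v.alt, min(p_alt, 1 - p_alt))
        )
    panel = HaplotypePanel(final_variants, samples, alleles)
    truth = pd.DataFrame(truth_rows, columns=["sample", "hap", "region", "label"])
    truth["sample_id"] = truth["sample"].map(lambda s: samples[s])
    log_kv(
        "panel_simulated",
        n_individuals=spec.n_individuals,
        n_variants=n_variants,
        seed=spec.seed,
    )
    return panel, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSpec:
    """Additive risk-dosage expression model with optional interactions.

    y_s = mu + sum_regions beta_region * (#R copies of the region in s)
        + sum_(v1,v2) gamma * x1 * x2 + Normal(0, sigma^2),

    with x the 0/1/2 alt-allele genotype codes.  Defaults emulate an
    expression cohort of 344 individuals with each risk haplotype copy
    lowering expression.
    """

    seed: int
    mu: float = 10.0
    beta: Mapping[str, float] = field(
        default_factory=lambda: {"P": -0.8, "E1": -0.3, "E2": -0.3, "E3": -0.4}
    )
    gamma: Mapping[tuple[str, str], float] = field(default_factory=dict)
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def risk_copies(truth: pd.DataFrame) -> pd.DataFrame:
    """Per-sample count of R-labeled chromosomes per region (0/1/2)."""
    t = truth.assign(is_r=(truth["label"] == "R").astype(int))
    return (
        t.pivot_table(
            index="sample_id", columns="region", values="is_r", aggfunc="sum"
        )
        .fillna(0)
        .astype(int)
    )


def simulate_expression(
    truth: pd.DataFrame,
    spec: ExpressionSpec,
    panel: HaplotypePanel | None = None,
) -> pd.DataFrame:
    """Simulate the per-sample expression table (columns sample, expression)."""
    rng = np.random.default_rng(spec.seed)
    copies = risk_copies(truth)
    unknown = set(spec.beta) - set(copies.columns)
    if unknown:
        raise ValueError(f"beta names unknown regions: {sorted(unknown)}")
    y = pd.Series(spec.mu, index=copies.index, dtype=float)
    for region, b in spec.beta.items():
        y = y + b * copies[region]
    if spec.gamma:
        if panel is None:
            raise ValueError("interaction terms require the panel")
        order = [panel.samples.index(s) for s in copies.index]
        for (v1, v2), g in spec.gamma.items():
            x1 = panel.genotype_codes(v1)[order]
            x2 = panel.genotype_codes(v2)[order]
            y = y + g * x1 * x2
    y = y + rng.normal(0.0, spec.sigma, size=len(y))
    out = pd.DataFrame({"sample": y.index, "expression": y.values})
    log_kv("expression_simulated", n_samples=len(out), seed=spec.seed)
    return out


# ---------------------------------------------------------------------------
# Allelic Hi-C
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedLoop:
    bin_i: int
    bin_j: int
    haplotype: str  # parent1 | parent2
    log2_fold_change: float


@dataclass
class HicSimSpec:
    """Replicate allelic contact matrices with planted differential loops.

    Expected count for bin pair (i, j) on haplotype h is

        baseline * (|i-j| * resolution + resolution)^(-alpha) * 2^lfc

    with lfc nonzero only for loops planted on h.  Replicate counts are
    negative binomial around that mean (Poisson when ``nb_dispersion`` is
    0).  When expanded to read pairs, each end carries its true parental
    label with probability ``informative_rate`` and UA otherwise.
    """

    seed: int
    window: GenomicInterval = field(
        default_factory=lambda: GenomicInterval("chr8", 11_331_001, 11_406_000)
    )
    resolution: int = 5_000
    alpha: float = 1.0
    baseline: float = 1.0e6
    planted_loops: tuple[PlantedLoop, ...] = ()
    n_replicates: int = 4
    nb_dispersion: float = 0.05
    informative_rate: float = 0.3

    def __post_init__(self) -> None:
        if self.window.length < self.resolution:
            raise ValueError("window shorter than one bin")
        if self.alpha <= 0:
            raise ValueError("decay exponent alpha must be > 0")
        if not 0.0 <= self.informative_rate <= 1.0:
            raise ValueError("informative_rate must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        n_bins = self.window.length // self.resolution
        for loop in self.planted_loops:
            if not (0 <= loop.bin_i < n_bins and 0 <= loop.bin_j < n_bins):
                raise ValueError(f"planted loop {loop} outside the window")
            if loop.haplotype not in (PARENT1, PARENT2):
                raise ValueError(f"unknown haplotype {loop.haplotype!r}")
            if not np.isfinite(loop.log2_fold_change):
                raise ValueError("fold change must be finite")


def expected_count(spec: HicSimSpec, i: int, j: int, haplotype: str) -> float:
    """Analytic mean count for one bin pair on one parental haplotype."""
    d = abs(i - j) * spec.resolution + spec.resolution
    mean = spec.baseline * d ** (-spec.alpha)
    for loop in spec.planted_loops:
        bi, bj = sorted((loop.bin_i, loop.bin_j))
        if (bi, bj) == tuple(sorted((i, j))) and loop.haplotype == haplotype:
            mean *= 2.0 ** loop.log2_fold_change
    return mean


def _draw_counts(rng: np.random.Generator, mean: float, dispersion: float, size: int):
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    if dispersion == 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_contacts(spec: HicSimSpec) -> AllelicContactSet:
    """Draw the per-replicate parental count matrices (truth, no labeling noise)."""
    rng = np.random.default_rng(spec.seed)
    n_bins = spec.window.length // spec.resolution
    cs = AllelicContactSet(resolution=spec.resolution, window=spec.window)
    for i in range(n_bins):
        for j in range(i, n_bins):
            for hap in (PARENT1, PARENT2):
                mean = expected_count(spec, i, j, hap)
                counts = _draw_counts(rng, mean, spec.nb_dispersion, spec.n_replicates)
                for r, c in enumerate(counts):
                    if c > 0:
                        cs.add(f"rep{r + 1}", hap, i, j, int(c))
    log_kv("contacts_simulated", n_bins=n_bins, seed=spec.seed)
    return cs


def expand_to_pairs(
    cs: AllelicContactSet, spec: HicSimSpec
) -> Iterator[PairRecord]:
    """Expand truth matrices into allele-labeled read-pair records.

    The haplotype of origin determines the true end label (M for parent1,
    P for parent2); each end keeps it with probability ``informative_rate``
    and reads UA otherwise.  Positions are drawn uniformly within bins
    using a child RNG so pair expansion does not perturb count draws.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    true_label = {PARENT1: "M", PARENT2: "P"}
    n = 0
    for (rep, hap), mat in sorted(cs.matrices.items()):
        for (i, j), count in sorted(mat.items()):
            lo1, hi1 = cs.bin_interval(i)
            lo2, hi2 = cs.bin_interval(j)
            for _ in range(count):
                pos1 = int(rng.integers(lo1, hi1 + 1))
                pos2 = int(rng.integers(lo2, hi2 + 1))
                l1 = true_label[hap] if rng.random() < spec.informative_rate else "UA"
                l2 = true_label[hap] if rng.random() < spec.informative_rate else "UA"
                n += 1
                yield PairRecord(
                    f"pair{n:08d}",
                    cs.window.chrom,
                    pos1,
                    l1,
                    cs.window.chrom,
                    pos2,
                    l2,
                    rep,
                )


def simulate_hic(spec: HicSimSpec) -> tuple[AllelicContactSet, list[PairRecord], pd.DataFrame]:
    """Full Hi-C simulation: truth matrices, read pairs, planted-loop table."""
    cs = simulate_contacts(spec)
    pairs = list(expand_to_pairs(cs, spec))
    loops = pd.DataFrame(
        [
            (l.bin_i, l.bin_j, l.haplotype, l.log2_fold_change)
            for l in spec.planted_loops
        ],
        columns=["bin_i", "bin_j", "haplotype", "log2_fold_change"],
    )
    return cs, pairs, loops


# ---------------------------------------------------------------------------
# Allelic qPCR
# ---------------------------------------------------------------------------

@dataclass
class QpcrSpec:
    """Allelic TaqMan standard curve plus input/ChIP measurements.

    Known mixes of the two homozygous genotypes at the stated non-risk
    fractions give measured log2(VIC/FAM) = slope * log2(f/(1-f)) +
    intercept + noise; the planted true input/ChIP fractions default to
    the observed ~57.5% / ~92% non-risk signal.
    """

    seed: int
    true_frac_input: float = 0.575
    true_frac_chip: float = 0.92
    slope: float = 1.0
    intercept: float = 0.0
    noise_sd: float = 0.05
    mix_fractions: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    n_replicates: int = 3

    def __post_init__(self) -> None:
        for f in (self.true_frac_input, self.true_frac_chip, *self.mix_fractions):
            if not 0.0 < f < 1.0:
                raise ValueError(f"fraction {f} outside the open interval (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _measured_log2_ratio(spec: QpcrSpec, frac: float, rng) -> float:
    logodds = np.log2(frac / (1.0 - frac))
    return spec.slope * logodds + spec.intercept + rng.normal(0.0, spec.noise_sd)


def simulate_qpcr(spec: QpcrSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Returns (standard-curve table, measurement table).

    Standards: one row per known mix with columns ``frac_nonrisk`` and
    ``log2_vic_fam``.  Measurements: ``n_replicates`` rows per sample type
    ("input", "chip") with the measured log2 VIC/FAM ratio.
    """
    rng = np.random.default_rng(spec.seed)
    standards = pd.DataFrame(
        {
            "frac_nonrisk": spec.mix_fractions,
            "log2_vic_fam": [
                _measured_log2_ratio(spec, f, rng) for f in spec.mix_fractions
            ],
        }
    )
    rows = []
    for sample_type, frac in (
        ("input", spec.true_frac_input),
        ("chip", spec.true_frac_chip),
    ):
        for r in range(spec.n_replicates):
            rows.append(
                (sample_type, r + 1, _measured_log2_ratio(spec, frac, rng))
            )
    measurements = pd.DataFrame(
        rows, columns=["sample_type", "replicate", "log2_vic_fam"]
    )
    log_kv("qpcr_simulated", n_mixes=len(spec.mix_fractions), seed=spec.seed)
    return standards, measurements
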
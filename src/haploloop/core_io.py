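"""Domain types and readers/writers for the external file formats.

The package works in 1-based, fully inclusive genomic coordinates, the
convention in which locus coordinates are usually printed (e.g. the E3
enhancer at chr8:11,402,260-11,405,263 on hg19).  BED input, which is
0-based half-open, is converted at the boundary and never used internally.

Formats handled here:

* phased VCF (via :mod:`cyvcf2`) -> :class:`HaplotypePanel`
* BED3/BED4(+role) -> :class:`RegionSet`
* allele-labeled Hi-C read-pair TSV -> stream of :class:`PairRecord`
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger("haploloop")

PAIR_LABELS = frozenset({"M", "P", "UA"})

REGION_ROLES = frozenset(
    {"promoter", "enhancer", "repressor_site", "scan_window", "capture_window"}
)

#: role guessed from a region name when the BED file carries no role column
_ROLE_BY_NAME = {
    "P": "promoter",
    "REST": "repressor_site",
    "R143k": "scan_window",
    "SCAN": "scan_window",
    "CAPTURE": "capture_window",
}


def log_kv(event: str, **kv) -> None:
    """Emit one structured key=value log line (stderr via logging)."""
    parts = [f"event={event}"] + [f"{k}={v}" for k, v in kv.items()]
    logger.info(" ".join(parts))


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"interval end {self.end} < start {self.start} ({self.name or self.chrom})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def to_bed_fields(self) -> list[str]:
        """Back-convert to 0-based half-open BED fields."""
        fields = [self.chrom, str(self.start - 1), str(self.end)]
        if self.name is not None:
            fields.append(self.name)
        return fields


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNV with its panel minor allele frequency."""

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    maf: float

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.id}: ref equals alt ({self.ref})")
        if self.pos < 1:
            raise ValueError(f"{self.id}: pos must be >= 1")
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.id}: maf {self.maf} outside [0, 0.5]")


@dataclass
class HaplotypePanel:
    """Phase-resolved alleles for a set of samples over ordered SNVs.

    ``alleles`` has shape ``(n_samples, 2, n_variants)`` with entries in
    {0, 1}; index 1 along axis 1 is the second haplotype of the phased
    genotype (``a|b`` in VCF order).
    """

    variants: list[VariantRecord]
    samples: list[str]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        expected = (len(self.samples), 2, len(self.variants))
        if self.alleles.shape != expected:
            raise ValueError(
                f"allele array shape {self.alleles.shape} != {expected}"
            )
        if self.alleles.size and not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("allele codes must be 0 or 1")
        pos = [v.pos for v in self.variants]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("variants must be strictly increasing by position")

    # -- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def variant_index(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"variant {variant_id!r} not in panel") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypePanel):
            return NotImplemented
        return (
            self.variants == other.variants
            and self.samples == other.samples
            and np.array_equal(self.alleles, other.alleles)
        )

    # -- views ---------------------------------------------------------------
    def subset(
        self,
        region: GenomicInterval | None = None,
        variant_ids: Sequence[str] | None = None,
    ) -> "HaplotypePanel":
        """Panel restricted to a region or an explicit (ordered) SNP list."""
        if variant_ids is not None:
            idx = [self.variant_index(v) for v in variant_ids]
            if sorted(idx) != idx:
                raise ValueError("requested variant order must follow position order")
        else:
            idx = [
                i
                for i, v in enumerate(self.variants)
                if region is None or region.contains(v.chrom, v.pos)
            ]
        return HaplotypePanel(
            variants=[self.variants[i] for i in idx],
            samples=list(self.samples),
            alleles=self.alleles[:, :, idx],
        )

    def haplotype_codes(self, sample: int, hap: int) -> np.ndarray:
        return self.alleles[sample, hap, :]

    def haplotype_string(self, sample: int, hap: int) -> str:
        """Nucleotide spelling of one haplotype (ref base for 0, alt for 1)."""
        codes = self.alleles[sample, hap, :]
        return "".join(
            v.alt if c else v.ref for v, c in zip(self.variants, codes)
        )

    def chromosomes(self) -> Iterator[tuple[str, int]]:
        """All (sample, hap) chromosome identifiers, file order."""
        for s in range(self.n_samples):
            yield s, 0
            yield s, 1

    def genotype_codes(self, variant_id: str) -> np.ndarray:
        """0/1/2 alt-allele counts per sample for one SNP."""
        i = self.variant_index(variant_id)
        return self.alleles[:, :, i].sum(axis=1).astype(np.int64)

    def alt_frequency(self, i: int) -> float:
        return float(self.alleles[:, :, i].mean())


@dataclass
class RegionSet:
    """Named regulatory/scan intervals with their roles."""

    regions: list[GenomicInterval]
    roles: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions if r.name is not None]
        if len(names) != len(set(names)):
            raise ValueError("region names must be unique")
        for role in self.roles.values():
            if role is not None and role not in REGION_ROLES:
                raise ValueError(f"unknown region role {role!r}")
        core = [
            r
            for r in self.regions
            if self.roles.get(r.name) in ("promoter", "enhancer")
        ]
        for a in range(len(core)):
            for b in range(a + 1, len(core)):
                if core[a].overlaps(core[b]):
                    raise ValueError(
                        f"promoter/enhancer regions overlap: {core[a].name}, {core[b].name}"
                    )

    def get(self, name: str) -> GenomicInterval:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(f"no region named {name!r}")

    def by_role(self, role: str) -> list[GenomicInterval]:
        return [r for r in self.regions if self.roles.get(r.name) == role]

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.regions)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_phased_vcf(
    path: str | Path,
    region: GenomicInterval | None = None,
    maf_min: float = 0.0,
) -> HaplotypePanel:
    """Load a phased VCF into a :class:`HaplotypePanel`.

    Only biallelic SNVs are retained; multiallelic or non-SNV records are
    skipped with a warning.  An unphased genotype is a hard error: phase is
    the substance of every downstream analysis.  Variants are filtered to
    ``region`` (if given) and to minor allele frequency >= ``maf_min``,
    with MAF computed from the loaded samples.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[tuple[str, str, int, str, str]] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            log_kv("vcf_skip_multiallelic", id=rec.ID or f"{rec.CHROM}:{rec.POS}")
            n_skipped += 1
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            log_kv("vcf_skip_non_snv", id=rec.ID or f"{rec.CHROM}:{rec.POS}")
            n_skipped += 1
            continue
        if region is not None and not region.contains(rec.CHROM, rec.POS):
            continue
        col = np.empty((len(samples), 2), dtype=np.int8)
        for s, gt in enumerate(rec.genotypes):
            a, b, phased = gt[0], gt[1], gt[-1]
            if not phased:
                raise ValueError(
                    f"unphased genotype for sample {samples[s]} at record "
                    f"{rec.ID or ''} {rec.CHROM}:{rec.POS}"
                )
            if a < 0 or b < 0:
                raise ValueError(
                    f"missing genotype at {rec.CHROM}:{rec.POS} sample {samples[s]}"
                )
            col[s, 0], col[s, 1] = a, b
        vid = rec.ID or f"{rec.CHROM}_{rec.POS}"
        variants.append((vid, rec.CHROM, rec.POS, ref, alt))
        columns.append(col)

    if columns:
        alleles = np.stack(columns, axis=2)
    else:
        alleles = np.zeros((len(samples), 2, 0), dtype=np.int8)

    keep: list[int] = []
    records: list[VariantRecord] = []
    for i, (vid, chrom, pos, ref, alt) in enumerate(variants):
        p_alt = float(alleles[:, :, i].mean()) if len(samples) else 0.0
        maf = min(p_alt, 1.0 - p_alt)
        if maf < maf_min:
            continue
        keep.append(i)
        records.append(VariantRecord(vid, chrom, pos, ref, alt, maf))
    log_kv(
        "vcf_loaded",
        path=str(path),
        n_samples=len(samples),
        n_variants=len(records),
        n_skipped=n_skipped,
    )
    return HaplotypePanel(records, samples, alleles[:, :, keep])


def write_phased_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a minimal deterministic phased VCF (v4.2, GT only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=haploloop\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        contigs = sorted({v.chrom for v in panel.variants})
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        for i, v in enumerate(panel.variants):
            gts = "\t".join(
                f"{panel.alleles[s, 0, i]}|{panel.alleles[s, 1, i]}"
                for s in range(panel.n_samples)
            )
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# BED regions
# ---------------------------------------------------------------------------

def _infer_role(name: str | None) -> str | None:
    if name is None:
        return None
    if name in _ROLE_BY_NAME:
        return _ROLE_BY_NAME[name]
    if name.startswith("E"):
        return "enhancer"
    return None


def read_regions(path: str | Path) -> RegionSet:
    """Read BED3+ into a :class:`RegionSet` (1-based inclusive internally).

    An optional 5th column gives the role; otherwise the role is guessed
    from the name (P -> promoter, E* -> enhancer, REST -> repressor_site).
    """
    regions: list[GenomicInterval] = []
    roles: dict[str, str | None] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has <3 fields")
            chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            start1, end1 = start0 + 1, end0
            if end1 < start1:
                raise ValueError(
                    f"{path}:{lineno}: empty or inverted interval "
                    f"({start0}, {end0}) after BED conversion"
                )
            name = fields[3] if len(fields) > 3 else f"region{len(regions) + 1}"
            role = fields[4] if len(fields) > 4 else _infer_role(name)
            regions.append(GenomicInterval(chrom, start1, end1, name))
            roles[name] = role
    log_kv("regions_loaded", path=str(path), n=len(regions))
    return RegionSet(regions, roles)


def write_regions(regions: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fields = r.to_bed_fields()
            role = regions.roles.get(r.name)
            if role is not None:
                fields.append(role)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Read-pair stream
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairRecord:
    """One allele-labeled Hi-C read pair (labels M / P / UA per end)."""

    pair_id: str
    chrom1: str
    pos1: int
    label1: str
    chrom2: str
    pos2: int
    label2: str
    replicate_id: str


class PairReader:
    """Iterate :class:`PairRecord` from a pairs TSV, counting malformed lines.

    Malformed lines (wrong field count, unparseable positions) are skipped
    and tallied in :attr:`n_malformed`; an unknown allele label is a hard
    error because it indicates a corrupted labeling step, not a bad line.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.n_records = 0
        self.n_malformed = 0

    def __iter__(self) -> Iterator[PairRecord]:
        with open(self.path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 8:
                    self.n_malformed += 1
                    log_kv("pairs_malformed_line", line=lineno, n_fields=len(fields))
                    continue
                pid, c1, p1, l1, c2, p2, l2, rep = fields
                if l1 not in PAIR_LABELS or l2 not in PAIR_LABELS:
                    raise ValueError(
                        f"{self.path}:{lineno}: unknown allele label "
                        f"({l1!r}, {l2!r}); expected M/P/UA"
                    )
                try:
                    pos1, pos2 = int(p1), int(p2)
                except ValueError:
                    self.n_malformed += 1
                    log_kv("pairs_malformed_line", line=lineno, reason="bad_pos")
                    continue
                self.n_records += 1
                yield PairRecord(pid, c1, pos1, l1, c2, pos2, l2, rep)
        log_kv(
            "pairs_read",
            path=str(self.path),
            n_records=self.n_records,
            n_malformed=self.n_malformed,
        )


def read_pairs(path: str | Path) -> PairReader:
    return PairReader(path)


def write_pairs(records, path: str | Path) -> int:
    """Write read pairs in the tab-delimited pairs format; returns the count."""
    n = 0
    with open(path, "w") as fh:
        fh.write(
            "#pair_id\tchrom1\tpos1\tlabel1\tchrom2\tpos2\tlabel2\treplicate_id\n"
        )
        for r in records:
            fh.write(
                f"{r.pair_id}\t{r.chrom1}\t{r.pos1}\t{r.label1}\t"
                f"{r.chrom2}\t{r.pos2}\t{r.label2}\t{r.replicate_id}\n"
            )
            n += 1
    log_kv("pairs_written", path=str(path), n_records=n)
    return n


# ---------------------------------------------------------------------------
# Run metadata sidecars
# ---------------------------------------------------------------------------

def write_meta(output_path: str | Path, **info) -> None:
    """Write a JSON run-metadata sidecar next to ``output_path``."""
    meta = {"output": str(output_path), **info}
    with open(str(output_path) + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")


def setup_logging(level: int = logging.INFO) -> None:
    """Route package logs as key=value lines to stderr (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)
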
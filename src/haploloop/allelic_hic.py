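"""Allele-assignment of Hi-C read pairs and parental contact matrices.

In a cell line heterozygous across a locus, each sequencing read that
covers a phased heterozygous SNP can be attributed to one homolog: label
M for the first parental haplotype, P for the second, UA when no
informative SNP is covered.  Read pairs are then grouped per parental
chromosome — {M,M} and {M,UA} pairs as parent-1, {P,P} and {P,UA} as
parent-2 — and binned into per-replicate contact matrices (5 kb bins by
default at this locus).

Pairs whose two ends disagree (M with P) or whose covered SNPs disagree
within one read (CONFLICT) cannot be attributed to a single homolog and
are tallied as DISCORDANT, excluded from both matrices.

Also provides the upstream mapping aid: masking every heterozygous or
homozygous-alternative site of a cell line's genome to 'N' so that reads
from either homolog align without reference bias.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np

from .core_io import GenomicInterval, HaplotypePanel, PairRecord, log_kv


class AlleleLabel(str, Enum):
    M = "M"           # all covered het SNPs match haplotype 1
    P = "P"           # all covered het SNPs match haplotype 2
    UA = "UA"         # no informative site
    CONFLICT = "CONFLICT"  # covered het SNPs disagree on the parent


class PairClass(str, Enum):
    PARENT1 = "PARENT1"
    PARENT2 = "PARENT2"
    UNASSIGNED = "UNASSIGNED"
    DISCORDANT = "DISCORDANT"


def classify_read(
    observed: Iterable[tuple[str, int]],
    phase: Mapping[str, tuple[int, int]],
) -> AlleleLabel:
    """Label one read from its observed alleles at heterozygous SNPs.

    Parameters
    ----------
    observed
        (variant_id, allele_code) for each covered het SNP; codes are
        0 (ref) / 1 (alt).
    phase
        variant_id -> (hap1_allele, hap2_allele) for the cell line; every
        referenced variant must be heterozygous.
    """
    votes: set[str] = set()
    for vid, allele in observed:
        h1, h2 = phase[vid]
        if h1 == h2:
            raise ValueError(f"variant {vid} is not heterozygous in this cell line")
        if allele == h1:
            votes.add("M")
        elif allele == h2:
            votes.add("P")
        else:
            # third base at a het site: treated as uninformative
            continue
    if not votes:
        return AlleleLabel.UA
    if votes == {"M"}:
        return AlleleLabel.M
    if votes == {"P"}:
        return AlleleLabel.P
    return AlleleLabel.CONFLICT


def group_pair(label1: AlleleLabel | str, label2: AlleleLabel | str) -> PairClass:
    """Group a read pair's two end labels into a parental pair class.

    Symmetric in its arguments: {M,M}/{M,UA} -> PARENT1, {P,P}/{P,UA} ->
    PARENT2, {UA,UA} -> UNASSIGNED, anything containing CONFLICT or the
    mixed {M,P} -> DISCORDANT.
    """
    labels = {AlleleLabel(label1), AlleleLabel(label2)}
    if AlleleLabel.CONFLICT in labels:
        return PairClass.DISCORDANT
    if labels == {AlleleLabel.M, AlleleLabel.P}:
        return PairClass.DISCORDANT
    if AlleleLabel.M in labels:
        return PairClass.PARENT1
    if AlleleLabel.P in labels:
        return PairClass.PARENT2
    return PairClass.UNASSIGNED


PARENT1 = "parent1"
PARENT2 = "parent2"

_GROUP_NAME = {PairClass.PARENT1: PARENT1, PairClass.PARENT2: PARENT2}


@dataclass
class AllelicContactSet:
    """Per-replicate, per-parental-haplotype sparse contact matrices.

    ``matrices[(replicate_id, group)]`` maps upper-triangle bin pairs
    (i <= j, window-relative indices) to integer counts.  ``tallies``
    counts every in-window pair by :class:`PairClass`; skipped
    (out-of-window) pairs are tallied separately so that
    PARENT1 + PARENT2 + UNASSIGNED + DISCORDANT + skipped = total input.
    """

    resolution: int
    window: GenomicInterval
    matrices: dict[tuple[str, str], Counter] = field(default_factory=dict)
    tallies: Counter = field(default_factory=Counter)
    n_skipped: int = 0

    @property
    def n_bins(self) -> int:
        return (self.window.length + self.resolution - 1) // self.resolution

    def bin_index(self, pos: int) -> int:
        return (pos - self.window.start) // self.resolution

    def bin_interval(self, i: int) -> tuple[int, int]:
        """1-based inclusive genomic span of bin ``i``."""
        start = self.window.start + i * self.resolution
        return start, min(start + self.resolution - 1, self.window.end)

    def matrix(self, replicate_id: str, group: str) -> Counter:
        return self.matrices.setdefault((replicate_id, group), Counter())

    def add(self, replicate_id: str, group: str, i: int, j: int, count: int = 1) -> None:
        if i > j:
            i, j = j, i
        self.matrix(replicate_id, group)[(i, j)] += count

    def total_pairs(self) -> int:
        return sum(self.tallies.values()) + self.n_skipped

    def replicates(self, group: str) -> list[str]:
        return sorted(rep for rep, g in self.matrices if g == group)


def bin_pairs(
    pairs: Iterable[PairRecord],
    resolution: int,
    window: GenomicInterval,
) -> AllelicContactSet:
    """Bin allele-labeled read pairs into parental contact matrices.

    Only PARENT1/PARENT2 pairs increment matrices; all in-window pairs are
    tallied by class.  Pairs with an end outside the window (or on another
    chromosome) are skipped with a warning count.
    """
    cs = AllelicContactSet(resolution=resolution, window=window)
    for rec in pairs:
        if not (
            window.contains(rec.chrom1, rec.pos1)
            and window.contains(rec.chrom2, rec.pos2)
        ):
            cs.n_skipped += 1
            continue
        cls = group_pair(rec.label1, rec.label2)
        cs.tallies[cls] += 1
        if cls in _GROUP_NAME:
            i = cs.bin_index(rec.pos1)
            j = cs.bin_index(rec.pos2)
            cs.add(rec.replicate_id, _GROUP_NAME[cls], i, j)
    total = cs.total_pairs()
    assigned = sum(cs.tallies.values())
    assert assigned + cs.n_skipped == total
    log_kv(
        "pairs_binned",
        total=total,
        parent1=cs.tallies[PairClass.PARENT1],
        parent2=cs.tallies[PairClass.PARENT2],
        unassigned=cs.tallies[PairClass.UNASSIGNED],
        discordant=cs.tallies[PairClass.DISCORDANT],
        skipped=cs.n_skipped,
    )
    return cs


def mask_genome(
    sequence: str,
    panel: HaplotypePanel,
    sample: str,
    offset: int = 1,
) -> tuple[str, int]:
    """Mask het and hom-alt sites of one cell line to 'N'.

    ``offset`` is the 1-based genomic coordinate of ``sequence[0]``.
    Returns the masked sequence and the number of masked bases.
    """
    s = panel.samples.index(sample)
    seq = np.frombuffer(sequence.encode(), dtype="S1").copy()
    n_masked = 0
    for i, v in enumerate(panel.variants):
        a, b = panel.alleles[s, :, i]
        if a == b == 0:  # hom-ref: leave the reference base
            continue
        idx = v.pos - offset
        if idx < 0 or idx >= len(seq):
            raise ValueError(
                f"variant {v.id} at {v.chrom}:{v.pos} outside the sequence"
            )
        seq[idx] = b"N"
        n_masked += 1
    log_kv("genome_masked", sample=sample, n_masked=n_masked)
    return seq.tobytes().decode(), n_masked


# ---------------------------------------------------------------------------
# Triplet matrix I/O (bin_i <TAB> bin_j <TAB> count)
# ---------------------------------------------------------------------------

def write_contact_matrices(cs: AllelicContactSet, directory) -> list[str]:
    """Write one sparse triplet file per (replicate, haplotype group)."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for (rep, group), mat in sorted(cs.matrices.items()):
        path = directory / f"{rep}.{group}.matrix.tsv"
        with open(path, "w") as fh:
            fh.write("#bin_i\tbin_j\tcount\n")
            for (i, j), c in sorted(mat.items()):
                fh.write(f"{i}\t{j}\t{c}\n")
        written.append(str(path))
    tallies = {cls.value: int(cs.tallies[cls]) for cls in PairClass}
    tallies["skipped"] = cs.n_skipped
    meta = {
        "resolution": cs.resolution,
        "window": {
            "chrom": cs.window.chrom,
            "start": cs.window.start,
            "end": cs.window.end,
        },
        "tallies": tallies,
    }
    with open(directory / "tallies.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return written


def read_contact_matrices(directory) -> AllelicContactSet:
    """Read back a directory written by :func:`write_contact_matrices`."""
    import json
    from pathlib import Path

    directory = Path(directory)
    with open(directory / "tallies.json") as fh:
        meta = json.load(fh)
    w = meta["window"]
    cs = AllelicContactSet(
        resolution=int(meta["resolution"]),
        window=GenomicInterval(w["chrom"], int(w["start"]), int(w["end"])),
    )
    for cls in PairClass:
        count = int(meta["tallies"].get(cls.value, 0))
        if count:
            cs.tallies[cls] = count
    cs.n_skipped = int(meta["tallies"].get("skipped", 0))
    for path in sorted(directory.glob("*.matrix.tsv")):
        rep, group, _ = path.name.split(".", 2)
        mat = cs.matrix(rep, group)
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                i, j, c = line.split("\t")
                mat[(int(i), int(j))] += int(c)
    return cs
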
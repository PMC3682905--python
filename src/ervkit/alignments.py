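"""Minimal alignment records and SAM/TSV input-output.

SAM parsing is delegated to pysam; the TSV mirror is a flat, header-ed
table carrying the same fields for dependency-free fixtures.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pysam

from .genome_model import GenomicInterval

TSV_COLUMNS = [
    "read_name", "chrom", "start", "end", "strand", "mapq", "mate", "fragment_size",
]


@dataclass(frozen=True)
class AlignedRead:
    """One aligned read (one mate of a pair, or a single-end read)."""

    read_name: str
    chrom: str
    start: int  # 0-based leftmost aligned base
    end: int    # half-open
    strand: str
    mapq: int
    mate: int = 0  # 0 single-end, 1 or 2 for paired
    fragment_size: Optional[int] = None  # outer distance; same-chrom pairs only

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def five_prime(self) -> int:
        """5' end position in read orientation."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class MatePair:
    """Both mates of one sequenced fragment."""

    read1: AlignedRead
    read2: AlignedRead

    @property
    def same_chrom(self) -> bool:
        return self.read1.chrom == self.read2.chrom

    @property
    def fragment_size(self) -> Optional[int]:
        """Outer distance (leftmost start to rightmost end), same-chrom only."""
        if not self.same_chrom:
            return None
        return max(self.read1.end, self.read2.end) - min(self.read1.start, self.read2.start)

    @property
    def start_key(self) -> tuple:
        """Coordinate signature used for duplicate-pair collapsing."""
        a = (self.read1.chrom, self.read1.start, self.read1.strand)
        b = (self.read2.chrom, self.read2.start, self.read2.strand)
        return tuple(sorted((a, b)))


# ---------------------------------------------------------------------------
# SAM


def write_sam(
    reads: Iterable[AlignedRead],
    path: str | Path,
    chrom_lengths: dict[str, int],
) -> None:
    """Write reads as plain-text SAM with mandatory fields only.

    Mates sharing a read name are emitted as a flagged pair; SEQ/QUAL are
    omitted ('*').
    """
    groups: dict[str, list[AlignedRead]] = defaultdict(list)
    order: list[str] = []
    for r in reads:
        if r.read_name not in groups:
            order.append(r.read_name)
        groups[r.read_name].append(r)

    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for name in order:
            recs = groups[name]
            paired = len(recs) == 2
            for idx, r in enumerate(recs):
                flag = 0
                if paired:
                    other = recs[1 - idx]
                    flag |= 0x1
                    flag |= 0x40 if r.mate == 1 else 0x80
                    if other.strand == "-":
                        flag |= 0x20
                    rnext = "=" if other.chrom == r.chrom else other.chrom
                    pnext = other.start + 1
                    if r.chrom == other.chrom:
                        frag = max(r.end, other.end) - min(r.start, other.start)
                        tlen = frag if r.start <= other.start else -frag
                    else:
                        tlen = 0
                else:
                    rnext, pnext, tlen = "*", 0, 0
                if r.strand == "-":
                    flag |= 0x10
                cigar = f"{r.end - r.start}M"
                fh.write(
                    f"{name}\t{flag}\t{r.chrom}\t{r.start + 1}\t{r.mapq}\t{cigar}\t"
                    f"{rnext}\t{pnext}\t{tlen}\t*\t*\n"
                )


def read_sam(path: str | Path) -> list[AlignedRead]:
    """Read aligned records from SAM/BAM into AlignedRead tuples."""
    out: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            mate = 0
            if rec.is_paired:
                mate = 1 if rec.is_read1 else 2
            frag = abs(rec.template_length) or None
            out.append(
                AlignedRead(
                    read_name=rec.query_name,
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    mapq=rec.mapping_quality,
                    mate=mate,
                    fragment_size=frag,
                )
            )
    return out


# ---------------------------------------------------------------------------
# TSV mirror


def write_alignments_tsv(reads: Iterable[AlignedRead], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(TSV_COLUMNS)
        for r in reads:
            w.writerow([
                r.read_name, r.chrom, r.start, r.end, r.strand, r.mapq, r.mate,
                "" if r.fragment_size is None else r.fragment_size,
            ])


def read_alignments_tsv(path: str | Path) -> list[AlignedRead]:
    out: list[AlignedRead] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            frag = row["fragment_size"]
            out.append(
                AlignedRead(
                    read_name=row["read_name"],
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    mapq=int(row["mapq"]),
                    mate=int(row["mate"]),
                    fragment_size=int(frag) if frag else None,
                )
            )
    return out


def read_alignments(path: str | Path) -> list[AlignedRead]:
    """Dispatch on extension: .sam/.bam via pysam, .tsv via the mirror."""
    suffix = Path(path).suffix.lower()
    if suffix in (".sam", ".bam"):
        return read_sam(path)
    if suffix in (".tsv", ".txt"):
        return read_alignments_tsv(path)
    raise ValueError(f"unrecognised alignment file extension: {suffix}")


def build_mate_pairs(reads: Iterable[AlignedRead]) -> list[MatePair]:
    """Group paired reads by name into MatePairs (unpaired reads dropped)."""
    by_name: dict[str, dict[int, AlignedRead]] = defaultdict(dict)
    order: list[str] = []
    for r in reads:
        if r.mate not in (1, 2):
            continue
        if r.read_name not in by_name:
            order.append(r.read_name)
        by_name[r.read_name][r.mate] = r
    pairs = []
    for name in order:
        mates = by_name[name]
        if 1 in mates and 2 in mates:
            pairs.append(MatePair(mates[1], mates[2]))
    return pairs
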
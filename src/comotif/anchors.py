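"""Anchor-site input handling.

Anchor sets come either as BED intervals over a genome FASTA or as a FASTA of
sequences centered on the anchor sites.  Each anchor is turned into an
:class:`AnchorRecord` carrying the anchor sequence plus ``n`` nucleotides of
upstream and downstream flank, oriented so that "upstream" is always 5' of
the anchor in its reading direction (minus-strand anchors are
reverse-complemented).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from Bio import SeqIO
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN"
)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes supported)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class AnchorRecord:
    """One anchor site with strand-oriented flanks of equal length ``n``."""

    id: str
    anchor_seq: str
    upstream: str
    downstream: str
    source: Union[GenomicInterval, str, None] = None

    @property
    def n(self) -> int:
        return len(self.upstream)

    def full_sequence(self) -> str:
        return self.upstream + self.anchor_seq + self.downstream


@dataclass
class GateResult:
    passed: bool
    count: int
    min_sites: int


def _parse_bed_line(line: str, lineno: int) -> GenomicInterval:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        fields = line.split()
    if len(fields) < 3:
        raise ValueError(f"malformed BED line {lineno}: {line!r}")
    try:
        chrom = fields[0]
        start = int(fields[1])
        end = int(fields[2])
    except ValueError as exc:
        raise ValueError(f"malformed BED line {lineno}: {line!r}") from exc
    name = fields[3] if len(fields) > 3 else f"site{lineno}"
    strand = fields[5] if len(fields) > 5 else "+"
    try:
        return GenomicInterval(chrom, start, end, strand, name)
    except ValueError as exc:
        raise ValueError(f"malformed BED line {lineno}: {exc}") from exc


def read_bed(path: Union[str, Path]) -> list[GenomicInterval]:
    """Parse a BED file (>=3 columns; name col 4, strand col 6 if present)."""
    intervals = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            intervals.append(_parse_bed_line(line, lineno))
    return intervals


def anchors_from_intervals(
    intervals: Iterable[GenomicInterval],
    genome: Union[str, Path, Fasta],
    flank_length: int = 30,
) -> list[AnchorRecord]:
    """Extract anchor + flank sequences for genomic intervals.

    Intervals whose flanks would run off a chromosome end are skipped with a
    warning (padding would inject artificial base composition).
    """
    if not isinstance(genome, Fasta):
        genome = Fasta(str(genome))
    n = flank_length
    records: list[AnchorRecord] = []
    skipped = 0
    for i, iv in enumerate(intervals):
        if iv.chrom not in genome:
            raise KeyError(f"chromosome {iv.chrom!r} absent from genome")
        chrom_len = len(genome[iv.chrom])
        if iv.end > chrom_len:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome length {chrom_len}"
            )
        if iv.start - n < 0 or iv.end + n > chrom_len:
            skipped += 1
            logger.warning(
                "skipping %s:%d-%d: flank of %d nt runs off the chromosome end",
                iv.chrom, iv.start, iv.end, n,
            )
            continue
        anchor = str(genome[iv.chrom][iv.start:iv.end]).upper()
        left = str(genome[iv.chrom][iv.start - n:iv.start]).upper()
        right = str(genome[iv.chrom][iv.end:iv.end + n]).upper()
        if iv.strand == "-":
            anchor, left, right = revcomp(anchor), revcomp(right), revcomp(left)
        name = iv.name or f"site{i + 1}"
        records.append(AnchorRecord(name, anchor, left, right, source=iv))
    if skipped:
        logger.warning("%d interval(s) skipped at chromosome boundaries", skipped)
    return records


def anchors_from_fasta(
    path: Union[str, Path],
    anchor_length: int,
    flank_length: int = 30,
) -> list[AnchorRecord]:
    """Read anchor-centered sequences from FASTA.

    The anchor occupies the central ``anchor_length`` positions; when the
    remainder is odd the extra base goes downstream.  Sequences too short to
    yield both flanks are skipped with a warning.
    """
    n = flank_length
    records: list[AnchorRecord] = []
    skipped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if len(seq) < anchor_length + 2 * n:
            skipped += 1
            logger.warning(
                "skipping %s: length %d < anchor %d + 2*%d flanks",
                rec.id, len(seq), anchor_length, n,
            )
            continue
        start = (len(seq) - anchor_length) // 2
        records.append(
            AnchorRecord(
                id=rec.id,
                anchor_seq=seq[start:start + anchor_length],
                upstream=seq[start - n:start],
                downstream=seq[start + anchor_length:start + anchor_length + n],
                source=rec.description,
            )
        )
    if skipped:
        logger.warning("%d FASTA record(s) too short for the requested flanks", skipped)
    return records


def read_anchors(
    path: Union[str, Path],
    format: str,
    anchor_length: int,
    flank_length: int = 30,
    genome: Optional[Union[str, Path]] = None,
) -> list[AnchorRecord]:
    """Read an anchor set from ``bed`` (requires ``genome``) or ``fasta``."""
    if format == "bed":
        if genome is None:
            raise ValueError("BED input requires a genome FASTA")
        return anchors_from_intervals(read_bed(path), genome, flank_length)
    if format == "fasta":
        return anchors_from_fasta(path, anchor_length, flank_length)
    raise ValueError(f"unknown format {format!r} (expected 'bed' or 'fasta')")


def write_anchors_fasta(records: Iterable[AnchorRecord], path: Union[str, Path]) -> None:
    """Write anchors as FASTA of upstream + anchor + downstream."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n{rec.full_sequence()}\n")


def dataset_size_gate(records: list[AnchorRecord], min_sites: int = 1000) -> GateResult:
    """Check the minimum dataset-size requirement for reliable discovery.

    Small collections do not provide enough recurrence for the factorization
    to separate a co-binding pattern from background, so discovery is skipped
    (overridable) below ``min_sites`` sites.
    """
    count = len(records)
    passed = count >= min_sites
    if not passed:
        logger.warning("dataset has %d sites (< %d): discovery gated", count, min_sites)
    return GateResult(passed=passed, count=count, min_sites=min_sites)
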
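"""Readers and writers for the formats the pipeline touches.

All coordinate and strand conventions are fixed at this boundary:
internally every interval is 0-based half-open on the plus strand of a
circular reference; GFF3's 1-based inclusive coordinates exist only in the
files.  Strand-specific libraries are resolved to a per-record transcript
strand here, so downstream code never inspects SAM flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pysam
from Bio import Phylo, SeqIO

__all__ = [
    "Plastome",
    "CdsFeature",
    "StrandedAlignmentRecord",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_sam",
    "write_sam",
    "read_newick",
    "write_newick",
]

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# CIGAR ops we accept; spliced/clipped-hard alignments are out of scope for
# plastid CDSs.
_SUPPORTED_CIGAR = frozenset("MIDS")


class FormatError(ValueError):
    """A file violated the supported dialect of its format."""


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CdsFeature:
    """A protein-coding feature on a circular reference.

    Coordinates are 0-based half-open on the plus strand.  A feature that
    spans the origin has ``wraps_origin=True`` and ``end > genome_length``
    in unrolled (virtual) coordinates, so ``start < end`` always holds
    internally.
    """

    gene_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    phase: int = 0
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start >= self.end:
            raise ValueError(f"empty interval for {self.gene_id}: [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def intervals(self, genome_length: int) -> list[tuple[int, int]]:
        """Concrete [start, end) pieces on [0, genome_length).

        A wrapping feature yields two pieces; all others one.
        """
        if not self.wraps_origin:
            return [(self.start, self.end)]
        return [(self.start, genome_length), (0, self.end - genome_length)]

    def contains(self, pos: int, genome_length: int) -> bool:
        return any(s <= pos < e for s, e in self.intervals(genome_length))

    def offset_of(self, pos: int, genome_length: int) -> int:
        """Offset of a genomic position within the CDS, in CDS reading order.

        Offset 0 is the first base of the start codon (strand-aware).
        """
        unrolled = pos
        if self.wraps_origin and pos < self.start:
            unrolled = pos + genome_length
        if not self.start <= unrolled < self.end:
            raise ValueError(f"position {pos} outside {self.gene_id}")
        if self.strand == "+":
            return unrolled - self.start
        return self.end - 1 - unrolled


@dataclass
class Plastome:
    """A circular plastid genome: sequence plus CDS annotations."""

    id: str
    sequence: str
    features: list[CdsFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(f"invalid bases in {self.id}: {sorted(bad)}")
        for f in self.features:
            if f.end - (self.length if f.wraps_origin else 0) > self.length:
                raise ValueError(f"feature {f.gene_id} outside genome {self.id}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence on the plus strand; indices may exceed length (circular)."""
        L = self.length
        start %= L
        end = start + (end - start)
        if end <= L:
            return self.sequence[start:end]
        return (self.sequence * 2)[start:end]

    def cds_sequence(self, feature: CdsFeature) -> str:
        """The coding sequence of a feature, 5'→3' on its own strand."""
        raw = self.fetch(feature.start, feature.end)
        return raw if feature.strand == "+" else revcomp(raw)


@dataclass
class StrandedAlignmentRecord:
    """One aligned read with its transcript strand already resolved."""

    read_id: str
    ref_id: str
    ref_start: int
    cigar: list[tuple[str, int]]  # (op, length) with op in M/I/D/S
    seq: str
    transcript_strand: str  # '+' or '-'
    is_read1: bool = True
    is_reverse: bool = False
    is_paired: bool = True

    @property
    def aligned_blocks(self) -> list[tuple[int, int]]:
        """Reference [start, end) blocks consumed by M operations."""
        blocks = []
        ref = self.ref_start
        for op, n in self.cigar:
            if op == "M":
                blocks.append((ref, ref + n))
                ref += n
            elif op == "D":
                ref += n
        return blocks

    @property
    def aligned_length(self) -> int:
        return sum(n for op, n in self.cigar if op == "M")

    def aligned_pairs(self) -> Iterable[tuple[int, str]]:
        """(reference position, read base) for every M-aligned base."""
        ref = self.ref_start
        q = 0
        for op, n in self.cigar:
            if op == "M":
                for k in range(n):
                    yield ref + k, self.seq[q + k]
                ref += n
                q += n
            elif op == "D":
                ref += n
            else:  # I or S consume query only
                q += n


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, upper-cased sequence) pairs, order kept."""
    path = Path(path)
    records: list[tuple[str, str]] = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper()
            bad = set(seq) - _VALID_BASES
            if bad:
                line_no = _find_bad_line(path, bad)
                raise FormatError(
                    f"{path}: invalid sequence character(s) {sorted(bad)} near line {line_no}"
                )
            records.append((rec.id, seq))
    except ValueError as exc:  # Biopython's malformed-record errors
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"{path}: {exc}") from exc
    return records


def _find_bad_line(path: Path, bad: set[str]) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith(">"):
                continue
            if set(line.strip().upper()) & bad:
                return i
    return 0


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(
    path: str | Path,
    genome_length: int,
    feature_types: Sequence[str] = ("CDS",),
    allow_wrap: bool = True,
) -> list[CdsFeature]:
    """Read CDS features from GFF3, converting to 0-based half-open.

    Origin-spanning features are written in the unrolled dialect
    (``end > genome_length``); with ``allow_wrap`` they come back flagged
    ``wraps_origin``.  Duplicate (gene_id, interval) rows are dropped with a
    warning.  Features are returned sorted by start.
    """
    path = Path(path)
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:
        raise FormatError(f"{path}: not parseable as GFF3 ({exc})") from exc

    feats: list[CdsFeature] = []
    seen: set[tuple[str, int, int, str]] = set()
    for ftype in feature_types:
        for f in db.features_of_type(ftype):
            if f.strand not in ("+", "-"):
                raise FormatError(f"{path}: unknown strand {f.strand!r} for {f.id}")
            start = f.start - 1  # GFF3 is 1-based inclusive
            end = f.end
            if end <= start:
                raise FormatError(f"{path}: end < start for feature at line with ID {f.id}")
            wraps = end > genome_length
            if wraps and not allow_wrap:
                raise FormatError(f"{path}: feature {f.id} exceeds genome length {genome_length}")
            gene_id = (
                f.attributes.get("gene", [None])[0]
                or f.attributes.get("ID", [None])[0]
                or f.id
            )
            # gffutils create_unique suffixes duplicate IDs with _1, _2 ...
            base_id = gene_id.rsplit("_", 1)[0] if gene_id and gene_id.rsplit("_", 1)[-1].isdigit() else gene_id
            key = (base_id, start, end, f.strand)
            if key in seen:
                warnings.warn(f"duplicate feature {base_id} at [{start},{end}) dropped")
                continue
            seen.add(key)
            phase = int(f.frame) if f.frame in ("0", "1", "2") else 0
            feats.append(
                CdsFeature(
                    gene_id=base_id,
                    start=start,
                    end=end,
                    strand=f.strand,
                    phase=phase,
                    wraps_origin=wraps,
                )
            )
    feats.sort(key=lambda x: (x.start, x.gene_id))
    return feats


def write_gff3(path: str | Path, genome: Plastome, source: str = "plastidflow") -> None:
    """Write the genome's CDS features as GFF3 (1-based inclusive, unrolled dialect)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {genome.length}\n")
        for f in genome.features:
            attrs = f"ID={f.gene_id};gene={f.gene_id}"
            fh.write(
                "\t".join(
                    [
                        genome.id,
                        source,
                        "CDS",
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        str(f.phase),
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# SAM


def _transcript_strand(read: pysam.AlignedSegment, convention: str) -> str:
    """Resolve the transcript strand of one alignment.

    Under the dUTP ``fr-firststrand`` convention the first read of a pair is
    antisense to the transcript, the second sense.  For single-end data the
    ``reverse`` convention means a reverse-mapped read is a '+' transcript.
    """
    if convention == "fr-firststrand":
        if read.is_paired:
            if read.is_read1:
                return "+" if read.is_reverse else "-"
            return "-" if read.is_reverse else "+"
        return "+" if read.is_reverse else "-"
    if convention == "fr-secondstrand":
        if read.is_paired:
            if read.is_read1:
                return "-" if read.is_reverse else "+"
            return "+" if read.is_reverse else "-"
        return "-" if read.is_reverse else "+"
    if convention == "reverse":  # single-end alias of firststrand
        return "+" if read.is_reverse else "-"
    if convention == "forward":
        return "-" if read.is_reverse else "+"
    raise ValueError(f"unknown library convention {convention!r}")


def read_sam(
    path: str | Path, library_convention: str = "fr-firststrand"
) -> list[StrandedAlignmentRecord]:
    """Read a plain-text SAM file and resolve transcript strands.

    Unmapped and secondary/supplementary records are dropped.  Only
    M/I/D/S CIGAR operations are supported.
    """
    records: list[StrandedAlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=True) as sam:
        if not sam.header.get("SQ"):
            raise FormatError(f"{path}: SAM header has no @SQ reference line")
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            cigar = []
            for op_code, n in read.cigartuples or []:
                op = "MIDNSHP=X"[op_code]
                if op not in _SUPPORTED_CIGAR:
                    raise FormatError(
                        f"{path}: unsupported CIGAR op {op!r} in read {read.query_name}"
                    )
                cigar.append((op, n))
            records.append(
                StrandedAlignmentRecord(
                    read_id=read.query_name,
                    ref_id=read.reference_name,
                    ref_start=read.reference_start,
                    cigar=cigar,
                    seq=read.query_sequence or "",
                    transcript_strand=_transcript_strand(read, library_convention),
                    is_read1=read.is_read1 if read.is_paired else True,
                    is_reverse=read.is_reverse,
                    is_paired=read.is_paired,
                )
            )
    return records


def write_sam(
    path: str | Path,
    records: Iterable[StrandedAlignmentRecord],
    ref_id: str,
    ref_length: int,
) -> None:
    """Write records as plain-text SAM with flags encoding the dUTP layout."""
    header = {"HD": {"VN": "1.6", "SO": "unsorted"}, "SQ": [{"SN": ref_id, "LN": ref_length}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.reference_id = 0
            a.reference_start = rec.ref_start
            a.mapping_quality = 60
            a.cigarstring = "".join(f"{n}{op}" for op, n in rec.cigar)
            a.query_sequence = rec.seq
            flag = 0
            if rec.is_paired:
                flag |= 0x1 | 0x2  # paired, proper pair
                flag |= 0x40 if rec.is_read1 else 0x80
                # mate strand is always the opposite in our FR layout
                if not rec.is_reverse:
                    flag |= 0x20
            if rec.is_reverse:
                flag |= 0x10
            a.flag = flag
            out.write(a)


# ---------------------------------------------------------------------------
# Newick


def read_newick(path: str | Path):
    """Read a newick tree with branch lengths (Bio.Phylo tree).

    Branches without a length are set to 0 with a warning, so patristic
    distances are always defined.
    """
    try:
        source = path if hasattr(path, "read") else str(path)
        tree = Phylo.read(source, "newick")
    except Exception as exc:
        raise FormatError(f"{path}: newick parse error ({exc})") from exc
    for clade in tree.find_clades():
        if clade.branch_length is None:
            if clade is not tree.root:
                warnings.warn(f"branch without length ({clade.name or 'internal'}); set to 0")
            clade.branch_length = 0.0
        elif clade.branch_length < 0:
            raise FormatError(f"{path}: negative branch length on {clade.name}")
    return tree


def write_newick(path: str | Path, tree) -> None:
    Phylo.write(tree, str(path), "newick")
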
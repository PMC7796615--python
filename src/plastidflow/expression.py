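"""Strand-aware CDS read counting, TPM, and ortholog expression correlation.

A read is assigned to a CDS when at least half of its aligned length
overlaps the CDS, sense or antisense according to whether the read's
transcript strand matches the CDS strand.  Sense counts are normalised to
transcripts per million (TPM): per-gene read rate (count / CDS length)
scaled so the rates sum to 10^6.  Expression conservation between two
species is the Pearson correlation of transformed TPM over their shared
single-copy orthologs, by default on a log10(TPM + 1) scale so that the few
dominant photosynthesis genes do not determine the coefficient alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import CdsFeature, Plastome, StrandedAlignmentRecord

__all__ = [
    "ExpressionTable",
    "OrthologyMap",
    "count_cds_reads",
    "tpm",
    "expression_table",
    "ortholog_expression_correlation",
    "log10p",
]


@dataclass
class ExpressionTable:
    """Per-CDS sense/antisense counts and sense TPM for one species."""

    species: str
    table: pd.DataFrame  # index gene_id; columns sense_count, antisense_count, length, tpm

    def __post_init__(self) -> None:
        required = {"sense_count", "antisense_count", "length", "tpm"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"expression table missing columns {sorted(missing)}")

    def tpm_of(self, gene_id: str) -> float:
        return float(self.table.loc[gene_id, "tpm"])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


class OrthologyMap:
    """Ortholog group -> per-species gene id (at most one gene per species)."""

    def __init__(self, groups: Mapping[str, Mapping[str, str]]):
        self.groups = {gid: dict(sp_map) for gid, sp_map in groups.items()}

    @classmethod
    def identity(cls, gene_ids: Iterable[str], species: Iterable[str]) -> "OrthologyMap":
        """Every species uses the same gene ids (synthetic families)."""
        species = list(species)
        return cls({g: {sp: g for sp in species} for g in gene_ids})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrthologyMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if "group" not in df.columns:
            raise ValueError("orthology TSV needs a 'group' column")
        groups = {}
        for _, row in df.iterrows():
            groups[row["group"]] = {
                sp: g for sp, g in row.drop("group").items() if pd.notna(g)
            }
        return cls(groups)

    def to_tsv(self, path: str | Path) -> None:
        species = sorted({sp for m in self.groups.values() for sp in m})
        rows = [
            {"group": gid, **{sp: m.get(sp) for sp in species}}
            for gid, m in self.groups.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def shared_pairs(self, sp_a: str, sp_b: str) -> list[tuple[str, str, str]]:
        """(group, gene in A, gene in B) for groups present in both species."""
        out = []
        for gid, m in self.groups.items():
            if sp_a in m and sp_b in m:
                out.append((gid, m[sp_a], m[sp_b]))
        return out


def count_cds_reads(
    records: Iterable[StrandedAlignmentRecord],
    features: Sequence[CdsFeature],
    genome_length: int | None = None,
) -> pd.DataFrame:
    """Per-CDS sense and antisense read counts under the 50%-overlap rule.

    A read belongs to a CDS if at least half its aligned length overlaps the
    CDS; when two CDSs qualify, the larger overlap wins, and an exact tie
    counts the read for both (flagged in the 'ambiguous' column).
    """
    feats = list(features)
    if genome_length is None:
        genome_length = max((f.end for f in feats), default=0)
    pieces = []  # (piece_start, piece_end, feature_index)
    for i, f in enumerate(feats):
        for s, e in f.intervals(genome_length):
            pieces.append((s, e, i))
    pieces.sort()
    piece_starts = np.array([p[0] for p in pieces])
    piece_ends = np.array([p[1] for p in pieces])
    # with non-overlapping pieces a read touches a small contiguous run of
    # pieces, found by bisection; overlapping annotations fall back to a scan
    disjoint = bool((piece_ends[:-1] <= piece_starts[1:]).all()) if len(pieces) > 1 else True
    counts = pd.DataFrame(
        {
            "sense_count": 0,
            "antisense_count": 0,
            "ambiguous": 0,
            "length": [f.length for f in feats],
        },
        index=pd.Index([f.gene_id for f in feats], name="gene_id"),
    )
    for rec in records:
        aln_len = rec.aligned_length
        if aln_len == 0:
            continue
        overlaps: dict[int, int] = {}
        for rs, re_ in rec.aligned_blocks:
            if disjoint:
                lo = int(np.searchsorted(piece_ends, rs, side="right"))
                hi = int(np.searchsorted(piece_starts, re_, side="left"))
                window = pieces[lo:hi]
            else:
                window = pieces
            for ps, pe, i in window:
                ov = min(re_, pe) - max(rs, ps)
                if ov > 0:
                    overlaps[i] = overlaps.get(i, 0) + ov
        eligible = {i: ov for i, ov in overlaps.items() if 2 * ov >= aln_len}
        if not eligible:
            continue
        best = max(eligible.values())
        winners = [i for i, ov in eligible.items() if ov == best]
        for i in winners:
            f = feats[i]
            col = "sense_count" if rec.transcript_strand == f.strand else "antisense_count"
            counts.iloc[i, counts.columns.get_loc(col)] += 1
            if len(winners) > 1:
                counts.iloc[i, counts.columns.get_loc("ambiguous")] += 1
    return counts


def tpm(counts: Sequence[float], lengths: Sequence[float]) -> np.ndarray:
    """Transcripts per million from read counts and feature lengths.

    ``rate_g = count_g / length_g``, scaled so the rates sum to 10^6.  An
    all-zero count vector yields all-zero TPM.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative read count")
    if (lengths <= 0).any():
        raise ValueError("non-positive CDS length")
    rates = counts / lengths
    total = rates.sum()
    if total == 0:
        return np.zeros_like(rates)
    return 1e6 * rates / total


def expression_table(
    records: Iterable[StrandedAlignmentRecord],
    features: Sequence[CdsFeature],
    species: str,
    genome: Plastome | None = None,
) -> ExpressionTable:
    """Count reads per CDS and attach sense TPM."""
    counts = count_cds_reads(
        records, features, genome.length if genome is not None else None
    )
    counts["tpm"] = tpm(counts["sense_count"].to_numpy(), counts["length"].to_numpy())
    return ExpressionTable(species=species, table=counts)


def log10p(x: np.ndarray) -> np.ndarray:
    return np.log10(np.asarray(x, dtype=float) + 1.0)


def ortholog_expression_correlation(
    table_a: ExpressionTable,
    table_b: ExpressionTable,
    orthology: OrthologyMap,
    transform: Callable[[np.ndarray], np.ndarray] | None = log10p,
) -> tuple[float, int, float]:
    """Pearson correlation of (transformed) TPM over shared orthologs.

    Returns ``(r, n, p)`` with the p-value from the two-sided t test on
    ``r`` and ``n`` ortholog pairs.  Defaults to the log10(TPM + 1) scale;
    pass ``transform=None`` for raw TPM.
    """
    from .association import pearson, pearson_pvalue

    pairs = orthology.shared_pairs(table_a.species, table_b.species)
    xs, ys = [], []
    for _, ga, gb in pairs:
        if ga in table_a.table.index and gb in table_b.table.index:
            xs.append(table_a.tpm_of(ga))
            ys.append(table_b.tpm_of(gb))
        else:
            warnings.warn(f"ortholog pair ({ga}, {gb}) missing from a table; skipped")
    if len(xs) < 3:
        raise ValueError(f"only {len(xs)} shared ortholog values; need >= 3")
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if transform is not None:
        x, y = transform(x), transform(y)
    r = pearson(x, y)
    p = pearson_pvalue(r, len(x))
    return r, len(x), p
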
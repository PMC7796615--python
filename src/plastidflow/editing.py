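"""Strand-aware C-to-U RNA-editing detection, classification and comparison.

An editing site is a transcribed position where the transcript-strand
reference base is C but a fraction of the covering reads show U (T).  On
'+' transcripts this is a plus-strand C with reads showing T; on '-'
transcripts it is a plus-strand G with reads showing A (the C, and the
edit, live on the minus strand).  Keeping the two transcript strands
separate is what makes antisense editing detectable and prevents antisense
reads from diluting sense sites.

A site is called when coverage (edited + unedited bases), the edited
fraction, and an exact one-sided binomial test against the sequencing error
rate all clear their thresholds (defaults 50, 0.1 and 1e-6).  Editing
efficiency is the edited fraction.  Sites inside a CDS on its own strand
are classified silent or non-silent by translating the codon (plastid/
bacterial code, table 11) before and after the C→U change; sites on the
opposite strand of a CDS are antisense; everything else is noncoding.

Cross-species comparison maps each site to a column of a codon-aware
protein-guided alignment of its ortholog group; sites in the same column
(same strand class) in two or more species are "shared", the rest
"specific".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from scipy import stats

from .genome_io import CdsFeature, Plastome, StrandedAlignmentRecord

__all__ = [
    "StrandedPileup",
    "EditingSite",
    "CallerConfig",
    "build_pileup",
    "call_c2u",
    "classify_site",
    "classify_sites",
    "align_orthologs",
    "shared_specific",
    "editing_summary",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class StrandedPileup:
    """Per-position, per-transcript-strand base counts (plus-strand bases)."""

    genome_length: int
    counts: dict[str, np.ndarray]  # strand -> (4, L) array indexed A,C,G,T

    @classmethod
    def empty(cls, genome_length: int) -> "StrandedPileup":
        return cls(
            genome_length,
            {
                "+": np.zeros((4, genome_length), dtype=np.int64),
                "-": np.zeros((4, genome_length), dtype=np.int64),
            },
        )

    def base_count(self, pos: int, strand: str, base: str) -> int:
        return int(self.counts[strand][_BASE_INDEX[base], pos])


@dataclass
class CallerConfig:
    """Thresholds of the editing caller."""

    min_coverage: int = 50
    min_variant_frequency: float = 0.1
    max_p_value: float = 1e-6
    base_error_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if not (0 < self.min_variant_frequency <= 1):
            raise ValueError("min_variant_frequency must be in (0, 1]")
        if not (0 < self.max_p_value <= 1):
            raise ValueError("max_p_value must be in (0, 1]")
        if not (0 < self.base_error_rate < 1):
            raise ValueError("base_error_rate must be in (0, 1)")


@dataclass
class EditingSite:
    """A called C-to-U event."""

    position: int
    transcript_strand: str
    edited_count: int
    unedited_count: int
    efficiency: float
    p_value: float
    category: str | None = None  # silent | non_silent | antisense | noncoding
    gene_id: str | None = None
    cds_offset: int | None = None  # offset within the CDS in reading order
    codon_position: int | None = None  # 1..3
    aa_change: str | None = None

    @property
    def edited_unedited_ratio(self) -> float:
        """The literal edited:unedited ratio (efficiency is the fraction)."""
        return self.edited_count / self.unedited_count if self.unedited_count else float("inf")


def build_pileup(
    records: Iterable[StrandedAlignmentRecord], genome: Plastome
) -> StrandedPileup:
    """Per-position base counts per transcript strand.

    Deletions are skipped; soft-clipped and inserted bases never touch the
    reference.  Overlapping mates are counted independently, matching the
    read-count semantics of the coverage vectors.
    """
    pileup = StrandedPileup.empty(genome.length)
    lut = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    for rec in records:
        arr = pileup.counts[rec.transcript_strand]
        if len(rec.cigar) == 1 and rec.cigar[0][0] == "M":
            # fast path: a single fully aligned block
            n = rec.cigar[0][1]
            if rec.ref_start < 0 or rec.ref_start + n > genome.length:
                raise ValueError(f"read {rec.read_id} outside genome bounds")
            bidx = lut[np.frombuffer(rec.seq.encode(), dtype=np.uint8)]
            keep = bidx >= 0
            np.add.at(
                arr,
                (bidx[keep], np.arange(rec.ref_start, rec.ref_start + n)[keep]),
                1,
            )
            continue
        for pos, base in rec.aligned_pairs():
            bi = _BASE_INDEX.get(base)
            if bi is None:  # N or ambiguity code: ignore
                continue
            if not 0 <= pos < genome.length:
                raise ValueError(f"read {rec.read_id} outside genome bounds")
            arr[bi, pos] += 1
    return pileup


def call_c2u(
    pileup: StrandedPileup, genome: Plastome, config: CallerConfig | None = None
) -> list[EditingSite]:
    """Call C-to-U sites on both transcript strands.

    At a candidate position, ``n = edited + unedited`` counts only the
    C-like and T-like bases (other bases are sequencing noise and are
    excluded).  A site is called when ``n >= min_coverage``,
    ``edited / n >= min_variant_frequency`` and the one-sided binomial tail
    ``P(X >= edited | n, base_error_rate) <= max_p_value``.
    """
    config = config or CallerConfig()
    ref = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    sites: list[EditingSite] = []
    # (strand, reference base, unedited read base, edited read base)
    for strand, ref_base, un_idx, ed_idx in (
        ("+", ord("C"), _BASE_INDEX["C"], _BASE_INDEX["T"]),
        ("-", ord("G"), _BASE_INDEX["G"], _BASE_INDEX["A"]),
    ):
        arr = pileup.counts[strand]
        is_ref = ref == ref_base
        unedited = arr[un_idx]
        edited = arr[ed_idx]
        n = unedited + edited
        with np.errstate(divide="ignore", invalid="ignore"):
            freq = np.where(n > 0, edited / np.maximum(n, 1), 0.0)
        candidate = (
            is_ref
            & (n >= config.min_coverage)
            & (freq >= config.min_variant_frequency)
            & (edited > 0)
        )
        for pos in np.flatnonzero(candidate):
            e, u = int(edited[pos]), int(unedited[pos])
            p = float(stats.binom.sf(e - 1, e + u, config.base_error_rate))
            if p <= config.max_p_value:
                sites.append(
                    EditingSite(
                        position=int(pos),
                        transcript_strand=strand,
                        edited_count=e,
                        unedited_count=u,
                        efficiency=e / (e + u),
                        p_value=p,
                    )
                )
    sites.sort(key=lambda s: (s.position, s.transcript_strand))
    return sites


def classify_site(
    site: EditingSite, features: Sequence[CdsFeature], genome: Plastome
) -> EditingSite:
    """Attach category (and codon change, for sense sites) to a site.

    Inside a CDS on the site's transcript strand the codon is translated
    (table 11) before and after the C→U change; a CDS on the opposite
    strand makes the site antisense; otherwise the site is noncoding.
    Overlapping CDSs resolve with sense priority.
    """
    containing = [f for f in features if f.contains(site.position, genome.length)]
    sense = [f for f in containing if f.strand == site.transcript_strand]
    if sense:
        f = sense[0]
        if f.length % 3 != 0:
            raise ValueError(f"CDS {f.gene_id} length not a multiple of 3")
        off = f.offset_of(site.position, genome.length) - f.phase
        if off < 0:
            site.category = "noncoding"
            return site
        cds = genome.cds_sequence(f)[f.phase :]
        if cds[off] != "C":
            raise ValueError(
                f"site {site.position}{site.transcript_strand}: CDS base is "
                f"{cds[off]}, not C"
            )
        ci = off // 3
        codon = cds[ci * 3 : ci * 3 + 3]
        edited = codon[: off % 3] + "T" + codon[off % 3 + 1 :]
        aa_before = str(Seq(codon).translate(table=11))
        aa_after = str(Seq(edited).translate(table=11))
        site.gene_id = f.gene_id
        site.cds_offset = off
        site.codon_position = off % 3 + 1
        site.aa_change = f"{aa_before}{ci + 1}{aa_after}"
        site.category = "silent" if aa_before == aa_after else "non_silent"
    elif containing:
        f = containing[0]
        site.gene_id = f.gene_id
        site.cds_offset = f.offset_of(site.position, genome.length) - f.phase
        site.category = "antisense"
    else:
        site.category = "noncoding"
    return site


def classify_sites(
    sites: Iterable[EditingSite], features: Sequence[CdsFeature], genome: Plastome
) -> list[EditingSite]:
    return [classify_site(s, features, genome) for s in sites]


# ---------------------------------------------------------------------------
# cross-species comparison


def _aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -10.0
    a.extend_gap_score = -0.5
    return a


def align_orthologs(seqs: Mapping[str, str]) -> dict[str, list[int | None]]:
    """Codon-aware alignment of one ortholog group across species.

    Sequences are translated (table 11) and globally aligned at the protein
    level with BLOSM62 affine-gap scoring, star-wise around the longest
    sequence; the protein alignment is back-mapped to nucleotides.  Returns,
    per species, the common column index of every nucleotide position
    (``None`` inside insertions relative to the centre).  Sequences with an
    internal stop codon are excluded with a warning.
    """
    proteins: dict[str, str] = {}
    for sp, nt in seqs.items():
        if len(nt) % 3 != 0:
            raise ValueError(f"{sp}: CDS length {len(nt)} not a multiple of 3")
        aa = str(Seq(nt).translate(table=11))
        if "*" in aa[:-1]:
            warnings.warn(f"{sp}: internal stop codon; sequence excluded from alignment")
            continue
        # the terminal stop stays as a residue so its codon columns align too
        proteins[sp] = aa
    if len(proteins) < 2:
        if len(proteins) == 1:
            sp = next(iter(proteins))
            return {sp: list(range(len(seqs[sp])))}
        return {}
    centre = max(proteins, key=lambda sp: len(proteins[sp]))
    aligner = _aligner()
    mapping: dict[str, list[int | None]] = {}
    mapping[centre] = list(range(len(seqs[centre])))
    for sp, aa in proteins.items():
        if sp == centre:
            continue
        aln = aligner.align(proteins[centre], aa)[0]
        res_map: dict[int, int] = {}  # sp residue -> centre residue
        for (ts, te), (qs, qe) in zip(*aln.aligned):
            for k in range(te - ts):
                res_map[qs + k] = ts + k
        cols: list[int | None] = []
        for p in range(len(seqs[sp])):
            ci = res_map.get(p // 3)
            cols.append(None if ci is None else ci * 3 + p % 3)
        mapping[sp] = cols
    return mapping


def shared_specific(
    sites_per_species: Mapping[str, Sequence[EditingSite]],
    alignments: Mapping[str, Mapping[str, list[int | None]]],
    gene_to_group: Mapping[tuple[str, str], str],
) -> tuple[dict[str, list[str]], dict[frozenset, int]]:
    """Label sites shared/specific and count exclusive intersections.

    ``alignments`` maps ortholog group -> (species -> nucleotide column
    map); ``gene_to_group`` maps (species, gene_id) -> group.  A site is
    shared when two or more species have a called site in the same
    alignment column of the same group with the same strand class (sense
    vs antisense).  Returns per-species labels (aligned with the input site
    lists) and exclusive intersection counts keyed by species subsets — the
    numbers behind an UpSet plot.
    """
    keys: dict[str, list[object]] = {}
    for sp, sites in sites_per_species.items():
        sp_keys: list[object] = []
        for s in sites:
            key = None
            group = gene_to_group.get((sp, s.gene_id)) if s.gene_id else None
            if group is None:
                if s.gene_id is not None:
                    warnings.warn(
                        f"{sp}: site {s.position} in gene {s.gene_id} absent from "
                        "orthology; treated as specific"
                    )
            else:
                colmap = alignments.get(group, {}).get(sp)
                if colmap is not None and s.cds_offset is not None:
                    if 0 <= s.cds_offset < len(colmap):
                        col = colmap[s.cds_offset]
                        if col is not None:
                            klass = "antisense" if s.category == "antisense" else "sense"
                            key = (group, col, klass)
            sp_keys.append(key)
        keys[sp] = sp_keys

    presence: dict[object, set[str]] = {}
    for sp, sp_keys in keys.items():
        for key in sp_keys:
            if key is not None:
                presence.setdefault(key, set()).add(sp)

    labels: dict[str, list[str]] = {}
    for sp, sp_keys in keys.items():
        labels[sp] = [
            "shared" if key is not None and len(presence[key]) >= 2 else "specific"
            for key in sp_keys
        ]

    intersections: dict[frozenset, int] = {}
    for key, spset in presence.items():
        intersections[frozenset(spset)] = intersections.get(frozenset(spset), 0) + 1
    # a specific site without an alignment key still belongs to its species' singleton
    for sp, sp_keys in keys.items():
        n_unmapped = sum(1 for key in sp_keys if key is None)
        if n_unmapped:
            single = frozenset([sp])
            intersections[single] = intersections.get(single, 0) + n_unmapped
    return labels, intersections


def editing_summary(
    sites_per_species: Mapping[str, Sequence[EditingSite]],
    labels: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Per-species counts, category proportions and efficiency summaries."""
    rows = []
    for sp, sites in sites_per_species.items():
        cats = pd.Series([s.category for s in sites], dtype=object)
        n = len(sites)
        row = {
            "species": sp,
            "n_sites": n,
            "n_silent": int((cats == "silent").sum()),
            "n_non_silent": int((cats == "non_silent").sum()),
            "n_antisense": int((cats == "antisense").sum()),
            "n_noncoding": int((cats == "noncoding").sum()),
        }
        coding = row["n_silent"] + row["n_non_silent"] + row["n_antisense"]
        row["pct_non_silent"] = 100.0 * row["n_non_silent"] / coding if coding else 0.0
        row["pct_silent"] = 100.0 * row["n_silent"] / coding if coding else 0.0
        for cat in ("silent", "non_silent", "antisense"):
            effs = [s.efficiency for s in sites if s.category == cat]
            row[f"eff_median_{cat}"] = float(np.median(effs)) if effs else np.nan
        if labels is not None and sp in labels:
            lab = pd.Series(list(labels[sp]), dtype=object)
            row["n_shared"] = int((lab == "shared").sum())
            row["n_specific"] = int((lab == "specific").sum())
            row["pct_specific"] = 100.0 * row["n_specific"] / n if n else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("species")
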
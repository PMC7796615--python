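"""Synthetic plastomes, rearrangements, stranded transcriptomes and reads.

The generator emulates the structure of a conifer plastid transcriptome at
desk scale: a circular genome of operon-structured genes on both strands,
polycistronic transcription with probabilistic read-through past operon
terminators, pervasive low-level antisense/intergenic background (so the
combined-strand transcribed fraction approaches 100%), C-to-U edits injected
at set efficiencies, and dUTP-protocol strand-specific paired reads with
per-base substitution error, emitted directly as alignments.

Every operation is a pure function of its inputs and an explicit seed, and a
ground-truth manifest accompanies each simulated species so downstream
stages (coverage, expression, rearrangement distance, editing) can be tested
against known answers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .genome_io import CdsFeature, Plastome, StrandedAlignmentRecord, revcomp

__all__ = [
    "SimConfig",
    "Operon",
    "OperonModel",
    "TranscriptEntry",
    "TranscriptPool",
    "EditSpec",
    "TruthManifest",
    "SpeciesSim",
    "build_genome",
    "apply_inversions",
    "invert_interval",
    "derive_operons",
    "simulate_transcripts",
    "inject_edits",
    "choose_edit_sites",
    "expected_coverage",
    "expected_gene_abundance",
    "simulate_reads",
    "simulate_expression_counts",
    "simulate_species",
    "simulate_family",
]

# codons that never introduce a stop, so synthetic CDSs translate cleanly
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic species.

    Defaults are the desk-scale analogue of the study design: ~40 plastid
    CDSs in ~12 polycistronic units, strand-specific paired reads, Q30-like
    base error, modest read-through and pervasive low-level background
    transcription on both strands.
    """

    n_genes: int = 40
    n_operons: int = 12
    gene_length_range: tuple[int, int] = (300, 900)  # bp, forced to codon multiples
    intra_spacer_range: tuple[int, int] = (20, 60)
    inter_spacer_range: tuple[int, int] = (120, 300)
    k_inversions: int = 0
    n_read_pairs: int = 100_000
    read_length: int = 80
    fragment_length: int = 240
    base_error_rate: float = 0.001
    readthrough_prob: float = 0.2
    antisense_rate: float = 0.02
    operon_log_sd: float = 1.0  # lognormal sigma of operon transcription rates
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_operons <= 0 or self.n_operons > self.n_genes:
            raise ValueError("need 0 < n_operons <= n_genes")
        if not (0 <= self.base_error_rate < 0.1):
            raise ValueError("base_error_rate must be in [0, 0.1)")
        if not (0 <= self.readthrough_prob <= 1):
            raise ValueError("readthrough_prob must be in [0, 1]")
        if self.antisense_rate < 0:
            raise ValueError("antisense_rate must be >= 0")
        if self.read_length <= 0 or self.fragment_length < self.read_length:
            raise ValueError("need 0 < read_length <= fragment_length")


@dataclass(frozen=True)
class Operon:
    genes: tuple[str, ...]
    strand: str
    rate: float


@dataclass
class OperonModel:
    """Transcription model: polycistronic units plus global parameters."""

    operons: list[Operon]
    readthrough_prob: float = 0.2
    antisense_rate: float = 0.02

    def __post_init__(self) -> None:
        if any(o.rate < 0 for o in self.operons):
            raise ValueError("operon rates must be >= 0")
        if not (0 <= self.readthrough_prob <= 1) or self.antisense_rate < 0:
            raise ValueError("invalid model probabilities")

    @property
    def gene_rates(self) -> dict[str, float]:
        return {g: o.rate for o in self.operons for g in o.genes}


@dataclass(frozen=True)
class TranscriptEntry:
    """One transcript species: an interval, a strand, and a relative density.

    ``weight`` is an expected per-copy density; fragments are sampled from
    entries with probability proportional to ``weight * length``.
    """

    start: int
    end: int
    strand: str
    weight: float
    kind: str = "operon"  # operon | readthrough | background


@dataclass(frozen=True)
class EditSpec:
    position: int  # 0-based, plus-strand coordinate
    strand: str  # transcript strand carrying the C
    efficiency: float

    def __post_init__(self) -> None:
        if not (0 <= self.efficiency <= 1):
            raise ValueError("efficiency must be in [0, 1]")


@dataclass
class TranscriptPool:
    genome: Plastome
    entries: list[TranscriptEntry]
    edits: list[EditSpec] = field(default_factory=list)


@dataclass
class TruthManifest:
    """Ground truth for one simulated species."""

    species: str
    gene_rates: dict[str, float]
    gene_abundance: dict[str, float] = field(default_factory=dict)
    inversions: list[tuple[int, int]] = field(default_factory=list)
    edit_sites: list[EditSpec] = field(default_factory=list)
    n_read_pairs: int = 0


@dataclass
class SpeciesSim:
    """Everything simulated for one species."""

    genome: Plastome
    model: OperonModel
    pool: TranscriptPool
    records: list[StrandedAlignmentRecord]
    manifest: TruthManifest
    config: SimConfig


# ---------------------------------------------------------------------------
# genome construction


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """A CDS of ``length`` bp (codon multiple) with no internal stop."""
    n_codons = max(3, length // 3)
    inner = rng.choice(_SENSE_CODONS, size=n_codons - 2)
    return "ATG" + "".join(inner) + "TAA"


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def build_genome(config: SimConfig) -> tuple[Plastome, OperonModel, TruthManifest]:
    """Build a circular operon-structured genome; deterministic given the seed.

    Genes are grouped into ``n_operons`` contiguous same-strand units with
    short intra-operon spacers and longer inter-operon spacers.  The genome
    starts and ends with spacer sequence, so no feature wraps the origin.
    """
    rng = np.random.default_rng(config.seed)
    sizes = np.full(config.n_operons, config.n_genes // config.n_operons)
    sizes[: config.n_genes % config.n_operons] += 1
    strands = rng.choice(["+", "-"], size=config.n_operons)
    rates = np.exp(rng.normal(0.0, config.operon_log_sd, size=config.n_operons))

    parts: list[str] = [_random_seq(rng, int(rng.integers(*config.inter_spacer_range)))]
    pos = len(parts[0])
    features: list[CdsFeature] = []
    operons: list[Operon] = []
    gene_no = 0
    for oi in range(config.n_operons):
        members: list[str] = []
        for gi in range(int(sizes[oi])):
            if gi > 0:
                spacer = _random_seq(rng, int(rng.integers(*config.intra_spacer_range)))
                parts.append(spacer)
                pos += len(spacer)
            glen = int(rng.integers(*config.gene_length_range)) // 3 * 3
            cds = _random_cds(rng, glen)
            gene_id = f"g{gene_no:03d}"
            gene_no += 1
            seq = cds if strands[oi] == "+" else revcomp(cds)
            parts.append(seq)
            features.append(
                CdsFeature(gene_id, pos, pos + len(seq), str(strands[oi]))
            )
            pos += len(seq)
            members.append(gene_id)
        if oi < config.n_operons - 1:
            spacer = _random_seq(rng, int(rng.integers(*config.inter_spacer_range)))
            parts.append(spacer)
            pos += len(spacer)
        operons.append(Operon(tuple(members), str(strands[oi]), float(rates[oi])))
    parts.append(_random_seq(rng, int(rng.integers(*config.inter_spacer_range))))

    genome = Plastome(id=f"sim{config.seed}", sequence="".join(parts), features=features)
    model = OperonModel(operons, config.readthrough_prob, config.antisense_rate)
    manifest = TruthManifest(species=genome.id, gene_rates=model.gene_rates)
    return genome, model, manifest


# ---------------------------------------------------------------------------
# inversions


@dataclass
class _Unit:
    kind: str  # 'gene' | 'spacer'
    seq: str
    gene_id: str | None = None
    strand: str = "+"
    pristine: bool = False  # spacer eligible as a fresh inversion endpoint


def _genome_to_units(genome: Plastome) -> list[_Unit]:
    feats = sorted(genome.features, key=lambda f: f.start)
    if any(f.wraps_origin for f in feats):
        raise ValueError("unit decomposition requires non-wrapping features")
    units: list[_Unit] = []
    pos = 0
    for f in feats:
        if f.start > pos:
            units.append(_Unit("spacer", genome.sequence[pos : f.start], pristine=True))
        elif f.start < pos:
            raise ValueError(f"overlapping features at {f.gene_id}")
        units.append(_Unit("gene", genome.sequence[f.start : f.end], f.gene_id, f.strand))
        pos = f.end
    if pos < genome.length:
        units.append(_Unit("spacer", genome.sequence[pos:], pristine=True))
    # the first and last spacers flank the origin of the circle; keep them
    # out of the eligible endpoint set so inversions never wrap
    if units and units[0].kind == "spacer":
        units[0].pristine = False
    if units and units[-1].kind == "spacer":
        units[-1].pristine = False
    return units


def _units_to_genome(units: list[_Unit], genome_id: str) -> Plastome:
    seq_parts: list[str] = []
    features: list[CdsFeature] = []
    pos = 0
    for u in units:
        if u.kind == "gene":
            features.append(CdsFeature(u.gene_id, pos, pos + len(u.seq), u.strand))
        seq_parts.append(u.seq)
        pos += len(u.seq)
    return Plastome(id=genome_id, sequence="".join(seq_parts), features=features)


def apply_inversions(
    genome: Plastome, k: int, seed: int
) -> tuple[Plastome, list[tuple[int, int]]]:
    """Apply ``k`` segment inversions with endpoints in intergenic spacers.

    Each inversion cuts two distinct, previously uncut spacers at their
    midpoints and reverse-complements the segment between, flipping the
    strand of every contained gene.  Because every endpoint is fresh, each
    inversion breaks two previously intact gene adjacencies and creates two
    new ones, so the derived genome sits at DCJ distance exactly ``k`` from
    the original.  Returns the derived genome and the log of inverted
    ``(start, end)`` intervals in the coordinates at time of application.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    rng = np.random.default_rng(seed)
    units = _genome_to_units(genome)
    log: list[tuple[int, int]] = []
    for _ in range(k):
        eligible = [
            i for i, u in enumerate(units) if u.kind == "spacer" and u.pristine and len(u.seq) >= 2
        ]
        if len(eligible) < 2:
            raise ValueError(
                f"not enough uncut spacers for {k} inversions (ran out after {len(log)})"
            )
        p, q = sorted(rng.choice(eligible, size=2, replace=False))
        offsets = np.cumsum([0] + [len(u.seq) for u in units])
        mid_p, mid_q = len(units[p].seq) // 2, len(units[q].seq) // 2
        start_bp = int(offsets[p]) + mid_p
        end_bp = int(offsets[q]) + mid_q
        left_p = _Unit("spacer", units[p].seq[:mid_p])
        right_p = _Unit("spacer", units[p].seq[mid_p:])
        left_q = _Unit("spacer", units[q].seq[:mid_q])
        right_q = _Unit("spacer", units[q].seq[mid_q:])
        segment = [right_p] + units[p + 1 : q] + [left_q]
        inverted = []
        for u in reversed(segment):
            inverted.append(
                _Unit(
                    u.kind,
                    revcomp(u.seq),
                    u.gene_id,
                    ("-" if u.strand == "+" else "+") if u.kind == "gene" else "+",
                    u.pristine,
                )
            )
        units = units[:p] + [left_p] + inverted + [right_q] + units[q + 1 :]
        log.append((start_bp, end_bp))
    derived = _units_to_genome(units, genome.id)
    return derived, log


def invert_interval(genome: Plastome, start: int, end: int) -> Plastome:
    """Reverse-complement ``[start, end)`` and remap the contained features.

    An involution: applying it twice with the same interval restores the
    genome.  Features straddling a cut point are an error.
    """
    if not (0 <= start < end <= genome.length):
        raise ValueError("interval out of bounds")
    new_feats: list[CdsFeature] = []
    for f in genome.features:
        if f.end <= start or f.start >= end:
            new_feats.append(f)
        elif start <= f.start and f.end <= end:
            new_feats.append(
                CdsFeature(
                    f.gene_id,
                    start + (end - f.end),
                    start + (end - f.start),
                    "-" if f.strand == "+" else "+",
                )
            )
        else:
            raise ValueError(f"feature {f.gene_id} straddles an inversion endpoint")
    seq = genome.sequence[:start] + revcomp(genome.sequence[start:end]) + genome.sequence[end:]
    new_feats.sort(key=lambda f: f.start)
    return Plastome(id=genome.id, sequence=seq, features=new_feats)


# ---------------------------------------------------------------------------
# transcription


def derive_operons(
    genome: Plastome,
    gene_rates: Mapping[str, float],
    readthrough_prob: float,
    antisense_rate: float,
    max_operon_gap: int = 80,
) -> OperonModel:
    """Re-derive polycistronic units from gene positions.

    Consecutive same-strand genes separated by at most ``max_operon_gap`` bp
    form one unit; the unit's rate is the geometric mean of its members'
    rates.  Used after rearrangement, where relocation re-wires which genes
    share a transcription unit — the mechanism by which rearrangement
    perturbs expression.
    """
    feats = sorted(genome.features, key=lambda f: f.start)
    groups: list[list[CdsFeature]] = []
    for f in feats:
        if (
            groups
            and groups[-1][-1].strand == f.strand
            and f.start - groups[-1][-1].end <= max_operon_gap
        ):
            groups[-1].append(f)
        else:
            groups.append([f])
    operons = []
    for grp in groups:
        logs = [math.log(max(gene_rates[f.gene_id], 1e-300)) for f in grp]
        rate = math.exp(sum(logs) / len(logs))
        operons.append(Operon(tuple(f.gene_id for f in grp), grp[0].strand, rate))
    return OperonModel(operons, readthrough_prob, antisense_rate)


def simulate_transcripts(
    genome: Plastome, model: OperonModel, seed: int | None = None
) -> TranscriptPool:
    """Expected transcript pool under the read-through model.

    Each operon contributes its primary transcript at its rate; with
    probability ``readthrough_prob`` transcription continues past the
    terminator into the next downstream unit (geometric continuation, two
    levels retained); a genome-wide background on each strand at
    ``antisense_rate`` times the mean operon rate models pervasive
    antisense/intergenic transcription.  The pool is deterministic; ``seed``
    is accepted for interface symmetry.
    """
    if not model.operons or all(o.rate == 0 for o in model.operons) and model.antisense_rate == 0:
        raise ValueError("all transcription rates are zero")
    feats = {f.gene_id: f for f in genome.features}
    spans = []
    for op in model.operons:
        starts = [feats[g].start for g in op.genes]
        ends = [feats[g].end for g in op.genes]
        spans.append((min(starts), max(ends)))
    order = sorted(range(len(model.operons)), key=lambda i: spans[i][0])

    entries: list[TranscriptEntry] = []
    for idx_pos, oi in enumerate(order):
        op = model.operons[oi]
        if op.rate == 0:
            continue
        s, e = spans[oi]
        entries.append(TranscriptEntry(s, e, op.strand, op.rate, "operon"))
        if model.readthrough_prob > 0:
            # extend into up to two downstream units in the direction of
            # transcription; clamped at the genome ends (origin spacer)
            cur_s, cur_e = s, e
            w = op.rate
            for level in range(1, 3):
                w *= model.readthrough_prob
                if op.strand == "+":
                    nxt = idx_pos + level
                    if nxt >= len(order):
                        break
                    cur_e = spans[order[nxt]][1]
                else:
                    nxt = idx_pos - level
                    if nxt < 0:
                        break
                    cur_s = spans[order[nxt]][0]
                entries.append(
                    TranscriptEntry(cur_s, cur_e, op.strand, w, "readthrough")
                )
    if model.antisense_rate > 0:
        mean_rate = float(np.mean([o.rate for o in model.operons]))
        bg = model.antisense_rate * mean_rate
        entries.append(TranscriptEntry(0, genome.length, "+", bg, "background"))
        entries.append(TranscriptEntry(0, genome.length, "-", bg, "background"))
    if not entries:
        raise ValueError("empty transcript pool")
    return TranscriptPool(genome=genome, entries=entries)


def inject_edits(pool: TranscriptPool, sites: Sequence[EditSpec]) -> TranscriptPool:
    """Attach C-to-U edit sites to the pool after validating the reference base.

    A '+' site requires a plus-strand C; a '−' site requires a plus-strand G
    (the C sits on the minus strand).  Each transcript fragment covering a
    site carries the edit independently with probability ``efficiency``.
    """
    for s in sites:
        ref = pool.genome.sequence[s.position]
        needed = "C" if s.strand == "+" else "G"
        if ref != needed:
            raise ValueError(
                f"edit site {s.position}{s.strand}: reference base {ref}, "
                f"but a {needed} is required for C-to-U on that strand"
            )
    return TranscriptPool(pool.genome, list(pool.entries), list(pool.edits) + list(sites))


# ---------------------------------------------------------------------------
# expectations (the manifest's oracle)


def _entry_geometry(pool: TranscriptPool, config: SimConfig):
    entries = pool.entries
    lens = np.array([e.end - e.start for e in entries])
    if (lens < config.read_length).any():
        raise ValueError("read_length exceeds a transcript length")
    frag = np.minimum(config.fragment_length, lens)
    windows = lens - frag + 1
    weights = np.array([e.weight * (e.end - e.start) for e in entries], dtype=float)
    probs = weights / weights.sum()
    return entries, frag, windows, probs


def expected_coverage(pool: TranscriptPool, config: SimConfig) -> dict[str, np.ndarray]:
    """Exact expected per-base read coverage per strand for the pool.

    For each entry, fragment starts are uniform over its window; each
    fragment contributes one read at each end.  Returned per plus-strand
    position for transcript strands '+' and '-'.
    """
    L = pool.genome.length
    entries, frag, windows, probs = _entry_geometry(pool, config)
    cov = {"+": np.zeros(L), "-": np.zeros(L)}
    rl = config.read_length
    for e, F, W, p in zip(entries, frag, windows, probs):
        per_start = config.n_read_pairs * p / W
        kernel = np.zeros(int(F))
        kernel[:rl] += 1.0
        kernel[int(F) - rl :] += 1.0
        contrib = np.convolve(np.full(int(W), per_start), kernel)
        cov[e.strand][e.start : e.start + int(W) + int(F) - 1] += contrib
    return cov


def expected_gene_abundance(pool: TranscriptPool, config: SimConfig) -> dict[str, float]:
    """Expected mean sense coverage over each gene body (TPM's target rank)."""
    cov = expected_coverage(pool, config)
    out = {}
    for f in pool.genome.features:
        out[f.gene_id] = float(cov[f.strand][f.start : f.end].mean())
    return out


# ---------------------------------------------------------------------------
# reads


def choose_edit_sites(
    pool: TranscriptPool,
    n_sites: int,
    seed: int,
    config: SimConfig,
    efficiency_range: tuple[float, float] = (0.2, 0.9),
    min_expected_coverage: float = 100.0,
    strand: str | None = None,
) -> list[EditSpec]:
    """Pick editable CDS positions (sense strand) with adequate coverage.

    Candidates are plus-strand C inside '+' CDSs ('+' transcript strand) and
    plus-strand G inside '-' CDSs ('-' transcript strand), restricted to
    positions whose expected sense coverage clears the floor.  ``strand``
    restricts to one transcript strand.
    """
    rng = np.random.default_rng(seed)
    cov = expected_coverage(pool, config)
    seq = pool.genome.sequence
    candidates: list[tuple[int, str]] = []
    for f in pool.genome.features:
        needed = "C" if f.strand == "+" else "G"
        if strand is not None and f.strand != strand:
            continue
        for pos in range(f.start, f.end):
            if seq[pos] == needed and cov[f.strand][pos] >= min_expected_coverage:
                candidates.append((pos, f.strand))
    if len(candidates) < n_sites:
        raise ValueError(
            f"only {len(candidates)} editable positions clear coverage "
            f">= {min_expected_coverage}; asked for {n_sites}"
        )
    idx = rng.choice(len(candidates), size=n_sites, replace=False)
    effs = rng.uniform(*efficiency_range, size=n_sites)
    return [
        EditSpec(candidates[i][0], candidates[i][1], float(e))
        for i, e in zip(sorted(idx, key=lambda i: candidates[i][0]), effs)
    ]


def simulate_reads(
    pool: TranscriptPool, config: SimConfig, seed: int | None = None
) -> list[StrandedAlignmentRecord]:
    """Simulate dUTP strand-specific read pairs as aligned SAM-like records.

    Fragments are drawn from pool entries with probability proportional to
    weight x length, with uniform starts.  Each fragment yields one read at
    each end with the FR layout that makes ``read_sam`` under
    ``fr-firststrand`` recover the fragment's transcript strand: for a '+'
    fragment, read 2 maps forward at the left end and read 1 reverse at the
    right end; mirrored for '-'.  Edits are sampled once per fragment (both
    mates agree); substitution errors are applied per base at
    ``base_error_rate``.
    """
    if config.n_read_pairs <= 0:
        raise ValueError("n_read_pairs must be > 0")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    entries, frag, windows, probs = _entry_geometry(pool, config)
    counts = rng.multinomial(config.n_read_pairs, probs)
    rl = config.read_length
    genome_seq = pool.genome.sequence
    edits_by_strand = {
        "+": [s for s in pool.edits if s.strand == "+"],
        "-": [s for s in pool.edits if s.strand == "-"],
    }

    records: list[StrandedAlignmentRecord] = []
    pair_no = 0
    for e, F, W, c in zip(entries, frag, windows, counts):
        if c == 0:
            continue
        starts = e.start + rng.integers(0, int(W), size=int(c))
        F = int(F)
        strand_edits = [
            s for s in edits_by_strand[e.strand] if e.start <= s.position < e.end
        ]
        for fs in starts:
            fs = int(fs)
            left = genome_seq[fs : fs + rl]
            right = genome_seq[fs + F - rl : fs + F]
            if strand_edits:
                for site in strand_edits:
                    if fs <= site.position < fs + F and rng.random() < site.efficiency:
                        sub = "T" if site.strand == "+" else "A"
                        off = site.position - fs
                        if off < rl:
                            left = left[:off] + sub + left[off + 1 :]
                        off2 = site.position - (fs + F - rl)
                        if 0 <= off2 < rl:
                            right = right[:off2] + sub + right[off2 + 1 :]
            if config.base_error_rate > 0:
                left = _with_errors(left, rng, config.base_error_rate)
                right = _with_errors(right, rng, config.base_error_rate)
            name = f"{pool.genome.id}_p{pair_no:07d}"
            pair_no += 1
            if e.strand == "+":
                r2 = (left, fs, False, False)  # seq, pos, read1?, reverse?
                r1 = (right, fs + F - rl, True, True)
            else:
                r1 = (left, fs, True, False)
                r2 = (right, fs + F - rl, False, True)
            for seq_, pos_, is1, rev in (r1, r2):
                records.append(
                    StrandedAlignmentRecord(
                        read_id=name,
                        ref_id=pool.genome.id,
                        ref_start=pos_,
                        cigar=[("M", rl)],
                        seq=seq_,
                        transcript_strand=e.strand,
                        is_read1=is1,
                        is_reverse=rev,
                        is_paired=True,
                    )
                )
    return records


def _with_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    arr = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[int(rng.integers(3))]
    return "".join(arr)


def simulate_expression_counts(
    pool: TranscriptPool, config: SimConfig, seed: int | None = None
) -> dict[str, int]:
    """Fast path: multinomial per-gene sense read counts from the pool.

    Skips base-level read construction; counts follow the same expected
    per-gene abundance as full read simulation.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    abundance = expected_gene_abundance(pool, config)
    genes = list(abundance)
    lengths = np.array([f.end - f.start for f in pool.genome.features], dtype=float)
    expected_reads = np.array([abundance[g] for g in genes]) * lengths / config.read_length
    total = expected_reads.sum()
    if total == 0:
        return {g: 0 for g in genes}
    n_reads = int(round(total))
    counts = rng.multinomial(n_reads, expected_reads / total)
    return dict(zip(genes, (int(c) for c in counts)))


# ---------------------------------------------------------------------------
# whole-species and whole-family bundles


def simulate_species(
    config: SimConfig,
    n_edit_sites: int = 0,
    efficiency_range: tuple[float, float] = (0.2, 0.9),
    min_edit_coverage: float = 100.0,
    edit_strand: str | None = None,
    species_id: str | None = None,
) -> SpeciesSim:
    """Build one species end-to-end: genome, inversions, transcripts, edits, reads."""
    rng = np.random.default_rng(config.seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=4)]
    genome, model, manifest = build_genome(replace(config, seed=sub[0]))
    if species_id:
        genome = Plastome(id=species_id, sequence=genome.sequence, features=genome.features)
        manifest.species = species_id
    inv_log: list[tuple[int, int]] = []
    if config.k_inversions > 0:
        genome, inv_log = apply_inversions(genome, config.k_inversions, seed=sub[1])
        model = derive_operons(
            genome, model.gene_rates, config.readthrough_prob, config.antisense_rate
        )
    pool = simulate_transcripts(genome, model)
    if n_edit_sites > 0:
        sites = choose_edit_sites(
            pool,
            n_edit_sites,
            seed=sub[2],
            config=config,
            efficiency_range=efficiency_range,
            min_expected_coverage=min_edit_coverage,
            strand=edit_strand,
        )
        pool = inject_edits(pool, sites)
    records = simulate_reads(pool, config, seed=sub[3])
    manifest.inversions = inv_log
    manifest.edit_sites = list(pool.edits)
    manifest.gene_abundance = expected_gene_abundance(pool, config)
    manifest.n_read_pairs = config.n_read_pairs
    return SpeciesSim(genome, model, pool, records, manifest, config)


def simulate_family(
    config: SimConfig,
    k_inversions: Sequence[int] = (0, 1, 2, 3, 4, 5),
    coupling: str = "coupled",
    per_inversion_sd: float = 0.35,
    seed: int = 0,
    reads: bool = False,
    n_edit_sites: int = 0,
    efficiency_range: tuple[float, float] = (0.2, 0.9),
    min_edit_coverage: float = 100.0,
) -> dict[str, SpeciesSim]:
    """Simulate a family of species derived from one ancestral genome.

    Species ``i`` receives ``k_inversions[i]`` inversions from the shared
    ancestor.  Under ``coupling='coupled'``, transcription units are
    re-derived from each rearranged genome (relocated genes acquire new
    operon contexts and read-through neighbours) and each species' per-gene
    log-transcription rates are additionally perturbed with standard
    deviation ``per_inversion_sd * sqrt(k)`` — expression divergence grows
    with rearrangement count, the study's alternative hypothesis.  Under
    ``'uncoupled'`` transcription is position-insensitive — every gene is
    its own transcription unit with no read-through, so rearrangement
    cannot affect expression — and every species receives the same
    perturbation magnitude (``per_inversion_sd * sqrt(mean k)``): the null,
    in which expression divergence and rearrangement count are independent.

    With ``reads=False`` expression counts come from the fast multinomial
    path; full read simulation is used otherwise.
    """
    if coupling not in ("coupled", "uncoupled"):
        raise ValueError(f"unknown coupling {coupling!r}")
    master = np.random.default_rng(seed)
    base_cfg = replace(config, seed=int(master.integers(0, 2**31 - 1)))
    base_genome, base_model, _ = build_genome(base_cfg)
    base_log = {g: math.log(r) for g, r in base_model.gene_rates.items()}
    mean_k = float(np.mean(list(k_inversions)))

    out: dict[str, SpeciesSim] = {}
    for i, k in enumerate(k_inversions):
        sp = f"sp{i}"
        rng = np.random.default_rng(int(master.integers(0, 2**31 - 1)))
        genome = Plastome(id=sp, sequence=base_genome.sequence, features=base_genome.features)
        inv_log: list[tuple[int, int]] = []
        if k > 0:
            genome, inv_log = apply_inversions(genome, k, seed=int(rng.integers(0, 2**31 - 1)))
        genes = list(base_log)
        if coupling == "coupled":
            sd = per_inversion_sd * math.sqrt(k)
            delta = rng.normal(0.0, sd, size=len(genes)) if sd > 0 else np.zeros(len(genes))
        else:
            # equal divergence for every species: the perturbation vector is
            # scaled to an exact common norm, so no species diverges more
            # than another and the null carries no rearrangement signal
            sd = per_inversion_sd * math.sqrt(mean_k)
            delta = rng.normal(0.0, 1.0, size=len(genes))
            delta *= sd * math.sqrt(len(genes)) / np.linalg.norm(delta)
        rates = {g: math.exp(base_log[g] + d) for g, d in zip(genes, delta)}
        if coupling == "coupled":
            model = derive_operons(
                genome, rates, config.readthrough_prob, config.antisense_rate
            )
        else:
            # position-insensitive transcription: one unit per gene, no
            # read-through, so rearrangement cannot touch expression
            model = OperonModel(
                [
                    Operon((f.gene_id,), f.strand, rates[f.gene_id])
                    for f in sorted(genome.features, key=lambda f: f.start)
                ],
                readthrough_prob=0.0,
                antisense_rate=config.antisense_rate,
            )
        pool = simulate_transcripts(genome, model)
        cfg_i = replace(config, k_inversions=k)
        if n_edit_sites > 0:
            sites = choose_edit_sites(
                pool,
                n_edit_sites,
                seed=int(rng.integers(0, 2**31 - 1)),
                config=cfg_i,
                efficiency_range=efficiency_range,
                min_expected_coverage=min_edit_coverage,
            )
            pool = inject_edits(pool, sites)
        records = (
            simulate_reads(pool, cfg_i, seed=int(rng.integers(0, 2**31 - 1))) if reads else []
        )
        manifest = TruthManifest(
            species=sp,
            gene_rates=rates,
            gene_abundance=expected_gene_abundance(pool, cfg_i),
            inversions=inv_log,
            edit_sites=list(pool.edits),
            n_read_pairs=cfg_i.n_read_pairs if reads else 0,
        )
        out[sp] = SpeciesSim(genome, model, pool, records, manifest, cfg_i)
    return out
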
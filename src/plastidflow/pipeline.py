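"""End-to-end orchestration: simulate -> profile -> express -> rearrange ->
edit -> associate, driven by one config with one seed.

The demo workflow simulates a family of species from a common ancestral
plastome, each separated by a known number of inversions, then runs every
analysis stage and assembles the per-pair table and the two headline
Pearson tests.  All stage outputs are plain TSV/JSON; a run manifest
records the seed, parameters and output checksums so a rerun with the same
config is reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import association, coverage_profile, editing, expression, rearrangement
from . import synthetic_data as sd
from .genome_io import (
    StrandedAlignmentRecord,
    read_newick,
    write_fasta,
    write_gff3,
    write_sam,
)

__all__ = [
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
    "subsample_reads",
    "random_star_tree",
    "family_headline",
]

log = logging.getLogger("plastidflow")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int = 0
    outdir: str = "plastidflow_out"
    k_inversions: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    coupling: str = "coupled"
    per_inversion_sd: float = 0.35
    n_edit_sites: int = 5
    # expected-coverage floor when placing synthetic edit sites; keep above
    # the caller's min_coverage so injected sites are callable at all
    edit_min_coverage: float = 60.0
    sim: sd.SimConfig = field(default_factory=sd.SimConfig)
    caller: editing.CallerConfig = field(default_factory=editing.CallerConfig)
    distance: str = "dcj"
    window: int = 100
    subsample: int | None = None
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "coverage": True,
            "expression": True,
            "rearrangement": True,
            "editing": True,
            "association": True,
        }
    )
    tree: str | None = None  # newick path; a random star tree if absent

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            sim = sd.SimConfig(**raw.pop("sim", {}))
            caller = editing.CallerConfig(**raw.pop("caller", {}))
            stages = {**cls().stages, **raw.pop("stages", {})}
            k = tuple(raw.pop("k_inversions", (0, 1, 2, 3, 4, 5)))
            return cls(sim=sim, caller=caller, stages=stages, k_inversions=k, **raw)
        except TypeError as exc:
            raise ValueError(f"bad run config {path}: {exc}") from exc


@dataclass
class PipelineResult:
    outdir: Path
    species: list[str]
    expression_tables: dict[str, expression.ExpressionTable] = field(default_factory=dict)
    rearrangement_matrix: pd.DataFrame | None = None
    breakpoint_matrix: pd.DataFrame | None = None
    pair_table: pd.DataFrame | None = None
    headline: dict[str, association.CorrelationResult] | None = None
    editing_sites: dict[str, list[editing.EditingSite]] = field(default_factory=dict)
    editing_summary: pd.DataFrame | None = None
    transcribed_fractions: dict[str, tuple[float, float, float]] = field(default_factory=dict)


def random_star_tree(species: Sequence[str], seed: int, mean_length: float = 0.05) -> str:
    """Newick star tree with lognormal branch lengths (substitutions/site).

    Sequence divergence in the simulator is independent of rearrangement
    count, mirroring the observation that genetic distance and rearrangement
    count need not track each other.
    """
    rng = np.random.default_rng(seed)
    lens = mean_length * rng.lognormal(0.0, 0.5, size=len(species))
    inner = ",".join(f"{sp}:{l:.6f}" for sp, l in zip(species, lens))
    return f"({inner});"


def subsample_reads(
    records: Sequence[StrandedAlignmentRecord], n: int, seed: int
) -> list[StrandedAlignmentRecord]:
    """Uniform sample of ``n`` read pairs without replacement, mate-consistent."""
    ids: list[str] = []
    seen = set()
    for rec in records:
        if rec.read_id not in seen:
            seen.add(rec.read_id)
            ids.append(rec.read_id)
    if n > len(ids):
        raise ValueError(f"requested {n} pairs but only {len(ids)} available")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    keep = set(rng.choice(len(ids), size=n, replace=False))
    chosen = {ids[i] for i in keep}
    return [rec for rec in records if rec.read_id in chosen]


def _md5(path: Path) -> str:
    h = hashlib.md5()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run all enabled stages; see the module docstring for the layout."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage_seed = {s: int(x) for s, x in zip(
        ("family", "tree", "subsample"), rng.integers(0, 2**31 - 1, size=3)
    )}

    log.info("simulating %d species, k=%s", len(config.k_inversions), config.k_inversions)
    family = sd.simulate_family(
        config.sim,
        k_inversions=config.k_inversions,
        coupling=config.coupling,
        per_inversion_sd=config.per_inversion_sd,
        seed=stage_seed["family"],
        reads=True,
        n_edit_sites=config.n_edit_sites,
        min_edit_coverage=config.edit_min_coverage,
    )
    species = list(family)
    result = PipelineResult(outdir=out, species=species)

    for sp, sim in family.items():
        spdir = out / sp
        spdir.mkdir(exist_ok=True)
        write_fasta(spdir / f"{sp}.fasta", [(sp, sim.genome.sequence)])
        write_gff3(spdir / f"{sp}.gff3", sim.genome)
        records = sim.records
        if config.subsample is not None:
            records = subsample_reads(records, config.subsample, stage_seed["subsample"])
        write_sam(spdir / f"{sp}.sam", records, sp, sim.genome.length)
        _write_manifest_tsv(spdir / f"{sp}.truth.tsv", sim)
        log.info("%s: %d genes, %d read records", sp, len(sim.genome.features), len(records))

    if config.stages.get("coverage", True):
        for sp, sim in family.items():
            cov = coverage_profile.per_base_coverage(sim.records, sim.genome)
            frames = [
                coverage_profile.window_scores(cov[s], config.window).to_frame()
                for s in ("+", "-")
            ]
            pd.concat(frames).to_csv(out / sp / f"{sp}.coverage.tsv", sep="\t", index=False)
            result.transcribed_fractions[sp] = coverage_profile.transcribed_fraction(cov)
        pd.DataFrame(
            result.transcribed_fractions, index=["plus", "minus", "combined"]
        ).T.to_csv(out / "transcribed_fractions.tsv", sep="\t")

    if config.stages.get("expression", True):
        for sp, sim in family.items():
            table = expression.expression_table(
                sim.records, sim.genome.features, sp, sim.genome
            )
            table.to_tsv(out / sp / f"{sp}.expression.tsv")
            result.expression_tables[sp] = table

    if config.stages.get("rearrangement", True):
        orders = {sp: rearrangement.genome_to_gene_order(s.genome) for sp, s in family.items()}
        blocks, signed = rearrangement.find_synteny_blocks(orders)
        log.info("%d synteny blocks across %d species", len(blocks), len(species))
        result.rearrangement_matrix = rearrangement.pairwise_matrix(signed, config.distance)
        result.breakpoint_matrix = rearrangement.pairwise_matrix(signed, "breakpoint")
        result.rearrangement_matrix.to_csv(out / "rearrangement_dcj.tsv", sep="\t")
        result.breakpoint_matrix.to_csv(out / "rearrangement_breakpoint.tsv", sep="\t")
        block_rows = [
            {"species": sp, "order_index": i, "block": b}
            for sp, g in signed.items()
            for i, b in enumerate(g.blocks)
        ]
        pd.DataFrame(block_rows).to_csv(out / "synteny_blocks.tsv", sep="\t", index=False)

    if config.stages.get("editing", True):
        gene_to_group: dict[tuple[str, str], str] = {}
        group_seqs: dict[str, dict[str, str]] = {}
        for sp, sim in family.items():
            for f in sim.genome.features:
                gene_to_group[(sp, f.gene_id)] = f.gene_id
                group_seqs.setdefault(f.gene_id, {})[sp] = sim.genome.cds_sequence(f)
        for sp, sim in family.items():
            pileup = editing.build_pileup(sim.records, sim.genome)
            sites = editing.call_c2u(pileup, sim.genome, config.caller)
            sites = editing.classify_sites(sites, sim.genome.features, sim.genome)
            result.editing_sites[sp] = sites
        touched = {
            s.gene_id for sites in result.editing_sites.values() for s in sites if s.gene_id
        }
        alignments = {g: editing.align_orthologs(group_seqs[g]) for g in sorted(touched)}
        labels, intersections = editing.shared_specific(
            result.editing_sites, alignments, gene_to_group
        )
        result.editing_summary = editing.editing_summary(result.editing_sites, labels)
        result.editing_summary.to_csv(out / "editing_summary.tsv", sep="\t")
        site_rows = []
        for sp, sites in result.editing_sites.items():
            for s, lab in zip(sites, labels[sp]):
                site_rows.append(
                    {
                        "species": sp,
                        "position": s.position,
                        "strand": s.transcript_strand,
                        "edited": s.edited_count,
                        "unedited": s.unedited_count,
                        "efficiency": s.efficiency,
                        "p_value": s.p_value,
                        "category": s.category,
                        "gene": s.gene_id,
                        "codon_position": s.codon_position,
                        "aa_change": s.aa_change,
                        "sharing": lab,
                    }
                )
        pd.DataFrame(site_rows).to_csv(out / "editing_sites.tsv", sep="\t", index=False)
        inter_rows = [
            {"species_set": "&".join(sorted(k)), "n_sites": v}
            for k, v in sorted(intersections.items(), key=lambda kv: (-kv[1], len(kv[0])))
        ]
        pd.DataFrame(inter_rows).to_csv(out / "editing_intersections.tsv", sep="\t", index=False)

    if config.stages.get("association", True):
        if not result.expression_tables or result.rearrangement_matrix is None:
            raise RuntimeError("association stage requires expression and rearrangement stages")
        ortho = expression.OrthologyMap.identity(
            [f.gene_id for f in family[species[0]].genome.features], species
        )
        expr_corrs = {}
        for a, b in itertools.combinations(species, 2):
            r, _, _ = expression.ortholog_expression_correlation(
                result.expression_tables[a], result.expression_tables[b], ortho
            )
            expr_corrs[(a, b)] = r
        if config.tree:
            tree = read_newick(config.tree)
        else:
            nwk = random_star_tree(species, stage_seed["tree"])
            (out / "tree.nwk").write_text(nwk + "\n")
            tree = read_newick(out / "tree.nwk")
        dist = association.patristic_distances(tree, species)
        result.pair_table = association.build_pair_table(
            expr_corrs, result.rearrangement_matrix, dist
        )
        result.pair_table.to_csv(out / "pair_table.tsv", sep="\t", index=False)
        result.headline = association.headline_analysis(result.pair_table)
        summary = {
            name: {"r": res.r, "n": res.n, "p": res.p}
            for name, res in result.headline.items()
        }
        (out / "headline.json").write_text(json.dumps(summary, indent=2) + "\n")

    _write_run_manifest(out, config)
    return result


def family_headline(
    config: sd.SimConfig | None = None,
    coupling: str = "coupled",
    seed: int = 0,
    k_inversions: Sequence[int] = (0, 1, 2, 3, 4, 5),
    per_inversion_sd: float = 0.35,
) -> dict[str, association.CorrelationResult]:
    """One family simulation and its two headline Pearson tests.

    Uses the fast multinomial expression path (no base-level reads), so
    repeated runs across many seeds are cheap.  Genetic distances come from
    a random star tree: sequence divergence in the simulator is independent
    of rearrangement count by construction.
    """
    config = config or sd.SimConfig()
    rng = np.random.default_rng(seed)
    fam = sd.simulate_family(
        config,
        k_inversions=k_inversions,
        coupling=coupling,
        per_inversion_sd=per_inversion_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    species = list(fam)
    tables: dict[str, expression.ExpressionTable] = {}
    for sp, sim in fam.items():
        counts = sd.simulate_expression_counts(
            sim.pool, sim.config, seed=int(rng.integers(0, 2**31 - 1))
        )
        genes = list(counts)
        lengths = [f.length for f in sim.genome.features]
        table = pd.DataFrame(
            {
                "sense_count": [counts[g] for g in genes],
                "antisense_count": 0,
                "length": lengths,
                "tpm": expression.tpm([counts[g] for g in genes], lengths),
            },
            index=pd.Index(genes, name="gene_id"),
        )
        tables[sp] = expression.ExpressionTable(sp, table)
    orders = {sp: rearrangement.genome_to_gene_order(s.genome) for sp, s in fam.items()}
    _, signed = rearrangement.find_synteny_blocks(orders)
    mat = rearrangement.pairwise_matrix(signed)
    ortho = expression.OrthologyMap.identity(list(tables[species[0]].table.index), species)
    corrs = {}
    for a, b in itertools.combinations(species, 2):
        r, _, _ = expression.ortholog_expression_correlation(tables[a], tables[b], ortho)
        corrs[(a, b)] = r
    import io as _io

    tree = read_newick(
        _io.StringIO(random_star_tree(species, int(rng.integers(0, 2**31 - 1))))
    )
    dist = association.patristic_distances(tree, species)
    pair_table = association.build_pair_table(corrs, mat, dist)
    return association.headline_analysis(pair_table)


def _write_manifest_tsv(path: Path, sim: sd.SpeciesSim) -> None:
    rows = []
    for g, rate in sim.manifest.gene_rates.items():
        rows.append(
            {
                "record": "gene",
                "id": g,
                "value": rate,
                "extra": sim.manifest.gene_abundance.get(g, ""),
            }
        )
    for i, (s, e) in enumerate(sim.manifest.inversions):
        rows.append({"record": "inversion", "id": i, "value": s, "extra": e})
    for site in sim.manifest.edit_sites:
        rows.append(
            {
                "record": "edit",
                "id": f"{site.position}{site.strand}",
                "value": site.efficiency,
                "extra": site.strand,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_run_manifest(out: Path, config: RunConfig) -> None:
    params = dataclasses.asdict(config)
    params["sim"] = dataclasses.asdict(config.sim)
    params["caller"] = dataclasses.asdict(config.caller)
    files = {
        str(p.relative_to(out)): _md5(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "run_manifest.json"
    }
    manifest = {"parameters": params, "outputs": files}
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
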
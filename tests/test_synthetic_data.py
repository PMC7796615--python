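import numpy as np
import pytest
from scipy import stats

from plastidflow.synthetic_data import (
    EditSpec,
    Operon,
    OperonModel,
    SimConfig,
    apply_inversions,
    build_genome,
    choose_edit_sites,
    expected_coverage,
    expected_gene_abundance,
    inject_edits,
    invert_interval,
    simulate_expression_counts,
    simulate_family,
    simulate_reads,
    simulate_transcripts,
)


class TestBuildGenome:
    def test_determinism(self):
        cfg = SimConfig(n_genes=10, n_operons=4, seed=5)
        g1, m1, _ = build_genome(cfg)
        g2, m2, _ = build_genome(cfg)
        assert g1.sequence == g2.sequence
        assert g1.features == g2.features
        assert m1.operons == m2.operons

    def test_operon_partition_and_codon_lengths(self):
        g, m, _ = build_genome(SimConfig(n_genes=4, n_operons=2, seed=0))
        assert len(m.operons) == 2
        assert [len(o.genes) for o in m.operons] == [2, 2]
        assert all(f.length % 3 == 0 for f in g.features)
        # CDSs translate cleanly: start codon, terminal stop, no internal stop
        for f in g.features:
            cds = g.cds_sequence(f)
            assert cds.startswith("ATG") and cds.endswith("TAA")
            assert all(
                cds[i : i + 3] not in ("TAA", "TAG", "TGA")
                for i in range(0, len(cds) - 3, 3)
            )

    def test_features_never_overlap(self):
        g, _, _ = build_genome(SimConfig(n_genes=30, n_operons=9, seed=3))
        feats = sorted(g.features, key=lambda f: f.start)
        assert all(a.end <= b.start for a, b in zip(feats, feats[1:]))
        assert feats[-1].end <= g.length

    def test_bad_config(self):
        with pytest.raises(ValueError):
            SimConfig(n_genes=2, n_operons=5)
        with pytest.raises(ValueError):
            SimConfig(base_error_rate=0.5)


class TestInversions:
    def test_k_zero_identity(self):
        g, _, _ = build_genome(SimConfig(n_genes=8, n_operons=3, seed=1))
        d, log = apply_inversions(g, 0, seed=0)
        assert d.sequence == g.sequence and d.features == g.features and log == []

    def test_reapplying_log_restores(self):
        g, _, _ = build_genome(SimConfig(n_genes=12, n_operons=4, seed=7))
        d, log = apply_inversions(g, 3, seed=9)
        assert d.sequence != g.sequence
        back = d
        for s, e in reversed(log):
            back = invert_interval(back, s, e)
        assert back.sequence == g.sequence
        assert back.features == g.features

    def test_invert_interval_is_involution(self):
        g, _, _ = build_genome(SimConfig(n_genes=6, n_operons=2, seed=4))
        f = g.features[2]
        twice = invert_interval(invert_interval(g, f.start - 1, f.end + 1),
                                f.start - 1, f.end + 1)
        assert twice.sequence == g.sequence and twice.features == g.features

    def test_gene_content_preserved(self):
        g, _, _ = build_genome(SimConfig(n_genes=15, n_operons=5, seed=2))
        d, _ = apply_inversions(g, 4, seed=3)
        assert d.length == g.length
        assert {f.gene_id for f in d.features} == {f.gene_id for f in g.features}
        # coding sequences survive strand-flipping untouched
        orig = {f.gene_id: g.cds_sequence(f) for f in g.features}
        for f in d.features:
            assert d.cds_sequence(f) == orig[f.gene_id]

    def test_too_many_inversions(self):
        g, _, _ = build_genome(SimConfig(n_genes=4, n_operons=2, seed=0))
        with pytest.raises(ValueError, match="spacers"):
            apply_inversions(g, 50, seed=0)


class TestTranscripts:
    def test_pure_operon_pool(self):
        g, m, _ = build_genome(
            SimConfig(n_genes=6, n_operons=3, seed=8, readthrough_prob=0.0, antisense_rate=0.0)
        )
        pool = simulate_transcripts(g, m)
        spans = set()
        feats = {f.gene_id: f for f in g.features}
        for op in m.operons:
            spans.add((min(feats[x].start for x in op.genes),
                       max(feats[x].end for x in op.genes)))
        assert {(e.start, e.end) for e in pool.entries} == spans

    def test_background_covers_whole_genome(self):
        cfg = SimConfig(n_genes=6, n_operons=3, seed=8, antisense_rate=0.05)
        g, m, _ = build_genome(cfg)
        cov = expected_coverage(simulate_transcripts(g, m), cfg)
        combined = cov["+"] + cov["-"]
        assert (combined > 0).all()

    def test_full_readthrough_boosts_downstream(self):
        cfg = SimConfig(n_genes=8, n_operons=4, seed=12, readthrough_prob=1.0,
                        antisense_rate=0.0)
        g, m, _ = build_genome(cfg)
        pool = simulate_transcripts(g, m)
        rt = [e for e in pool.entries if e.kind == "readthrough"]
        assert rt, "full read-through must extend transcripts"
        ops = [e for e in pool.entries if e.kind == "operon"]
        for e in rt:  # extension carries the full upstream rate at prob 1
            assert any(o.strand == e.strand and e.weight >= o.weight * 0.999
                       for o in ops)

    def test_all_rates_zero_errors(self):
        g, m, _ = build_genome(SimConfig(n_genes=4, n_operons=2, seed=0))
        dead = OperonModel(
            [Operon(o.genes, o.strand, 0.0) for o in m.operons],
            readthrough_prob=0.0,
            antisense_rate=0.0,
        )
        with pytest.raises(ValueError):
            simulate_transcripts(g, dead)


class TestEditsAndReads:
    def test_inject_requires_c(self):
        g, m, _ = build_genome(SimConfig(n_genes=4, n_operons=2, seed=0))
        pool = simulate_transcripts(g, m)
        pos_a = g.sequence.index("A")
        with pytest.raises(ValueError, match="required"):
            inject_edits(pool, [EditSpec(pos_a, "+", 0.5)])

    @pytest.mark.parametrize("eff,expect_all", [(1.0, True), (0.0, False)])
    def test_extreme_efficiencies(self, eff, expect_all):
        cfg = SimConfig(n_genes=4, n_operons=1, n_read_pairs=800, seed=3,
                        base_error_rate=0.0, antisense_rate=0.0, readthrough_prob=0.0)
        g, m, _ = build_genome(cfg)
        pool = simulate_transcripts(g, m)
        f = g.features[0]
        strand = f.strand
        target = "C" if strand == "+" else "G"
        pos = next(p for p in range(f.start + 30, f.end) if g.sequence[p] == target)
        pool = inject_edits(pool, [EditSpec(pos, strand, eff)])
        sub = "T" if strand == "+" else "A"
        seen = set()
        for rec in simulate_reads(pool, cfg):
            for rpos, base in rec.aligned_pairs():
                if rpos == pos:
                    seen.add(base)
        assert (seen == {sub}) if expect_all else (sub not in seen)

    def test_binomial_efficiency_recovery(self):
        cfg = SimConfig(n_genes=4, n_operons=1, n_read_pairs=2000, seed=9,
                        base_error_rate=0.0, antisense_rate=0.0, readthrough_prob=0.0)
        g, m, _ = build_genome(cfg)
        pool = simulate_transcripts(g, m)
        sites = choose_edit_sites(pool, 1, seed=1, config=cfg,
                                  efficiency_range=(0.4, 0.4),
                                  min_expected_coverage=150)
        pool = inject_edits(pool, sites)
        site = sites[0]
        sub = "T" if site.strand == "+" else "A"
        ref = "C" if site.strand == "+" else "G"
        counts = {sub: 0, ref: 0}
        for rec in simulate_reads(pool, cfg):
            for rpos, base in rec.aligned_pairs():
                if rpos == site.position and base in counts:
                    counts[base] += 1
        n = counts[sub] + counts[ref]
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.4)
        assert lo <= counts[sub] <= hi

    def test_read_counts_and_error_free_match(self):
        cfg = SimConfig(n_genes=4, n_operons=2, n_read_pairs=500, seed=6,
                        base_error_rate=0.0)
        g, m, _ = build_genome(cfg)
        pool = simulate_transcripts(g, m)
        recs = simulate_reads(pool, cfg)
        assert len(recs) == 2 * cfg.n_read_pairs
        assert len({r.read_id for r in recs}) == cfg.n_read_pairs
        for rec in recs[:200]:
            assert rec.seq == g.sequence[rec.ref_start : rec.ref_start + cfg.read_length]

    def test_strand_recovery_through_sam(self, tmp_path, clean_sim):
        from plastidflow.genome_io import read_sam, write_sam

        p = tmp_path / "x.sam"
        write_sam(p, clean_sim.records, clean_sim.genome.id, clean_sim.genome.length)
        truth = {}
        for rec in clean_sim.records:
            truth[(rec.read_id, rec.is_read1)] = rec.transcript_strand
        back = read_sam(p, "fr-firststrand")
        assert len(back) == len(clean_sim.records)
        assert all(truth[(r.read_id, r.is_read1)] == r.transcript_strand for r in back)


class TestManifest:
    def test_coverage_expectation_matches_simulation(self, small_sim):
        """Simulated coverage tracks the manifest's exact expectation (3 SE)."""
        from plastidflow.coverage_profile import per_base_coverage

        cov = per_base_coverage(small_sim.records, small_sim.genome)
        exp = expected_coverage(small_sim.pool, small_sim.config)
        rng = np.random.default_rng(0)
        for f in small_sim.genome.features:
            pos = int(rng.integers(f.start + 5, f.end - 5))
            mu = exp[f.strand][pos]
            se = max(np.sqrt(mu), 1.0)
            assert abs(cov[f.strand].counts[pos] - mu) <= 3 * se

    def test_expression_counts_track_abundance(self):
        cfg = SimConfig(n_genes=20, n_operons=6, seed=21)
        g, m, _ = build_genome(cfg)
        pool = simulate_transcripts(g, m)
        ab = expected_gene_abundance(pool, cfg)
        counts = simulate_expression_counts(pool, cfg, seed=5)
        lens = {f.gene_id: f.length for f in g.features}
        dens = {g_: counts[g_] / lens[g_] for g_ in counts}
        rho = stats.spearmanr(list(dens.values()), [ab[g_] for g_ in dens]).statistic
        assert rho > 0.95


class TestFamily:
    def test_family_shapes_and_determinism(self):
        cfg = SimConfig(n_genes=18, n_operons=6)
        fam1 = simulate_family(cfg, k_inversions=(0, 2, 4), seed=3)
        fam2 = simulate_family(cfg, k_inversions=(0, 2, 4), seed=3)
        assert list(fam1) == ["sp0", "sp1", "sp2"]
        for sp in fam1:
            assert fam1[sp].genome.sequence == fam2[sp].genome.sequence
            assert len(fam1[sp].manifest.inversions) == {"sp0": 0, "sp1": 2, "sp2": 4}[sp]

    def test_uncoupled_is_position_insensitive(self):
        cfg = SimConfig(n_genes=18, n_operons=6)
        fam = simulate_family(cfg, k_inversions=(0, 3), coupling="uncoupled", seed=1)
        for sim in fam.values():
            assert sim.model.readthrough_prob == 0.0
            assert all(len(o.genes) == 1 for o in sim.model.operons)
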
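import numpy as np
import pytest
from Bio.Align import substitution_matrices

from oracles import affine_global_score
from plastidflow.editing import (
    CallerConfig,
    EditingSite,
    StrandedPileup,
    align_orthologs,
    build_pileup,
    call_c2u,
    classify_site,
    editing_summary,
    shared_specific,
)
from plastidflow.genome_io import CdsFeature, Plastome, StrandedAlignmentRecord, revcomp
from plastidflow.synthetic_data import SimConfig, simulate_species


def _read(name, start, seq, strand):
    return StrandedAlignmentRecord(name, "g", start, [("M", len(seq))], seq, strand)


def _pileup_with(genome, pos, strand, ref_like, edit_like):
    """A pileup holding given counts of reference-like and edited-like bases."""
    p = StrandedPileup.empty(genome.length)
    ref = "C" if strand == "+" else "G"
    alt = "T" if strand == "+" else "A"
    p.counts[strand][{"A": 0, "C": 1, "G": 2, "T": 3}[ref], pos] = ref_like
    p.counts[strand][{"A": 0, "C": 1, "G": 2, "T": 3}[alt], pos] = edit_like
    return p


class TestPileup:
    def test_perfect_read_counts_reference(self):
        genome = Plastome("g", "ACGTACGTAC")
        pileup = build_pileup([_read("r", 2, "GTACG", "+")], genome)
        for i, base in enumerate("GTACG"):
            assert pileup.base_count(2 + i, "+", base) == 1
        assert pileup.counts["-"].sum() == 0

    def test_mates_counted_independently(self):
        genome = Plastome("g", "ACGTACGTAC")
        r1 = _read("p", 0, "ACGT", "+")
        r2 = _read("p", 2, "GTAC", "+")
        pileup = build_pileup([r1, r2], genome)
        assert pileup.base_count(2, "+", "G") == 2

    def test_soft_clip_and_insertion_skipped(self):
        genome = Plastome("g", "ACGTACGTAC")
        rec = StrandedAlignmentRecord(
            "r", "g", 2, [("S", 2), ("M", 3), ("I", 2), ("M", 2)], "TTGTATTCG", "+"
        )
        pileup = build_pileup([rec], genome)
        assert pileup.base_count(2, "+", "G") == 1
        assert pileup.base_count(5, "+", "C") == 1
        assert pileup.counts["+"].sum() == 5

    def test_matches_truth_without_error(self, clean_sim):
        """At zero sequencing error every pileup base equals the reference."""
        pileup = build_pileup(clean_sim.records, clean_sim.genome)
        seq = clean_sim.genome.sequence
        for strand in "+-":
            arr = pileup.counts[strand]
            covered = arr.sum(axis=0) > 0
            for pos in np.flatnonzero(covered)[:: max(1, covered.sum() // 200)]:
                ref_idx = {"A": 0, "C": 1, "G": 2, "T": 3}[seq[pos]]
                assert arr[:, pos].sum() == arr[ref_idx, pos]


class TestCaller:
    GENOME = Plastome("g", "ACGT" * 50)

    def test_basic_call_and_efficiency(self):
        pileup = _pileup_with(self.GENOME, 1, "+", ref_like=60, edit_like=40)
        (site,) = call_c2u(pileup, self.GENOME, CallerConfig())
        assert site.efficiency == pytest.approx(0.40)
        assert site.edited_count == 40 and site.unedited_count == 60
        assert site.p_value < 1e-6

    def test_minimum_coverage_threshold(self):
        pileup = _pileup_with(self.GENOME, 1, "+", ref_like=29, edit_like=20)  # n = 49
        assert call_c2u(pileup, self.GENOME, CallerConfig()) == []
        pileup = _pileup_with(self.GENOME, 1, "+", ref_like=30, edit_like=20)  # n = 50
        assert len(call_c2u(pileup, self.GENOME, CallerConfig())) == 1

    def test_minimum_frequency_threshold(self):
        pileup = _pileup_with(self.GENOME, 1, "+", ref_like=95, edit_like=5)
        assert call_c2u(pileup, self.GENOME, CallerConfig()) == []

    def test_binomial_pvalue_threshold(self):
        # 10/100 passes coverage and frequency but not significance at e = 0.05
        cfg = CallerConfig(base_error_rate=0.05)
        pileup = _pileup_with(self.GENOME, 1, "+", ref_like=90, edit_like=10)
        assert call_c2u(pileup, self.GENOME, cfg) == []

    def test_never_calls_non_c_positions(self):
        # a T-heavy pile on a reference A must not be called on either strand
        pileup = StrandedPileup.empty(self.GENOME.length)
        pileup.counts["+"][3, 0] = 100  # T count at an 'A' position
        pileup.counts["-"][0, 0] = 100
        assert call_c2u(pileup, self.GENOME, CallerConfig()) == []

    def test_minus_strand_site(self):
        pileup = _pileup_with(self.GENOME, 2, "-", ref_like=50, edit_like=50)  # ref G
        (site,) = call_c2u(pileup, self.GENOME, CallerConfig())
        assert site.transcript_strand == "-" and site.efficiency == 0.5


def _site(pos, strand, eff=0.4):
    return EditingSite(pos, strand, int(eff * 100), 100 - int(eff * 100), eff, 1e-9)


class TestClassification:
    def test_third_position_silent(self):
        # ACC -> ACT is Thr -> Thr
        genome = Plastome("g", "TT" + "ATGACCTAA" + "TT",
                          [CdsFeature("x", 2, 11, "+")])
        site = classify_site(_site(7, "+"), genome.features, genome)
        assert site.category == "silent" and site.codon_position == 3
        assert site.aa_change == "T2T"

    def test_second_position_non_silent(self):
        # TCA -> TTA is Ser -> Leu
        genome = Plastome("g", "TT" + "ATGTCATAA" + "TT",
                          [CdsFeature("x", 2, 11, "+")])
        site = classify_site(_site(6, "+"), genome.features, genome)
        assert site.category == "non_silent" and site.codon_position == 2
        assert site.aa_change == "S2L"

    def test_minus_strand_cds(self):
        cds = "ATGTCATAA"  # minus-strand gene; plus strand holds its revcomp
        genome = Plastome("g", "GG" + revcomp(cds) + "GG",
                          [CdsFeature("x", 2, 11, "-")])
        # CDS offset 4 is the C of TCA; on the plus strand that is a G at
        # position 2 + (9 - 1 - 4)
        site = classify_site(_site(2 + 4, "-"), genome.features, genome)
        assert site.category == "non_silent" and site.cds_offset == 4

    def test_antisense_and_noncoding(self):
        genome = Plastome("g", "TT" + "ATGACCTAA" + "TT",
                          [CdsFeature("x", 2, 11, "+")])
        assert classify_site(_site(7, "-"), genome.features, genome).category == "antisense"
        assert classify_site(_site(0, "+"), genome.features, genome).category == "noncoding"

    def test_frame_error(self):
        genome = Plastome("g", "ATGACCTA", [CdsFeature("x", 0, 8, "+")])
        with pytest.raises(ValueError, match="multiple of 3"):
            classify_site(_site(5, "+"), genome.features, genome)


class TestAlignment:
    def test_identity_alignment(self):
        seqs = {"A": "ATGACCTGGTAA", "B": "ATGACCTGGTAA"}
        cols = align_orthologs(seqs)
        assert cols["A"] == list(range(12)) and cols["B"] == list(range(12))

    def test_single_codon_gap(self):
        a = "ATGACCTGGAAATAA"
        b = "ATGACCAAATAA"  # TGG codon missing
        cols = align_orthologs({"A": a, "B": b})
        # B's fourth codon (AAA) must land on A's fourth codon columns
        assert cols["B"][6:9] == [9, 10, 11]
        assert cols["B"][:6] == list(range(6))

    def test_internal_stop_excluded(self):
        with pytest.warns(UserWarning, match="internal stop"):
            cols = align_orthologs({"A": "ATGTAAACCTAA", "B": "ATGACCTAA", "C": "ATGACTTAA"})
        assert "A" not in cols and set(cols) == {"B", "C"}

    def test_pairwise_score_matches_dp_oracle(self, rng):
        """Protein alignment scores equal brute-force affine DP on small toys."""
        from plastidflow.editing import _aligner

        blosum = substitution_matrices.load("BLOSUM62")
        aligner = _aligner()
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(25):
            a = "".join(rng.choice(list(aa), size=int(rng.integers(3, 10))))
            b = "".join(rng.choice(list(aa), size=int(rng.integers(3, 10))))
            assert aligner.score(a, b) == pytest.approx(
                affine_global_score(a, b, blosum)
            )


class TestSharedSpecific:
    def _mk(self, offsets, gene="gA"):
        sites = []
        for off in offsets:
            s = _site(0, "+")
            s.gene_id = gene
            s.cds_offset = off
            s.category = "non_silent"
            sites.append(s)
        return sites

    def test_set_arithmetic(self):
        # sites {a,b}, {b}, {b,c} at offsets a=3, b=6, c=9
        per_species = {
            "s1": self._mk([3, 6]),
            "s2": self._mk([6]),
            "s3": self._mk([6, 9]),
        }
        aln = {"grp": {sp: list(range(12)) for sp in per_species}}
        g2g = {(sp, "gA"): "grp" for sp in per_species}
        labels, inter = shared_specific(per_species, aln, g2g)
        assert labels["s1"] == ["specific", "shared"]
        assert labels["s2"] == ["shared"]
        assert labels["s3"] == ["shared", "specific"]
        assert inter == {
            frozenset({"s1"}): 1,
            frozenset({"s3"}): 1,
            frozenset({"s1", "s2", "s3"}): 1,
        }

    def test_strand_class_kept_separate(self):
        sense = self._mk([3])
        anti = self._mk([3])
        anti[0].category = "antisense"
        aln = {"grp": {"s1": list(range(6)), "s2": list(range(6))}}
        g2g = {("s1", "gA"): "grp", ("s2", "gA"): "grp"}
        labels, _ = shared_specific({"s1": sense, "s2": anti}, aln, g2g)
        assert labels["s1"] == ["specific"] and labels["s2"] == ["specific"]

    def test_unmapped_gene_is_specific_with_warning(self):
        sites = self._mk([3], gene="mystery")
        with pytest.warns(UserWarning, match="orthology"):
            labels, inter = shared_specific({"s1": sites}, {}, {})
        assert labels["s1"] == ["specific"]
        assert inter == {frozenset({"s1"}): 1}


class TestSummary:
    def test_proportions(self):
        sites = [_site(i, "+") for i in range(10)]
        for s in sites[:8]:
            s.category = "non_silent"
        for s in sites[8:]:
            s.category = "silent"
        df = editing_summary({"sp": sites})
        assert df.loc["sp", "n_sites"] == 10
        assert df.loc["sp", "pct_non_silent"] == pytest.approx(80.0)

    def test_empty(self):
        df = editing_summary({"sp": []})
        assert df.loc["sp", "n_sites"] == 0


class TestRecovery:
    def test_injected_sites_recovered(self, small_sim):
        pileup = build_pileup(small_sim.records, small_sim.genome)
        called = call_c2u(pileup, small_sim.genome, CallerConfig())
        truth = {(s.position, s.strand): s.efficiency for s in small_sim.manifest.edit_sites}
        got = {(s.position, s.transcript_strand): s.efficiency for s in called}
        tp = set(truth) & set(got)
        assert len(tp) / len(truth) >= 0.95
        assert len(tp) / len(got) >= 0.95
        assert all(abs(got[k] - truth[k]) <= 0.1 for k in tp)

    def test_minus_only_edits_never_call_plus(self):
        """Strand separation: '-' transcript edits are invisible on '+' at e = 0."""
        for seed in range(5):
            cfg = SimConfig(n_genes=8, n_operons=3, n_read_pairs=4000,
                            seed=seed, base_error_rate=0.0)
            try:
                sim = simulate_species(cfg, n_edit_sites=3, min_edit_coverage=80,
                                       edit_strand="-")
            except ValueError:
                continue  # this seed has no sufficiently covered '-' genes
            pileup = build_pileup(sim.records, sim.genome)
            called = call_c2u(pileup, sim.genome, CallerConfig())
            assert called, "injected '-' sites should be recovered"
            assert all(s.transcript_strand == "-" for s in called)
            return
        pytest.fail("no seed produced minus-strand editable genes")
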
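import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from t6mine.detection import FamilyAnnotation, LocusRegion
from t6mine.genome_io import ContigRecord, GeneRecord, GenomeRecord
from t6mine.ice import (detect_tra_genes, find_hsps, ice_extent,
                        pairwise_ice_identity,
                        percent_identity_from_mismatches, tra_proximity)
from t6mine.profiles import MotifHit, calibrate_evalues
from t6mine.synthetic import SynthConfig, generate_genome_set, mutate_dna


def _revcomp(seq):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(seq))


def _block(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="module")
def tra_profiles(registry):
    rng = np.random.default_rng(55)
    profs = registry.profile_sets()["tra"]
    for p in profs:
        if p.calibration is None:
            calibrate_evalues(p, 10_000, 200, rng)
    return profs


@pytest.fixture(scope="module")
def genomes(registry):
    cfg = SynthConfig(n_genomes=3,
                      architecture_mix={"GA1": 1, "GA2": 1, "none": 1},
                      contig_split_prob=0.0, decoy_rate=0.0, seed=41)
    return generate_genome_set(cfg, registry)


class TestDetectTraGenes:

    def test_ga1_flank_yields_five_tra_hits(self, genomes, tra_profiles,
                                            config):
        gs, truths = genomes
        hits = detect_tra_genes(gs[0], tra_profiles, config)
        assert len(hits) == 5
        assert {h.gene_id for h in hits} == set(truths[0].loci[0].tra_gene_ids)

    def test_ga2_flank_yields_nine_tra_hits(self, genomes, tra_profiles,
                                            config):
        gs, truths = genomes
        hits = detect_tra_genes(gs[1], tra_profiles, config)
        assert len(hits) == 9
        assert {h.profile_name for h in hits} == \
            {"TraO", "TraN", "TraM", "TraK", "TraJ", "TrbJ", "TraG", "TraI",
             "TraD"}

    def test_genome_without_ice_has_no_hits(self, genomes, tra_profiles,
                                            config):
        gs, _ = genomes
        assert detect_tra_genes(gs[2], tra_profiles, config) == []


def _locus_with_tra(tra_families, tra_starts, locus_span=(100_000, 120_000),
                    contig_len=400_000, flipped=False):
    genes = [GeneRecord("lg0", "c1", locus_span[0], locus_span[1], "+", 50,
                        "M")]
    locus = LocusRegion("L1", "G", ["c1"], genes, 1,
                        {"lg0": FamilyAnnotation("VgrG", 0, "VgrG", 1.0)},
                        oriented=True, flipped=flipped)
    tra_genes = []
    hits = []
    all_genes = list(genes)
    for i, (fam, start) in enumerate(zip(tra_families, tra_starts)):
        g = GeneRecord(f"t{i}", "c1", start, start + 900, "+", i, "M")
        tra_genes.append(g)
        all_genes.append(g)
        hits.append(MotifHit(f"t{i}", fam, 100.0, 1e-9, (0, 10)))
    ordered = sorted(all_genes, key=lambda g: g.start)
    for ordinal, g in enumerate(ordered):
        g.ordinal = ordinal
    genome = GenomeRecord("G", "", [ContigRecord("c1", "N" * contig_len,
                                                 ordered)])
    return locus, hits, genome


class TestTraProximity:
    def test_cluster_ten_kb_upstream_is_associated(self, config):
        starts = [90_000 - 1200 * k for k in range(5)][::-1]
        locus, hits, genome = _locus_with_tra(
            ["TraG", "TraK", "TraM", "TraN", "TraD"], starts)
        assoc = tra_proximity(locus, hits, genome, config)
        assert assoc.verdict == "ICE-associated"
        assert assoc.pattern == "GA1-pattern"
        assert min(d for _g, _f, d in assoc.tra_hits) == \
            100_000 - (max(starts) + 900)

    def test_distant_tra_not_associated(self, config):
        locus, hits, genome = _locus_with_tra(["TraG"], [320_000])
        assoc = tra_proximity(locus, hits, genome, config)
        assert assoc.verdict == "not-associated"
        assert assoc.tra_hits[0][2] == 320_000 - 120_000

    def test_no_tra_genes_pattern_none(self, config):
        locus, _hits, genome = _locus_with_tra([], [])
        assoc = tra_proximity(locus, [], genome, config)
        assert assoc.verdict == "not-associated"
        assert assoc.pattern == "none"

    def test_other_contig_hits_never_count(self, config):
        locus, hits, genome = _locus_with_tra(["TraG"], [99_000])
        other = GenomeRecord("G", "", [
            genome.contigs[0],
            ContigRecord("c2", "N" * 2000,
                         [GeneRecord("x1", "c2", 10, 910, "+", 0, "M")])])
        far_hit = MotifHit("x1", "TraK", 50.0, 1e-9, (0, 10))
        assoc = tra_proximity(locus, hits + [far_hit], other, config)
        assert [t[0] for t in assoc.tra_hits] == ["t0"]

    def test_partial_roster_in_order_matches_pattern(self, config):
        # 7 of the 9 GA2 families, canonical order preserved
        fams = ["TraO", "TraN", "TraM", "TraK", "TrbJ", "TraG", "TraD"]
        starts = [90_000 + 1100 * k for k in range(7)]
        locus, hits, genome = _locus_with_tra(fams, starts)
        assoc = tra_proximity(locus, hits, genome, config)
        assert assoc.pattern == "GA2-pattern"

    def test_shuffled_roster_is_inconsistent(self, config):
        fams = ["TraD", "TraG", "TrbJ", "TraK", "TraM", "TraN", "TraO"]
        starts = [90_000 + 1100 * k for k in range(7)]
        locus, hits, genome = _locus_with_tra(fams, starts)
        assoc = tra_proximity(locus, hits, genome, config)
        assert assoc.pattern == "inconsistent"
        assert assoc.verdict == "ICE-associated"  # proximity rule still holds


class TestFindHsps:
    def test_identical_sequences_single_full_hsp(self, config):
        rng = np.random.default_rng(61)
        seq = _block(rng, 5000)
        hsps = find_hsps(seq, seq, config)
        assert len(hsps) == 1
        h = hsps[0]
        assert (h.query_start, h.query_end, h.identity, h.strand) == \
            (0, 5000, 1.0, "+")

    def test_unrelated_sequences_never_reach_the_floor(self, config):
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            assert find_hsps(_block(rng, 5000), _block(rng, 5000),
                             config) == []

    def test_thousand_bp_filter_keeps_two_of_three_blocks(self, config):
        rng = np.random.default_rng(62)
        blocks = [_block(rng, n) for n in (800, 1200, 3000)]
        q = (_block(rng, 500) + blocks[0] + _block(rng, 400) + blocks[1]
             + _block(rng, 400) + blocks[2] + _block(rng, 500))
        s = (_block(rng, 300) + blocks[0] + _block(rng, 700) + blocks[1]
             + _block(rng, 200) + blocks[2] + _block(rng, 100))
        hsps = find_hsps(q, s, config)
        assert len(hsps) == 2
        assert [h.query_start for h in hsps] == sorted(h.query_start
                                                       for h in hsps)
        assert all(h.length >= config.hsp_min_len for h in hsps)

    def test_filter_removal_only_adds_shorter_hsps(self, config):
        from dataclasses import replace
        rng = np.random.default_rng(63)
        blocks = [_block(rng, n) for n in (600, 2000)]
        q = blocks[0] + _block(rng, 300) + blocks[1]
        s = blocks[0] + _block(rng, 500) + blocks[1]
        strict = find_hsps(q, s, config)
        loose = find_hsps(q, s, replace(config, hsp_min_len=100))
        kept = {(h.query_start, h.query_end) for h in strict}
        assert kept <= {(h.query_start, h.query_end) for h in loose}
        assert all(h.length < config.hsp_min_len
                   for h in loose
                   if (h.query_start, h.query_end) not in kept)

    def test_strand_symmetry(self, config):
        rng = np.random.default_rng(64)
        shared = _block(rng, 2500)
        q = _block(rng, 200) + shared + _block(rng, 200)
        s = _block(rng, 350) + shared + _block(rng, 150)
        fwd = find_hsps(q, s, config)
        rev = find_hsps(q, _revcomp(s), config)
        assert len(fwd) == len(rev) == 1
        f, r = fwd[0], rev[0]
        assert (f.query_start, f.query_end) == (r.query_start, r.query_end)
        assert f.strand == "+" and r.strand == "-"
        assert (r.subject_start, r.subject_end) == \
            (len(s) - f.subject_end, len(s) - f.subject_start)

    def test_empty_sequence_raises(self, config):
        with pytest.raises(ValueError):
            find_hsps("", "ACGT", config)


class TestPercentIdentity:
    def test_published_worked_example(self):
        assert percent_identity_from_mismatches(109_805, 3) == 99.997

    def test_no_mismatches_is_hundred(self):
        for L in (1, 10, 109_805):
            assert percent_identity_from_mismatches(L, 0) == 100.0

    def test_simple_arithmetic(self):
        assert percent_identity_from_mismatches(1000, 10) == 99.0

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            percent_identity_from_mismatches(0, 0)
        with pytest.raises(ValueError):
            percent_identity_from_mismatches(10, 11)

    @given(st.integers(1, 10 ** 7), st.integers(0, 10 ** 7))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounds(self, length, mismatches):
        mismatches = min(mismatches, length)
        v = percent_identity_from_mismatches(length, mismatches)
        assert 0.0 <= v <= 100.0


def _ice_pair_genomes(rng, divergence=0.0):
    """Two single-contig genomes sharing an implanted 20-kb element."""
    element = _block(rng, 20_000)
    g1_seq = _block(rng, 5_000) + element + _block(rng, 5_000)
    e2 = mutate_dna(element, divergence, rng) if divergence else element
    g2_seq = _block(rng, 9_000) + e2 + _block(rng, 2_000)
    gene = GeneRecord("a1", "c1", 12_000, 18_000, "+", 0, "M")
    locus = LocusRegion("L1", "G1", ["c1"], [gene], 1,
                        {"a1": FamilyAnnotation("VgrG", 0, "VgrG", 1.0)})
    g1 = GenomeRecord("G1", "", [ContigRecord("c1", g1_seq, [gene])])
    g2 = GenomeRecord("G2", "", [ContigRecord("c1", g2_seq, [])])
    return locus, g1, g2


class TestIceExtent:
    def test_identical_element_recovered(self, config):
        rng = np.random.default_rng(71)
        locus, g1, g2 = _ice_pair_genomes(rng)
        ext = ice_extent(locus, g1, g2, config, window_bp=10_000)
        assert ext.found
        lo, hi = ext.span
        assert lo == pytest.approx(5_000, abs=50)
        assert hi == pytest.approx(25_000, abs=50)

    def test_absent_element_flagged(self, config):
        rng = np.random.default_rng(72)
        locus, g1, _g2 = _ice_pair_genomes(rng)
        empty = GenomeRecord("G3", "",
                             [ContigRecord("c1", _block(rng, 30_000), [])])
        ext = ice_extent(locus, g1, empty, config)
        assert not ext.found
        assert ext.span == (12_000, 18_000)  # falls back to the locus span

    def test_refinement_is_monotone(self, config):
        rng = np.random.default_rng(73)
        locus, g1, g2 = _ice_pair_genomes(rng, divergence=0.02)
        ext = ice_extent(locus, g1, g2, config, window_bp=10_000)
        assert ext.found and ext.iterations <= 3
        lo, hi = ext.span
        assert 12_000 - 10_000 <= lo <= 12_000
        assert 18_000 <= hi <= 18_000 + 10_000


class TestPairwiseIceIdentity:
    def test_identical_elements(self, config):
        rng = np.random.default_rng(74)
        e = _block(rng, 15_000)
        m = pairwise_ice_identity({"A": e, "B": e}, config)
        assert m["A"]["B"] == 1.0 and m["A"]["A"] == 1.0

    def test_one_percent_divergence(self, config):
        rng = np.random.default_rng(75)
        e = _block(rng, 15_000)
        spans = {f"S{k}": mutate_dna(e, 0.005, rng) for k in range(3)}
        m = pairwise_ice_identity(spans, config)
        vals = [m[a][b] for a in spans for b in spans if a != b]
        assert all(abs(v - 0.99) < 0.005 for v in vals)

    def test_matrix_symmetric_within_tolerance(self, config):
        rng = np.random.default_rng(76)
        e = _block(rng, 12_000)
        spans = {f"S{k}": mutate_dna(e, 0.01, rng) for k in range(3)}
        m = pairwise_ice_identity(spans, config)
        for a in spans:
            for b in spans:
                assert abs(m[a][b] - m[b][a]) <= 0.005

    def test_unrelated_pair_is_missing(self, config):
        rng = np.random.default_rng(78)
        m = pairwise_ice_identity({"A": _block(rng, 5000),
                                   "B": _block(rng, 5000)}, config)
        assert m["A"]["B"] is None
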
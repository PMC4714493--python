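import numpy as np
import pytest

from t6mine.detection import (FamilyAnnotation, LocusRegion, RawWindow,
                              SentinelPair, extract_region,
                              find_sentinel_pairs, orient_region,
                              second_pass_scan, trim_region)
from t6mine.genome_io import (ContigRecord, GeneRecord, GenomeRecord,
                              reverse_complement_contig)
from t6mine.profiles import MotifHit
from t6mine.synthetic import SynthConfig, generate_genome_set


def _toy_genome(n_genes=40, contig_id="c1", genome_id="G"):
    genes = []
    pos = 0
    for i in range(n_genes):
        genes.append(GeneRecord(f"{genome_id}_{contig_id}_g{i}", contig_id,
                                pos, pos + 90, "+", i, "M" * 30))
        pos += 100
    return GenomeRecord(genome_id, "",
                        [ContigRecord(contig_id, "A" * pos, genes)])


def _hit(gene, profile):
    return MotifHit(gene.gene_id, profile, 100.0, 1e-9, (0, 10))


class TestSentinelPairs:
    def test_pair_within_fifteen_genes(self, config):
        g = _toy_genome()
        genes = g.contigs[0].genes
        hits = [_hit(genes[3], "VgrG"), _hit(genes[10], "ClpV")]
        pairs = find_sentinel_pairs(hits, g, config)
        assert len(pairs) == 1

    def test_gap_beyond_fifteen_rejected(self, config):
        g = _toy_genome()
        genes = g.contigs[0].genes
        hits = [_hit(genes[3], "VgrG"), _hit(genes[25], "ClpV")]
        assert find_sentinel_pairs(hits, g, config) == []

    def test_boundary_gap_of_exactly_fifteen_accepted(self, config):
        g = _toy_genome()
        genes = g.contigs[0].genes
        hits = [_hit(genes[3], "VgrG"), _hit(genes[19], "ClpV")]
        assert len(find_sentinel_pairs(hits, g, config)) == 1

    def test_different_contigs_never_pair(self, config):
        g1 = _toy_genome()
        extra = _toy_genome(10, contig_id="c2")
        genome = GenomeRecord("G2", "", [g1.contigs[0], extra.contigs[0]])
        hits = [_hit(g1.contigs[0].genes[3], "VgrG"),
                _hit(extra.contigs[0].genes[2], "ClpV")]
        assert find_sentinel_pairs(hits, genome, config) == []

    def test_overlapping_pairs_merge(self, config):
        g = _toy_genome()
        genes = g.contigs[0].genes
        hits = [_hit(genes[3], "ClpV"), _hit(genes[10], "VgrG"),
                _hit(genes[12], "ClpV")]
        pairs = find_sentinel_pairs(hits, g, config)
        assert len(pairs) == 1
        assert len(pairs[0].clpv_genes) == 2


class TestExtractRegion:
    def test_flank_arithmetic(self, config):
        g = _toy_genome(100)
        genes = g.contigs[0].genes
        pair = SentinelPair("c1", [genes[40]], [genes[30]])
        window = extract_region(g, pair, config)
        ords = [x.ordinal for x in window.genes]
        assert (min(ords), max(ords)) == (5, 65)

    def test_truncation_at_contig_start(self, config):
        g = _toy_genome(60)
        genes = g.contigs[0].genes
        pair = SentinelPair("c1", [genes[3]], [genes[10]])
        window = extract_region(g, pair, config)
        assert window.genes[0].ordinal == 0

    def test_window_size_bound(self, config):
        g = _toy_genome(200)
        genes = g.contigs[0].genes
        for a, b in [(20, 30), (100, 115), (5, 8)]:
            pair = SentinelPair("c1", [genes[a]], [genes[b]])
            window = extract_region(g, pair, config)
            assert len(window.genes) <= (b - a + 1) + 2 * config.flank_genes


def _window_with_labels(labelled_at, n=46, families=None):
    g = _toy_genome(n)
    genes = g.contigs[0].genes
    ann = {}
    for k, i in enumerate(labelled_at):
        fam = families[k] if families else "TssB"
        ann[genes[i].gene_id] = FamilyAnnotation(fam, k, fam, 10.0)
    return RawWindow("G", "c1", genes), ann


class TestTrimRegion:
    def test_trims_to_labelled_interval(self):
        window, ann = _window_with_labels(range(7, 21))
        locus = trim_region(window, ann, "L1")
        assert [g.ordinal for g in locus.genes] == list(range(7, 21))

    def test_effector_with_interior_gap_included(self):
        window, ann = _window_with_labels([7, 8, 9, 12],
                                          families=["TssB", "TssC", "VgrG",
                                                    "effector"])
        locus = trim_region(window, ann, "L1")
        assert [g.ordinal for g in locus.genes] == list(range(7, 13))

    def test_fully_labelled_window_kept_whole(self):
        window, ann = _window_with_labels(range(0, 46))
        locus = trim_region(window, ann, "L1")
        assert len(locus.genes) == 46

    def test_distant_standalone_gene_excluded(self):
        window, ann = _window_with_labels([2, 20, 21, 22, 23],
                                          families=["ClpV", "TssB", "TssC",
                                                    "VgrG", "ClpV"])
        locus = trim_region(window, ann, "L1")
        assert [g.ordinal for g in locus.genes] == [20, 21, 22, 23]

    def test_unlabelled_window_is_error(self):
        window, _ = _window_with_labels([])
        with pytest.raises(ValueError, match="no labelled"):
            trim_region(window, {}, "L1")


class TestOrientRegion:
    def _locus(self, vgrg_strand):
        g = _toy_genome(5)
        genes = list(g.contigs[0].genes)
        genes[2] = GeneRecord(genes[2].gene_id, "c1", genes[2].start,
                              genes[2].end, vgrg_strand, 2, "M" * 30)
        ann = {genes[2].gene_id: FamilyAnnotation("VgrG", 0, "VgrG", 50.0)}
        return LocusRegion("L1", "G", ["c1"], genes, 1, ann)

    def test_plus_strand_unchanged(self):
        locus = orient_region(self._locus("+"))
        assert locus.oriented and not locus.flipped

    def test_minus_strand_flips(self):
        locus = orient_region(self._locus("-"))
        assert locus.flipped
        display = locus.oriented_genes()
        assert display[0][0].ordinal == 4  # order mirrored
        vgrg = [s for g, s in display if g.ordinal == 2]
        assert vgrg == ["+"]

    def test_idempotent(self):
        locus = self._locus("-")
        once = orient_region(locus)
        state = (once.flipped, [g.gene_id for g in once.genes])
        twice = orient_region(once)
        assert (twice.flipped, [g.gene_id for g in twice.genes]) == state

    def test_missing_vgrg_is_error(self):
        locus = self._locus("+")
        locus.annotations = {}
        with pytest.raises(ValueError):
            orient_region(locus)


class TestSecondPass:
    def test_split_locus_recovered_by_rescan_only(self, registry, config):
        from t6mine.pipeline import run_pipeline
        cfg = SynthConfig(n_genomes=6,
                          architecture_mix={"GA1": 3, "GA3": 3},
                          contig_split_prob=0.4, seed=24)
        genomes, truths = generate_genome_set(cfg, registry)
        split_genomes = {t.genome_id for t in truths
                         for l in t.loci if l.split_across_contigs}
        assert len(split_genomes) == 2  # this seed splits one GA1, one GA3
        r1 = run_pipeline(config, genomes, registry.profile_sets(),
                          enable_pass2=False)
        # sentinels never co-localize on a split locus
        assert {l.genome_id for l in r1.loci} == \
            {t.genome_id for t in truths} - split_genomes
        r2 = run_pipeline(config, genomes, registry.profile_sets())
        assert {l.genome_id for l in r2.loci
                if l.discovery_pass == 2} == split_genomes

    def test_decoys_become_orphans_not_loci(self, registry, config, small_run):
        _genomes, truths, result = small_run
        decoys = {gid for t in truths for gid in t.decoy_gene_ids}
        truth_locus_genes = {gid for t in truths for l in t.loci
                             for gid in l.gene_ids}
        assert decoys
        # no predicted locus is built out of decoys alone: every locus is
        # dominated by true implant genes
        for l in result.loci:
            assert len(l.gene_ids & truth_locus_genes) > \
                2 * len(l.gene_ids & decoys)
        # standalone clpV/hcp/tetR/rhs genes surface as orphan hits
        orphan_ids = {h.gene_id for h in result.orphans}
        assert decoys & orphan_ids
        assert not (orphan_ids & truth_locus_genes)

    def test_clean_genome_yields_nothing(self, registry, config):
        from t6mine.pipeline import run_pipeline
        cfg = SynthConfig(n_genomes=2, architecture_mix={"none": 2},
                          decoy_rate=0.0, seed=24)
        genomes, _ = generate_genome_set(cfg, registry)
        result = run_pipeline(config, genomes, registry.profile_sets())
        assert result.loci == [] and result.orphans == []

    def test_pass_membership_disjoint(self, default_run):
        _g, _t, result, _r = default_run
        seen = {}
        for l in result.loci:
            for gid in l.gene_ids:
                assert gid not in seen
                seen[gid] = l.locus_id


class TestStrandInvariance:
    def test_detection_invariant_to_contig_reverse_complement(
            self, registry, config):
        from t6mine.pipeline import run_pipeline
        cfg = SynthConfig(n_genomes=1, architecture_mix={"GA1": 1},
                          contig_split_prob=0.0, seed=25)
        genomes, truths = generate_genome_set(cfg, registry)
        locus_contig = truths[0].loci[0].contig_ids[0]
        mirrored = [reverse_complement_contig(genomes[0], locus_contig)]
        r1 = run_pipeline(config, genomes, registry.profile_sets(),
                          enable_pass2=False)
        r2 = run_pipeline(config, mirrored, registry.profile_sets(),
                          enable_pass2=False)
        assert [sorted(l.gene_ids) for l in r1.loci] == \
            [sorted(l.gene_ids) for l in r2.loci]
        assert [c.call for c in r1.architecture_calls.values()] == \
            [c.call for c in r2.architecture_calls.values()]
        # the two representations disagree on strand, so exactly one is flipped
        assert r1.loci[0].flipped != r2.loci[0].flipped
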
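"""Two-pass T6SS locus discovery.

Pass 1 seeds on co-localized VgrG/ClpV sentinel hits (same contig, at most
15 intervening genes), retrieves the intervening genes plus 25 flanking
genes each side, and trims to the outermost family-labelled genes. Pass 2
rescans every genome with profiles rebuilt from pass-1 clusters and calls
additional loci wherever a 30-gene window carries hits of at least four
distinct core Tss families outside any pass-1 locus — this is what rescues
loci whose vgrG and clpV ended up on different contigs in a draft assembly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import GeneRecord, GenomeRecord
from .profiles import MotifHit, score_protein
from .synthetic import CORE_TSS_FAMILIES, family_label

__all__ = [
    "FamilyAnnotation", "LocusRegion", "SentinelPair", "RawWindow",
    "find_sentinel_pairs", "extract_region", "trim_region", "orient_region",
    "second_pass_scan", "TRIM_KEEP_FAMILIES",
]

# family labels that define the trimmed extent of a locus
TRIM_KEEP_FAMILIES = (
    {"TssB", "TssC", "TssE", "TssF", "TssG", "TssK", "TssN", "TssO", "TssP",
     "TssQ", "TssR", "TagA", "TagB", "TagC", "TetR", "Hcp", "VgrG", "ClpV",
     "PAAR", "Rhs", "effector", "immunity"}
)


@dataclass
class FamilyAnnotation:
    family: str
    cluster_id: int | None = None
    profile_name: str | None = None
    score: float = 0.0
    evalue: float | None = None
    evolved_hcp: bool = False


@dataclass
class LocusRegion:
    locus_id: str
    genome_id: str
    contig_ids: list[str]
    genes: list[GeneRecord]  # genomic order
    discovery_pass: int
    annotations: dict[str, FamilyAnnotation] = field(default_factory=dict)
    oriented: bool = False
    flipped: bool = False
    architecture: str | None = None

    @property
    def gene_ids(self) -> set[str]:
        return {g.gene_id for g in self.genes}

    @property
    def spans(self) -> dict[str, tuple[int, int]]:
        out = {}
        for cid in self.contig_ids:
            coords = [g for g in self.genes if g.contig_id == cid]
            out[cid] = (min(g.start for g in coords), max(g.end for g in coords))
        return out

    def oriented_genes(self) -> list[tuple[GeneRecord, str]]:
        """Genes in display order with display strands: mirrored when the
        locus was flipped so that vgrG reads left to right."""
        flip = {"+": "-", "-": "+"}
        if not self.flipped:
            return [(g, g.strand) for g in self.genes]
        return [(g, flip[g.strand]) for g in reversed(self.genes)]

    def families(self) -> list[str]:
        return [self.annotations[g.gene_id].family for g in self.genes
                if g.gene_id in self.annotations]


@dataclass
class SentinelPair:
    contig_id: str
    vgrg_genes: list[GeneRecord]
    clpv_genes: list[GeneRecord]

    @property
    def ordinals(self) -> list[int]:
        return sorted(g.ordinal for g in self.vgrg_genes + self.clpv_genes)


@dataclass
class RawWindow:
    genome_id: str
    contig_id: str
    genes: list[GeneRecord]  # contiguous in ordinals
    pair: SentinelPair | None = None


def find_sentinel_pairs(hits: list[MotifHit], genome: GenomeRecord, config,
                        vgrg_profile: str = "VgrG", clpv_profile: str = "ClpV",
                        ) -> list[SentinelPair]:
    """Co-localized sentinel pairs: same contig, at most
    config.max_sentinel_gene_gap intervening genes. Pairs sharing a gene are
    merged into one candidate neighborhood (union of sentinels)."""
    genes = {g.gene_id: g for g in genome.iter_genes()}
    vgrg = [genes[h.gene_id] for h in hits if h.profile_name == vgrg_profile]
    clpv = [genes[h.gene_id] for h in hits if h.profile_name == clpv_profile]
    raw_pairs = []
    for v in vgrg:
        for c in clpv:
            if v.contig_id != c.contig_id:
                continue
            if abs(v.ordinal - c.ordinal) - 1 <= config.max_sentinel_gene_gap:
                raw_pairs.append((v, c))
    # merge pairs sharing any gene (the locus, not the pair, is the unit)
    merged: list[SentinelPair] = []
    for v, c in raw_pairs:
        home = None
        for cand in merged:
            if cand.contig_id == v.contig_id and (
                    v in cand.vgrg_genes or c in cand.clpv_genes):
                home = cand
                break
        if home is None:
            merged.append(SentinelPair(v.contig_id, [v], [c]))
        else:
            if v not in home.vgrg_genes:
                home.vgrg_genes.append(v)
            if c not in home.clpv_genes:
                home.clpv_genes.append(c)
    return merged


def extract_region(genome: GenomeRecord, pair: SentinelPair, config) -> RawWindow:
    """All genes between the outermost sentinels plus flank_genes each
    side, truncated at contig ends."""
    contig = genome.contig(pair.contig_id)
    ordinals = pair.ordinals
    lo = max(0, ordinals[0] - config.flank_genes)
    hi = min(len(contig.genes) - 1, ordinals[-1] + config.flank_genes)
    return RawWindow(genome.genome_id, pair.contig_id,
                     contig.genes[lo:hi + 1], pair)


def trim_region(window: RawWindow, annotations: dict[str, FamilyAnnotation],
                locus_id: str, discovery_pass: int = 1,
                max_interior_gap: int = 5) -> LocusRegion:
    """Trim a raw window to the contiguous block of family-labelled genes.

    Labelled genes chain together while at most max_interior_gap unlabelled
    genes separate them (interior unlabelled genes are kept); the block
    holding the sentinel pair anchors the trim, else the largest block.
    Standalone labelled genes far out in the flanks (the decoy clpV/hcp/tetR
    situation) therefore stay outside the locus.
    """
    labelled = [i for i, g in enumerate(window.genes)
                if g.gene_id in annotations
                and annotations[g.gene_id].family in TRIM_KEEP_FAMILIES]
    if not labelled:
        raise ValueError(f"window on {window.contig_id} has no labelled genes")
    blocks = [[labelled[0]]]
    for i in labelled[1:]:
        if i - blocks[-1][-1] - 1 <= max_interior_gap:
            blocks[-1].append(i)
        else:
            blocks.append([i])
    anchor = None
    if window.pair is not None:
        vgrg_ids = {g.gene_id for g in window.pair.vgrg_genes}
        clpv_ids = {g.gene_id for g in window.pair.clpv_genes}

        def block_rank(b):
            ids = {window.genes[i].gene_id for i in b}
            # a block holding both sentinel kinds is the true locus core;
            # a lone sentinel out in the flank is a standalone decoy
            return (bool(ids & vgrg_ids) + bool(ids & clpv_ids), len(b))

        ranked = max(blocks, key=block_rank)
        if block_rank(ranked)[0] > 0:
            anchor = ranked
    if anchor is None:
        anchor = max(blocks, key=len)
    genes = window.genes[anchor[0]:anchor[-1] + 1]
    ann = {g.gene_id: annotations[g.gene_id] for g in genes
           if g.gene_id in annotations}
    return LocusRegion(locus_id, window.genome_id, [window.contig_id],
                       genes, discovery_pass, ann)


def orient_region(locus: LocusRegion) -> LocusRegion:
    """Orient so that vgrG is transcribed left to right; the anchor is the
    highest-scoring VgrG gene. Idempotent; the gene list keeps genomic
    order, only the display flag flips."""
    vgrgs = [(locus.annotations[g.gene_id].score, g) for g in locus.genes
             if g.gene_id in locus.annotations
             and locus.annotations[g.gene_id].family == "VgrG"]
    if not vgrgs:
        raise ValueError(f"{locus.locus_id}: no VgrG gene to orient on")
    anchor = max(vgrgs, key=lambda t: t[0])[1]
    locus.flipped = anchor.strand == "-"
    locus.oriented = True
    return locus


def second_pass_scan(profiles, genomes, config,
                     pass1_loci: list[LocusRegion] | None = None,
                     ) -> tuple[list[LocusRegion], list[MotifHit]]:
    """Sliding-window rescan with self-thresholded family profiles.

    A new locus is called where a pass2_window_genes-gene window carries
    hits of >= pass2_min_core_families distinct core Tss families and does
    not overlap a pass-1 locus. Hits outside every locus come back as
    orphans (the standalone clpV/hcp/tetR observation).
    """
    pass1_loci = pass1_loci or []
    claimed = {gid for l in pass1_loci for gid in l.gene_ids}
    loci: list[LocusRegion] = []
    orphans: list[MotifHit] = []
    counter = len(pass1_loci)
    for genome in genomes:
        gene_hits: dict[str, tuple[FamilyAnnotation, GeneRecord]] = {}
        for contig in genome.contigs:
            for gene in contig.genes:
                best = None
                for prof in profiles:
                    if prof.threshold_score is None:
                        raise ValueError(f"profile {prof.name} has no threshold")
                    if not prof.shares_words(gene.protein):
                        continue
                    score, span = score_protein(prof, gene.protein)
                    if score >= prof.threshold_score and (
                            best is None or score > best[1]):
                        best = (prof.name, score, span)
                if best is not None:
                    name, score, span = best
                    fam = family_label(name.split("|")[0])
                    cluster = None
                    if "|" in name:
                        cluster = int(name.split("|")[1])
                    ann = FamilyAnnotation(fam, cluster, name, score)
                    gene_hits[gene.gene_id] = (ann, gene)
        new_gene_ids: set[str] = set()
        for contig in genome.contigs:
            hit_ords = [g.ordinal for g in contig.genes
                        if g.gene_id in gene_hits]
            if not hit_ords:
                continue
            W = config.pass2_window_genes
            keep: set[int] = set()
            for start in range(0, len(contig.genes)):
                inside = [o for o in hit_ords if start <= o < start + W]
                fams = {gene_hits[contig.genes[o].gene_id][0].family
                        for o in inside}
                if len(fams & CORE_TSS_FAMILIES) >= config.pass2_min_core_families:
                    keep.update(inside)
            if not keep:
                continue
            # group kept ordinals into regions separated by long gaps
            ords = sorted(keep)
            groups = [[ords[0]]]
            for o in ords[1:]:
                if o - groups[-1][-1] - 1 <= config.max_sentinel_gene_gap:
                    groups[-1].append(o)
                else:
                    groups.append([o])
            for grp in groups:
                genes = contig.genes[grp[0]:grp[-1] + 1]
                if any(g.gene_id in claimed for g in genes):
                    continue  # already part of a pass-1 locus
                grp_fams = {gene_hits[contig.genes[o].gene_id][0].family
                            for o in grp}
                if len(grp_fams & CORE_TSS_FAMILIES) < config.pass2_min_core_families:
                    continue  # stray decoys that rode along in a window
                counter += 1
                ann = {g.gene_id: gene_hits[g.gene_id][0] for g in genes
                       if g.gene_id in gene_hits}
                window = RawWindow(genome.genome_id, contig.contig_id, genes)
                locus = trim_region(window, ann, f"L{counter:03d}",
                                    discovery_pass=2,
                                    max_interior_gap=config.trim_max_gap)
                if any(a.family == "VgrG" for a in locus.annotations.values()):
                    orient_region(locus)
                loci.append(locus)
                new_gene_ids.update(locus.gene_ids)
        for ann, gene in gene_hits.values():
            if gene.gene_id not in claimed and gene.gene_id not in new_gene_ids:
                orphans.append(MotifHit(gene.gene_id, ann.profile_name,
                                        ann.score, ann.evalue or 0.0, (0, 0)))
    return loci, orphans
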
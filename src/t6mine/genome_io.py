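"""Genome containers and on-disk formats.

Internal coordinates are 0-based half-open nucleotide intervals; GFF3 I/O
converts to/from the 1-based inclusive convention. Gene "distance"
throughout the package is measured in ordinals (per-contig gene rank), the
unit of the within-fifteen-genes co-localization rule.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .profiles import EvalueCalibration, ProfileModel

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "ContigRecord",
    "GenomeRecord",
    "PipelineConfig",
    "read_genome_bundle",
    "write_genome_bundle",
    "read_protein_bundle",
    "read_profile_set",
    "write_profile_set",
    "write_locus_report",
    "write_orf_map",
]


@dataclass
class GeneRecord:
    gene_id: str
    contig_id: str
    start: int  # 0-based, inclusive
    end: int  # exclusive
    strand: str  # '+' or '-'
    ordinal: int  # 0-based rank on its contig by start
    protein: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.gene_id}: bad interval {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.protein:
            raise ValueError(f"{self.gene_id}: empty protein")


@dataclass
class ContigRecord:
    contig_id: str
    sequence: str
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self):
        for g in self.genes:
            if g.end > len(self.sequence):
                raise ValueError(f"{g.gene_id} extends past contig {self.contig_id}")


@dataclass
class GenomeRecord:
    genome_id: str
    species_label: str
    contigs: list[ContigRecord]

    def __post_init__(self):
        ids = [c.contig_id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.genome_id}: duplicate contig ids")
        gids = [g.gene_id for c in self.contigs for g in c.genes]
        if len(set(gids)) != len(gids):
            raise ValueError(f"{self.genome_id}: duplicate gene ids")

    def iter_genes(self):
        for c in self.contigs:
            yield from c.genes

    def contig(self, contig_id: str) -> ContigRecord:
        for c in self.contigs:
            if c.contig_id == contig_id:
                return c
        raise KeyError(contig_id)

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.iter_genes():
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass
class PipelineConfig:
    """Thresholds of the whole pipeline (defaults follow the study design)."""

    sentinel_evalue_max: float = 1e-3
    max_sentinel_gene_gap: int = 15  # max intervening genes between vgrG and clpV
    flank_genes: int = 25
    cluster_identity_min: float = 0.30
    cluster_coverage_min: float = 0.70
    hsp_min_len: int = 1000  # bp
    ice_window_bp: int = 50_000
    toxin_evalue_max: float = 1e-3
    rng_seed: int = 1
    # second pass (HMM-style rescan)
    pass2_window_genes: int = 30
    pass2_min_core_families: int = 4
    # trimming: max unlabelled genes bridged inside a locus
    trim_max_gap: int = 5
    # profile calibration
    decoy_db_size: int = 10_000
    calibration_shuffles: int = 200
    # conserved/variable region delineation
    conserved_coverage_min: float = 0.8
    conserved_merge_gap_bp: int = 200
    variable_min_len_bp: int = 500
    # blastn-like HSP search
    hsp_word: int = 11
    hsp_match: float = 1.0
    hsp_mismatch: float = -2.0
    hsp_xdrop: float = 40.0
    # architecture scoring
    architecture_score_min: float = 0.7

    def __post_init__(self):
        for name in ("sentinel_evalue_max", "max_sentinel_gene_gap", "flank_genes",
                     "hsp_min_len", "ice_window_bp", "toxin_evalue_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("cluster_identity_min", "cluster_coverage_min"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")


# ---------------------------------------------------------------------------
# FASTA + GFF3

def _translate_cds(cds: str) -> str:
    prot = str(Seq(cds).translate(table=11))
    return prot[:-1] if prot.endswith("*") else prot


def read_genome_bundle(fasta_path, gff_path, genome_id: str | None = None,
                       species_label: str = "") -> GenomeRecord:
    """Load an annotated genome from nucleotide FASTA + GFF3 CDS features.

    CDS proteins are translated with the bacterial code (table 11, stop
    stripped, codons containing N give X); GFF3 1-based inclusive
    coordinates become internal 0-based half-open; ordinals are assigned
    per contig in start order. A GFF contig absent from the FASTA is a hard
    error; a CDS whose length is not divisible by 3 is skipped with a
    warning.
    """
    fasta_path = Path(fasta_path)
    contigs: dict[str, str] = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    raw: dict[str, list] = {cid: [] for cid in contigs}
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{gff_path}:{lineno}: expected 9 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "CDS":
                continue
            if seqid not in contigs:
                raise ValueError(
                    f"{gff_path}:{lineno}: contig {seqid!r} not present in FASTA")
            start0, end0 = int(start) - 1, int(end)
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            gid = attr_map.get("ID", f"{seqid}_{lineno}")
            if (end0 - start0) % 3 != 0:
                logger.warning("skipping CDS %s: length not divisible by 3", gid)
                continue
            cds = contigs[seqid][start0:end0]
            if strand == "-":
                cds = str(Seq(cds).reverse_complement())
            raw[seqid].append((start0, end0, strand, gid, _translate_cds(cds)))
    out = []
    for cid, seq in contigs.items():
        genes = []
        for ordinal, (s, e, strand, gid, prot) in enumerate(sorted(raw[cid])):
            genes.append(GeneRecord(gid, cid, s, e, strand, ordinal, prot))
        out.append(ContigRecord(cid, seq, genes))
    gid = genome_id or fasta_path.stem
    return GenomeRecord(gid, species_label, out)


def write_genome_bundle(genome: GenomeRecord, fasta_path, gff_path) -> None:
    records = [SeqRecord(Seq(c.sequence), id=c.contig_id, description="")
               for c in genome.contigs]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in genome.contigs:
            fh.write(f"##sequence-region {c.contig_id} 1 {len(c.sequence)}\n")
        for c in genome.contigs:
            for g in c.genes:
                fh.write("\t".join([
                    c.contig_id, "t6mine", "CDS", str(g.start + 1), str(g.end),
                    ".", g.strand, "0", f"ID={g.gene_id}",
                ]) + "\n")


def read_protein_bundle(protein_fasta, coords_tsv, genome_id: str,
                        species_label: str = "") -> GenomeRecord:
    """Alternative loader: protein FASTA plus a 4-column coordinate table
    (contig, start, end, strand; 0-based half-open). Contig sequences are
    unknown and stand in as N runs of the required length."""
    prots = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(protein_fasta), "fasta")}
    per_contig: dict[str, list] = {}
    with open(coords_tsv) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            gid, cid, start, end, strand = line.split("\t")[:5]
            per_contig.setdefault(cid, []).append(
                (int(start), int(end), strand.strip(), gid))
    contigs = []
    for cid, rows in per_contig.items():
        length = max(e for _s, e, _st, _g in rows)
        genes = [GeneRecord(gid, cid, s, e, st, i, prots[gid])
                 for i, (s, e, st, gid) in enumerate(sorted(rows))]
        contigs.append(ContigRecord(cid, "N" * length, genes))
    return GenomeRecord(genome_id, species_label, contigs)


def reverse_complement_contig(genome: GenomeRecord, contig_id: str) -> GenomeRecord:
    """Mirror one contig (sequence reverse-complemented, gene coordinates
    and strands mapped); detection results must be invariant to this."""
    contigs = []
    for c in genome.contigs:
        if c.contig_id != contig_id:
            contigs.append(c)
            continue
        L = len(c.sequence)
        seq = str(Seq(c.sequence).reverse_complement())
        genes = []
        for g in reversed(c.genes):
            genes.append(GeneRecord(
                g.gene_id, c.contig_id, L - g.end, L - g.start,
                "-" if g.strand == "+" else "+", len(genes), g.protein))
        contigs.append(ContigRecord(c.contig_id, seq, genes))
    return GenomeRecord(genome.genome_id, genome.species_label, contigs)


# ---------------------------------------------------------------------------
# Profile set text format
#
# Per record:
#   >name length aa
#   <length> whitespace-separated rows of 20 log-odds values (bits)
#   #null f1 .. f20
#   #threshold x                    (optional)
#   #calibration db lambda n s1..sn (optional, empirical null sample)

def read_profile_set(path) -> list[ProfileModel]:
    profiles: list[ProfileModel] = []
    name = None
    length = 0
    rows: list[list[float]] = []
    null = None
    threshold = None
    cal = None

    def flush(lineno):
        nonlocal name, rows, null, threshold, cal
        if name is None:
            return
        if len(rows) != length:
            raise ValueError(f"{path}:{lineno}: profile {name} declares length "
                             f"{length} but has {len(rows)} rows")
        if null is None:
            raise ValueError(f"{path}:{lineno}: profile {name} missing #null line")
        prof = ProfileModel(name, np.array(rows), np.array(null),
                            threshold_score=threshold, calibration=cal)
        profiles.append(prof)
        name, rows, null, threshold, cal = None, [], None, None, None

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                parts = line[1:].split()
                if len(parts) != 3 or parts[2] != "aa":
                    raise ValueError(f"{path}:{lineno}: malformed header")
                name, length = parts[0], int(parts[1])
            elif line.startswith("#null"):
                null = [float(x) for x in line.split()[1:]]
                if len(null) != 20:
                    raise ValueError(f"{path}:{lineno}: #null needs 20 values")
            elif line.startswith("#threshold"):
                threshold = float(line.split()[1])
            elif line.startswith("#calibration"):
                parts = line.split()[1:]
                db, lam, n = float(parts[0]), float(parts[1]), int(parts[2])
                scores = np.array([float(x) for x in parts[3:]])
                if scores.size != n:
                    raise ValueError(f"{path}:{lineno}: calibration sample size "
                                     f"mismatch ({scores.size} != {n})")
                cal = EvalueCalibration(db, scores, lam)
            else:
                try:
                    row = [float(x) for x in line.split()]
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed matrix row") from exc
                if len(row) != 20:
                    raise ValueError(f"{path}:{lineno}: matrix row needs 20 values, "
                                     f"got {len(row)}")
                rows.append(row)
        flush("EOF")
    return profiles


def write_profile_set(profiles: list[ProfileModel], path) -> None:
    with open(path, "w") as fh:
        for p in profiles:
            fh.write(f">{p.name} {p.length} aa\n")
            for row in p.match_scores:
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
            fh.write("#null " + " ".join(f"{v:.12g}" for v in p.null_freqs) + "\n")
            if p.threshold_score is not None:
                fh.write(f"#threshold {p.threshold_score:.10g}\n")
            if p.calibration is not None:
                c = p.calibration
                fh.write(f"#calibration {c.db_size:.1f} {c.tail_lambda:.6f} "
                         f"{c.null_scores.size} "
                         + " ".join(f"{s:.4f}" for s in c.null_scores) + "\n")


# ---------------------------------------------------------------------------
# Reports

LOCUS_REPORT_COLUMNS = [
    "genome_id", "locus_id", "contig_ids", "start", "end", "architecture",
    "n_genes", "discovery_pass", "families",
]


def write_locus_report(loci, path) -> None:
    """TSV, one row per locus (deterministic: loci written in given order)."""
    with open(path, "w") as fh:
        fh.write("\t".join(LOCUS_REPORT_COLUMNS) + "\n")
        for locus in loci:
            spans = locus.spans
            start = min(s for s, _e in spans.values())
            end = max(e for _s, e in spans.values())
            families = ",".join(
                locus.annotations[g.gene_id].family if g.gene_id in locus.annotations
                else "unknown"
                for g in locus.genes)
            fh.write("\t".join([
                locus.genome_id, locus.locus_id, ",".join(locus.contig_ids),
                str(start), str(end),
                locus.architecture or "unclassified",
                str(len(locus.genes)), str(locus.discovery_pass), families,
            ]) + "\n")


_PALETTE = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd", "#8c564b",
    "#e377c2", "#7f7f7f", "#bcbd22", "#17becf", "#aec7e8", "#ffbb78",
    "#98df8a", "#ff9896", "#c5b0d5", "#c49c94", "#f7b6d2", "#c7c7c7",
    "#dbdb8d", "#9edae5", "#393b79", "#637939", "#8c6d31", "#843c39",
    "#7b4173", "#5254a3", "#8ca252", "#bd9e39", "#ad494a", "#a55194",
]


def write_orf_map(locus, path) -> None:
    """JSON arrow document for one oriented locus (the ORF-map figure
    twin): per-gene offset from the locus start, length, strand after
    orientation, family label and cluster id. The color key is a pure
    function of the sorted family roster so same-roster loci share keys."""
    genes = locus.oriented_genes()
    families = sorted({locus.annotations[g.gene_id].family
                       for g, _s in genes if g.gene_id in locus.annotations})
    colors = {fam: _PALETTE[i % len(_PALETTE)] for i, fam in enumerate(families)}
    span_start = min(g.start for g, _s in genes)
    span_end = max(g.end for g, _s in genes)
    arrows = []
    for g, strand in genes:
        ann = locus.annotations.get(g.gene_id)
        if locus.flipped:
            offset = span_end - g.end
        else:
            offset = g.start - span_start
        arrows.append({
            "gene_id": g.gene_id,
            "offset": offset,
            "length": g.end - g.start,
            "strand": strand,
            "family": ann.family if ann else "unknown",
            "cluster_id": ann.cluster_id if ann else None,
            "color": colors.get(ann.family) if ann else None,
        })
    doc = {"locus_id": locus.locus_id, "genome_id": locus.genome_id,
           "architecture": locus.architecture, "color_key": colors,
           "arrows": arrows}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
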
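"""Seeded synthetic Bacteroidales-like genome sets with implanted T6SS loci.

The generator emulates the statistical structure the pipeline assumes:
multi-contig draft genomes whose background genes are random proteins, with
implanted GA1/GA2/GA3 loci diverged from per-family consensuses, tra-gene
(ICE) flanks for GA1/GA2, decoy standalone clpV/hcp/tetR/rhs genes, and a
fraction of loci split across contigs between clpV and vgrG. Ground truth
is recorded for every implant so detection, classification and ICE verdicts
can be scored exactly.

DNA model: each family consensus is back-translated once per registry
(seeded uniform synonymous codons) into a reference CDS; every implanted
copy mutates residues i.i.d. and inherits the reference codon wherever the
residue is unchanged. DNA divergence therefore tracks amino-acid
divergence, preserving the high within-architecture DNA identity the
analysis relies on.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from ._aln import AA_ALPHABET
from .genome_io import ContigRecord, GeneRecord, GenomeRecord
from .profiles import ProfileModel

__all__ = [
    "ArchitectureTemplate", "TruthLocus", "TruthRecord", "SynthConfig",
    "FamilyRegistry", "generate_family_consensus", "mutate_protein",
    "mutate_dna", "implant_locus", "generate_genome_set",
    "GA_TEMPLATES", "TRA_ROSTERS", "family_label", "CORE_TSS_FAMILIES",
]

# ---------------------------------------------------------------------------
# Family vocabulary

CORE_TSS = ["TssB", "TssC", "TssE", "TssF", "TssG", "TssK",
            "TssN", "TssO", "TssP", "TssQ", "TssR"]
SENTINELS = ["VgrG", "ClpV"]
TAGS = ["TagA", "TagB", "TagC"]
TETR = ["TetR.a", "TetR.b"]
HCP = [f"Hcp.c{i}" for i in range(1, 9)]
ACCESSORY = ["PAAR", "Rhs"]
TRA_FAMILIES = ["TraD", "TraG", "TraI", "TraJ", "TraK",
                "TraM", "TraN", "TraO", "TrbJ"]
TOXINS = ["Tox.nuclease", "Tox.deaminase", "Tox.pore", "Tox.hcptail"]
IMMUNITY = ["Imm.nuclease", "Imm.deaminase", "Imm.pore"]

ALL_FAMILIES = (CORE_TSS + SENTINELS + TAGS + TETR + HCP + ACCESSORY
                + TRA_FAMILIES + TOXINS + IMMUNITY)

# families whose hits count toward the pass-2 trigger
CORE_TSS_FAMILIES = set(CORE_TSS) | {"Hcp", "VgrG", "ClpV"}

TOXIN_KINDS = ["nuclease", "deaminase", "pore"]

_FIXED_LENGTHS = {f: 160 for f in HCP}
_FIXED_LENGTHS["Tox.hcptail"] = 120


def family_label(profile_name: str) -> str:
    """Canonical family label for a profile/subfamily name."""
    if profile_name.startswith("Tox."):
        return "effector"
    if profile_name.startswith("Imm."):
        return "immunity"
    if profile_name in TRA_FAMILIES:
        return "Tra"
    if profile_name == "EvolvedHcp":
        return "Hcp"
    return profile_name.split(".")[0]


@dataclass
class ArchitectureTemplate:
    name: str
    gene_order: list[str]  # subfamily names; "TOX"/"IMM" mark variable slots
    variable_slots: list[int]

    def __post_init__(self):
        for sentinel in ("VgrG", "ClpV"):
            if self.gene_order.count(sentinel) != 1:
                raise ValueError(f"{self.name}: {sentinel} must appear exactly once")


GA_TEMPLATES = {
    "GA1": ArchitectureTemplate("GA1", [
        "TetR.a", "TssB", "TssC", "Hcp.c1", "TssE", "TssF", "TssG", "TssK",
        "TssN", "TssO", "TssP", "TssQ", "TssR", "TagA", "TagB", "ClpV",
        "VgrG", "Hcp.c1", "PAAR", "TOX", "IMM",
    ], variable_slots=[19, 20]),
    "GA2": ArchitectureTemplate("GA2", [
        "TetR.b", "TssB", "TssC", "Hcp.c1", "TssE", "TssF", "TssG", "TssK",
        "TssN", "TssO", "TssP", "TssQ", "TssR", "Hcp.c2", "Hcp.c3", "Hcp.c4",
        "Hcp.c4", "EvolvedHcp", "TagA", "ClpV", "VgrG", "TOX", "IMM",
    ], variable_slots=[21, 22]),
    "GA3": ArchitectureTemplate("GA3", [
        "TetR.a", "TssB", "TssC", "Hcp.c1", "Hcp.c6", "Hcp.c7", "Hcp.c8",
        "Hcp.c8", "TssE", "TssF", "TssG", "TssK", "TssN", "TssO", "TssP",
        "TssQ", "TssR", "TOX", "IMM", "TagC", "ClpV", "VgrG", "TOX", "IMM",
    ], variable_slots=[17, 18, 22, 23]),
}

# tra-gene order flanking each ICE-borne architecture, left to right
TRA_ROSTERS = {
    "GA1": ["TraG", "TraK", "TraM", "TraN", "TraD"],
    "GA2": ["TraO", "TraN", "TraM", "TraK", "TraJ", "TrbJ",
            "TraG", "TraI", "TraD"],
}


# ---------------------------------------------------------------------------
# Registry: consensuses, reference CDSs, curated profiles

_table11 = CodonTable.unambiguous_dna_by_id[11]
_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(_table11.forward_table.items()):
    _AA_TO_CODONS.setdefault(aa, []).append(codon)


@dataclass
class FamilyRegistry:
    seed: int
    consensus: dict[str, str]
    reference_cds: dict[str, str]  # stop codon excluded
    profiles: dict[str, ProfileModel]
    # per-architecture intergenic spacer templates: loci of one architecture
    # share descent, so their spacers diverge from a common template rather
    # than being independent random DNA
    locus_spacers: dict[str, list[str]] = field(default_factory=dict)
    tra_spacers: dict[str, list[str]] = field(default_factory=dict)

    def profile_sets(self) -> dict[str, list[ProfileModel]]:
        fam = CORE_TSS + SENTINELS + TAGS + TETR + HCP + ACCESSORY
        return {
            "sentinel": [self.profiles[f] for f in SENTINELS],
            "family": [self.profiles[f] for f in fam],
            "tra": [self.profiles[f] for f in TRA_FAMILIES],
            "toxin": [self.profiles[f] for f in TOXINS + IMMUNITY],
        }


def _random_protein(rng, length: int) -> str:
    return "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, size=length))


def _consensus_profile(name: str, consensus: str) -> ProfileModel:
    """Log-odds of a 90%-consensus / 10%-background emission vs uniform."""
    L = len(consensus)
    scores = np.full((L, 20), np.log2((0.1 / 20) / (1 / 20)))
    hit = np.log2((0.9 + 0.1 / 20) / (1 / 20))
    for i, aa in enumerate(consensus):
        scores[i, AA_ALPHABET.index(aa)] = hit
    return ProfileModel(name, scores, np.full(20, 1 / 20))


def back_translate(protein: str, rng) -> str:
    """Uniform synonymous codon choice (no stop codon appended)."""
    return "".join(
        _AA_TO_CODONS[aa][int(rng.integers(len(_AA_TO_CODONS[aa])))]
        for aa in protein)


def generate_family_consensus(seed: int) -> FamilyRegistry:
    """Fixed-length random consensus (80-600 aa) per family, a reference
    CDS per family, and a curated profile per family. Inter-family
    identity is far below the 30%/70% clustering cut by construction
    (independent uniform sequences)."""
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 101])
    consensus: dict[str, str] = {}
    cds: dict[str, str] = {}
    profiles: dict[str, ProfileModel] = {}
    for fam in ALL_FAMILIES:
        length = _FIXED_LENGTHS.get(fam, int(rng.integers(80, 601)))
        consensus[fam] = _random_protein(rng, length)
        cds[fam] = back_translate(consensus[fam], rng)
        profiles[fam] = _consensus_profile(fam, consensus[fam])
    # evolved Hcp: Hcp domain (subfamily c5) fused to a toxin tail
    consensus["EvolvedHcp"] = consensus["Hcp.c5"] + consensus["Tox.hcptail"]
    cds["EvolvedHcp"] = cds["Hcp.c5"] + cds["Tox.hcptail"]
    profiles["Hcp.c5"] = _consensus_profile("Hcp.c5", consensus["Hcp.c5"])
    registry = FamilyRegistry(seed, consensus, cds, profiles)

    def spacer():
        n = int(rng.integers(20, 201))
        return "".join(_NT[i] for i in rng.integers(0, 4, size=n))

    for arch, template in GA_TEMPLATES.items():
        registry.locus_spacers[arch] = [spacer()
                                        for _ in template.gene_order]
        registry.tra_spacers[arch] = [spacer()
                                      for _ in TRA_ROSTERS.get(arch, [])]
    return registry


def mutate_protein(protein: str, rate: float, rng) -> str:
    """I.i.d. substitutions at the given per-residue rate; a substitution
    draws uniformly from all 20 residues (so rate 1 leaves ~1/20 identity)."""
    if not (0 <= rate <= 1):
        raise ValueError("rate must be in [0, 1]")
    if rate == 0 or not protein:
        return protein
    arr = list(protein)
    mask = rng.random(len(arr)) < rate
    draws = rng.integers(0, 20, size=int(mask.sum()))
    k = 0
    for i, hit in enumerate(mask):
        if hit:
            arr[i] = AA_ALPHABET[draws[k]]
            k += 1
    return "".join(arr)


_NT = "ACGT"


def mutate_dna(seq: str, rate: float, rng) -> str:
    """Nucleotide substitutions to a uniformly chosen different base."""
    arr = list(seq)
    mask = rng.random(len(arr)) < rate
    for i in np.flatnonzero(mask):
        choices = _NT.replace(arr[i], "") if arr[i] in _NT else _NT
        arr[i] = choices[int(rng.integers(len(choices)))]
    return "".join(arr)


# ---------------------------------------------------------------------------
# Genome drafting

@dataclass
class _GeneSpec:
    subfamily: str | None  # registry name, None for background
    protein: str
    cds: str  # coding strand, stop codon included
    strand: str
    role: str  # background | locus | tra | decoy
    spacer_before: str | None = None  # template-derived intergenic DNA


@dataclass
class TruthLocus:
    architecture: str
    gene_ids: list[str]
    families: dict[str, str]  # gene_id -> canonical family label
    contig_ids: list[str]
    spans: dict[str, tuple[int, int]]
    split_across_contigs: bool
    tra_gene_ids: list[str] = field(default_factory=list)
    ice_span: tuple[str, int, int] | None = None  # (contig, start, end)


@dataclass
class TruthRecord:
    genome_id: str
    loci: list[TruthLocus]
    decoy_gene_ids: list[str]

    def to_json(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "decoy_gene_ids": self.decoy_gene_ids,
            "loci": [{
                "architecture": l.architecture,
                "gene_ids": l.gene_ids,
                "families": l.families,
                "contig_ids": l.contig_ids,
                "spans": {k: list(v) for k, v in l.spans.items()},
                "split_across_contigs": l.split_across_contigs,
                "tra_gene_ids": l.tra_gene_ids,
                "ice_span": list(l.ice_span) if l.ice_span else None,
            } for l in self.loci],
        }

    @classmethod
    def from_json(cls, doc: dict) -> "TruthRecord":
        loci = [TruthLocus(
            architecture=d["architecture"], gene_ids=d["gene_ids"],
            families=d["families"], contig_ids=d["contig_ids"],
            spans={k: tuple(v) for k, v in d["spans"].items()},
            split_across_contigs=d["split_across_contigs"],
            tra_gene_ids=d["tra_gene_ids"],
            ice_span=tuple(d["ice_span"]) if d["ice_span"] else None,
        ) for d in doc["loci"]]
        return cls(doc["genome_id"], loci, doc["decoy_gene_ids"])


@dataclass
class SynthConfig:
    n_genomes: int = 30
    architecture_mix: dict = field(
        default_factory=lambda: {"GA1": 10, "GA2": 5, "GA3": 10, "none": 5})
    mutation_rate: float = 0.05
    contig_split_prob: float = 0.2
    decoy_rate: float = 0.05
    background_genes: int = 55
    seed: int = 1

    def __post_init__(self):
        if sum(self.architecture_mix.values()) != self.n_genomes:
            raise ValueError("architecture_mix must sum to n_genomes")
        for name in ("mutation_rate", "contig_split_prob", "decoy_rate"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")


DECOY_FAMILIES = ["ClpV", "Hcp.c1", "TetR.a", "Rhs"]


def _family_gene(registry, subfamily: str, rate: float, rng, role: str) -> _GeneSpec:
    cons = registry.consensus[subfamily]
    ref = registry.reference_cds[subfamily]
    prot = mutate_protein(cons, rate, rng)
    codons = []
    for i, aa in enumerate(prot):
        if aa == cons[i]:
            codons.append(ref[3 * i: 3 * i + 3])
        else:
            opts = _AA_TO_CODONS[aa]
            codons.append(opts[int(rng.integers(len(opts)))])
    return _GeneSpec(subfamily, prot, "".join(codons) + "TAA", "+", role)


def _background_gene(rng) -> _GeneSpec:
    prot = _random_protein(rng, int(rng.integers(100, 401)))
    return _GeneSpec(None, prot, back_translate(prot, rng) + "TAA", "+", "background")


def implant_locus(template: ArchitectureTemplate, registry: FamilyRegistry,
                  mutation_rate: float, rng) -> tuple[list[_GeneSpec], list[_GeneSpec]]:
    """Materialize one locus from a template: per-family mutated proteins
    with codon-memory back-translation, variable effector/immunity slots
    drawn per locus, plus the architecture's tra flank (empty for GA3)."""
    # intergenic DNA diverges from the architecture's shared spacer
    # template at roughly the coding-region nucleotide rate (~0.6 of the
    # per-residue rate)
    dna_rate = 0.6 * mutation_rate
    genes = []
    kind = None
    for i, slot in enumerate(template.gene_order):
        if slot == "TOX":
            # each variable region draws its own effector/immunity pair
            kind = TOXIN_KINDS[int(rng.integers(len(TOXIN_KINDS)))]
            sub = f"Tox.{kind}"
        elif slot == "IMM":
            sub = f"Imm.{kind}"
        else:
            sub = slot
        gene = _family_gene(registry, sub, mutation_rate, rng, "locus")
        gene.spacer_before = mutate_dna(
            registry.locus_spacers[template.name][i], dna_rate, rng)
        genes.append(gene)
    tra = []
    for i, fam in enumerate(TRA_ROSTERS.get(template.name, [])):
        gene = _family_gene(registry, fam, mutation_rate, rng, "tra")
        gene.spacer_before = mutate_dna(
            registry.tra_spacers[template.name][i], dna_rate, rng)
        tra.append(gene)
    return genes, tra


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp.get(b, "N") for b in reversed(seq))


def _flip_block(specs: list[_GeneSpec]) -> list[_GeneSpec]:
    """Reverse-complement a gene block as a unit: order reversed, strands
    flipped, and each spacer moves to precede the gene that followed it."""
    n = len(specs)
    spacers = [s.spacer_before for s in specs]
    out = list(reversed(specs))
    for s in out:
        s.strand = "-" if s.strand == "+" else "+"
    for j, s in enumerate(out):
        src = spacers[n - j] if 1 <= j else None
        s.spacer_before = _revcomp(src) if src else None
    return out


def _materialize_contig(contig_id: str, specs: list[_GeneSpec], rng,
                        next_gene_no) -> tuple[ContigRecord, list[tuple[str, _GeneSpec]]]:
    """Lay genes along a contig with random 20-200 bp spacers; returns the
    contig and (gene_id, spec) pairs in emitted order."""
    parts = []
    pos = 0
    genes = []
    emitted = []
    for spec in specs:
        if spec.spacer_before is not None:
            spacer = spec.spacer_before
        else:
            spacer_len = int(rng.integers(20, 201))
            spacer = "".join(_NT[i] for i in rng.integers(0, 4, size=spacer_len))
        parts.append(spacer)
        pos += len(spacer)
        cds = spec.cds if spec.strand == "+" else _revcomp(spec.cds)
        start, end = pos, pos + len(cds)
        parts.append(cds)
        pos = end
        gene_id = next_gene_no()
        genes.append(GeneRecord(gene_id, contig_id, start, end, spec.strand,
                                len(genes), spec.protein))
        emitted.append((gene_id, spec))
    tail = int(rng.integers(20, 201))
    parts.append("".join(_NT[i] for i in rng.integers(0, 4, size=tail)))
    return ContigRecord(contig_id, "".join(parts), genes), emitted


def _build_genome(genome_id: str, architecture: str, config: SynthConfig,
                  registry: FamilyRegistry, rng) -> tuple[GenomeRecord, TruthRecord]:
    n_bg = config.background_genes + int(rng.integers(-10, 11))
    bg_specs = []
    decoy_flags = []
    for _ in range(n_bg):
        if rng.random() < config.decoy_rate:
            fam = DECOY_FAMILIES[int(rng.integers(len(DECOY_FAMILIES)))]
            bg_specs.append(_family_gene(registry, fam, config.mutation_rate,
                                         rng, "decoy"))
            decoy_flags.append(True)
        else:
            bg_specs.append(_background_gene(rng))
            decoy_flags.append(False)

    # split background across three contigs
    cut1 = n_bg // 3
    cut2 = 2 * n_bg // 3
    contig_specs: list[list[_GeneSpec]] = [
        bg_specs[:cut1], bg_specs[cut1:cut2], bg_specs[cut2:]]

    split = False
    part2: list[_GeneSpec] = []
    if architecture != "none":
        template = GA_TEMPLATES[architecture]
        locus, tra = implant_locus(template, registry, config.mutation_rate, rng)
        gap = [_background_gene(rng) for _ in range(int(rng.integers(0, 3)))]
        implant = tra + gap + locus
        split = bool(rng.random() < config.contig_split_prob)
        flip = bool(rng.random() < 0.5)
        if split:
            vgrg_at = next(i for i, s in enumerate(implant)
                           if s.subfamily == "VgrG")
            part2 = implant[vgrg_at:]
            implant = implant[:vgrg_at]
        if flip:
            implant = _flip_block(implant)
            if part2:
                part2 = _flip_block(part2)
        at = int(rng.integers(0, len(contig_specs[0]) + 1))
        contig_specs[0] = contig_specs[0][:at] + implant + contig_specs[0][at:]
        if part2:
            part2 = part2 + [_background_gene(rng) for _ in range(2)]
            contig_specs.append(part2)

    contigs = []
    emitted_all: list[tuple[str, str, _GeneSpec]] = []  # (gene_id, contig_id, spec)
    counter = [0]

    def next_gene_no():
        counter[0] += 1
        return f"{genome_id}_g{counter[0]:04d}"

    for ci, specs in enumerate(contig_specs):
        cid = f"{genome_id}_c{ci + 1}"
        contig, emitted = _materialize_contig(cid, specs, rng, next_gene_no)
        contigs.append(contig)
        emitted_all.extend((gid, cid, spec) for gid, spec in emitted)
    genome = GenomeRecord(genome_id, f"synthetic ({architecture})", contigs)

    decoys = [gid for gid, _cid, spec in emitted_all if spec.role == "decoy"]
    loci = []
    if architecture != "none":
        locus_entries = [(gid, cid, s) for gid, cid, s in emitted_all
                         if s.role == "locus"]
        tra_entries = [(gid, cid, s) for gid, cid, s in emitted_all
                       if s.role == "tra"]
        gene_ids = [gid for gid, _c, _s in locus_entries]
        families = {gid: family_label(s.subfamily)
                    for gid, _c, s in locus_entries}
        contig_ids = sorted({cid for _g, cid, _s in locus_entries},
                            key=lambda c: [x.contig_id for x in contigs].index(c))
        spans = {}
        for cid in contig_ids:
            coords = [genome.gene(gid) for gid, c, _s in locus_entries if c == cid]
            spans[cid] = (min(g.start for g in coords), max(g.end for g in coords))
        ice_span = None
        tra_ids = [gid for gid, _c, _s in tra_entries]
        if tra_ids:
            # ICE = everything from the outermost tra gene to the locus end
            # on the tra-bearing contig
            tcid = tra_entries[0][1]
            coords = [genome.gene(g) for g in tra_ids] + [
                genome.gene(gid) for gid, c, _s in locus_entries if c == tcid]
            ice_span = (tcid, min(g.start for g in coords),
                        max(g.end for g in coords))
        loci.append(TruthLocus(architecture, gene_ids, families, contig_ids,
                               spans, split, tra_ids, ice_span))
    return genome, TruthRecord(genome_id, loci, decoys)


def generate_genome_set(config: SynthConfig,
                        registry: FamilyRegistry | None = None,
                        ) -> tuple[list[GenomeRecord], list[TruthRecord]]:
    """Deterministic synthetic genome collection with ground truth."""
    if registry is None:
        registry = generate_family_consensus(config.seed)
    assignments = []
    for arch in ("GA1", "GA2", "GA3", "none"):
        assignments += [arch] * config.architecture_mix.get(arch, 0)
    genomes, truths = [], []
    for i, arch in enumerate(assignments):
        rng = np.random.default_rng([int(config.seed) & 0x7FFFFFFF, 202, i])
        genome_id = f"SYN{i:03d}"
        g, t = _build_genome(genome_id, arch, config, registry, rng)
        genomes.append(g)
        truths.append(t)
    return genomes, truths


def write_genome_set(genomes, truths, outdir) -> None:
    from pathlib import Path

    from .genome_io import write_genome_bundle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for g in genomes:
        write_genome_bundle(g, outdir / f"{g.genome_id}.fna",
                            outdir / f"{g.genome_id}.gff")
    with open(outdir / "truth.json", "w") as fh:
        json.dump([t.to_json() for t in truths], fh, indent=1, sort_keys=True)
        fh.write("\n")
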
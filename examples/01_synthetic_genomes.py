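"""Generate a small synthetic Bacteroidales-like genome collection.

Builds four annotated draft genomes — one per condition (GA1, GA2, GA3,
and no T6SS locus) — writes FASTA + GFF3 + a ground-truth JSON, and prints
what was implanted where. The truth record is what the evaluation stage
scores detection against.
"""
from pathlib import Path

from t6mine.synthetic import (SynthConfig, generate_family_consensus,
                              generate_genome_set, write_genome_set)

outdir = Path("scratch/example_genomes")
registry = generate_family_consensus(seed=1)
config = SynthConfig(
    n_genomes=4,
    architecture_mix={"GA1": 1, "GA2": 1, "GA3": 1, "none": 1},
    mutation_rate=0.05,       # per-residue divergence from family consensus
    contig_split_prob=0.0,
    seed=1,
)
genomes, truths = generate_genome_set(config, registry)
write_genome_set(genomes, truths, outdir)

print(f"wrote {len(genomes)} genomes to {outdir}/")
for genome, truth in zip(genomes, truths):
    n_genes = sum(len(c.genes) for c in genome.contigs)
    print(f"\n{genome.genome_id}: {len(genome.contigs)} contigs, "
          f"{n_genes} genes, {len(truth.decoy_gene_ids)} decoy genes")
    for locus in truth.loci:
        print(f"  implanted {locus.architecture} locus: "
              f"{len(locus.gene_ids)} genes on {locus.contig_ids}, "
              f"{len(locus.tra_gene_ids)} flanking tra genes"
              + (" (ICE)" if locus.ice_span else ""))
# Each implanted locus follows its architecture's canonical gene order;
# GA1/GA2 loci carry the conjugative-transfer (tra) flank that marks an
# integrative conjugative element, GA3 loci do not.
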
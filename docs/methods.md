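# Methods

`t6mine` mines annotated bacterial genomes for type VI secretion system
(T6SS) loci of the kind found in human gut Bacteroidales, classifies each
locus into one of three genetic architectures (GA1/GA2/GA3), and asks
whether the locus rides on an integrative conjugative element (ICE) — the
mobile elements that spread these antagonism systems between co-resident
gut species. Because the real 205-genome corpus and the TIGRFAM/Pfam/CDD
profile databases are external resources, the package ships a seeded
synthetic-genome generator that emulates the statistical structure the
analysis depends on, with exact ground truth for scoring.

## Locus discovery

**Pass 1 — sentinel co-localization.** Every proteome is scanned with two
sentinel profiles, VgrG (the spike protein, TssI) and ClpV (the sheath
ATPase, TssH), the two components reliably detectable by profile search
across phyla. A candidate is called when both hit on the same contig with
at most 15 intervening genes (gene distance is measured in ordinals — the
per-contig gene rank — not base pairs). Sentinel hits require an empirical
E-value ≤ `sentinel_evalue_max` (default 1e-3). The region between the
outermost sentinels plus 25 genes of flank on each side is retrieved,
truncating at contig ends.

**Clustering and annotation.** All window proteins are clustered greedily
at ≥ 30% identity over ≥ 70% of *both* lengths (free-end-gap global
alignment, BLOSUM62, affine gaps 11/1; identity = identical columns /
aligned columns with terminal gaps excluded and internal gap columns
counted as mismatches). Proteins are sorted longest-first (ties by id);
each unassigned protein seeds a cluster and recruits everything matching
the seed. A pseudo-random but seeded representative of each cluster is
scored against the curated family profiles; the best profile with E ≤ 1e-3
(and, for self-thresholded profiles, score ≥ threshold) labels the whole
cluster. An optional shared-4-mer prescreen (the same word-hit idea BLAST
and blastclust use) skips hopeless alignments; it is off by default in the
library function and enabled in the pipeline, where the ±25-gene flanks
contribute ~1.5k mutually unrelated proteins.

**Trimming and orientation.** A locus is trimmed to the contiguous block
of family-labelled genes (Tss*, Tag*, TetR, Hcp, VgrG, ClpV, PAAR, Rhs,
effector, immunity), chaining labelled genes across at most
`trim_max_gap` (default 5) interior unlabelled genes and anchoring on the
block that carries both sentinel kinds. The gap cap keeps standalone
decoy genes (lone clpV/hcp/tetR copies out in the flanks, which real
genomes are full of) outside the locus while still absorbing unlabelled
interior genes and nearby effector/immunity genes. Each locus is oriented
so vgrG reads left to right, anchored on the highest-scoring VgrG gene;
orientation is a display flag and is idempotent.

**Pass 2 — self-trained rescan.** For every labelled cluster (Tss/Tag/
TetR/Hcp/VgrG/ClpV/PAAR/Rhs families) the members are made non-redundant
at 100%/100%, star-aligned to the longest member, and turned into a new
profile (≥50%-occupancy columns, +0.1 Laplace pseudo-counts, log2 odds
against a uniform background) with a self-scan inclusion threshold. All
genomes are rescanned; a new locus is called where a 30-gene window holds
threshold-passing hits of ≥ 4 distinct core families (Tss*, Hcp, VgrG,
ClpV) outside any pass-1 locus, and a called group must itself satisfy
that trigger so stray decoys that merely share a window with a real locus
are not promoted. This pass is what recovers loci whose vgrG and clpV fell
on different contigs of a draft assembly; remaining hits are reported as
orphans. Pass-2 loci then receive the same curated-profile annotation as
pass-1 loci.

Profiles are rebuilt per *cluster*, labelled by family, rather than per
merged family: the synthetic Hcp subfamilies are unrelated by construction
(< 25% identity), so one merged Hcp alignment would be meaningless. This
matches the Hcp-clusters-1..11 style of accounting for real data, where a
family's clusters are the operational unit.

### Threshold rule

The inclusion threshold of a rebuilt profile is derived from its training
set. The naive rule — minimum training-member score — looks safe but is
biased: a profile's emission frequencies contain each member's own private
substitutions, so training members outscore equally diverged unseen
members by a wide margin (~3.4 bits per private substitution here), and a
min-of-training threshold rejects most fresh family members. When the
training MSA is available the threshold is therefore the minimum
*leave-one-out* path score: each member scored along its own alignment row
against column frequencies recomputed without it. This is the score an
unseen member actually faces; it is never above the direct minimum, so
training-set recall remains 100% by construction.

### E-values

E-values are empirical: each profile is scored against `n_shuffles`
(default 200) random proteins of profile length drawn from the null
distribution, and E(s) = db_size × survival(s) with a +1 pseudo-count.
Above the largest null score the tail is extrapolated exponentially with a
rate fitted by maximum likelihood on top-decile exceedances; without the
extrapolation the E-value would saturate at db_size/(n+1) and could never
certify strong matches at db_size 1e4. E(s) is monotone non-increasing by
construction.

## Architecture classification

A decision list over marker families, applied to the annotated, oriented
locus:

1. TagB and TagC together → `other` (contradictory exclusive markers).
2. TagC present → GA3 (TagC is exclusive to GA3).
3. TagB present → GA1 (TagB is exclusive to GA1; TagA co-occurs).
4. TagA without TagB, plus an evolved Hcp or ≥ 4 distinct Hcp clusters →
   GA2.
5. Otherwise, each template is scored on family content, synteny (longest
   common subsequence of the family order against the template) and TetR
   presence; the best call needs a score ≥ 0.7, else `other`.

The rule order, the 0.7 floor, and the conserved-region parameters below
are design choices of this package — the source classification was done by
eye — and all are configurable. An "evolved" Hcp is a gene labelled Hcp
whose Hcp-profile hit lies in the N-terminal half while the protein
exceeds 1.5× the Hcp family's median length (Hcp domain up front, toxin
domain behind).

**Conserved vs variable regions.** Within an architecture, each
non-reference locus is aligned to a reference locus with the blastn-like
HSP search; reference positions covered by qualifying HSPs in ≥ 80% of the
other loci are conserved (gaps < 200 bp merged), and remaining gaps
≥ 500 bp are the numbered variable regions, left to right — these are
where effector/immunity cassettes live. `ga_identity_check` compares the
mean within-conserved-segment identity against the published floors
(GA1 > 95%, GA2 > 80%, GA3 > 95%).

## ICE association and DNA relatedness

tra genes (the conjugation machinery: TraD, TraG, TraI, TraJ, TraK, TraM,
TraN, TraO, TrbJ) are detected with their own profile set at E ≤ 1e-3. A
locus is ICE-associated when at least one tra gene lies within
`ice_window_bp` (50 kb) on the same contig; distances to tra genes on
other contigs are undefined in a draft assembly and never satisfy the
window. The detected roster is pattern-matched against the canonical GA1
(TraG-TraK-TraM-TraN-TraD, ≥ 4/5 present) and GA2 (nine families, ≥ 7/9)
arrangements as an order-preserving subsequence after orientation.

The HSP search is a seed-and-extend: exact 11-mers, ungapped X-drop
extension (match +1, mismatch −2, X-drop 40), per-diagonal merging, both
strands, HSPs < 1000 bp removed, sorted by query start. These are
megablast-like defaults; the source analysis delegates them to blastn
without stating parameters. `ice_extent` starts from locus ± 50 kb and
iteratively trims the query to the outermost HSP boundaries until stable
(monotone, ≤ 2 iterations typical). Pairwise ICE relatedness is the
length-weighted mean HSP identity; the transfer-evidence statistic for a
shared element is 100 × (length − mismatches)/length to three decimals
(109,805 bp with 3 mismatches → 99.997).

## The synthetic generator

`generate_family_consensus(seed)` draws an independent random consensus
(80–600 aa; Hcp subfamilies fixed at 160 aa so coverage thresholds behave
predictably) for every family — 11 core Tss, the sentinels, TagA/B/C, two
unrelated TetR variants (GA2's TetR has no similarity to the others), 8
Hcp subfamilies, PAAR/Rhs, 9 tra families, toxins of three classes plus an
Hcp-tail toxin, and matching immunity families — along with a curated
profile per family (log-odds of a 90% consensus / 10% background emission)
and a single reference CDS per family (seeded uniform synonymous codons).

Genome templates: GA1 carries two Hcp of one subfamily, TagA+TagB, and one
effector/immunity cassette; GA2 carries five Hcp of four subfamilies plus
an evolved Hcp, TagA only; GA3 carries TagC, five Hcp of four (different)
subfamilies and two cassettes. GA1/GA2 implants get their tra flank in the
canonical order; GA3 gets none. Cassette contents are drawn per locus —
that is what creates the variable regions.

Per implant, each protein is mutated i.i.d. per residue
(`mutation_rate`, default 0.05; a substitution draws uniformly from all
20 residues) and codons are inherited from the family reference CDS
wherever the residue is unchanged, so DNA divergence tracks amino-acid
divergence (~0.6× the residue rate). Intergenic spacers inside an implant
come from a per-architecture template mutated at that same DNA rate —
loci of one architecture share descent, which is precisely the
within-architecture DNA identity the conserved-region and ICE analyses
measure. Independent per-implant codon choice or per-genome random
spacers would erase that structure. Background genes are random proteins
(100–400 aa) back-translated with random codons; spacers elsewhere are
random. With probability `contig_split_prob` the implant is cut between
clpV and vgrG onto two contigs (the draft-assembly failure mode pass 2
exists for); with probability 0.5 the whole implant is reverse-
complemented in place. Decoy standalone ClpV/Hcp/TetR/Rhs genes replace
background genes at `decoy_rate`; no decoy is a VgrG, so decoys can never
complete a sentinel pair by themselves.

What the generator does **not** emulate: phylogenetic structure between
genomes, indels, codon bias or GC content, gene gain/loss inside loci,
promoters, or assembly gaps (N runs are handled by the I/O layer —
codons containing N translate to X and X scores zero everywhere — but the
generator does not produce them). Passing tests therefore demonstrate the
pipeline's logic and calibration on cleanly structured data, not
performance on real draft assemblies, where annotation errors and
fragmented loci beyond the single split mode would add failure modes.

## Evaluation and problem sizes

A predicted locus matches a truth locus when their gene-set Jaccard index
is ≥ 0.5; recall and precision are computed over those matches, the
architecture confusion matrix and ICE-verdict accuracy over matched pairs,
and family-assignment accuracy over truth genes inside matched loci. A
split implant is recovered as its clpV-side fragment (the vgrG-side
fragment carries fewer than four core families and is deliberately not
promoted to a locus); its Jaccard against truth is ~0.76–0.87.

The default validation collection is 30 genomes (10 GA1, 5 GA2, 10 GA3,
5 without a locus), ~55 background genes per genome in three contigs —
small enough that the full pipeline, both passes included, runs in a few
minutes on one core, while every stage (detection, clustering, profile
rebuild, rescan, classification, ICE analysis) operates at a non-trivial
scale. E-value calibration uses 200 shuffles per profile in the pipeline
and 1000 where a test pins the decoy pass rate.

## Numerical and degenerate-input notes

- Alignment scores are in bits; gap costs 11 (open, first gapped position)
  + 1 per additional position, applied uniformly in the profile scorer and
  the Biopython pairwise aligner.
- Local profile alignment restarts only in the match state, so scores are
  ≥ 0; an all-X protein scores exactly 0 with an empty span.
- Ties in family assignment break by higher score, then lexicographic
  profile name; cluster seeds by longer length, then id; representative
  choice is uniform under a per-cluster seeded stream.
- `trim_region` on a window with no labelled gene is an error (nothing to
  trim); `orient_region` requires a VgrG gene; loci without one (possible
  for split fragments) simply stay unoriented.
- Reports are byte-deterministic for identical inputs: stable sort orders,
  fixed float formats, sorted JSON keys.
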
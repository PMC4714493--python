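"""Greedy percent-identity/coverage protein clustering (the blastclust stage).

Proteins are sorted longest-first (ties broken by id), each unassigned
protein seeds a cluster and recruits every remaining unassigned protein
matching the seed at >= 30% identity over >= 70% of BOTH lengths. The
optional k-mer prescreen mirrors blastclust's BLAST word-hit stage and only
skips alignments; it is off by default so the exact contract holds.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .profiles import GAP_EXT, GAP_OPEN

__all__ = ["ProteinCluster", "pairwise_identity", "greedy_cluster",
           "pick_representative"]


@dataclass
class ProteinCluster:
    cluster_id: int
    member_ids: list[str]
    representative_id: str | None = None


_ALIGNER = None


def _aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -GAP_OPEN
        a.extend_gap_score = -GAP_EXT
        a.end_gap_score = 0.0
        _ALIGNER = a
    return _ALIGNER


def pairwise_identity(a: str, b: str) -> tuple[float, float, float]:
    """Identity and mutual coverage under a free-end-gap global alignment.

    identity = identical columns / aligned columns, where aligned columns
    run from the first to the last residue-residue pair (terminal gaps
    excluded, internal gap columns counted as mismatches); coverage_x =
    aligned span on x / len(x).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if a == b:
        return 1.0, 1.0, 1.0
    aln = next(iter(_aligner().align(a, b)))
    t_blocks, q_blocks = (np.asarray(x) for x in aln.aligned)
    if t_blocks.size == 0:
        return 0.0, 0.0, 0.0
    ident = 0
    columns = 0
    t_prev = q_prev = None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if t_prev is not None:
            columns += (ts - t_prev) + (qs - q_prev)
        for k in range(te - ts):
            columns += 1
            if a[ts + k] == b[qs + k]:
                ident += 1
        t_prev, q_prev = te, qe
    a0, a1 = int(t_blocks[0][0]), int(t_blocks[-1][1])
    b0, b1 = int(q_blocks[0][0]), int(q_blocks[-1][1])
    return ident / columns, (a1 - a0) / len(a), (b1 - b0) / len(b)


def _kmer_set(seq: str, k: int) -> frozenset:
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


def greedy_cluster(proteins: dict[str, str], config,
                   prescreen_kmer: int | None = None,
                   prescreen_min_shared: int = 3) -> list[ProteinCluster]:
    """Deterministic greedy seed-recruitment clustering.

    proteins: gene_id -> sequence. Order of the input mapping is
    irrelevant; the internal (length desc, id asc) sort canonicalizes it.
    """
    id_min = config.cluster_identity_min
    cov_min = config.cluster_coverage_min
    order = sorted(proteins, key=lambda g: (-len(proteins[g]), g))
    kmers = None
    if prescreen_kmer:
        kmers = {g: _kmer_set(proteins[g], prescreen_kmer) for g in order}
    assigned: set[str] = set()
    clusters: list[ProteinCluster] = []
    for i, seed in enumerate(order):
        if seed in assigned:
            continue
        members = [seed]
        assigned.add(seed)
        for cand in order[i + 1:]:
            if cand in assigned:
                continue
            # identical sequences always co-cluster; cheap fast path
            if proteins[cand] == proteins[seed]:
                members.append(cand)
                assigned.add(cand)
                continue
            if kmers is not None and len(kmers[seed] & kmers[cand]) < prescreen_min_shared:
                continue
            ident, cov_a, cov_b = pairwise_identity(proteins[seed], proteins[cand])
            if ident >= id_min and cov_a >= cov_min and cov_b >= cov_min:
                members.append(cand)
                assigned.add(cand)
        clusters.append(ProteinCluster(len(clusters), members))
    return clusters


def pick_representative(cluster: ProteinCluster, rng_seed: int) -> str:
    """Pseudo-random but reproducible member choice (uniform)."""
    if not cluster.member_ids:
        raise ValueError("empty cluster")
    rng = np.random.default_rng([int(rng_seed) & 0x7FFFFFFF, cluster.cluster_id])
    rep = cluster.member_ids[int(rng.integers(len(cluster.member_ids)))]
    cluster.representative_id = rep
    return rep
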
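"""ICE association of T6SS loci and DNA relatedness between ICEs.

tra genes are detected with the nine-family conjugative-transfer profile
set; a locus is ICE-associated when at least one tra gene lies within the
50-kb window, and the detected tra roster is pattern-matched (order after
orientation, missing members tolerated) against the canonical GA1/GA2
arrangements. DNA relatedness between ICE spans is measured with a
blastn-like exact-word seed-and-extend (word 11, +1/-2, ungapped X-drop),
HSPs under 1000 bp removed, identity length-weighted across HSPs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._aln import count_matches, encode_dna, xdrop_extend
from .profiles import MotifHit, scan_proteome
from .synthetic import TRA_ROSTERS

__all__ = [
    "HSP", "IceAssociation", "detect_tra_genes", "tra_proximity",
    "find_hsps", "ice_extent", "percent_identity_from_mismatches",
    "pairwise_ice_identity",
]


@dataclass(frozen=True)
class HSP:
    query_start: int
    query_end: int  # exclusive, bp on the query
    subject_start: int
    subject_end: int
    strand: str  # subject strand
    identity: float
    score: float

    @property
    def length(self) -> int:
        return self.query_end - self.query_start


@dataclass
class IceAssociation:
    locus_id: str
    tra_hits: list[tuple[str, str, int]]  # (gene_id, tra family, distance bp)
    within_window: bool
    pattern: str  # GA1-pattern | GA2-pattern | inconsistent | none
    verdict: str  # ICE-associated | not-associated


def detect_tra_genes(genome, tra_profiles, config) -> list[MotifHit]:
    """Qualifying tra hits (E <= sentinel_evalue_max) across the genome."""
    return scan_proteome(tra_profiles, genome, config.sentinel_evalue_max)


def _is_subsequence(sub: list[str], full: list[str]) -> bool:
    it = iter(full)
    return all(x in it for x in sub)


def tra_proximity(locus, tra_hits: list[MotifHit], genome, config) -> IceAssociation:
    """Distance of each tra gene from the locus boundary (same contig only;
    cross-contig distances are undefined in a draft assembly and never
    satisfy the window), plus roster/order pattern matching."""
    spans = locus.spans
    genes = {g.gene_id: g for g in genome.iter_genes()}
    entries = []  # (distance, gene, family)
    for hit in tra_hits:
        gene = genes[hit.gene_id]
        if gene.contig_id not in spans:
            continue
        lo, hi = spans[gene.contig_id]
        if gene.end <= lo:
            dist = lo - gene.end
        elif gene.start >= hi:
            dist = gene.start - hi
        else:
            dist = 0
        entries.append((dist, gene, hit.profile_name))
    entries.sort(key=lambda t: (t[1].contig_id, t[1].start))
    near = [(g, fam) for d, g, fam in entries if d <= config.ice_window_bp]
    within = bool(near)
    # pattern: family order along the contig, mirrored if the locus is flipped
    ordered = [fam for _g, fam in near]
    if locus.flipped:
        ordered = list(reversed(ordered))
    pattern = "none"
    if ordered:
        pattern = "inconsistent"
        best_name, best_n = None, 0
        for name, roster in TRA_ROSTERS.items():
            need = 4 if name == "GA1" else 7
            distinct = len(set(ordered) & set(roster))
            consistent = _is_subsequence(ordered, roster)
            if distinct >= need and consistent and distinct > best_n:
                best_name, best_n = name, distinct
        if best_name:
            pattern = f"{best_name}-pattern"
    verdict = "ICE-associated" if within else "not-associated"
    return IceAssociation(locus.locus_id,
                          [(g.gene_id, fam, d) for d, g, fam in entries],
                          within, pattern, verdict)


# ---------------------------------------------------------------------------
# blastn-like HSP search

def _seed_index(s: np.ndarray, word: int) -> dict[int, list[int]]:
    index: dict[int, list[int]] = {}
    if s.size < word:
        return index
    code = 0
    valid = 0  # length of the current run without ambiguous bases
    for i in range(s.size):
        b = int(s[i])
        if b > 3:
            valid = 0
            code = 0
            continue
        code = ((code << 2) | b) & ((1 << (2 * word)) - 1)
        valid += 1
        if valid >= word:
            index.setdefault(code, []).append(i - word + 1)
    return index


def _scan_strand(q: np.ndarray, s: np.ndarray, config) -> list[tuple[int, int, int, int]]:
    """Seed-and-extend on one subject strand.

    Returns (q_start, q_end, diag, n_matches) segments, merged per diagonal.
    """
    word = config.hsp_word
    index = _seed_index(s, word)
    if not index or q.size < word:
        return []
    # collect seeds per diagonal
    per_diag: dict[int, list[int]] = {}
    code = 0
    valid = 0
    mask = (1 << (2 * word)) - 1
    for i in range(q.size):
        b = int(q[i])
        if b > 3:
            valid = 0
            code = 0
            continue
        code = ((code << 2) | b) & mask
        valid += 1
        if valid >= word:
            qpos = i - word + 1
            for spos in index.get(code, ()):
                per_diag.setdefault(qpos - spos, []).append(qpos)
    segments = []
    for diag, qposs in per_diag.items():
        qposs.sort()
        done_until = -1
        raw = []
        for qpos in qposs:
            if qpos + word <= done_until:
                continue
            spos = qpos - diag
            qs, qe, nm = xdrop_extend(q, s, qpos, spos, word,
                                      config.hsp_match, config.hsp_mismatch,
                                      config.hsp_xdrop)
            raw.append((qs, qe))
            done_until = qe
        # merge overlapping extensions on the same diagonal
        raw.sort()
        merged = []
        for qs, qe in raw:
            if merged and qs <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], qe))
            else:
                merged.append((qs, qe))
        for qs, qe in merged:
            nm = int(count_matches(q, s, qs, qe, -diag))
            segments.append((qs, qe, diag, nm))
    return segments


def find_hsps(query: str, subject: str, config) -> list[HSP]:
    """Both-strand seed-and-extend; HSPs shorter than hsp_min_len are
    removed and the survivors are sorted by query start."""
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    q = encode_dna(query)
    s_fwd = encode_dna(subject)
    hsps = []
    for strand, s in (("+", s_fwd), ("-", s_fwd[::-1] ^ np.int8(3))):
        # reverse complement of the encoding: A<->T (0<->3), C<->G (1<->2);
        # ambiguous 4 maps to 7 which never matches
        for qs, qe, diag, nm in _scan_strand(q, s, config):
            length = qe - qs
            if length < config.hsp_min_len:
                continue
            ss, se = qs - diag, qe - diag
            if strand == "-":
                ss, se = len(subject) - se, len(subject) - ss
            score = nm * config.hsp_match + (length - nm) * config.hsp_mismatch
            hsps.append(HSP(qs, qe, ss, se, strand, nm / length, score))
    hsps.sort(key=lambda h: (h.query_start, h.subject_start, h.strand))
    return hsps


@dataclass
class IceExtent:
    span: tuple[int, int]  # on the anchor contig
    hsps: list[HSP]
    found: bool
    iterations: int = 0


def ice_extent(anchor_locus, anchor_genome, other_genome, config,
               window_bp: int | None = None, max_iter: int = 5) -> IceExtent:
    """Iteratively refine the homologous span around a locus.

    The query starts as locus +- window_bp on the anchor contig; after each
    HSP round the query is trimmed to the outermost HSP boundaries, until
    the boundaries are stable. Monotone: the span never grows after the
    first trim. Returns the locus span flagged not-found when no HSP
    survives the length filter.
    """
    window_bp = config.ice_window_bp if window_bp is None else window_bp
    (contig_id, (lo, hi)), *rest = anchor_locus.spans.items()
    for cid, (s, e) in anchor_locus.spans.items():
        if e - s > hi - lo:
            contig_id, lo, hi = cid, s, e
    contig = anchor_genome.contig(contig_id)
    start = max(0, lo - window_bp)
    end = min(len(contig.sequence), hi + window_bp)
    it = 0
    final_hsps: list[HSP] = []
    while it < max_iter:
        it += 1
        query = contig.sequence[start:end]
        best: list[HSP] = []
        for other_contig in other_genome.contigs:
            hsps = find_hsps(query, other_contig.sequence, config)
            if sum(h.length for h in hsps) > sum(h.length for h in best):
                best = hsps
        if not best:
            return IceExtent((lo, hi), [], False, it)
        new_start = start + min(h.query_start for h in best)
        new_end = start + max(h.query_end for h in best)
        final_hsps = best
        if (new_start, new_end) == (start, end):
            break
        start, end = new_start, new_end
    return IceExtent((start, end), final_hsps, True, it)


def percent_identity_from_mismatches(length_bp: int, mismatches: int) -> float:
    """Percent identity of an alignment block, to 3 decimal places."""
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    if not (0 <= mismatches <= length_bp):
        raise ValueError("mismatches out of range")
    return round(100.0 * (length_bp - mismatches) / length_bp, 3)


def pairwise_ice_identity(spans: dict[str, str], config) -> dict[str, dict[str, float | None]]:
    """Length-weighted HSP identity for every ordered strain pair.

    spans: strain -> ICE nucleotide sequence. Pairs with no qualifying HSP
    are reported as None (missing); the diagonal is 1.0.
    """
    strains = sorted(spans)
    matrix: dict[str, dict[str, float | None]] = {a: {} for a in strains}
    for a in strains:
        for b in strains:
            if a == b:
                matrix[a][b] = 1.0
                continue
            hsps = find_hsps(spans[a], spans[b], config)
            total = sum(h.length for h in hsps)
            if total == 0:
                matrix[a][b] = None
            else:
                matrix[a][b] = sum(h.length * h.identity for h in hsps) / total
    return matrix
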
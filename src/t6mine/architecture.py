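"""GA1/GA2/GA3 locus classification and conserved/variable region analysis.

Classification is a decision list over marker families: TagC is exclusive
to GA3, TagB to GA1, and TagA-without-TagB together with an evolved Hcp or
>= 4 distinct Hcp clusters marks GA2. Loci matching no rule are scored
against the architecture templates on feature content and synteny and
called only above a score floor, otherwise "other". Conserved vs variable
regions within an architecture come from HSP coverage of a reference locus
across its peers.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ice import find_hsps
from .synthetic import GA_TEMPLATES, family_label

__all__ = ["ArchitectureCall", "RegionComparison", "signature_match",
           "conserved_regions", "ga_identity_check", "GA_IDENTITY_FLOORS"]

GA_IDENTITY_FLOORS = {"GA1": 0.95, "GA2": 0.80, "GA3": 0.95}


@dataclass
class ArchitectureCall:
    locus_id: str
    call: str  # GA1 | GA2 | GA3 | other
    matched: list[str]
    missing: list[str]
    score: float


def _hcp_cluster_count(locus) -> int:
    clusters = {a.cluster_id for a in locus.annotations.values()
                if a.family == "Hcp" and a.cluster_id is not None}
    return len(clusters)


def _template_families(name: str) -> list[str]:
    return [family_label(s) if s not in ("TOX", "IMM")
            else ("effector" if s == "TOX" else "immunity")
            for s in GA_TEMPLATES[name].gene_order]


def _lcs_len(a: list[str], b: list[str]) -> int:
    dp = np.zeros((len(a) + 1, len(b) + 1), dtype=np.int64)
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                dp[i, j] = dp[i - 1, j - 1] + 1
            else:
                dp[i, j] = max(dp[i - 1, j], dp[i, j - 1])
    return int(dp[len(a), len(b)])


def signature_match(locus, config) -> ArchitectureCall:
    """Classify one annotated, oriented locus."""
    if not locus.annotations:
        raise ValueError(f"{locus.locus_id}: locus is not annotated")
    fams = set(locus.families())
    has = lambda f: f in fams
    evolved = any(a.evolved_hcp for a in locus.annotations.values())
    n_hcp_clusters = _hcp_cluster_count(locus)

    if has("TagB") and has("TagC"):
        return ArchitectureCall(locus.locus_id, "other",
                                ["TagB", "TagC"], [],
                                score=0.0)  # contradictory exclusive markers
    if has("TagC"):
        return ArchitectureCall(locus.locus_id, "GA3", ["TagC"], [], 1.0)
    if has("TagB"):
        matched = ["TagB"] + (["TagA"] if has("TagA") else [])
        return ArchitectureCall(locus.locus_id, "GA1", matched, [], 1.0)
    if has("TagA") and (evolved or n_hcp_clusters >= 4):
        matched = ["TagA"] + (["evolved-Hcp"] if evolved else []) + (
            [f"{n_hcp_clusters} Hcp clusters"] if n_hcp_clusters >= 4 else [])
        return ArchitectureCall(locus.locus_id, "GA2", matched, [], 1.0)

    # fallback: feature scoring against each template
    order = [locus.annotations[g.gene_id].family
             for g, _s in locus.oriented_genes()
             if g.gene_id in locus.annotations]
    best = ArchitectureCall(locus.locus_id, "other", [], [], 0.0)
    for name in ("GA1", "GA2", "GA3"):
        tmpl = _template_families(name)
        feats = {
            "core-content": len(set(order) & set(tmpl)) / len(set(tmpl)),
            "synteny": _lcs_len(order, tmpl) / len(tmpl),
            "tetr": 1.0 if "TetR" in fams else 0.0,
        }
        score = sum(feats.values()) / len(feats)
        if score > best.score:
            matched = [k for k, v in feats.items() if v >= 0.5]
            missing = [k for k, v in feats.items() if v < 0.5]
            best = ArchitectureCall(locus.locus_id, name, matched, missing, score)
    if best.score < config.architecture_score_min:
        return ArchitectureCall(locus.locus_id, "other", best.matched,
                                best.missing, best.score)
    return best


@dataclass
class RegionComparison:
    architecture: str
    reference_locus_id: str
    conserved_segments: list[tuple[int, int]]  # on the reference, bp
    variable_regions: list[tuple[int, int, int]]  # (number, start, end)
    pair_identity: dict[str, float] = field(default_factory=dict)


def _locus_sequence(locus, genome) -> str:
    parts = []
    for cid, (lo, hi) in sorted(locus.spans.items()):
        parts.append(genome.contig(cid).sequence[lo:hi])
    return "".join(parts)


def conserved_regions(loci, genomes: dict, config,
                      reference=None) -> RegionComparison:
    """Delineate conserved vs variable DNA across loci of one architecture.

    Reference positions covered by qualifying HSPs in >= 80% of the other
    loci form conserved segments (gaps < 200 bp merged); remaining gaps of
    >= 500 bp are the numbered variable regions, left to right.
    """
    if len(loci) < 2:
        raise ValueError("need at least two loci")
    reference = reference or loci[0]
    others = [l for l in loci if l is not reference]
    ref_seq = _locus_sequence(reference, genomes[reference.genome_id])
    cover = np.zeros(len(ref_seq), dtype=np.int64)
    per_other_hsps = {}
    for other in others:
        seq = _locus_sequence(other, genomes[other.genome_id])
        hsps = find_hsps(ref_seq, seq, config)
        per_other_hsps[other.locus_id] = hsps
        mask = np.zeros(len(ref_seq), dtype=bool)
        for h in hsps:
            mask[h.query_start:h.query_end] = True
        cover += mask
    conserved = cover >= config.conserved_coverage_min * len(others)
    # per-pair identity restricted to the conserved portion of each HSP
    pair_identity = {}
    for lid, hsps in per_other_hsps.items():
        wsum = isum = 0.0
        for h in hsps:
            w = int(conserved[h.query_start:h.query_end].sum())
            wsum += w
            isum += w * h.identity
        pair_identity[lid] = isum / wsum if wsum else 0.0
    # merge short gaps
    gap_start = None
    for i in range(len(conserved) + 1):
        inside = i < len(conserved) and not conserved[i]
        if inside and gap_start is None:
            gap_start = i
        elif not inside and gap_start is not None:
            if (i - gap_start < config.conserved_merge_gap_bp
                    and gap_start > 0 and i < len(conserved)):
                conserved[gap_start:i] = True
            gap_start = None
    segments = []
    run = None
    for i in range(len(conserved) + 1):
        inside = i < len(conserved) and conserved[i]
        if inside and run is None:
            run = i
        elif not inside and run is not None:
            segments.append((run, i))
            run = None
    variable = []
    bounds = [0] + [x for s in segments for x in s] + [len(ref_seq)]
    n = 0
    for lo, hi in zip(bounds[::2], bounds[1::2]):
        if hi - lo >= config.variable_min_len_bp:
            n += 1
            variable.append((n, lo, hi))
    arch = reference.architecture or "?"
    return RegionComparison(arch, reference.locus_id, segments, variable,
                            pair_identity)


def ga_identity_check(comparison: RegionComparison, architecture: str,
                      ) -> tuple[bool, dict[str, float]]:
    """Compare the mean within-conserved-segment identity against the
    architecture's published floor (GA1 0.95, GA2 0.80, GA3 0.95)."""
    floor = GA_IDENTITY_FLOORS[architecture]
    values = comparison.pair_identity
    if not values:
        return False, {}
    mean = sum(values.values()) / len(values)
    return mean >= floor, dict(values)
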
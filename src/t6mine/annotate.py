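"""Family labels for protein clusters and effector/immunity scanning.

Cluster representatives are scored against the curated family profiles
(the profile-vs-representative stand-in for the profile-profile search
stage); the winning label propagates to every cluster member. Locus
proteins are additionally scanned against the toxin/immunity profile set,
and oversized Hcp proteins whose Hcp hit sits in the N-terminal half are
flagged as "evolved" Hcps (Hcp domain + C-terminal toxin).
"""
from __future__ import annotations

import statistics
from dataclasses import dataclass

from .detection import FamilyAnnotation
from .profiles import score_protein
from .synthetic import family_label

__all__ = ["FamilyCall", "EffectorHit", "assign_families", "scan_effectors",
           "flag_evolved_hcp"]


@dataclass
class FamilyCall:
    family: str  # 'unknown' if nothing qualifies
    profile_name: str | None
    score: float
    evalue: float | None


@dataclass(frozen=True)
class EffectorHit:
    gene_id: str
    profile_name: str
    evalue: float
    score: float
    class_tag: str  # nuclease / deaminase / pore / immunity family


def assign_families(clusters, representatives: dict[int, str], profiles,
                    config) -> dict[int, FamilyCall]:
    """Score every cluster representative against every family profile.

    The best profile with E <= sentinel_evalue_max (and score >= the
    profile's threshold when one is set) wins; ties break by higher score,
    then lexicographic profile name. Unassigned clusters are 'unknown'.
    """
    calls: dict[int, FamilyCall] = {}
    for cluster in clusters:
        rep = representatives[cluster.cluster_id]
        best: tuple[float, str, float] | None = None  # (score, name, evalue)
        for prof in profiles:
            if prof.calibration is None:
                raise ValueError(f"profile {prof.name} is not calibrated")
            if not prof.shares_words(rep):
                continue
            score, _span = score_protein(prof, rep)
            if score <= 0.0:
                continue
            ev = prof.calibration.evalue(score)
            if ev > config.sentinel_evalue_max:
                continue
            if prof.threshold_score is not None and score < prof.threshold_score:
                continue
            if best is None or score > best[0] or (
                    score == best[0] and prof.name < best[1]):
                best = (score, prof.name, ev)
        if best is None:
            calls[cluster.cluster_id] = FamilyCall("unknown", None, 0.0, None)
        else:
            score, name, ev = best
            calls[cluster.cluster_id] = FamilyCall(family_label(name), name,
                                                   score, ev)
    return calls


def annotations_from_calls(clusters, calls, gene_to_cluster=None,
                           ) -> dict[str, FamilyAnnotation]:
    """Propagate each cluster's call to all members (gene-level table)."""
    out: dict[str, FamilyAnnotation] = {}
    for cluster in clusters:
        call = calls[cluster.cluster_id]
        if call.family == "unknown":
            continue
        for gid in cluster.member_ids:
            out[gid] = FamilyAnnotation(call.family, cluster.cluster_id,
                                        call.profile_name, call.score,
                                        call.evalue)
    return out


def scan_effectors(locus_proteins: dict[str, str], toxin_profiles, config,
                   ) -> list[EffectorHit]:
    """All toxin/immunity hits with E <= toxin_evalue_max (inclusive); a
    protein may legitimately hit both a toxin and an immunity profile and
    every qualifying hit is reported."""
    hits = []
    for gid in sorted(locus_proteins):
        prot = locus_proteins[gid]
        for prof in toxin_profiles:
            if prof.calibration is None:
                raise ValueError(f"profile {prof.name} is not calibrated")
            score, _span = score_protein(prof, prot)
            if score <= 0.0:
                continue
            ev = prof.calibration.evalue(score)
            if ev <= config.toxin_evalue_max:
                tag = prof.name.split(".", 1)[1] if "." in prof.name else prof.name
                if prof.name.startswith("Imm."):
                    tag = f"immunity-{tag}"
                hits.append(EffectorHit(gid, prof.name, ev, score, tag))
    return hits


def flag_evolved_hcp(protein: str, hcp_hit_span: tuple[int, int],
                     hcp_median_length: float) -> bool:
    """Evolved Hcp: the Hcp-profile hit lies in the N-terminal half and the
    protein is over 1.5x the Hcp family's median length."""
    start, end = hcp_hit_span
    midpoint = (start + end) / 2
    return (midpoint <= len(protein) / 2
            and len(protein) > 1.5 * hcp_median_length)


def hcp_median_length(proteins: list[str]) -> float:
    if not proteins:
        raise ValueError("no Hcp proteins")
    return float(statistics.median(len(p) for p in proteins))
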
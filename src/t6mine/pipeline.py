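"""End-to-end orchestration: scan -> detect -> cluster -> annotate ->
rebuild profiles -> second pass -> classify -> ICE analysis, plus the
evaluation of a run against synthetic ground truth.

All randomness derives from PipelineConfig.rng_seed through named
substreams, so stage-order changes cannot silently shift random draws, and
two runs with the same config and inputs are byte-identical.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import annotate as ann_mod
from .architecture import ArchitectureCall, signature_match
from .cluster import greedy_cluster, pick_representative
from .detection import (FamilyAnnotation, LocusRegion, extract_region,
                        find_sentinel_pairs, orient_region, second_pass_scan,
                        trim_region)
from .genome_io import PipelineConfig, write_locus_report, write_orf_map
from .ice import IceAssociation, detect_tra_genes, tra_proximity
from .profiles import (build_msa, build_profile, calibrate_evalues,
                       calibrate_threshold, dedupe_members, scan_proteome)

logger = logging.getLogger(__name__)

__all__ = ["RunResult", "RunManifest", "EvaluationReport", "run_pipeline",
            "evaluate"]

_SUBSTREAM = {"calibration": 11, "representatives": 13, "rebuild": 17}


def _rng(config: PipelineConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(config.rng_seed) & 0x7FFFFFFF,
                                  _SUBSTREAM[stage]])


@dataclass
class RunManifest:
    seed: int
    config: dict
    input_checksums: dict[str, str]
    stage_counts: dict[str, int | dict]
    version: str = "0.1.0"


@dataclass
class RunResult:
    loci: list[LocusRegion]
    orphans: list
    clusters: list
    family_calls: dict
    architecture_calls: dict[str, ArchitectureCall]
    ice: dict[str, IceAssociation]
    effector_hits: list
    manifest: RunManifest
    genomes: dict = field(default_factory=dict)


def _ensure_calibrated(profiles, config: PipelineConfig, rng) -> None:
    for prof in profiles:
        if prof.calibration is None:
            calibrate_evalues(prof, config.decoy_db_size,
                              config.calibration_shuffles, rng)


def _genome_checksum(genome) -> str:
    h = hashlib.sha256()
    for contig in genome.contigs:
        h.update(contig.contig_id.encode())
        h.update(contig.sequence.encode())
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig, genomes, profile_sets,
                 outdir=None, enable_pass2: bool = True) -> RunResult:
    """Run the complete discovery/classification pipeline.

    profile_sets: dict with keys 'sentinel', 'family', 'tra', 'toxin'
    (lists of ProfileModel). Calibration is performed in place for any
    profile lacking it. Stage outputs are written under outdir when given.
    """
    genomes = list(genomes)
    cal_rng = _rng(config, "calibration")
    for key in ("sentinel", "family", "tra", "toxin"):
        _ensure_calibrated(profile_sets.get(key, []), config, cal_rng)

    counts: dict = {}
    genome_map = {g.genome_id: g for g in genomes}

    # ---- pass 1: sentinel co-localization -------------------------------
    windows = []
    n_hits = 0
    for genome in genomes:
        hits = scan_proteome(profile_sets["sentinel"], genome,
                             config.sentinel_evalue_max)
        n_hits += len(hits)
        for pair in find_sentinel_pairs(hits, genome, config):
            windows.append(extract_region(genome, pair, config))
    counts["sentinel_hits"] = n_hits
    counts["sentinel_windows"] = len(windows)
    logger.info("pass 1: %d sentinel hits, %d candidate windows",
                n_hits, len(windows))

    # ---- cluster all window proteins ------------------------------------
    window_proteins: dict[str, str] = {}
    for w in windows:
        for g in w.genes:
            window_proteins[g.gene_id] = g.protein
    clusters = greedy_cluster(window_proteins, config, prescreen_kmer=4)
    counts["clusters"] = len(clusters)

    rep_seed = int(_rng(config, "representatives").integers(2 ** 31 - 1))
    representatives = {
        c.cluster_id: window_proteins[pick_representative(c, rep_seed)]
        for c in clusters}

    # ---- annotate clusters via curated profiles --------------------------
    assign_profiles = (profile_sets["family"] + profile_sets["tra"]
                       + profile_sets["toxin"])
    family_calls = ann_mod.assign_families(clusters, representatives,
                                           assign_profiles, config)
    annotations = ann_mod.annotations_from_calls(clusters, family_calls)

    # ---- trim pass-1 windows into loci -----------------------------------
    loci: list[LocusRegion] = []
    for w in windows:
        locus = trim_region(w, annotations, f"L{len(loci) + 1:03d}",
                            discovery_pass=1,
                            max_interior_gap=config.trim_max_gap)
        orient_region(locus)
        loci.append(locus)
    counts["pass1_loci"] = len(loci)

    # ---- rebuild per-cluster profiles for the labelled families ----------
    pass2_loci: list[LocusRegion] = []
    orphans = []
    if enable_pass2:
        rebuild_rng = _rng(config, "rebuild")
        rebuilt = []
        for cluster in clusters:
            call = family_calls[cluster.cluster_id]
            if call.family in ("unknown", "Tra", "effector", "immunity"):
                continue
            members = dedupe_members(
                [window_proteins[g] for g in cluster.member_ids])
            msa = build_msa(members)
            prof = build_profile(msa, f"{call.family}|{cluster.cluster_id}")
            calibrate_threshold(prof, members, msa=msa)
            calibrate_evalues(prof, config.decoy_db_size,
                              config.calibration_shuffles, rebuild_rng)
            rebuilt.append(prof)
        counts["rebuilt_profiles"] = len(rebuilt)
        pass2_loci, orphans = second_pass_scan(rebuilt, genomes, config,
                                               pass1_loci=loci)
        # pass-2 loci get the same motif annotation as pass-1 loci: genes
        # the self-thresholded rescan left unlabelled are assigned from the
        # curated profiles by E-value
        from .profiles import score_protein as _score
        for locus in pass2_loci:
            for g in locus.genes:
                if g.gene_id in locus.annotations:
                    continue
                best = None
                for prof in assign_profiles:
                    if not prof.shares_words(g.protein):
                        continue
                    score, _span = _score(prof, g.protein)
                    if score <= 0.0:
                        continue
                    ev = prof.calibration.evalue(score)
                    if ev <= config.sentinel_evalue_max and (
                            best is None or score > best[1]):
                        best = (prof.name, score, ev)
                if best is not None:
                    from .synthetic import family_label
                    locus.annotations[g.gene_id] = FamilyAnnotation(
                        family_label(best[0]), None, best[0], best[1], best[2])
        counts["pass2_loci"] = len(pass2_loci)
        counts["orphan_hits"] = len(orphans)
        loci = loci + pass2_loci

    # ---- effector/immunity scan and evolved-Hcp flags ---------------------
    locus_proteins = {g.gene_id: g.protein for l in loci for g in l.genes}
    effector_hits = ann_mod.scan_effectors(locus_proteins,
                                           profile_sets["toxin"], config)
    counts["effector_hits"] = len(effector_hits)
    hcp_proteins = [g.protein for l in loci for g in l.genes
                    if g.gene_id in l.annotations
                    and l.annotations[g.gene_id].family == "Hcp"]
    if hcp_proteins:
        median = ann_mod.hcp_median_length(hcp_proteins)
        for l in loci:
            for g in l.genes:
                a = l.annotations.get(g.gene_id)
                if a and a.family == "Hcp":
                    # span of the winning Hcp profile hit on the protein
                    span = _hcp_hit_span(g.protein, a, profile_sets["family"])
                    a.evolved_hcp = ann_mod.flag_evolved_hcp(
                        g.protein, span, median)

    # ---- architecture classification -------------------------------------
    arch_calls = {l.locus_id: signature_match(l, config) for l in loci}
    for l in loci:
        l.architecture = arch_calls[l.locus_id].call
    counts["architecture"] = {
        name: sum(1 for c in arch_calls.values() if c.call == name)
        for name in ("GA1", "GA2", "GA3", "other")}

    # ---- ICE association ---------------------------------------------------
    ice_results: dict[str, IceAssociation] = {}
    tra_by_genome = {
        g.genome_id: detect_tra_genes(g, profile_sets["tra"], config)
        for g in genomes}
    for l in loci:
        ice_results[l.locus_id] = tra_proximity(
            l, tra_by_genome[l.genome_id], genome_map[l.genome_id], config)
    counts["ice_associated"] = sum(
        1 for a in ice_results.values() if a.verdict == "ICE-associated")

    manifest = RunManifest(
        seed=config.rng_seed, config=asdict(config),
        input_checksums={g.genome_id: _genome_checksum(g) for g in genomes},
        stage_counts=counts)
    result = RunResult(loci, orphans, clusters, family_calls, arch_calls,
                       ice_results, effector_hits, manifest,
                       genomes=genome_map)
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _hcp_hit_span(protein, annotation, family_profiles):
    from .profiles import score_protein
    prof = next((p for p in family_profiles
                 if p.name == annotation.profile_name), None)
    if prof is None:
        return (0, len(protein))
    _score, span = score_protein(prof, protein)
    return span


def _write_outputs(result: RunResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_locus_report(result.loci, outdir / "loci.tsv")
    with open(outdir / "clusters.tsv", "w") as fh:
        fh.write("cluster_id\trepresentative\tfamily\tmembers\n")
        for c in result.clusters:
            call = result.family_calls[c.cluster_id]
            fh.write(f"{c.cluster_id}\t{c.representative_id}\t{call.family}\t"
                     + ",".join(c.member_ids) + "\n")
    with open(outdir / "annotation.tsv", "w") as fh:
        fh.write("locus_id\tgene_id\tfamily\tcluster_id\tprofile\tscore\t"
                 "evolved_hcp\n")
        for l in result.loci:
            for g in l.genes:
                a = l.annotations.get(g.gene_id)
                if a is None:
                    fh.write(f"{l.locus_id}\t{g.gene_id}\tunknown\t\t\t\t\n")
                else:
                    fh.write(f"{l.locus_id}\t{g.gene_id}\t{a.family}\t"
                             f"{a.cluster_id}\t{a.profile_name}\t"
                             f"{a.score:.2f}\t{int(a.evolved_hcp)}\n")
    with open(outdir / "architecture.tsv", "w") as fh:
        fh.write("locus_id\tcall\tscore\tmatched\tmissing\n")
        for lid in sorted(result.architecture_calls):
            c = result.architecture_calls[lid]
            fh.write(f"{lid}\t{c.call}\t{c.score:.3f}\t"
                     + ";".join(c.matched) + "\t" + ";".join(c.missing) + "\n")
    with open(outdir / "ice.tsv", "w") as fh:
        fh.write("locus_id\tverdict\tpattern\twithin_window\tn_tra\n")
        for lid in sorted(result.ice):
            a = result.ice[lid]
            fh.write(f"{lid}\t{a.verdict}\t{a.pattern}\t"
                     f"{int(a.within_window)}\t{len(a.tra_hits)}\n")
    maps_dir = outdir / "orf_maps"
    maps_dir.mkdir(exist_ok=True)
    for l in result.loci:
        if l.oriented:
            write_orf_map(l, maps_dir / f"{l.locus_id}.json")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(asdict(result.manifest), fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Evaluation against synthetic truth

@dataclass
class EvaluationReport:
    locus_recall: float
    locus_precision: float
    architecture_accuracy: float
    architecture_confusion: dict[str, dict[str, int]]
    ice_verdict_accuracy: float
    family_assignment_accuracy: float
    n_truth_loci: int
    n_predicted_loci: int
    matches: list[tuple[str, str, float]] = field(default_factory=list)


def evaluate(result: RunResult, truths) -> EvaluationReport:
    """Score a run against ground truth.

    A predicted locus matches a truth locus when their gene-set Jaccard
    index is >= 0.5; precision/recall are computed on those matches, the
    confusion matrix over matched pairs. ICE verdict accuracy compares
    ICE-associated against the truth record's tra flank; family accuracy
    covers truth genes present in matched predicted loci.
    """
    truth_loci = [(t.genome_id, tl) for t in truths for tl in t.loci]
    pred = list(result.loci)
    matches = []  # (locus_id, truth idx, jaccard)
    used_truth: set[int] = set()
    for locus in pred:
        best_j, best_i = 0.0, None
        for i, (gid, tl) in enumerate(truth_loci):
            if i in used_truth or gid != locus.genome_id:
                continue
            a, b = locus.gene_ids, set(tl.gene_ids)
            j = len(a & b) / len(a | b)
            if j > best_j:
                best_j, best_i = j, i
        if best_i is not None and best_j >= 0.5:
            matches.append((locus.locus_id, best_i, best_j))
            used_truth.add(best_i)
    recall = len(matches) / len(truth_loci) if truth_loci else 1.0
    precision = len(matches) / len(pred) if pred else 1.0

    confusion: dict[str, dict[str, int]] = {}
    arch_correct = ice_correct = 0
    fam_total = fam_correct = 0
    for lid, ti, _j in matches:
        tl = truth_loci[ti][1]
        call = result.architecture_calls[lid].call
        confusion.setdefault(tl.architecture, {}).setdefault(call, 0)
        confusion[tl.architecture][call] += 1
        if call == tl.architecture:
            arch_correct += 1
        verdict = result.ice[lid].verdict
        expected = "ICE-associated" if tl.tra_gene_ids else "not-associated"
        if verdict == expected:
            ice_correct += 1
        locus = next(l for l in pred if l.locus_id == lid)
        for g in locus.genes:
            if g.gene_id in tl.families:
                fam_total += 1
                a = locus.annotations.get(g.gene_id)
                if a is not None and a.family == tl.families[g.gene_id]:
                    fam_correct += 1
    n = len(matches)
    return EvaluationReport(
        locus_recall=recall, locus_precision=precision,
        architecture_accuracy=arch_correct / n if n else 0.0,
        architecture_confusion=confusion,
        ice_verdict_accuracy=ice_correct / n if n else 0.0,
        family_assignment_accuracy=fam_correct / fam_total if fam_total else 0.0,
        n_truth_loci=len(truth_loci), n_predicted_loci=len(pred),
        matches=[(lid, truth_loci[ti][1].architecture, j)
                 for lid, ti, j in matches])
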
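"""Position-specific profile scoring, E-value calibration and profile building.

This is the package's substitute for the rpsblast / hmmbuild / hmmsearch
stages of a classical locus-mining workflow: a profile is a per-column
log-odds matrix (bits) over the 20 amino acids with a background (null)
distribution, an empirical E-value calibration and, for profiles built from
a training set, a self-scan inclusion threshold.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._aln import AA_ALPHABET, AA_INDEX, encode_protein, sw_profile

GAP_OPEN = 11.0
GAP_EXT = 1.0

__all__ = [
    "ProfileModel",
    "EvalueCalibration",
    "MotifHit",
    "score_protein",
    "calibrate_evalues",
    "scan_proteome",
    "dedupe_members",
    "build_msa",
    "build_profile",
    "calibrate_threshold",
    "consensus_of",
]


@dataclass
class EvalueCalibration:
    """Empirical null for one profile.

    E(s) = db_size * S(s) where S is the +1-pseudocount survival function of
    the shuffled-decoy score sample; above the largest null score the tail is
    extrapolated exponentially (rate fitted by MLE on top-decile exceedances)
    so that very strong scores get E-values far below the 1/(n+1) resolution
    of the sample. E is monotone non-increasing in s by construction.
    """

    db_size: float
    null_scores: np.ndarray  # sorted ascending
    tail_lambda: float

    def evalue(self, score: float) -> float:
        n = self.null_scores.size
        # number of null scores >= score
        c = n - int(np.searchsorted(self.null_scores, score, side="left"))
        if c > 0:
            return self.db_size * (c + 1) / (n + 1)
        smax = float(self.null_scores[-1])
        p = 1.0 / (n + 1) * math.exp(-self.tail_lambda * (score - smax))
        return self.db_size * p


@dataclass
class ProfileModel:
    name: str
    match_scores: np.ndarray  # (length, 20) log-odds in bits
    null_freqs: np.ndarray  # (20,) background frequencies, sums to 1
    threshold_score: float | None = None
    calibration: EvalueCalibration | None = None
    _padded: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.match_scores = np.asarray(self.match_scores, dtype=np.float64)
        self.null_freqs = np.asarray(self.null_freqs, dtype=np.float64)
        if self.match_scores.ndim != 2 or self.match_scores.shape[1] != 20:
            raise ValueError("match_scores must be (length, 20)")
        if self.match_scores.shape[0] < 1:
            raise ValueError("profile length must be >= 1")
        if abs(float(self.null_freqs.sum()) - 1.0) > 1e-9:
            raise ValueError("null_freqs must sum to 1")

    @property
    def length(self) -> int:
        return self.match_scores.shape[0]

    def padded_scores(self) -> np.ndarray:
        """Score matrix with an extra all-zero column for X residues."""
        if self._padded is None or self._padded.shape[0] != self.length:
            pad = np.zeros((self.length, 21))
            pad[:, :20] = self.match_scores
            self._padded = pad
        return self._padded

    @property
    def max_score(self) -> float:
        """Score of the consensus: per-column maxima, clipped at zero
        (columns whose best residue scores negative are skipped locally)."""
        return float(np.clip(self.match_scores.max(axis=1), 0.0, None).sum())

    def shares_words(self, protein: str, word: int = 4, min_shared: int = 2) -> bool:
        """BLAST-style word-hit prescreen: does the protein share at least
        min_shared exact words with the profile consensus? True family
        members share hundreds; unrelated proteins almost never reach 2."""
        key = (word,)
        cache = getattr(self, "_word_cache", None)
        if cache is None or cache[0] != key:
            cons = "".join(AA_ALPHABET[i] for i in self.match_scores.argmax(axis=1))
            words = frozenset(cons[i:i + word] for i in range(len(cons) - word + 1))
            cache = (key, words)
            self._word_cache = cache
        words = cache[1]
        if len(protein) < 2 * word:
            return True  # too short to prescreen reliably; score it fully
        n = 0
        for i in range(len(protein) - word + 1):
            if protein[i:i + word] in words:
                n += 1
                if n >= min_shared:
                    return True
        return False


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    profile_name: str
    score: float
    evalue: float
    query_span: tuple[int, int]  # half-open on the protein


def consensus_of(profile: ProfileModel) -> str:
    return "".join(AA_ALPHABET[i] for i in profile.match_scores.argmax(axis=1))


def score_protein(profile: ProfileModel, protein: str) -> tuple[float, tuple[int, int]]:
    """Best local segment score (bits) of a protein against the profile.

    Affine gaps (open 11, extend 1 bits); X residues score 0 in every
    column; non-amino-acid characters other than X raise ValueError.
    """
    if len(protein) < 1:
        raise ValueError("protein must be non-empty")
    enc = encode_protein(protein)
    score, start, end = sw_profile(profile.padded_scores(), enc, GAP_OPEN, GAP_EXT)
    if score <= 0.0:
        return 0.0, (0, 0)
    return float(score), (int(start), int(end))


def _random_protein(rng: np.random.Generator, length: int, freqs: np.ndarray) -> str:
    idx = rng.choice(20, size=length, p=freqs)
    return "".join(AA_ALPHABET[i] for i in idx)


def calibrate_evalues(
    profile: ProfileModel,
    decoy_db_size: int,
    n_shuffles: int,
    rng: np.random.Generator,
) -> EvalueCalibration:
    """Fit the empirical null from length-matched random decoy proteins."""
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    scores = np.empty(n_shuffles)
    for k in range(n_shuffles):
        decoy = _random_protein(rng, profile.length, profile.null_freqs)
        scores[k], _ = score_protein(profile, decoy)
    scores.sort()
    # exponential tail: MLE rate on exceedances over the 90th percentile
    q90 = float(np.quantile(scores, 0.9))
    exc = scores[scores > q90] - q90
    lam = 1.0 / float(exc.mean()) if exc.size and float(exc.mean()) > 0 else 1.0
    cal = EvalueCalibration(float(decoy_db_size), scores, lam)
    profile.calibration = cal
    return cal


def scan_proteome(profiles, genome, evalue_max: float,
                  prescreen: bool = True) -> list[MotifHit]:
    """All hits with E <= evalue_max, best hit per (gene, profile), sorted
    by (contig order, gene ordinal, profile name). The word-hit prescreen
    (on by default, as in BLAST) skips full scoring of proteins sharing
    fewer than two exact 4-mers with the profile consensus."""
    hits = []
    for contig in genome.contigs:
        for gene in contig.genes:
            for prof in profiles:
                if prof.calibration is None:
                    raise ValueError(f"profile {prof.name} is not calibrated")
                if prescreen and not prof.shares_words(gene.protein):
                    continue
                score, span = score_protein(prof, gene.protein)
                if score <= 0.0:
                    continue
                ev = prof.calibration.evalue(score)
                if ev <= evalue_max:
                    hits.append(MotifHit(gene.gene_id, prof.name, score, ev, span))
    order = {
        (c.contig_id, g.gene_id): (ci, g.ordinal)
        for ci, c in enumerate(genome.contigs)
        for g in c.genes
    }
    gene_pos = {g.gene_id: order[(c.contig_id, g.gene_id)]
                for c in genome.contigs for g in c.genes}
    hits.sort(key=lambda h: (gene_pos[h.gene_id], h.profile_name))
    return hits


def dedupe_members(proteins: list[str]) -> list[str]:
    """Collapse exact duplicates, keeping the first occurrence (the
    non-redundant-at-100%-identity step before alignment)."""
    seen = set()
    out = []
    for p in proteins:
        if p not in seen:
            seen.add(p)
            out.append(p)
    return out


@dataclass
class Msa:
    rows: list[str]  # equal-length aligned sequences, '-' for gaps

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def _pairwise_global(center: str, member: str):
    # lazy import: Bio.Align brings in a fair amount of machinery
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXT
    aligner.end_gap_score = 0.0
    return next(iter(aligner.align(center, member)))


def _to_center_rows(center: str, member: str):
    """Decompose one pairwise alignment into (residue-per-center-column,
    insertions-before-each-center-column) for the star merge."""
    aln = _pairwise_global(center, member)
    t_blocks, q_blocks = aln.aligned
    C = len(center)
    row = ["-"] * C
    ins: list[str] = ["" for _ in range(C + 1)]
    t_prev, q_prev = 0, 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        # member residues not aligned to any center column -> insertion
        if qs > q_prev:
            ins[ts] += member[q_prev:qs]
        for k in range(te - ts):
            row[ts + k] = member[qs + k]
        t_prev, q_prev = te, qe
    if q_prev < len(member):
        ins[C] += member[q_prev:]
    return row, ins


def build_msa(members: list[str]) -> Msa:
    """Star alignment: every member globally aligned (free end gaps,
    BLOSUM62, affine 11/1) to the longest member, merged on its columns."""
    if not members:
        raise ValueError("need at least one member")
    if len(members) == 1:
        return Msa([members[0]])
    center_i = max(range(len(members)), key=lambda i: (len(members[i]), -i))
    center = members[center_i]
    C = len(center)
    rows, inss = [], []
    for m in members:
        if m == center:
            row = list(center)
            ins = ["" for _ in range(C + 1)]
        else:
            row, ins = _to_center_rows(center, m)
        rows.append(row)
        inss.append(ins)
    width = [max(len(ins[c]) for ins in inss) for c in range(C + 1)]
    out = []
    for row, ins in zip(rows, inss):
        parts = []
        for c in range(C):
            parts.append(ins[c].ljust(width[c], "-"))
            parts.append(row[c])
        parts.append(ins[C].ljust(width[C], "-"))
        out.append("".join(parts))
    return Msa(out)


def build_profile(alignment: Msa, name: str, pseudocount: float = 0.1) -> ProfileModel:
    """Profile from an MSA: columns with >=50% residue occupancy become
    match columns; emissions are residue frequencies with +pseudocount
    Laplace smoothing; scores are log2 odds against a uniform background."""
    if not alignment.rows:
        raise ValueError("empty alignment")
    nrows = len(alignment.rows)
    cols = []
    for c in range(alignment.n_columns):
        residues = [r[c] for r in alignment.rows if r[c] != "-"]
        if len(residues) * 2 < nrows:
            continue  # insert-dominated column dropped
        counts = np.full(20, pseudocount)
        for aa in residues:
            if aa in AA_INDEX:
                counts[AA_INDEX[aa]] += 1.0
        freqs = counts / counts.sum()
        cols.append(np.log2(freqs * 20.0))
    if not cols:
        raise ValueError("alignment has no match columns")
    null = np.full(20, 1.0 / 20.0)
    return ProfileModel(name, np.vstack(cols), null)


def calibrate_threshold(profile: ProfileModel, members: list[str],
                        msa: "Msa | None" = None,
                        pseudocount: float = 0.1) -> ProfileModel:
    """Self-scan inclusion threshold from the training set.

    The baseline rule is the minimum training-member score, which by
    construction recalls every member. A profile slightly overfits its own
    training sample (each member's private substitutions inflate their own
    emission frequencies), so when the training MSA is supplied the
    threshold is instead the minimum leave-one-out path score: each
    member's score along its own MSA row against column frequencies
    recomputed without it. That is what an unseen family member actually
    faces, and it is never above the direct minimum.
    """
    if not members:
        raise ValueError("need at least one member")
    direct_min = min(score_protein(profile, m)[0] for m in members)
    threshold = direct_min
    if msa is not None and len(msa.rows) > 1:
        nrows = len(msa.rows)
        loo_scores = []
        # reproduce build_profile's match-column selection
        match_cols = [c for c in range(msa.n_columns)
                      if sum(r[c] != "-" for r in msa.rows) * 2 >= nrows]
        counts = []
        for c in match_cols:
            cnt = np.full(20, pseudocount)
            for r in msa.rows:
                if r[c] in AA_INDEX:
                    cnt[AA_INDEX[r[c]]] += 1.0
            counts.append(cnt)
        for row in msa.rows:
            score = 0.0
            gap_run = 0
            for cnt, c in zip(counts, match_cols):
                aa = row[c]
                if aa in AA_INDEX:
                    if gap_run:
                        score -= GAP_OPEN + GAP_EXT * (gap_run - 1)
                        gap_run = 0
                    loo = cnt.copy()
                    loo[AA_INDEX[aa]] -= 1.0
                    score += np.log2(max(loo[AA_INDEX[aa]], pseudocount)
                                     / loo.sum() * 20.0)
                else:
                    gap_run += 1
            loo_scores.append(score)
        threshold = min(direct_min, min(loo_scores))
    profile.threshold_score = float(max(threshold, 0.0))
    return profile
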
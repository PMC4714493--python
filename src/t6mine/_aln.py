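"""Low-level alignment kernels (numba).

Two primitives live here: a local profile-vs-sequence Smith-Waterman with
affine gaps (the stand-in for an rpsblast/hmmsearch scoring core) and an
ungapped X-drop extension used by the blastn-like HSP finder.
"""
from __future__ import annotations

import numpy as np
from numba import njit

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
X_INDEX = 20  # 'X' scores 0 against every profile column

NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode_protein(protein: str) -> np.ndarray:
    """Encode an amino-acid string to indices; X (and only X) maps to 20."""
    out = np.empty(len(protein), dtype=np.int8)
    for i, aa in enumerate(protein):
        if aa == "X":
            out[i] = X_INDEX
        else:
            try:
                out[i] = AA_INDEX[aa]
            except KeyError:
                raise ValueError(f"non-amino-acid character {aa!r} at position {i}")
    return out


def encode_dna(seq: str) -> np.ndarray:
    """Encode nucleotides; anything outside ACGT (e.g. N) maps to 4."""
    out = np.full(len(seq), 4, dtype=np.int8)
    for i, nt in enumerate(seq.upper()):
        out[i] = NT_INDEX.get(nt, 4)
    return out


@njit(cache=True)
def sw_profile(scores: np.ndarray, prot: np.ndarray, gap_open: float, gap_ext: float):
    """Local alignment of a protein against profile columns.

    scores: (L, 21) per-column log-odds in bits, column 20 (X) all zero.
    Returns (best score, prot_start, prot_end) with a half-open span.
    Affine gaps: first gapped position costs gap_open, each further gap_ext.
    Only the match state may restart at zero (local convention), so the
    score is always >= 0.
    """
    L = scores.shape[0]
    n = prot.shape[0]
    NEG = -1e30
    # Gotoh with three states, rows = profile columns i, cols = residues j.
    # M: residue j aligned to column i; X: column i deleted (gap in protein);
    # Y: residue j inserted (gap in profile). Start index of the local
    # alignment on the protein is carried alongside each state.
    m_prev = np.full(n, NEG)
    x_prev = np.full(n, NEG)
    y_prev = np.full(n, NEG)
    sm_prev = np.zeros(n, dtype=np.int64)
    sx_prev = np.zeros(n, dtype=np.int64)
    sy_prev = np.zeros(n, dtype=np.int64)
    best = 0.0
    best_start = 0
    best_end = 0
    for i in range(L):
        m_cur = np.full(n, NEG)
        x_cur = np.full(n, NEG)
        y_cur = np.full(n, NEG)
        sm_cur = np.zeros(n, dtype=np.int64)
        sx_cur = np.zeros(n, dtype=np.int64)
        sy_cur = np.zeros(n, dtype=np.int64)
        for j in range(n):
            # match state: best of diagonal predecessors or a fresh start
            diag = 0.0
            start = j
            if i > 0 and j > 0:
                if m_prev[j - 1] > diag:
                    diag = m_prev[j - 1]
                    start = sm_prev[j - 1]
                if x_prev[j - 1] > diag:
                    diag = x_prev[j - 1]
                    start = sx_prev[j - 1]
                if y_prev[j - 1] > diag:
                    diag = y_prev[j - 1]
                    start = sy_prev[j - 1]
            m_cur[j] = diag + scores[i, prot[j]]
            sm_cur[j] = start
            # X: consume profile column i without a residue
            if i > 0:
                a = m_prev[j] - gap_open
                b = x_prev[j] - gap_ext
                if a >= b:
                    x_cur[j] = a
                    sx_cur[j] = sm_prev[j]
                else:
                    x_cur[j] = b
                    sx_cur[j] = sx_prev[j]
            # Y: consume residue j while staying between columns
            if j > 0:
                a = m_cur[j - 1] - gap_open
                b = y_cur[j - 1] - gap_ext
                if a >= b:
                    y_cur[j] = a
                    sy_cur[j] = sm_cur[j - 1]
                else:
                    y_cur[j] = b
                    sy_cur[j] = sy_cur[j - 1]
            if m_cur[j] > best:
                best = m_cur[j]
                best_start = sm_cur[j]
                best_end = j + 1
        m_prev = m_cur
        x_prev = x_cur
        y_prev = y_cur
        sm_prev = sm_cur
        sx_prev = sx_cur
        sy_prev = sy_cur
    return best, best_start, best_end


@njit(cache=True)
def xdrop_extend(q: np.ndarray, s: np.ndarray, qpos: int, spos: int, word: int,
                 match: float, mismatch: float, xdrop: float):
    """Ungapped two-sided X-drop extension of an exact word seed.

    Returns (q_start, q_end, n_matches) for the best-scoring extension,
    half-open on the query. Non-ACGT codes (4) never match.
    """
    # right extension from the end of the seed
    score = word * match
    best = score
    qe = qpos + word
    se = spos + word
    best_qe = qe
    while qe < q.shape[0] and se < s.shape[0]:
        if q[qe] == s[se] and q[qe] != 4:
            score += match
        else:
            score += mismatch
        qe += 1
        se += 1
        if score > best:
            best = score
            best_qe = qe
        if score <= best - xdrop:
            break
    # left extension
    score = best
    best2 = score
    qs = qpos
    ss = spos
    best_qs = qs
    while qs > 0 and ss > 0:
        qs -= 1
        ss -= 1
        if q[qs] == s[ss] and q[qs] != 4:
            score += match
        else:
            score += mismatch
        if score > best2:
            best2 = score
            best_qs = qs
        if score <= best2 - xdrop:
            break
    # count matches over the final span
    nm = 0
    for k in range(best_qs, best_qe):
        if q[k] == s[k - qpos + spos] and q[k] != 4:
            nm += 1
    return best_qs, best_qe, nm


@njit(cache=True)
def count_matches(q: np.ndarray, s: np.ndarray, qs: int, qe: int, soff: int):
    """Matches between q[qs:qe] and s shifted by soff (diagonal compare)."""
    nm = 0
    for k in range(qs, qe):
        if q[k] == s[k + soff] and q[k] != 4:
            nm += 1
    return nm
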
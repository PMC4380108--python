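"""Low-level pairwise alignment kernels (numba-compiled).

Two dynamic programs back the whole package:

* :func:`banded_local` — affine-gap Smith–Waterman restricted to a diagonal
  band, used to extend exact seed matches. Tracks the start coordinates of the
  optimal local alignment so callers get spans, not just scores.
* :func:`overlap_align` — semi-global ("overlap") alignment with free end gaps
  on both sequences and full traceback, used for the coverage / p-distance
  metrics and reference-anchored stacking.

Gap model: a gap of length L costs ``gap_open + L * gap_extend`` (both
negative), i.e. the first gapped base pays ``gap_open + gap_extend``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int64(-(10**9))

# ---------------------------------------------------------------- alphabets

DNA_ALPHABET = "ACGTN"
_DNA_INDEX = np.full(128, 4, dtype=np.int8)  # unknown/ambiguity -> N
for _i, _c in enumerate(DNA_ALPHABET):
    _DNA_INDEX[ord(_c)] = _i

PROTEIN_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_PROT_INDEX = np.full(128, PROTEIN_ALPHABET.index("X"), dtype=np.int8)
for _i, _c in enumerate(PROTEIN_ALPHABET):
    _PROT_INDEX[ord(_c)] = _i


def encode_dna(seq: str) -> np.ndarray:
    return _DNA_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]

def encode_protein(seq: str) -> np.ndarray:
    return _PROT_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def dna_matrix(match: int, mismatch: int) -> np.ndarray:
    m = np.full((5, 5), mismatch, dtype=np.int32)
    np.fill_diagonal(m, match)
    m[4, :] = mismatch  # N never matches, not even N/N
    m[:, 4] = mismatch
    return m


def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 over :data:`PROTEIN_ALPHABET`; ``*`` mismatches everything."""
    from Bio.Align import substitution_matrices

    b = substitution_matrices.load("BLOSUM62")
    n = len(PROTEIN_ALPHABET)
    m = np.zeros((n, n), dtype=np.int32)
    for i, ci in enumerate(PROTEIN_ALPHABET):
        for j, cj in enumerate(PROTEIN_ALPHABET):
            m[i, j] = int(b[ci, cj])
    star = PROTEIN_ALPHABET.index("*")
    m[star, :] = -4
    m[:, star] = -4
    return m


# ---------------------------------------------------------------- kernels

@njit(cache=True)
def xdrop_dir(a, b, sub, gap_open, gap_extend, band, xdrop):  # pragma: no cover
    """One-directional gapped X-drop extension from an anchor at (0, 0).

    Aligns prefixes of ``a`` and ``b`` within ``band`` diagonals of the
    anchor's diagonal; a cell is pruned once its score falls more than
    ``xdrop`` below the running best, and extension stops when a whole row is
    pruned. Returns ``(best_score, a_consumed, b_consumed)``; (0, 0, 0) means
    the extension never improved on the bare anchor.
    """
    la = len(a)
    lb = len(b)
    W = 2 * band + 1
    ge1 = gap_open + gap_extend

    m_sc = np.full(W, NEG)
    e_sc = np.full(W, NEG)
    f_sc = np.full(W, NEG)
    # row 0: anchor at offset `band` (j = 0); gaps right of the anchor
    m_sc[band] = 0
    for o in range(band + 1, W):
        cand = m_sc[o - 1] + ge1
        if e_sc[o - 1] + gap_extend > cand:
            cand = e_sc[o - 1] + gap_extend
        e_sc[o] = cand

    best = np.int64(0)
    best_i = 0
    best_j = 0
    nm_sc = np.empty(W, np.int64)
    ne_sc = np.empty(W, np.int64)
    nf_sc = np.empty(W, np.int64)

    for i in range(1, la + 1):
        nm_sc[:] = NEG; ne_sc[:] = NEG; nf_sc[:] = NEG
        alive = False
        for o in range(W):
            j = i + (o - band)
            if j < 0 or j > lb:
                continue
            if j > 0:
                # M from (i-1, j-1): previous row, same offset
                pbest = m_sc[o]
                if e_sc[o] > pbest:
                    pbest = e_sc[o]
                if f_sc[o] > pbest:
                    pbest = f_sc[o]
                if pbest > NEG // 2:
                    nm_sc[o] = pbest + sub[a[i - 1], b[j - 1]]
                # E (gap in a, consume b) from (i, j-1): same row, offset o-1
                if o >= 1:
                    cand = nm_sc[o - 1] + ge1
                    if ne_sc[o - 1] + gap_extend > cand:
                        cand = ne_sc[o - 1] + gap_extend
                    if nf_sc[o - 1] + ge1 > cand:
                        cand = nf_sc[o - 1] + ge1
                    if cand > NEG // 2:
                        ne_sc[o] = cand
            # F (gap in b, consume a) from (i-1, j): previous row, offset o+1
            if o + 1 < W:
                cand = m_sc[o + 1] + ge1
                if f_sc[o + 1] + gap_extend > cand:
                    cand = f_sc[o + 1] + gap_extend
                if e_sc[o + 1] + ge1 > cand:
                    cand = e_sc[o + 1] + ge1
                if cand > NEG // 2:
                    nf_sc[o] = cand
            h = nm_sc[o]
            if ne_sc[o] > h:
                h = ne_sc[o]
            if nf_sc[o] > h:
                h = nf_sc[o]
            if h < best - xdrop:
                nm_sc[o] = NEG; ne_sc[o] = NEG; nf_sc[o] = NEG
                continue
            alive = True
            if nm_sc[o] > best:  # alignments end on an aligned column
                best = nm_sc[o]; best_i = i; best_j = j
        if not alive:
            break
        m_sc, nm_sc = nm_sc, m_sc
        e_sc, ne_sc = ne_sc, e_sc
        f_sc, nf_sc = nf_sc, f_sc

    return best, best_i, best_j


@njit(cache=True)
def overlap_fill(a, b, sub, gap_open_e, gap_extend_e, gap_open_f, gap_extend_f):  # pragma: no cover
    """Fill phase of overlap alignment. Returns score, end cell/state, pointers.

    States: 0 = M (diagonal), 1 = E (gap in a, consumes b), 2 = F (gap in b,
    consumes a), 3 = boundary (free end gap). E and F take separate affine
    costs so callers can make insertions in ``a`` (e.g. introns in a genomic
    contig aligned to a spliced reference) cheaper than deletions. Tie-break
    preference everywhere: M > E > F.
    """
    la = len(a)
    lb = len(b)
    ge1e = gap_open_e + gap_extend_e
    ge1f = gap_open_f + gap_extend_f

    M = np.full((la + 1, lb + 1), NEG)
    E = np.full((la + 1, lb + 1), NEG)
    F = np.full((la + 1, lb + 1), NEG)
    PM = np.full((la + 1, lb + 1), 3, np.int8)
    PE = np.full((la + 1, lb + 1), 3, np.int8)
    PF = np.full((la + 1, lb + 1), 3, np.int8)
    # boundary H = 0 is represented implicitly via state 3

    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            # H at (i-1, j-1) with state preference M > E > F > boundary(0)
            hm = M[i - 1, j - 1]; he = E[i - 1, j - 1]; hf = F[i - 1, j - 1]
            hb = np.int64(0) if (i - 1 == 0 or j - 1 == 0) else NEG
            p = 0; h = hm
            if he > h:
                p = 1; h = he
            if hf > h:
                p = 2; h = hf
            if hb > h:
                p = 3; h = hb
            M[i, j] = h + sub[a[i - 1], b[j - 1]]
            PM[i, j] = p
            # E from (i, j-1)
            hm = M[i, j - 1] + ge1e; he = E[i, j - 1] + gap_extend_e; hf = F[i, j - 1] + ge1e
            hb = ge1e if (i == 0 or j - 1 == 0) else NEG
            p = 0; h = hm
            if he > h:
                p = 1; h = he
            if hf > h:
                p = 2; h = hf
            if hb > h:
                p = 3; h = hb
            E[i, j] = h
            PE[i, j] = p
            # F from (i-1, j)
            hm = M[i - 1, j] + ge1f; he = E[i - 1, j] + ge1f; hf = F[i - 1, j] + gap_extend_f
            hb = ge1f if (i - 1 == 0 or j == 0) else NEG
            p = 0; h = hm
            if he > h:
                p = 1; h = he
            if hf > h:
                p = 2; h = hf
            if hb > h:
                p = 3; h = hb
            F[i, j] = h
            PF[i, j] = p

    # best end over last row then last column, preference M > E > F
    best = NEG
    ei = la; ej = 0; estate = 3
    for j in range(0, lb + 1):
        for s in range(3):
            v = M[la, j] if s == 0 else (E[la, j] if s == 1 else F[la, j])
            if j == 0:
                v = np.int64(0) if s == 0 else NEG
            if v > best:
                best = v; ei = la; ej = j; estate = s
    for i in range(0, la + 1):
        for s in range(3):
            v = M[i, lb] if s == 0 else (E[i, lb] if s == 1 else F[i, lb])
            if i == 0:
                v = np.int64(0) if s == 0 else NEG
            if v > best:
                best = v; ei = i; ej = lb; estate = s
    if estate == 0 and (ei == 0 or ej == 0):
        estate = 3
    return best, ei, ej, estate, PM, PE, PF
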
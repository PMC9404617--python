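"""Pairwise and progressive alignment.

Needleman-Wunsch/Gotoh with affine gaps: a gap run of length L costs
``gap_open + (L-1) * gap_extend`` (penalties given positive).  DNA defaults
match +2 / mismatch -1 / open 10 / extend 2, emulating the ClustalW-style
"-gapopen 10 -gapext 2" settings used for spacer alignment.  Traceback is
deterministic: on ties prefer the diagonal move, then the gap-in-b ("up")
move, then the gap-in-a ("left") move.

The same DP kernel aligns sequences and column profiles, so the
progressive multiple aligner (pairwise distances -> UPGMA guide tree ->
profile-profile merges) shares one deterministic code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["PairwiseAlignment", "global_align", "semiglobal_align",
           "local_align", "alignment_identity", "progressive_msa"]

_NEG = np.float32(-1e30)


@njit(cache=True)
def _gotoh_local(S, gap_open, gap_ext):  # pragma: no cover - numba
    """Smith-Waterman with affine gaps; deterministic argmax (smallest
    (i, j), diagonal preferred).  Returns score, ops, end_i, end_j,
    start_i, start_j."""
    la, lb = S.shape
    M = np.full((la + 1, lb + 1), _NEG, dtype=np.float32)
    X = np.full((la + 1, lb + 1), _NEG, dtype=np.float32)
    Y = np.full((la + 1, lb + 1), _NEG, dtype=np.float32)
    PM = np.zeros((la + 1, lb + 1), dtype=np.int8)  # 3 marks a fresh start
    PX = np.zeros((la + 1, lb + 1), dtype=np.int8)
    PY = np.zeros((la + 1, lb + 1), dtype=np.int8)
    best_score = np.float32(0.0)
    bi = bj = 0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            best, arg = np.float32(0.0), 3
            if M[i - 1, j - 1] > best:
                best, arg = M[i - 1, j - 1], 0
            if X[i - 1, j - 1] > best:
                best, arg = X[i - 1, j - 1], 1
            if Y[i - 1, j - 1] > best:
                best, arg = Y[i - 1, j - 1], 2
            M[i, j] = best + S[i - 1, j - 1]
            PM[i, j] = arg
            best, arg = M[i - 1, j] - gap_open, 0
            if X[i - 1, j] - gap_ext > best:
                best, arg = X[i - 1, j] - gap_ext, 1
            X[i, j] = best
            PX[i, j] = arg
            best, arg = M[i, j - 1] - gap_open, 0
            if Y[i, j - 1] - gap_ext > best:
                best, arg = Y[i, j - 1] - gap_ext, 2
            Y[i, j] = best
            PY[i, j] = arg
            if M[i, j] > best_score:
                best_score, bi, bj = M[i, j], i, j
    ops = np.empty(la + lb, dtype=np.int8)
    nops = 0
    i, j, state = bi, bj, 0
    while i > 0 or j > 0:
        if state == 0:
            pred = PM[i, j]
            ops[nops] = 0
            nops += 1
            i -= 1
            j -= 1
            if pred == 3:
                break
            state = pred
        elif state == 1:
            ops[nops] = 1
            nops += 1
            state = PX[i, j]
            i -= 1
        else:
            ops[nops] = 2
            nops += 1
            state = PY[i, j]
            j -= 1
    return best_score, ops[:nops][::-1].copy(), bi, bj, i, j


@njit(cache=True)
def _gotoh(S, gap_open, gap_ext, free_ends):  # pragma: no cover - numba
    la, lb = S.shape
    M = np.full((la + 1, lb + 1), _NEG, dtype=np.float32)
    X = np.full((la + 1, lb + 1), _NEG, dtype=np.float32)  # gap in b (up)
    Y = np.full((la + 1, lb + 1), _NEG, dtype=np.float32)  # gap in a (left)
    # predecessor state per state-cell: 0=M, 1=X, 2=Y
    PM = np.zeros((la + 1, lb + 1), dtype=np.int8)
    PX = np.zeros((la + 1, lb + 1), dtype=np.int8)
    PY = np.zeros((la + 1, lb + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = 0.0 if free_ends else -(gap_open + (i - 1) * gap_ext)
        PX[i, 0] = 1
    for j in range(1, lb + 1):
        Y[0, j] = 0.0 if free_ends else -(gap_open + (j - 1) * gap_ext)
        PY[0, j] = 2
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            # M: align a[i-1] with b[j-1]
            best, arg = M[i - 1, j - 1], 0
            if X[i - 1, j - 1] > best:
                best, arg = X[i - 1, j - 1], 1
            if Y[i - 1, j - 1] > best:
                best, arg = Y[i - 1, j - 1], 2
            M[i, j] = best + S[i - 1, j - 1]
            PM[i, j] = arg
            # X: gap in b, consume a[i-1]
            best, arg = M[i - 1, j] - gap_open, 0
            if X[i - 1, j] - gap_ext > best:
                best, arg = X[i - 1, j] - gap_ext, 1
            if Y[i - 1, j] - gap_open > best:
                best, arg = Y[i - 1, j] - gap_open, 2
            X[i, j] = best
            PX[i, j] = arg
            # Y: gap in a, consume b[j-1]
            best, arg = M[i, j - 1] - gap_open, 0
            if X[i, j - 1] - gap_open > best:
                best, arg = X[i, j - 1] - gap_open, 1
            if Y[i, j - 1] - gap_ext > best:
                best, arg = Y[i, j - 1] - gap_ext, 2
            Y[i, j] = best
            PY[i, j] = arg

    # endpoint selection
    ei, ej = la, lb
    state = 0
    best = M[la, lb]
    if X[la, lb] > best:
        best, state = X[la, lb], 1
    if Y[la, lb] > best:
        best, state = Y[la, lb], 2
    if free_ends:
        # best cell on last row/column; strict > keeps the corner on ties,
        # then cells nearest the corner.
        for i in range(la, -1, -1):
            for st in range(3):
                v = M[i, lb] if st == 0 else (X[i, lb] if st == 1 else Y[i, lb])
                if v > best:
                    best, ei, ej, state = v, i, lb, st
        for j in range(lb, -1, -1):
            for st in range(3):
                v = M[la, j] if st == 0 else (X[la, j] if st == 1 else Y[la, j])
                if v > best:
                    best, ei, ej, state = v, la, j, st
    score = best

    ops = np.empty(la + lb, dtype=np.int8)  # 0=diag, 1=up (gap in b), 2=left
    nops = 0
    i, j = ei, ej
    while i > 0 or j > 0:
        if state == 0:
            if i == 0 or j == 0:
                break
            ops[nops] = 0
            state = PM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            ops[nops] = 1
            state = PX[i, j]
            i -= 1
        else:
            ops[nops] = 2
            state = PY[i, j]
            j -= 1
        nops += 1
    return score, ops[:nops][::-1].copy(), ei, ej


@dataclass
class PairwiseAlignment:
    """A global pairwise alignment of two sequences."""

    a: str
    b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ValueError("aligned rows differ in length")

    @property
    def columns(self) -> int:
        return len(self.a)

    def pairs(self):
        """Iterate over (char_a, char_b) columns."""
        return zip(self.a, self.b)


def _encode(seq: str, alphabet: str, default_idx: int | None = None) -> np.ndarray:
    lut = np.full(256, default_idx if default_idx is not None else len(alphabet) - 1,
                  dtype=np.int64)
    for i, c in enumerate(alphabet):
        lut[ord(c)] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _dna_score_matrix(a: str, b: str, match: float, mismatch: float) -> np.ndarray:
    # N (and other ambiguity codes) score 0 against everything
    alphabet = "ACGTN"
    ea, eb = _encode(a, alphabet), _encode(b, alphabet)
    sub = np.full((5, 5), mismatch, dtype=np.float32)
    np.fill_diagonal(sub, match)
    sub[4, :] = 0.0
    sub[:, 4] = 0.0
    return sub[np.ix_(ea, eb)].astype(np.float32)


def _align_ops(a: str, b: str, ops: np.ndarray, ei: int, ej: int) -> tuple[str, str]:
    ra, rb = [], []
    i = ei - int(np.sum(ops == 0)) - int(np.sum(ops == 1))
    j = ej - int(np.sum(ops == 0)) - int(np.sum(ops == 2))
    # leading overhang (free-end mode only; empty otherwise)
    if i > 0:
        ra.append(a[:i])
        rb.append("-" * i)
    if j > 0:
        ra.append("-" * j)
        rb.append(b[:j])
    for op in ops:
        if op == 0:
            ra.append(a[i]); rb.append(b[j]); i += 1; j += 1
        elif op == 1:
            ra.append(a[i]); rb.append("-"); i += 1
        else:
            ra.append("-"); rb.append(b[j]); j += 1
    if i < len(a):
        ra.append(a[i:])
        rb.append("-" * (len(a) - i))
    if j < len(b):
        ra.append("-" * (len(b) - j))
        rb.append(b[j:])
    return "".join(ra), "".join(rb)


def global_align(a: str, b: str, match: float = 2.0, mismatch: float = -1.0,
                 gap_open: float = 10.0, gap_extend: float = 2.0
                 ) -> PairwiseAlignment:
    """Global Needleman-Wunsch alignment with affine gaps (Gotoh).

    Penalties are positive; a gap run of length L costs
    ``gap_open + (L-1)*gap_extend``.  Deterministic traceback.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    S = _dna_score_matrix(a, b, match, mismatch)
    score, ops, ei, ej = _gotoh(S, np.float32(gap_open), np.float32(gap_extend), False)
    ra, rb = _align_ops(a, b, ops, ei, ej)
    return PairwiseAlignment(ra, rb, float(score))


def semiglobal_align(a: str, b: str, match: float = 2.0, mismatch: float = -1.0,
                     gap_open: float = 10.0, gap_extend: float = 2.0
                     ) -> PairwiseAlignment:
    """Overlap alignment: terminal gap runs in either sequence are free."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    S = _dna_score_matrix(a, b, match, mismatch)
    score, ops, ei, ej = _gotoh(S, np.float32(gap_open), np.float32(gap_extend), True)
    ra, rb = _align_ops(a, b, ops, ei, ej)
    return PairwiseAlignment(ra, rb, float(score))


def local_align(a: str, b: str, match: float = 2.0, mismatch: float = -1.0,
                gap_open: float = 10.0, gap_extend: float = 2.0
                ) -> PairwiseAlignment:
    """Smith-Waterman local alignment; unaligned flanks are padded back as
    terminal gap columns so row lengths stay equal."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    S = _dna_score_matrix(a, b, match, mismatch)
    score, ops, ei, ej, si, sj = _gotoh_local(S, np.float32(gap_open),
                                              np.float32(gap_extend))
    ra, rb = [], []
    if si > 0:
        ra.append(a[:si]); rb.append("-" * si)
    if sj > 0:
        ra.append("-" * sj); rb.append(b[:sj])
    i, j = si, sj
    for op in ops:
        if op == 0:
            ra.append(a[i]); rb.append(b[j]); i += 1; j += 1
        elif op == 1:
            ra.append(a[i]); rb.append("-"); i += 1
        else:
            ra.append("-"); rb.append(b[j]); j += 1
    if i < len(a):
        ra.append(a[i:]); rb.append("-" * (len(a) - i))
    if j < len(b):
        ra.append("-" * (len(b) - j)); rb.append(b[j:])
    return PairwiseAlignment("".join(ra), "".join(rb), float(score))


def alignment_identity(aln: PairwiseAlignment) -> float:
    """Matches over columns where both rows carry a base."""
    both = matches = 0
    for x, y in aln.pairs():
        if x != "-" and y != "-":
            both += 1
            if x == y:
                matches += 1
    return matches / both if both else 0.0


# ---------------------------------------------------------------------------
# Progressive multiple alignment
# ---------------------------------------------------------------------------

_PROTEIN_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"


def _protein_submatrix() -> np.ndarray:
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    k = len(_PROTEIN_ALPHABET)
    sub = np.zeros((k, k), dtype=np.float32)
    for i, x in enumerate(_PROTEIN_ALPHABET):
        for j, y in enumerate(_PROTEIN_ALPHABET):
            try:
                sub[i, j] = blosum[x, y]
            except (KeyError, IndexError):
                sub[i, j] = 0.0
    return sub


def _dna_submatrix(match: float, mismatch: float) -> np.ndarray:
    sub = np.full((5, 5), mismatch, dtype=np.float32)
    np.fill_diagonal(sub, match)
    sub[4, :] = 0.0
    sub[:, 4] = 0.0
    return sub


def _profile_freqs(rows: list[str], alphabet: str) -> np.ndarray:
    """Column frequency matrix (ncols x |alphabet|+1); last slot is gap."""
    k = len(alphabet)
    lut = np.full(256, k - 1, dtype=np.int64)  # unknowns -> last residue slot
    for i, c in enumerate(alphabet):
        lut[ord(c)] = i
    lut[ord("-")] = k
    ncols = len(rows[0])
    freqs = np.zeros((ncols, k + 1), dtype=np.float32)
    for row in rows:
        idx = lut[np.frombuffer(row.encode("ascii"), dtype=np.uint8)]
        freqs[np.arange(ncols), idx] += 1.0
    return freqs / len(rows)


def _merge_profiles(rows_a: list[str], rows_b: list[str], sub: np.ndarray,
                    alphabet: str, gap_open: float, gap_extend: float
                    ) -> tuple[list[str], list[str]]:
    fa = _profile_freqs(rows_a, alphabet)
    fb = _profile_freqs(rows_b, alphabet)
    k = len(alphabet)
    padded = np.zeros((k + 1, k + 1), dtype=np.float32)
    padded[:k, :k] = sub  # gap slot scores 0 against everything
    S = (fa @ padded @ fb.T).astype(np.float32)
    _, ops, ei, ej = _gotoh(S, np.float32(gap_open), np.float32(gap_extend), False)
    out_a = ["".join(c) for c in _thread(rows_a, rows_b, ops)]
    return out_a[: len(rows_a)], out_a[len(rows_a):]


def _thread(rows_a: list[str], rows_b: list[str], ops: np.ndarray) -> list[list[str]]:
    na, nb = len(rows_a), len(rows_b)
    out: list[list[str]] = [[] for _ in range(na + nb)]
    i = j = 0
    for op in ops:
        if op == 0:
            for r in range(na):
                out[r].append(rows_a[r][i])
            for r in range(nb):
                out[na + r].append(rows_b[r][j])
            i += 1
            j += 1
        elif op == 1:
            for r in range(na):
                out[r].append(rows_a[r][i])
            for r in range(nb):
                out[na + r].append("-")
            i += 1
        else:
            for r in range(na):
                out[r].append("-")
            for r in range(nb):
                out[na + r].append(rows_b[r][j])
            j += 1
    # ops from a global profile alignment always consume both profiles fully
    assert i == len(rows_a[0]) and j == len(rows_b[0])
    return out


def _upgma_merge_order(dist: np.ndarray, labels: list[str]
                       ) -> list[tuple[int, int]]:
    """Average-linkage agglomeration; returns merge pairs over a growing
    cluster list where cluster k (k >= n) is created by the (k-n)-th merge.

    Ties broken by smallest (i, j) with clusters ordered by creation.
    """
    n = len(labels)
    active: dict[int, list[int]] = {i: [i] for i in range(n)}
    d = {(i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)}
    merges = []
    nxt = n
    while len(active) > 1:
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                key = d[(i, j)]
                if best is None or key < best[0] - 1e-12:
                    best = (key, i, j)
        _, i, j = best
        members = active[i] + active[j]
        for k in sorted(active):
            if k in (i, j):
                continue
            ni, nj = len(active[i]), len(active[j])
            dik = d[(min(i, k), max(i, k))]
            djk = d[(min(j, k), max(j, k))]
            d[(k, nxt) if k < nxt else (nxt, k)] = (ni * dik + nj * djk) / (ni + nj)
        active[nxt] = members
        del active[i], active[j]
        merges.append((i, j))
        nxt += 1
    return merges


def progressive_msa(seqs: dict[str, str], kind: str = "dna",
                    match: float = 2.0, mismatch: float = -1.0,
                    gap_open: float = 10.0, gap_extend: float = 2.0
                    ) -> dict[str, str]:
    """Progressive multiple alignment (pairwise NW -> UPGMA -> profile merges).

    Deterministic for a given input order.  ``kind`` is 'dna' or 'protein'
    (protein uses BLOSUM62).
    """
    names = list(seqs)
    for name in names:
        if not seqs[name]:
            raise ValueError(f"empty sequence for {name}")
    if len(names) == 1:
        return dict(seqs)
    if kind == "protein":
        sub = _protein_submatrix()
        alphabet = _PROTEIN_ALPHABET

        def pair(a, b):
            ea, eb = _encode_prot(a), _encode_prot(b)
            S = sub[np.ix_(ea, eb)].astype(np.float32)
            score, ops, ei, ej = _gotoh(S, np.float32(gap_open),
                                        np.float32(gap_extend), False)
            return _align_ops(a, b, ops, ei, ej)
    else:
        sub = _dna_submatrix(match, mismatch)
        alphabet = "ACGTN"

        def pair(a, b):
            aln = global_align(a, b, match, mismatch, gap_open, gap_extend)
            return aln.a, aln.b

    n = len(names)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ra, rb = pair(seqs[names[i]], seqs[names[j]])
            ident = alignment_identity(PairwiseAlignment(ra, rb, 0.0))
            dist[i, j] = dist[j, i] = 1.0 - ident

    merges = _upgma_merge_order(dist, names)
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([names[i]], [seqs[names[i]]]) for i in range(n)}
    nxt = n
    for i, j in merges:
        na, ra = clusters.pop(i)
        nb, rb = clusters.pop(j)
        ma, mb = _merge_profiles(ra, rb, sub, alphabet, gap_open, gap_extend)
        clusters[nxt] = (na + nb, ma + mb)
        nxt += 1
    (final_names, final_rows), = clusters.values()
    out = dict(zip(final_names, final_rows))
    return {name: out[name] for name in names}


def _encode_prot(seq: str) -> np.ndarray:
    return _encode(seq, _PROTEIN_ALPHABET, _PROTEIN_ALPHABET.index("X"))
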
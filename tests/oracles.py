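"""Independent oracles: deliberately naive re-implementations used only to
cross-check the package's fast paths."""

from itertools import permutations

from Bio.Seq import Seq


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment of a and b as (row_a, row_b)."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ra, rb in enumerate_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in enumerate_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb
    if a and b:
        for ra, rb in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb


def score_alignment(ra: str, rb: str, match=2.0, mismatch=-1.0,
                    gap_open=10.0, gap_extend=2.0) -> float:
    """Score an explicit alignment; a gap run of length L costs
    open + (L-1)*extend."""
    score = 0.0
    run = None  # 'a' or 'b'
    for x, y in zip(ra, rb):
        if x == "-" or y == "-":
            which = "a" if x == "-" else "b"
            score -= gap_open if run != which else gap_extend
            run = which
        else:
            score += match if x == y else mismatch
            run = None
    return score


def best_alignment_score(a: str, b: str, **params) -> float:
    return max(score_alignment(ra, rb, **params)
               for ra, rb in enumerate_alignments(a, b))


def plain_gotoh_score(a: str, b: str, match=2.0, mismatch=-1.0,
                      gap_open=10.0, gap_extend=2.0) -> float:
    """Score-only affine-gap DP, written independently of the package."""
    NEG = float("-inf")
    la, lb = len(a), len(b)
    M = [[NEG] * (lb + 1) for _ in range(la + 1)]
    X = [[NEG] * (lb + 1) for _ in range(la + 1)]
    Y = [[NEG] * (lb + 1) for _ in range(la + 1)]
    M[0][0] = 0.0
    for i in range(1, la + 1):
        X[i][0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, lb + 1):
        Y[0][j] = -(gap_open + (j - 1) * gap_extend)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - gap_open)
            Y[i][j] = max(M[i][j - 1] - gap_open, X[i][j - 1] - gap_open,
                          Y[i][j - 1] - gap_extend)
    return max(M[la][lb], X[la][lb], Y[la][lb])


def naive_upgma_heights(dist) -> list[float]:
    """O(n^3) average-linkage agglomeration; returns merge heights in order."""
    import numpy as np

    d = np.asarray(dist, dtype=float).copy()
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    heights = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ii, i in enumerate(keys):
            for j in keys[ii + 1:]:
                val = sum(d[x][y] for x in clusters[i] for y in clusters[j])
                val /= len(clusters[i]) * len(clusters[j])
                if best is None or val < best[0] - 1e-12:
                    best = (val, i, j)
        h, i, j = best
        heights.append(h)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return heights


STOPS = {"TAA", "TAG", "TGA"}
BASES = "ACGT"


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def ng86_brute(a: str, b: str):
    """Independent NG86 counting: (S_sites, N_sites, Sd, Nd).

    Site fractions from the 9 one-step changes per codon (changes to stop
    codons nonsynonymous); differences averaged over permutations of the
    differing positions, excluding pathways through stop codons (all
    pathways if every one is blocked)."""
    assert len(a) == len(b) and len(a) % 3 == 0
    syn_counts = 0.0
    ncod = 0
    Sd = Nd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if any(ch not in BASES for ch in ca + cb) or ca in STOPS or cb in STOPS:
            continue
        ncod += 1
        for codon in (ca, cb):
            for pos in range(3):
                for base in BASES:
                    if base == codon[pos]:
                        continue
                    mut = codon[:pos] + base + codon[pos + 1:]
                    if mut not in STOPS and _aa(mut) == _aa(codon):
                        syn_counts += 1
        diff = [p for p in range(3) if ca[p] != cb[p]]
        if diff:
            paths = []
            for order in permutations(diff):
                cur, sd, nd, blocked = ca, 0, 0, False
                for pos in order:
                    nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                    if nxt in STOPS and nxt != cb:
                        blocked = True
                    if _aa(nxt) == _aa(cur):
                        sd += 1
                    else:
                        nd += 1
                    cur = nxt
                paths.append((blocked, sd, nd))
            ok = [(s, n) for bl, s, n in paths if not bl] or \
                 [(s, n) for _, s, n in paths]
            Sd += sum(s for s, _ in ok) / len(ok)
            Nd += sum(n for _, n in ok) / len(ok)
    S = syn_counts / 6.0
    N = 3.0 * ncod - S
    return S, N, Sd, Nd, ncod
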
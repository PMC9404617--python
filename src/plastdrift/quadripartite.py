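"""Quadripartite structure detection and junction analysis.

A plastome is partitioned into LSC-IRb-SSC-IRa by locating the longest
pair of exact maximal inverted repeats on the circular sequence
(seed-and-extend against the reverse complement).  The partition is
reported in a canonical rotation with the LSC starting at position 0 and
regions in the order LSC, IRb, SSC, IRa; the four junctions JLB, JSB,
JSA, JLA are the coordinates of the first base of the downstream region
(half-open convention, so a gene ending exactly at a junction is at
distance 0 from it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import AnnotatedPlastome, GeneFeature, revcomp, rotate_plastome

__all__ = ["QuadripartitePartition", "JunctionContext", "detect_inverted_repeat",
           "canonical_rotation", "junction_report", "assign_genes_to_regions",
           "partition_regions"]

JUNCTIONS = ("JLB", "JSB", "JSA", "JLA")


@dataclass
class QuadripartitePartition:
    """LSC/IRb/SSC/IRa intervals in canonical-rotation coordinates.

    ``rotation`` is the original coordinate that maps to canonical 0, so
    canonical = (original - rotation) mod n.
    """

    has_quadripartite: bool
    n: int
    rotation: int = 0
    lsc: tuple[int, int] | None = None
    irb: tuple[int, int] | None = None
    ssc: tuple[int, int] | None = None
    ira: tuple[int, int] | None = None
    ir_length: int = 0
    junctions: dict[str, int] = field(default_factory=dict)

    def to_canonical(self, pos: int) -> int:
        return (pos - self.rotation) % self.n

    def region_lengths(self) -> dict[str, int]:
        if not self.has_quadripartite:
            return {}
        return {name: iv[1] - iv[0]
                for name, iv in zip(("LSC", "IRb", "SSC", "IRa"),
                                    (self.lsc, self.irb, self.ssc, self.ira))}


@dataclass
class JunctionContext:
    """Nearest annotated genes around one junction."""

    junction: str
    left_gene: str
    left_strand: str
    left_distance: int
    right_gene: str
    right_strand: str
    right_distance: int
    spanning_gene: str | None = None


def _kmer(seq: str, pos: int, k: int) -> str:
    n = len(seq)
    end = pos + k
    if end <= n:
        return seq[pos:end]
    return seq[pos:] + seq[: end - n]


def _find_inverted_repeats(seq: str, min_len: int) -> list[tuple[int, int, int]]:
    """All maximal exact inverted-repeat matches of length >= min_len.

    A match (i, j, L) means seq[i..i+L) == revcomp(seq[j..j+L)) on the
    circle.  The quantity (i + j + L) mod n is invariant along a match and
    indexes its anti-diagonal, used to deduplicate seeds.
    """
    n = len(seq)
    comp = revcomp(seq)[::-1]  # positionwise complement
    k = min(24, min_len)
    index: dict[str, list[int]] = {}
    for j in range(n):
        index.setdefault(_kmer(seq, j, k), []).append(j)

    covered: dict[int, list[tuple[int, int]]] = {}
    out: dict[tuple[int, int, int], None] = {}
    for i in range(n):
        query = revcomp(_kmer(seq, i, k))
        hits = index.get(query)
        if not hits:
            continue
        for j in hits:
            c = (i + j + k) % n
            runs = covered.get(c)
            if runs and any((i - s) % n < L for s, L in runs):
                continue
            # extend: left of arm1 pairs with right of arm2, and vice versa
            ii, jj, L = i, j, k
            while L < n and seq[(ii - 1) % n] == comp[(jj + L) % n]:
                ii = (ii - 1) % n
                L += 1
            while L < n and seq[(ii + L) % n] == comp[(jj - 1) % n]:
                jj = (jj - 1) % n
                L += 1
            covered.setdefault(c, []).append((ii, L))
            if L >= min_len:
                a1, a2 = sorted(((ii % n), (jj % n)))
                out[(a1, a2, L)] = None
    return list(out)


def detect_inverted_repeat(p: AnnotatedPlastome, min_len: int = 1000
                           ) -> QuadripartitePartition:
    """Partition a circular plastome by its longest exact inverted repeat.

    The longer single-copy region between the repeat arms is labeled LSC,
    the shorter SSC.  Ties between equally long repeat pairs are broken by
    the smaller SSC, then by the smaller arm start.  When no inverted
    repeat of at least ``min_len`` exists the partition is returned with
    ``has_quadripartite=False``.
    """
    if min_len < 50:
        raise ValueError("min_len must be >= 50")
    n = len(p.sequence)
    if n < 2 * min_len:
        raise ValueError(f"sequence ({n} nt) shorter than 2*min_len ({2 * min_len})")

    candidates = _find_inverted_repeats(p.sequence, min_len)
    scored = []
    overlapping = False
    for a1, a2, L in candidates:
        gap1 = (a2 - (a1 + L)) % n
        gap2 = (a1 - (a2 + L)) % n
        if gap1 + gap2 != n - 2 * L:
            overlapping = True
            continue
        scored.append((-L, min(gap1, gap2), a1, a2, L, gap1, gap2))
    if not scored:
        if overlapping:
            raise ValueError("IR arms overlap")
        return QuadripartitePartition(has_quadripartite=False, n=n)

    scored.sort()
    _, _, a1, a2, L, gap1, gap2 = scored[0]
    # gap1 follows arm1, gap2 follows arm2 (circularly)
    if gap1 > gap2 or (gap1 == gap2 and (a1 + L) % n <= (a2 + L) % n):
        lsc_len, ssc_len = gap1, gap2
        rotation = (a1 + L) % n  # LSC starts after arm1; arm2 is IRb
    else:
        lsc_len, ssc_len = gap2, gap1
        rotation = (a2 + L) % n

    lsc = (0, lsc_len)
    irb = (lsc_len, lsc_len + L)
    ssc = (lsc_len + L, lsc_len + L + ssc_len)
    ira = (lsc_len + L + ssc_len, n)
    return QuadripartitePartition(
        has_quadripartite=True, n=n, rotation=rotation,
        lsc=lsc, irb=irb, ssc=ssc, ira=ira, ir_length=L,
        junctions={"JLB": lsc_len, "JSB": lsc_len + L,
                   "JSA": lsc_len + L + ssc_len, "JLA": 0})


def canonical_rotation(p: AnnotatedPlastome, q: QuadripartitePartition
                       ) -> AnnotatedPlastome:
    """The plastome rotated so the LSC starts at position 0."""
    if not q.has_quadripartite:
        raise ValueError("no quadripartite structure detected")
    return rotate_plastome(p, q.rotation)


def partition_regions(p: AnnotatedPlastome, q: QuadripartitePartition
                      ) -> list[tuple[str, int, int, str]]:
    """BED-style rows (chrom, start, end, name) in canonical coordinates."""
    if not q.has_quadripartite:
        raise ValueError("no quadripartite structure detected")
    return [(p.id, s, e, name)
            for name, (s, e) in zip(("LSC", "IRb", "SSC", "IRa"),
                                    (q.lsc, q.irb, q.ssc, q.ira))]


def _span_circular(f: GeneFeature, n: int) -> tuple[int, int]:
    """Feature span (start, length) honoring an origin-wrapping split
    interval pair like [(s, n), (0, e)]."""
    ivs = sorted(f.intervals)
    if len(ivs) > 1 and ivs[0][0] == 0 and ivs[-1][1] == n:
        start = ivs[-1][0]
        length = (n - start) + ivs[0][1]
    else:
        start, length = f.start, f.end - f.start
    return start, length


def _canonical_span(f: GeneFeature, q: QuadripartitePartition) -> tuple[int, int]:
    """Feature span in canonical coordinates; end may exceed n when the
    feature wraps the canonical origin."""
    start, length = _span_circular(f, q.n)
    s = q.to_canonical(start)
    return s, s + length


def junction_report(p: AnnotatedPlastome, q: QuadripartitePartition
                    ) -> list[JunctionContext]:
    """Nearest gene on each side of all four junctions, with nt distances."""
    if not q.has_quadripartite:
        raise ValueError("no quadripartite structure detected")
    if not p.features:
        raise ValueError("no annotation")
    n = q.n
    spans = [(f, *_canonical_span(f, q)) for f in p.features]
    contexts = []
    for name in JUNCTIONS:
        jpos = q.junctions[name] % n
        best_left = best_right = None
        spanning = None
        for f, s, e in spans:
            ld = (jpos - e) % n
            rd = (s - jpos) % n
            if best_left is None or (ld, f.name) < best_left[:2]:
                best_left = (ld, f.name, f)
            if best_right is None or (rd, f.name) < best_right[:2]:
                best_right = (rd, f.name, f)
            # junction strictly inside the feature span (circular containment)
            off = (jpos - s) % n
            if 0 < off < (e - s):
                spanning = f.name
        contexts.append(JunctionContext(
            junction=name,
            left_gene=best_left[2].name, left_strand=best_left[2].strand,
            left_distance=best_left[0],
            right_gene=best_right[2].name, right_strand=best_right[2].strand,
            right_distance=best_right[0],
            spanning_gene=spanning))
    return contexts


def assign_genes_to_regions(p: AnnotatedPlastome, q: QuadripartitePartition
                            ) -> dict[GeneFeature, str]:
    """Region label per feature: midpoint containment, junction-crossing
    features labeled 'spanning'."""
    if not q.has_quadripartite:
        raise ValueError("no quadripartite structure detected")
    n = q.n
    bounds = [q.junctions["JLB"], q.junctions["JSB"], q.junctions["JSA"], n]
    labels = ("LSC", "IRb", "SSC", "IRa")
    out: dict[GeneFeature, str] = {}
    for f in p.features:
        s, e = _canonical_span(f, q)
        length = e - s
        crosses = False
        for jname in JUNCTIONS:
            jpos = q.junctions[jname] % n
            off = (jpos - s) % n
            if 0 < off < length:
                crosses = True
        if crosses:
            out[f] = "spanning"
            continue
        mid = (s + length // 2) % n
        for label, b in zip(labels, bounds):
            if mid < b:
                out[f] = label
                break
    return out
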
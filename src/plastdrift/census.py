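"""Gene presence / pseudogenization / loss census.

Each reference protein-coding gene is searched against a target plastome
with an in-repo seeded aligner (k-mer seeding, banded window extraction,
local re-alignment).  A gene with no acceptable hit (identity >= 0.6
over >= 30% of the reference length by default) is *lost*; a hit that is
truncated (< 90% reference coverage), carries a frameshifting indel (an
internal gap run whose length is not a multiple of 3), or an in-frame
premature stop (before the final 5% of codons) is a *pseudogene*;
otherwise the gene is *present*.  IR-duplicated copies collapse to the
best status (present > pseudogene > lost).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .align import alignment_identity, local_align
from .io import AnnotatedPlastome, extract_feature_sequence, normalize_gene_name, revcomp

__all__ = ["CensusThresholds", "GeneStatus", "GeneStatusMatrix",
           "DegradationProfile", "classify_gene", "census_matrix",
           "degradation_ratios", "cluster_species", "STATUS_GLYPHS"]

STATUS_GLYPHS = {"present": "•", "pseudogene": "Ψ", "lost": "○"}

_STOPS = {"TAA", "TAG", "TGA"}
_STARTS = {"ATG", "GTG"}


@dataclass
class CensusThresholds:
    """Classification cutoffs (the qualitative rule made operational)."""

    hit_identity: float = 0.6
    hit_coverage: float = 0.3
    truncation_coverage: float = 0.9
    stop_grace: float = 0.05  # final fraction of codons where a stop is normal
    kmer: int = 12
    seed_step: int = 4
    diag_tolerance: int = 40
    # mismatch steeper than the spacer-alignment default so chance matches
    # in flanking sequence cannot extend a truncated hit
    match: float = 2.0
    mismatch: float = -3.0


@dataclass
class GeneStatus:
    gene: str
    status: str  # present | pseudogene | lost
    evidence: str  # intact | frameshift | premature_stop | truncated | no_hit
    identity: float = 0.0
    coverage: float = 0.0

    def __post_init__(self) -> None:
        if (self.status == "lost") != (self.evidence == "no_hit"):
            raise ValueError("status 'lost' iff evidence 'no_hit'")
        if self.status == "pseudogene" and self.evidence not in (
                "frameshift", "premature_stop", "truncated"):
            raise ValueError(f"bad pseudogene evidence {self.evidence!r}")


class TargetIndex:
    """k-mer index of a target genome (doubled, so origin-wrapping genes
    appear contiguous)."""

    def __init__(self, target: AnnotatedPlastome, k: int = 12):
        self.n = len(target.sequence)
        self.seq2 = target.sequence + target.sequence
        self.k = k
        idx: dict[str, list[int]] = {}
        for p in range(len(self.seq2) - k + 1):
            idx.setdefault(self.seq2[p:p + k], []).append(p)
        self.index = idx


def _validate_ref(ref_cds: str, symbol: str) -> None:
    if len(ref_cds) % 3 != 0 or len(ref_cds) < 9:
        raise ValueError(f"invalid reference CDS {symbol}: length {len(ref_cds)}")
    if ref_cds[:3] not in _STARTS:
        raise ValueError(f"invalid reference CDS {symbol}: no start codon")
    for i in range(3, len(ref_cds) - 3, 3):
        if ref_cds[i:i + 3] in _STOPS:
            raise ValueError(
                f"invalid reference CDS {symbol}: internal stop at codon {i // 3}")


def _best_window(query: str, index: TargetIndex, th: CensusThresholds
                 ) -> tuple[int, int, int] | None:
    """Best seed cluster -> (win_start, win_end, covered_query_bases)."""
    k, step = index.k, th.seed_step
    hits: list[tuple[int, int]] = []  # (diag, qpos) with tpos = diag + qpos
    for qpos in range(0, len(query) - k + 1, step):
        for tpos in index.index.get(query[qpos:qpos + k], ()):
            hits.append((tpos - qpos, qpos))
    if not hits:
        return None
    hits.sort()
    clusters: list[list[tuple[int, int]]] = []
    for d, q in hits:
        if clusters and d - clusters[-1][-1][0] <= th.diag_tolerance:
            clusters[-1].append((d, q))
        else:
            clusters.append([(d, q)])
    best, best_cov = None, -1
    for cl in clusters:
        qset = {q for _, q in cl}
        cov = len(qset) * step
        if cov > best_cov:
            best, best_cov = cl, cov
    d0 = best[len(best) // 2][0]
    qmin = min(q for _, q in best)
    qmax = max(q for _, q in best) + k
    margin = 50 + len(query) // 10
    ws = max(0, d0 + qmin - qmin - margin)  # extend to putative gene start
    ws = max(0, d0 - margin)
    we = min(len(index.seq2), d0 + len(query) + margin)
    return ws, we, best_cov


def _internal_gap_runs(a: str, b: str) -> list[int]:
    """Lengths of gap runs strictly inside the mutually aligned core."""
    both = [i for i, (x, y) in enumerate(zip(a, b)) if x != "-" and y != "-"]
    if not both:
        return []
    lo, hi = both[0], both[-1]
    runs: list[int] = []
    cur_char, cur_len = None, 0
    for i in range(lo, hi + 1):
        g = "a" if a[i] == "-" else ("b" if b[i] == "-" else None)
        if g is not None and g == cur_char:
            cur_len += 1
        else:
            if cur_len:
                runs.append(cur_len)
            cur_char, cur_len = g, (1 if g else 0)
    if cur_len:
        runs.append(cur_len)
    return runs


def _premature_stop(a: str, b: str, ref_len: int, grace: float) -> bool:
    """Scan the target in the reference frame for an early in-frame stop."""
    both = [i for i, (x, y) in enumerate(zip(a, b)) if x != "-" and y != "-"]
    if not both:
        return False
    lo, hi = both[0], both[-1]
    r0 = sum(1 for c in a[:lo] if c != "-")  # ref offset of aligned core
    t_seg = "".join(y for x, y in zip(a[lo:hi + 1], b[lo:hi + 1]) if y != "-")
    phase = (-r0) % 3
    t_seg = t_seg[phase:]
    ncod_ref = ref_len // 3
    limit = int((1.0 - grace) * (ncod_ref - 1))
    base_codon = (r0 + phase) // 3
    for j in range(0, len(t_seg) - 2, 3):
        if t_seg[j:j + 3] in _STOPS and base_codon + j // 3 < limit:
            return True
    return False


def classify_gene(target: AnnotatedPlastome, ref_cds: str, symbol: str,
                  thresholds: CensusThresholds | None = None,
                  index: TargetIndex | None = None) -> GeneStatus:
    """Classify one reference CDS as present / pseudogene / lost in a target."""
    th = thresholds or CensusThresholds()
    _validate_ref(ref_cds, symbol)
    if index is None:
        index = TargetIndex(target, th.kmer)

    best = None  # (cov, strand, window)
    for strand, query in (("+", ref_cds), ("-", revcomp(ref_cds))):
        win = _best_window(query, index, th)
        if win and (best is None or win[2] > best[0]):
            best = (win[2], strand, win)
    if best is None:
        return GeneStatus(symbol, "lost", "no_hit")

    _, strand, (ws, we, _) = best
    window = index.seq2[ws:we]
    if strand == "-":
        window = revcomp(window)
    aln = local_align(ref_cds, window, match=th.match, mismatch=th.mismatch)
    identity = alignment_identity(aln)
    aligned_ref = sum(1 for x, y in aln.pairs() if x != "-" and y != "-")
    coverage = aligned_ref / len(ref_cds)
    if identity < th.hit_identity or coverage < th.hit_coverage:
        return GeneStatus(symbol, "lost", "no_hit", identity, coverage)

    runs = _internal_gap_runs(aln.a, aln.b)
    if any(r % 3 for r in runs):
        return GeneStatus(symbol, "pseudogene", "frameshift", identity, coverage)
    if _premature_stop(aln.a, aln.b, len(ref_cds), th.stop_grace):
        return GeneStatus(symbol, "pseudogene", "premature_stop", identity, coverage)
    if coverage < th.truncation_coverage:
        return GeneStatus(symbol, "pseudogene", "truncated", identity, coverage)
    return GeneStatus(symbol, "present", "intact", identity, coverage)


@dataclass
class GeneStatusMatrix:
    """Species x reference-PCG status table (the census)."""

    species: list[str]
    genes: list[str]  # display symbols of reference PCGs
    cells: dict = field(default_factory=dict)  # (species, gene) -> GeneStatus
    n_ref_pcg: int = 0
    other_genes: dict = field(default_factory=dict)  # tRNA/rRNA presence

    def status(self, species: str, gene: str) -> str:
        return self.cells[(species, gene)].status

    def counts(self, species: str) -> dict[str, int]:
        out = {"present": 0, "pseudogene": 0, "lost": 0}
        for g in self.genes:
            out[self.cells[(species, g)].status] += 1
        return out

    def to_dataframe(self, glyphs: bool = False) -> pd.DataFrame:
        data = {sp: [self.cells[(sp, g)].status for g in self.genes]
                for sp in self.species}
        df = pd.DataFrame(data, index=self.genes)
        if glyphs:
            df = df.replace(STATUS_GLYPHS)
        return df


def census_matrix(targets: list[AnnotatedPlastome], reference: AnnotatedPlastome,
                  thresholds: CensusThresholds | None = None) -> GeneStatusMatrix:
    """Census of every reference PCG in every target plastome.

    The denominator is the number of distinct (IR-collapsed) valid CDSs in
    the supplied reference record; it is reported, never hard-coded.
    """
    th = thresholds or CensusThresholds()
    if not targets:
        raise ValueError("empty target list")
    ref_pcg: dict[str, str] = {}
    display: dict[str, str] = {}
    for f in reference.features_of_kind("CDS"):
        key = normalize_gene_name(f.name)
        if key in ref_pcg:
            continue  # IR duplicate collapses to one census entry
        try:
            cds = extract_feature_sequence(reference, f)
            _validate_ref(cds, f.name)
        except ValueError as exc:
            warnings.warn(f"skipping reference gene {f.name}: {exc}")
            continue
        ref_pcg[key] = cds
        display[key] = f.name
    if not ref_pcg:
        raise ValueError("reference has no usable CDS features")

    genes = [display[k] for k in ref_pcg]
    matrix = GeneStatusMatrix(species=[t.id for t in targets], genes=genes,
                              n_ref_pcg=len(ref_pcg))
    for t in targets:
        index = TargetIndex(t, th.kmer)
        for key, cds in ref_pcg.items():
            st = classify_gene(t, cds, display[key], th, index)
            matrix.cells[(t.id, display[key])] = st
        # tRNA/rRNA tracked by annotation only, excluded from the ratios
        annotated = {normalize_gene_name(f.name): f.kind
                     for f in t.features_of_kind("tRNA", "rRNA", "pseudo")}
        for f in reference.features_of_kind("tRNA", "rRNA"):
            key = normalize_gene_name(f.name)
            kind = annotated.get(key)
            state = ("present" if kind in ("tRNA", "rRNA")
                     else "pseudogene" if kind == "pseudo" else "lost")
            matrix.other_genes[(t.id, f.name)] = state
    return matrix


@dataclass
class DegradationProfile:
    species: str
    n_lost: int
    n_pseudo: int
    n_ref_pcg: int

    @property
    def ratio_lost(self) -> float:
        return self.n_lost / self.n_ref_pcg

    @property
    def ratio_pseudo(self) -> float:
        return self.n_pseudo / self.n_ref_pcg

    @property
    def vector(self) -> tuple[float, float]:
        return (self.ratio_lost, self.ratio_pseudo)


def degradation_ratios(m: GeneStatusMatrix) -> list[DegradationProfile]:
    """Lost-gene and pseudogene ratios per species (denominator = number of
    reference PCGs used in the census)."""
    out = []
    for sp in m.species:
        c = m.counts(sp)
        if sum(c.values()) != len(m.genes):
            raise ValueError(f"incomplete census for {sp}")
        out.append(DegradationProfile(sp, c["lost"], c["pseudogene"], m.n_ref_pcg))
    return out


def cluster_species(profiles) -> tuple[str, np.ndarray]:
    """UPGMA (average linkage, Euclidean) over per-species ratio vectors.

    Accepts a list of DegradationProfile or a dict name -> vector.
    Returns (Newick string with ultrametric branch lengths, scipy linkage
    matrix).  Deterministic leaf order.
    """
    if isinstance(profiles, dict):
        labels = list(profiles)
        vectors = [list(map(float, profiles[k])) for k in labels]
    else:
        labels = [p.species for p in profiles]
        vectors = [list(p.vector) for p in profiles]
    if len(labels) < 2:
        raise ValueError("need at least two species to cluster")
    lens = {len(v) for v in vectors}
    if len(lens) != 1:
        raise ValueError("profiles of unequal length")
    X = np.asarray(vectors, dtype=float)
    Z = hierarchy.linkage(X, method="average", metric="euclidean")
    tree = hierarchy.to_tree(Z)

    def fmt(node, parent_height: float) -> str:
        height = 0.0 if node.is_leaf() else node.dist
        branch = (parent_height - height) / 2.0
        if node.is_leaf():
            return f"{labels[node.id]}:{branch:.6g}"
        left = fmt(node.left, node.dist)
        right = fmt(node.right, node.dist)
        return f"({left},{right}):{branch:.6g}"

    newick = fmt(tree, tree.dist).rsplit(":", 1)[0] + ";"
    return newick, Z
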
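"""Shared intergenic spacers and K2p divergence ranking.

Spacers are enumerated between consecutive annotated features in each
plastome (including the origin-wrapping spacer on circular records); a
spacer is *shared* when the same unordered flanking-gene pair bounds a
spacer in every input plastome.  Each shared spacer is aligned pairwise
between species (Needleman-Wunsch, affine gaps, match +2 / mismatch -1 /
open 10 / extend 2) and its Kimura 2-parameter distance

    d = -1/2 ln[(1 - 2P - Q) sqrt(1 - 2Q)]

computed from the transition (P) and transversion (Q) proportions over
gap-free, unambiguous columns.  Regions are ranked by mean pairwise d.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .align import PairwiseAlignment, global_align
from .io import AnnotatedPlastome, normalize_gene_name, revcomp

__all__ = ["IGSRegion", "K2pResult", "extract_shared_igs", "k2p_distance",
           "rank_igs"]

_PURINES = {"A", "G"}
_TRANSITION_PAIRS = {frozenset(("A", "G")), frozenset(("C", "T"))}


@dataclass
class IGSRegion:
    """One intergenic spacer shared across plastomes."""

    name: str  # "geneA-geneB" in the first plastome's flank order
    flanks: tuple[str, str]
    per_species: dict = field(default_factory=dict)  # sp -> (start, end, seq)


@dataclass
class K2pResult:
    P: float  # transition proportion
    Q: float  # transversion proportion
    d: float  # substitutions per site
    sites: int
    region: str | None = None
    pair: tuple[str, str] | None = None


def _spacers(p: AnnotatedPlastome) -> list[tuple[str, str, int, int]]:
    """(upstream, downstream, start, end) for spacers of positive length,
    in coordinate order; includes the wrap-around spacer when circular."""
    spans = sorted((f.start, f.end, f.name) for f in p.features)
    if len(spans) < 2:
        raise ValueError(f"plastome {p.id} has fewer than two features")
    out = []
    prev_end, prev_name = None, None
    for s, e, name in spans:
        if prev_end is not None and s > prev_end:
            out.append((prev_name, name, prev_end, s))
        if prev_end is None or e > prev_end:
            prev_end, prev_name = e, name
    if p.circular:
        first_s, _, first_name = spans[0]
        n = len(p.sequence)
        gap = (n - prev_end) + first_s  # around the origin
        if gap > 0 and prev_name != first_name:
            out.append((prev_name, first_name, prev_end, n + first_s))
    return out


def _spacer_seq(p: AnnotatedPlastome, s: int, e: int) -> str:
    n = len(p.sequence)
    if e <= n:
        return p.sequence[s:e]
    return p.sequence[s:] + p.sequence[: e - n]


def extract_shared_igs(plastomes: list[AnnotatedPlastome]) -> list[IGSRegion]:
    """Spacers whose unordered flanking-gene pair bounds a spacer in every
    plastome; sequences are orientation-normalized to the first plastome's
    flank order (reversed occurrences are reverse-complemented)."""
    if not plastomes:
        raise ValueError("no plastomes given")
    per_plastome: list[dict] = []
    for p in plastomes:
        table: dict[frozenset, tuple[str, str, int, int]] = {}
        for up, down, s, e in _spacers(p):
            key = frozenset((normalize_gene_name(up), normalize_gene_name(down)))
            if len(key) == 2 and key not in table and e - s >= 1:
                table[key] = (up, down, s, e)
        per_plastome.append(table)
    shared = set(per_plastome[0])
    for table in per_plastome[1:]:
        shared &= set(table)

    regions = []
    first = per_plastome[0]
    order = sorted(shared, key=lambda k: first[k][2])
    for key in order:
        up0, down0, _, _ = first[key]
        ref_order = (normalize_gene_name(up0), normalize_gene_name(down0))
        region = IGSRegion(name=f"{up0}-{down0}",
                           flanks=(up0, down0))
        for p, table in zip(plastomes, per_plastome):
            up, down, s, e = table[key]
            seq = _spacer_seq(p, s, e)
            if (normalize_gene_name(up), normalize_gene_name(down)) != ref_order:
                seq = revcomp(seq)
            region.per_species[p.id] = (s, e, seq)
        regions.append(region)
    return regions


def k2p_distance(aln: PairwiseAlignment | tuple[str, str]) -> K2pResult:
    """Kimura 2-parameter distance from a pairwise alignment.

    Columns containing a gap or an ambiguous base are excluded from the
    site count.  Raises on saturation ((1-2P-Q) <= 0 or (1-2Q) <= 0) and
    on zero usable sites.
    """
    a, b = (aln.a, aln.b) if isinstance(aln, PairwiseAlignment) else aln
    sites = ts = tv = 0
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        sites += 1
        if x == y:
            continue
        if frozenset((x, y)) in _TRANSITION_PAIRS:
            ts += 1
        else:
            tv += 1
    if sites == 0:
        raise ValueError("no usable sites (all columns gapped or ambiguous)")
    P, Q = ts / sites, tv / sites
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise ValueError("distance undefined (saturation)")
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return K2pResult(P=P, Q=Q, d=d, sites=sites)


def rank_igs(regions: list[IGSRegion], align_params: dict | None = None
             ) -> tuple[pd.DataFrame, list[K2pResult]]:
    """Min/mean/max pairwise K2p distance per shared spacer.

    Saturated pairs are skipped with a warning; a region with no
    computable pair is dropped.  The table is sorted by mean distance,
    descending, ties by region name; percent columns mirror distmat-style
    x100 output (presentation only).
    """
    params = align_params or {}
    rows = []
    results: list[K2pResult] = []
    for region in regions:
        species = list(region.per_species)
        if len(species) < 2:
            raise ValueError("ranking needs at least two species per region")
        dists = []
        for sa, sb in combinations(species, 2):
            seq_a = region.per_species[sa][2]
            seq_b = region.per_species[sb][2]
            if not seq_a or not seq_b:
                continue
            if seq_a == seq_b:
                res = K2pResult(P=0.0, Q=0.0, d=0.0, sites=len(seq_a))
            else:
                aln = global_align(seq_a, seq_b, **params)
                try:
                    res = k2p_distance(aln)
                except ValueError as exc:
                    warnings.warn(f"{region.name} {sa}/{sb}: {exc}")
                    continue
            res.region = region.name
            res.pair = (sa, sb)
            dists.append(res.d)
            results.append(res)
        if not dists:
            warnings.warn(f"region {region.name} dropped: no computable pair")
            continue
        rows.append({
            "region": region.name,
            "pairs": len(dists),
            "d_min": min(dists),
            "d_mean": sum(dists) / len(dists),
            "d_max": max(dists),
        })
    df = pd.DataFrame(rows, columns=["region", "pairs", "d_min", "d_mean", "d_max"])
    if not df.empty:
        for col in ("d_min", "d_mean", "d_max"):
            df[col + "_pct"] = df[col] * 100.0
        df = df.sort_values(["d_mean", "region"], ascending=[False, True],
                            kind="mergesort").reset_index(drop=True)
    return df, results
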
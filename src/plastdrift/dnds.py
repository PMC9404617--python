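"""Pairwise dN/dS screening of shared protein-coding genes.

Nei-Gojobori (1986) counting: synonymous site fractions per codon from
the three possible changes at each position (changes to stop codons count
as nonsynonymous), observed differences averaged over all minimal
substitution pathways between codon pairs (pathways through stop codons
excluded), and Jukes-Cantor correction d = -3/4 ln(1 - 4p/3).  The ratio
omega = dN/dS flags candidate genes under relaxed or positive selection
when its per-gene median exceeds 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations, permutations
from math import log

import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .align import progressive_msa

__all__ = ["DnDsEstimate", "codon_align", "ng86_dn_ds", "omega_table",
           "collect_present_cds"]

_TABLE = unambiguous_dna_by_id[1]
_CODON_AA = dict(_TABLE.forward_table)
_STOPS = set(_TABLE.stop_codons)
_BASES = "ACGT"


def _aa(codon: str) -> str:
    return "*" if codon in _STOPS else _CODON_AA[codon]


def _syn_changes(codon: str) -> int:
    """Number of the 9 one-step neighbours that are synonymous sense codons."""
    aa = _aa(codon)
    count = 0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if mut not in _STOPS and _aa(mut) == aa:
                count += 1
    return count


_SYN_CHANGES = {c: _syn_changes(c) for c in _CODON_AA}


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) differences averaged over minimal pathways c1 -> c2.

    Pathways passing through a stop codon are excluded; when every pathway
    is blocked, all pathways are used (steps to/from stops are
    nonsynonymous by the amino-acid comparison).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS and nxt != c2:
                blocked = True
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((blocked, sd, nd))
    usable = [(s, n) for b, s, n in paths if not b]
    if not usable:
        usable = [(s, n) for _, s, n in paths]
    sd = sum(s for s, _ in usable) / len(usable)
    nd = sum(n for _, n in usable) / len(usable)
    return sd, nd


@dataclass
class DnDsEstimate:
    gene: str | None
    pair: tuple[str, str] | None
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    dS: float
    dN: float
    omega: float | None  # None when dS == 0
    codons: int


def _jc(p: float, strict: bool) -> float:
    if p >= 0.75:
        if strict:
            raise ValueError("distance undefined (saturation)")
        return float("nan")
    return -0.75 * log(1.0 - 4.0 * p / 3.0) if p > 0 else 0.0


def ng86_dn_ds(a: str, b: str, gene: str | None = None,
               pair: tuple[str, str] | None = None,
               strict_saturation: bool = False) -> DnDsEstimate:
    """NG86 estimate from two equal-length, codon-aligned sequences.

    Codons containing a gap or ambiguous base in either sequence are
    skipped; site counts are averaged over the two sequences.  A
    proportion pS or pN >= 0.75 leaves the Jukes-Cantor correction
    undefined: the corresponding rate is NaN (and omega None), or a
    "saturation" ValueError when ``strict_saturation`` is set (a
    one-codon synonymous change legitimately has pS == 1, so the lenient
    behaviour is the default).
    """
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    if len(a) % 3:
        raise ValueError("length is not a multiple of 3")
    syn_a = syn_b = 0
    Sd = Nd = 0.0
    ncod = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if any(ch not in _BASES for ch in ca + cb):
            continue
        if ca in _STOPS or cb in _STOPS:
            continue
        ncod += 1
        syn_a += _SYN_CHANGES[ca]
        syn_b += _SYN_CHANGES[cb]
        sd, nd = _pathway_counts(ca, cb)
        Sd += sd
        Nd += nd
    if ncod == 0:
        raise ValueError("zero comparable codons")
    S = (syn_a + syn_b) / 6.0  # each codon contributes syn_changes/3 sites
    N = 3.0 * ncod - S
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS, dN = _jc(pS, strict_saturation), _jc(pN, strict_saturation)
    omega = (dN / dS) if (dS == dS and dN == dN and dS > 0) else None
    return DnDsEstimate(gene=gene, pair=pair, S_sites=S, N_sites=N,
                        Sd=Sd, Nd=Nd, dS=dS, dN=dN, omega=omega, codons=ncod)


# ---------------------------------------------------------------------------
# Codon-aware alignment
# ---------------------------------------------------------------------------


def _prepare_cds(name: str, cds: str) -> tuple[str, str]:
    """Trim to codon length, drop a terminal stop, translate or raise."""
    cds = cds[: len(cds) - len(cds) % 3]
    if len(cds) < 3:
        raise ValueError(f"{name}: CDS shorter than one codon")
    if cds[-3:] in _STOPS:
        cds = cds[:-3]
    prot = []
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3]
        if any(ch not in _BASES for ch in codon):
            prot.append("X")
            continue
        aa = _aa(codon)
        if aa == "*":
            raise ValueError(f"internal stop in {name} at codon {i // 3}")
        prot.append(aa)
    return cds, "".join(prot)


def codon_align(gene_seqs: dict[str, str]) -> dict[str, str]:
    """Codon-aware MSA: align translations, back-thread nucleotides.

    Every gap is a multiple of 3 on a codon boundary; removing gaps
    reproduces each (stop-trimmed) input CDS exactly.
    """
    if not gene_seqs:
        raise ValueError("no sequences")
    trimmed: dict[str, str] = {}
    prots: dict[str, str] = {}
    for name, cds in gene_seqs.items():
        trimmed[name], prots[name] = _prepare_cds(name, cds)
    if len(prots) == 1:
        return dict(trimmed)
    pal = progressive_msa(prots, kind="protein", gap_open=10.0, gap_extend=0.5)
    out: dict[str, str] = {}
    for name, row in pal.items():
        cds = trimmed[name]
        chunks, i = [], 0
        for ch in row:
            if ch == "-":
                chunks.append("---")
            else:
                chunks.append(cds[i:i + 3])
                i += 3
        assert i == len(cds)
        out[name] = "".join(chunks)
    return out


def collect_present_cds(plastomes: dict[str, "object"], census=None,
                        genes: list[str] | None = None
                        ) -> dict[str, dict[str, str]]:
    """gene -> species -> CDS for genes annotated (and, when a census is
    given, classified present) in each species."""
    from .io import extract_feature_sequence, normalize_gene_name

    table: dict[str, dict[str, str]] = {}
    for sp, p in plastomes.items():
        for f in p.features_of_kind("CDS"):
            key = normalize_gene_name(f.name)
            if genes is not None and key not in {normalize_gene_name(g) for g in genes}:
                continue
            if census is not None:
                display = {normalize_gene_name(g): g for g in census.genes}
                if key not in display:
                    continue
                if census.cells.get((sp, display[key])) is None:
                    continue
                if census.cells[(sp, display[key])].status != "present":
                    continue
            table.setdefault(f.name, {})
            if sp not in table[f.name]:
                table[f.name][sp] = extract_feature_sequence(p, f)
    return table


def omega_table(gene_seqs: dict[str, dict[str, str]]
                ) -> tuple[pd.DataFrame, dict[str, list[DnDsEstimate]]]:
    """All pairwise NG86 estimates per gene plus a per-gene summary.

    Genes shared by fewer than two species are skipped with a warning;
    the positive-selection flag marks genes whose median pairwise omega
    exceeds 1.
    """
    rows = []
    estimates: dict[str, list[DnDsEstimate]] = {}
    for gene in sorted(gene_seqs):
        seqs = gene_seqs[gene]
        if len(seqs) < 2:
            warnings.warn(f"gene {gene} present in <2 species; skipped")
            continue
        try:
            msa = codon_align(seqs)
        except ValueError as exc:
            warnings.warn(f"gene {gene}: {exc}; skipped")
            continue
        ests = []
        for sa, sb in combinations(msa, 2):
            try:
                ests.append(ng86_dn_ds(msa[sa], msa[sb], gene=gene, pair=(sa, sb),
                                       strict_saturation=True))
            except ValueError as exc:
                warnings.warn(f"gene {gene} {sa}/{sb}: {exc}")
        if not ests:
            continue
        estimates[gene] = ests
        omegas = sorted(e.omega for e in ests if e.omega is not None)
        if omegas:
            mid = len(omegas) // 2
            median = (omegas[mid] if len(omegas) % 2
                      else 0.5 * (omegas[mid - 1] + omegas[mid]))
            o_min, o_max = omegas[0], omegas[-1]
        else:
            median = o_min = o_max = float("nan")
        rows.append({
            "gene": gene, "pairs": len(ests),
            "dN_mean": sum(e.dN for e in ests) / len(ests),
            "dS_mean": sum(e.dS for e in ests) / len(ests),
            "omega_median": median, "omega_min": o_min, "omega_max": o_max,
            "positive_selection_candidate": bool(median == median and median > 1.0),
        })
    df = pd.DataFrame(rows, columns=["gene", "pairs", "dN_mean", "dS_mean",
                                     "omega_median", "omega_min", "omega_max",
                                     "positive_selection_candidate"])
    return df, estimates
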
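"""Synthetic plastomes with planted, recoverable truth.

The generator emulates the degradation syndrome of holoparasite plastid
genomes: a circular quadripartite reference (LSC-IRb-SSC-IRa, IRa the
exact reverse complement of IRb) carrying valid protein-coding ORFs, then
per-species gene deletions, pseudogenization (frameshift / premature stop
/ truncation), IR boundary migration at the IRb|SSC junction, optional
SSC inversion, and intergenic point mutations with a controlled
transition/transversion ratio kappa.  Everything is driven by a single
seed; each species draws from an independent substream so adding a
species never perturbs the others.

Default toy scale (~13-15 kb, 30 protein-coding genes) keeps the whole
pipeline fast; pass ``realistic_config()`` for a 120 kb / 80-gene build.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np

from .io import AnnotatedPlastome, GeneFeature, revcomp

__all__ = ["SpeciesSpec", "SimulationConfig", "ReferenceLayout", "SpeciesTruth",
           "TruthManifest", "make_reference", "degrade", "plant_marker",
           "simulate_bundle", "default_scenario", "realistic_config"]

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
_SENSE = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES
               if a + b + c not in _STOPS)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

_MIN_SPACER = 60


@dataclass
class SpeciesSpec:
    """Degradation recipe for one synthetic species."""

    name: str
    deleted_genes: tuple[str, ...] = ()
    deletion_rate: float = 0.0
    pseudo_genes: dict = field(default_factory=dict)  # gene -> mechanism
    pseudo_rate: float = 0.0
    # (frameshift, premature_stop, truncation) sampling weights
    mechanism_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    ir_delta: int = 0
    invert_ssc: bool = False
    igs_sub_rate: float = 0.0
    kappa: float = 2.0
    hypervariable_igs: tuple[str, float] | None = None

    def __post_init__(self) -> None:
        for r in (self.deletion_rate, self.pseudo_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0,1]")
        if not 0.0 <= self.igs_sub_rate <= 1.0:
            raise ValueError("igs_sub_rate must lie in [0,1]")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_pcg: int = 30
    n_trna: int = 6
    lsc_len: int = 8500
    ssc_len: int = 2200
    ir_len: int = 1400
    species: tuple[SpeciesSpec, ...] = ()
    # (k_snps, m_indels, flank_len) planted into a shared spacer, or None
    marker: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.n_pcg < 1:
            raise ValueError("need at least one protein-coding gene")
        for sp in self.species:
            if abs(sp.ir_delta) >= min(self.lsc_len, self.ssc_len):
                raise ValueError("ir_delta cannot exceed adjacent single-copy length")


@dataclass
class ReferenceLayout:
    """Where everything was planted in the reference."""

    lsc_len: int
    ir_len: int
    ssc_len: int
    genes: list = field(default_factory=list)  # (name, kind, region, start, end, strand)
    pcg_names: tuple[str, ...] = ()
    # flanks of the guaranteed-long LSC spacer reserved for marker planting
    marker_flanks: tuple[str, str] = ("", "")

    @property
    def total(self) -> int:
        return self.lsc_len + 2 * self.ir_len + self.ssc_len

    def boundaries(self) -> dict[str, int]:
        return {"JLB": self.lsc_len, "JSB": self.lsc_len + self.ir_len,
                "JSA": self.lsc_len + self.ir_len + self.ssc_len,
                "length": self.total}


@dataclass
class SpeciesTruth:
    """Planted truth for one degraded species."""

    species: str
    lost: list[str] = field(default_factory=list)
    pseudo: dict = field(default_factory=dict)  # gene -> mechanism
    boundaries: dict = field(default_factory=dict)  # JLB/JSB/JSA/length
    ssc_inverted: bool = False
    igs_substitutions: dict = field(default_factory=dict)  # igs -> [ts, tv]
    diagnostic_sites: list = field(default_factory=list)


@dataclass
class TruthManifest:
    layout: ReferenceLayout
    species: dict = field(default_factory=dict)  # name -> SpeciesTruth

    def to_dict(self) -> dict:
        return {"layout": asdict(self.layout),
                "species": {k: asdict(v) for k, v in self.species.items()}}


def _species_rng(seed: int, name: str) -> np.random.Generator:
    sub = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng([seed & 0x7FFFFFFF, sub])


def _random_orf(rng: np.random.Generator, length: int) -> str:
    """A valid ORF: ATG + sense codons + TAA, total `length` nt."""
    assert length % 3 == 0 and length >= 9
    n_internal = length // 3 - 2
    codons = rng.choice(len(_SENSE), size=n_internal)
    return "ATG" + "".join(_SENSE[i] for i in codons) + "TAA"


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _pack_region(rng: np.random.Generator, target_len: int,
                 elements: list[tuple[str, str, str]],
                 boost: tuple[int, int] | None = None) -> tuple[str, list]:
    """Lay out (name, kind, seq) elements with random spacers to exactly
    target_len nt.  ``boost=(i, extra)`` widens spacer i by `extra` nt (a
    guaranteed long spacer for marker planting).  Returns (sequence, local
    features)."""
    total_genes = sum(len(seq) for _, _, seq in elements)
    k = len(elements)
    boosts = np.zeros(k + 1, dtype=int)
    if boost is not None:
        boosts[min(boost[0], k)] = boost[1]
    min_total = total_genes + (k + 1) * _MIN_SPACER + int(boosts.sum())
    if min_total > target_len:
        raise ValueError(
            f"infeasible packing: {total_genes} nt of genes + minimum spacers "
            f"({min_total}) exceed region target {target_len}")
    slack = target_len - min_total
    extra = rng.multinomial(slack, np.full(k + 1, 1.0 / (k + 1))) + boosts
    parts: list[str] = []
    feats: list = []
    pos = 0
    for idx, (name, kind, seq) in enumerate(elements):
        spacer = _random_dna(rng, _MIN_SPACER + int(extra[idx]))
        parts.append(spacer)
        pos += len(spacer)
        strand = "+" if rng.random() < 0.5 else "-"
        placed = seq if strand == "+" else revcomp(seq)
        parts.append(placed)
        feats.append([name, kind, [[pos, pos + len(seq)]], strand])
        pos += len(seq)
    parts.append(_random_dna(rng, _MIN_SPACER + int(extra[k])))
    region = "".join(parts)
    assert len(region) == target_len
    return region, feats


def make_reference(cfg: SimulationConfig) -> tuple[AnnotatedPlastome, ReferenceLayout]:
    """Build the quadripartite reference genome for a configuration.

    Same config (and seed) always yields a byte-identical genome.
    """
    rng = np.random.default_rng(cfg.seed & 0x7FFFFFFF)
    n_lsc = max(1, int(round(cfg.n_pcg * 0.8)))
    n_ssc = cfg.n_pcg - n_lsc
    pcg_names = tuple(f"g{i + 1}" for i in range(cfg.n_pcg))
    lengths = 3 * rng.integers(50, 101, size=cfg.n_pcg)  # 150-300 nt ORFs

    lsc_elements: list[tuple[str, str, str]] = []
    ssc_elements: list[tuple[str, str, str]] = []
    for i, name in enumerate(pcg_names):
        orf = _random_orf(rng, int(lengths[i]))
        (lsc_elements if i < n_lsc else ssc_elements).append((name, "CDS", orf))
    n_trna_ir = min(2, cfg.n_trna)
    for t in range(cfg.n_trna - n_trna_ir):
        lsc_elements.insert(2 * t + 1 if 2 * t + 1 <= len(lsc_elements) else len(lsc_elements),
                            (f"trn{chr(65 + t)}", "tRNA", _random_dna(rng, 72)))

    ir_elements: list[tuple[str, str, str]] = [
        ("rrnA", "rRNA", _random_dna(rng, 280)),
        ("rrnB", "rRNA", _random_dna(rng, 160)),
    ]
    for t in range(n_trna_ir):
        ir_elements.append((f"trn{chr(88 + t)}", "tRNA", _random_dna(rng, 72)))

    boost_idx = max(1, len(lsc_elements) // 2)
    lsc_seq, lsc_feats = _pack_region(rng, cfg.lsc_len, lsc_elements,
                                      boost=(boost_idx, 300))
    marker_flanks = (lsc_elements[boost_idx - 1][0], lsc_elements[boost_idx][0])
    irb_seq, irb_feats = _pack_region(rng, cfg.ir_len, ir_elements)
    ssc_seq, ssc_feats = _pack_region(rng, cfg.ssc_len, ssc_elements)

    # sentinel bases stop seed extension exactly at the planted junctions:
    # last(LSC) must not pair with comp(first(LSC)), first(SSC) not with
    # comp(last(SSC)) -- all four sit inside spacers
    lsc_seq = "A" + lsc_seq[1:-1] + "A"
    ssc_seq = "A" + ssc_seq[1:-1] + "A"

    ira_seq = revcomp(irb_seq)
    jlb = cfg.lsc_len
    jsb = jlb + cfg.ir_len
    jsa = jsb + cfg.ssc_len
    sequence = lsc_seq + irb_seq + ssc_seq + ira_seq

    feats: list = []
    layout_genes: list = []
    for name, kind, ivs, strand in lsc_feats:
        s, e = ivs[0]
        feats.append([name, kind, [[s, e]], strand])
        layout_genes.append((name, kind, "LSC", s, e, strand))
    for name, kind, ivs, strand in irb_feats:
        s, e = ivs[0]
        feats.append([name, kind, [[jlb + s, jlb + e]], strand])
        layout_genes.append((name, kind, "IRb", jlb + s, jlb + e, strand))
        # mirrored IRa copy
        ms, me = jsa + (cfg.ir_len - e), jsa + (cfg.ir_len - s)
        mstrand = "-" if strand == "+" else "+"
        feats.append([name, kind, [[ms, me]], mstrand])
        layout_genes.append((name, kind, "IRa", ms, me, mstrand))
    for name, kind, ivs, strand in ssc_feats:
        s, e = ivs[0]
        feats.append([name, kind, [[jsb + s, jsb + e]], strand])
        layout_genes.append((name, kind, "SSC", jsb + s, jsb + e, strand))

    plastome = AnnotatedPlastome(
        id="reference", sequence=sequence,
        features=[GeneFeature(n, k, tuple(tuple(iv) for iv in ivs), st)
                  for n, k, ivs, st in feats])
    layout = ReferenceLayout(lsc_len=cfg.lsc_len, ir_len=cfg.ir_len,
                             ssc_len=cfg.ssc_len, genes=layout_genes,
                             pcg_names=pcg_names, marker_flanks=marker_flanks)
    return plastome, layout


# ---------------------------------------------------------------------------
# Degradation
# ---------------------------------------------------------------------------


class _Editable:
    """Mutable genome view supporting coordinate-preserving splices."""

    def __init__(self, p: AnnotatedPlastome, boundaries: list[int]):
        self.seq = p.sequence
        self.feats = [[f.name, f.kind, [list(iv) for iv in f.intervals], f.strand]
                      for f in p.features]
        self.bounds = list(boundaries)  # [JLB, JSB, JSA, length]

    def find(self, name: str) -> int:
        for idx, f in enumerate(self.feats):
            if f[0] == name:
                return idx
        raise KeyError(name)

    def splice(self, pos: int, dellen: int, ins: str, within: int | None = None) -> None:
        delta = len(ins) - dellen
        end = pos + dellen
        self.seq = self.seq[:pos] + ins + self.seq[end:]
        for idx, (_, _, ivs, _) in enumerate(self.feats):
            for iv in ivs:
                s, e = iv
                if e <= pos:
                    continue
                if s >= end:
                    iv[0], iv[1] = s + delta, e + delta
                elif idx == within and s <= pos and end <= e:
                    iv[1] = e + delta
                else:
                    raise ValueError(
                        f"splice [{pos},{end}) overlaps feature {self.feats[idx][0]}")
        self.bounds = [b if b <= pos else b + delta for b in self.bounds]

    def replace_bases(self, pos: int, new: str) -> None:
        self.seq = self.seq[:pos] + new + self.seq[pos + len(new):]

    def feature_free(self, s: int, e: int) -> bool:
        return all(iv[1] <= s or iv[0] >= e
                   for _, _, ivs, _ in self.feats for iv in ivs)

    def to_plastome(self, species_id: str) -> AnnotatedPlastome:
        return AnnotatedPlastome(
            id=species_id, sequence=self.seq,
            features=[GeneFeature(n, k, tuple(tuple(iv) for iv in ivs), st)
                      for n, k, ivs, st in self.feats])


def _single_copy_spacers(ed: _Editable) -> list[tuple[str, int, int]]:
    """(name, start, end) of spacers in LSC and SSC, between consecutive
    features in coordinate order."""
    jlb, jsb, jsa, n = ed.bounds
    spans = sorted((min(iv[0] for iv in ivs), max(iv[1] for iv in ivs), name)
                   for name, _, ivs, _ in ed.feats)
    out = []
    prev_end, prev_name = 0, "origin"
    for s, e, name in spans:
        if s > prev_end:
            out.append((f"{prev_name}-{name}", prev_end, s))
        prev_end, prev_name = max(prev_end, e), name
    if prev_end < n:
        out.append((f"{prev_name}-end", prev_end, n))
    single = []
    for name, s, e in out:
        if e <= jlb or (jsb <= s and e <= jsa):
            single.append((name, s, e))
    return single


def _fix_boundary_sentinels(ed: _Editable) -> None:
    """Keep seed extension from running past the planted junctions."""
    jlb, jsb, jsa, n = ed.bounds

    def fix(pos_a: int, pos_b: int) -> None:
        # require seq[pos_a] != comp(seq[pos_b]); adjust pos_a if violated
        comp_b = revcomp(ed.seq[pos_b])
        if ed.seq[pos_a] == comp_b:
            if not ed.feature_free(pos_a, pos_a + 1):
                raise ValueError("cannot place boundary sentinel inside a feature")
            ed.replace_bases(pos_a, "A" if comp_b != "A" else "C")

    fix(jlb - 1, 0)        # last LSC base vs first LSC base
    fix(jsb, jsa - 1)      # first SSC base vs last SSC base


def degrade(ref: AnnotatedPlastome, layout: ReferenceLayout, spec: SpeciesSpec,
            seed: int) -> tuple[AnnotatedPlastome, SpeciesTruth]:
    """Apply one species' degradation recipe to the reference.

    Order of operations: gene deletions, pseudogenization, IR boundary
    shift (at JSB), optional SSC inversion, intergenic point mutations.
    With all rates zero and ir_delta 0 the output differs from the
    reference only in its id.
    """
    rng = _species_rng(seed, spec.name)
    b = layout.boundaries()
    ed = _Editable(ref, [b["JLB"], b["JSB"], b["JSA"], b["length"]])
    truth = SpeciesTruth(species=spec.name)

    pcg_set = list(layout.pcg_names)
    deleted = [g for g in spec.deleted_genes]
    if spec.deletion_rate > 0:
        draws = rng.random(len(pcg_set))
        # the reserved marker spacer's flanks are never deleted at random,
        # so the spacer's adjacency stays shared across species
        deleted += [g for g, u in zip(pcg_set, draws)
                    if u < spec.deletion_rate and g not in deleted
                    and g not in layout.marker_flanks]
    pseudo: dict[str, str] = dict(spec.pseudo_genes)
    if spec.pseudo_rate > 0:
        remaining = [g for g in pcg_set if g not in deleted and g not in pseudo]
        draws = rng.random(len(remaining))
        mech = rng.choice(3, size=len(remaining),
                          p=np.asarray(spec.mechanism_mix) / sum(spec.mechanism_mix))
        names = ("frameshift", "premature_stop", "truncation")
        for g, u, m in zip(remaining, draws, mech):
            if u < spec.pseudo_rate:
                pseudo[g] = names[int(m)]
    overlap = set(deleted) & set(pseudo)
    if overlap:
        raise ValueError(f"genes both deleted and pseudogenized: {sorted(overlap)}")

    # deletions, right-to-left so coordinates stay valid
    del_feats = sorted((ed.feats[ed.find(g)] for g in deleted),
                       key=lambda f: -f[2][0][0])
    for f in del_feats:
        s, e = f[2][0]
        ed.feats.remove(f)
        ed.splice(s, e - s, "")
    truth.lost = sorted(deleted, key=pcg_set.index)

    # pseudogenization
    for gene in sorted(pseudo, key=pcg_set.index, reverse=True):
        mech = pseudo[gene]
        idx = ed.find(gene)
        _, _, ivs, strand = ed.feats[idx]
        s, e = ivs[0]
        ncod = (e - s) // 3
        if mech == "frameshift":
            # keep a 3-codon margin: an indel in the last couple of codons
            # would not meaningfully disrupt the product
            pos = s + 9 + int(rng.integers(0, e - s - 18))
            if rng.random() < 0.5:
                ins_len = 1 + int(rng.integers(0, 2))
                ed.splice(pos, 0, _random_dna(rng, ins_len), within=idx)
            else:
                ed.splice(pos, 1 + int(rng.integers(0, 2)), "", within=idx)
        elif mech == "premature_stop":
            c = 2 + int(rng.integers(0, max(1, int(0.7 * ncod) - 2)))
            if strand == "+":
                ed.replace_bases(s + 3 * c, "TAA")
            else:
                ed.replace_bases(e - 3 * c - 3, "TTA")  # revcomp(TAA)
        elif mech == "truncation":
            m = max(int(np.ceil(0.13 * ncod)),
                    int(rng.uniform(0.16, 0.4) * ncod))
            m = min(m, ncod - 2)
            if strand == "+":
                ed.splice(e - 3 * m, 3 * m, "", within=idx)
            else:
                ed.splice(s, 3 * m, "", within=idx)
        else:
            raise ValueError(f"unknown pseudogenization mechanism {mech!r}")
    truth.pseudo = {g: pseudo[g] for g in sorted(pseudo, key=pcg_set.index)}

    # IR boundary shift at the IRb|SSC junction
    if spec.ir_delta:
        jlb, jsb, jsa, n = ed.bounds
        d = spec.ir_delta
        if d > 0:
            if not ed.feature_free(jsb, jsb + d):
                raise ValueError("ir_delta window contains a feature")
            w = ed.seq[jsb:jsb + d]
            ed.splice(jsa, 0, revcomp(w))
            ed.bounds[1] = jsb + d  # IRb absorbs the window
        else:
            m = -d
            if not (ed.feature_free(jsb - m, jsb) and ed.feature_free(jsa, jsa + m)):
                raise ValueError("ir_delta window contains a feature")
            ed.splice(jsa, m, "")
            ed.bounds[1] = jsb - m

    # SSC inversion
    if spec.invert_ssc:
        jlb, jsb, jsa, n = ed.bounds
        ed.seq = ed.seq[:jsb] + revcomp(ed.seq[jsb:jsa]) + ed.seq[jsa:]
        for f in ed.feats:
            s, e = f[2][0]
            if jsb <= s and e <= jsa:
                f[2][0] = [jsb + (jsa - e), jsb + (jsa - s)]
                f[3] = "-" if f[3] == "+" else "+"
        truth.ssc_inverted = True

    # intergenic point mutations (single-copy spacers only, preserving the
    # IRa == revcomp(IRb) invariant)
    if spec.igs_sub_rate > 0:
        spacers = _single_copy_spacers(ed)
        hyper_name, hyper_mult = (None, 1.0)
        if spec.hypervariable_igs is not None:
            hyper_name, hyper_mult = spec.hypervariable_igs
            if hyper_name == "auto":
                # longest single-copy spacer, excluding the one reserved
                # for marker planting (its content gets overwritten)
                reserved = {f"{layout.marker_flanks[0]}-{layout.marker_flanks[1]}",
                            f"{layout.marker_flanks[1]}-{layout.marker_flanks[0]}"}
                pool = [t for t in spacers if t[0] not in reserved] or spacers
                hyper_name = max(pool, key=lambda t: (t[2] - t[1], t[0]))[0]
        seq = list(ed.seq)
        p_ts = spec.kappa / (spec.kappa + 2.0)
        for name, s, e in spacers:
            rate = spec.igs_sub_rate * (hyper_mult if name == hyper_name else 1.0)
            rate = min(rate, 1.0)
            hits = np.flatnonzero(rng.random(e - s) < rate)
            ts = tv = 0
            for off in hits:
                pos = s + int(off)
                base = seq[pos]
                if base not in _BASES:
                    continue
                if rng.random() < p_ts:
                    seq[pos] = _TRANSITION[base]
                    ts += 1
                else:
                    seq[pos] = _TRANSVERSIONS[base][int(rng.integers(0, 2))]
                    tv += 1
            if ts or tv:
                truth.igs_substitutions[name] = [ts, tv]
        ed.seq = "".join(seq)

    _fix_boundary_sentinels(ed)
    jlb, jsb, jsa, n = ed.bounds
    truth.boundaries = {"JLB": jlb, "JSB": jsb, "JSA": jsa, "length": len(ed.seq)}
    return ed.to_plastome(spec.name), truth


# ---------------------------------------------------------------------------
# Marker planting
# ---------------------------------------------------------------------------


def _spacer_map(p: AnnotatedPlastome
                ) -> tuple[dict[frozenset, tuple[str, str, int, int]],
                           dict[frozenset, int]]:
    """Unordered flanking-pair -> (upstream, downstream, start, end), plus
    per-pair occurrence counts (IR-duplicated adjacencies occur twice)."""
    spans = sorted((f.start, f.end, f.name) for f in p.features)
    out: dict[frozenset, tuple[str, str, int, int]] = {}
    counts: dict[frozenset, int] = {}
    prev_end, prev_name = None, None
    for s, e, name in spans:
        if prev_end is not None and s > prev_end:
            key = frozenset((prev_name, name))
            if len(key) == 2:
                counts[key] = counts.get(key, 0) + 1
                if key not in out:
                    out[key] = (prev_name, name, prev_end, s)
        if prev_end is None or e > prev_end:
            prev_end, prev_name = e, name
    return out, counts


def plant_marker(genomes: dict[str, AnnotatedPlastome], k_snps: int, m_indels: int,
                 flank_len: int, seed: int, region: tuple[str, str] | None = None,
                 manifest: TruthManifest | None = None
                 ) -> tuple[dict[str, AnnotatedPlastome], list[dict]]:
    """Plant private SNPs and indels inside one shared spacer.

    The spacer is overwritten in every species with a common template plus
    that species' private edits, so the flanks are exactly conserved; the
    k SNPs and m 3-nt deletions are assigned round-robin across species.
    Returns the modified genomes and the planted-site truth records.
    """
    species = list(genomes)
    if len(species) < 2:
        raise ValueError("marker planting needs at least two species")
    maps: dict[str, dict] = {}
    shared: set | None = None
    for sp in species:
        smap, counts = _spacer_map(genomes[sp])
        # spacers with IR-duplicated adjacencies cannot be edited in one
        # place only, so they are never marker candidates
        smap = {k: v for k, v in smap.items() if counts[k] == 1}
        if manifest is not None and sp in manifest.species:
            tb = manifest.species[sp].boundaries
            jlb, jsb, jsa = tb["JLB"], tb["JSB"], tb["JSA"]
            smap = {k: v for k, v in smap.items()
                    if v[3] <= jlb or (jsb <= v[2] and v[3] <= jsa)}
        maps[sp] = smap
        shared = set(smap) if shared is None else shared & set(smap)
    if region is not None:
        key = frozenset(region)
        if key not in shared:
            raise ValueError(
                f"spacer {region[0]}-{region[1]} is not shared by all species "
                "(a flanking gene may have been deleted)")
        candidates = [key]
    else:
        candidates = sorted(
            shared, key=lambda k: (-(maps[species[0]][k][3] - maps[species[0]][k][2]),
                                   sorted(k)))
    n_sites = k_snps + m_indels
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 9733])
    chosen = None
    for key in candidates:
        up, down, s, e = maps[species[0]][key]
        if (e - s) - 2 * flank_len >= 8 * (n_sites + 1):
            chosen = key
            break
    if chosen is None:
        raise ValueError("insufficient spacer length for requested marker")

    up, down, s0, e0 = maps[species[0]][chosen]
    template = genomes[species[0]].sequence[s0:e0]
    core_len = len(template) - 2 * flank_len
    offsets = [flank_len + (i + 1) * core_len // (n_sites + 1) for i in range(n_sites)]
    kinds = ["SNP"] * k_snps + ["indel"] * m_indels
    order = rng.permutation(n_sites)
    region_name = f"{up}-{down}"
    sites = []
    for rank, idx in enumerate(order):
        sp = species[rank % len(species)]
        sites.append({"kind": kinds[int(idx)], "species": sp,
                      "template_pos": offsets[int(idx)], "region": region_name})
    sites.sort(key=lambda d: d["template_pos"])

    out: dict[str, AnnotatedPlastome] = {}
    shifts: dict[str, tuple[int, int]] = {}
    for sp in species:
        edits = [st for st in sites if st["species"] == sp]
        seq = template
        for st in sorted(edits, key=lambda d: -d["template_pos"]):
            pos = st["template_pos"]
            if st["kind"] == "SNP":
                base = seq[pos]
                alt = _BASES[(_BASES.index(base) + 1 + int(rng.integers(0, 3))) % 4]
                if alt == base:
                    alt = _BASES[(_BASES.index(base) + 1) % 4]
                seq = seq[:pos] + alt + seq[pos + 1:]
                st["state"] = alt
                st["background_state"] = base
            else:
                st["state"] = "-" * 3
                st["background_state"] = seq[pos:pos + 3]
                seq = seq[:pos] + seq[pos + 3:]
        # replace the spacer in this genome
        up_sp, down_sp, s, e = maps[sp][chosen]
        p = genomes[sp]
        body = seq if (up_sp, down_sp) == (up, down) else revcomp(seq)
        new_seq = p.sequence[:s] + body + p.sequence[e:]
        delta = len(body) - (e - s)
        feats = []
        for f in p.features:
            if f.start >= e:
                ivs = tuple((a + delta, b_ + delta) for a, b_ in f.intervals)
                feats.append(GeneFeature(f.name, f.kind, ivs, f.strand))
            else:
                feats.append(f)
        out[sp] = AnnotatedPlastome(id=p.id, sequence=new_seq, features=feats,
                                    circular=p.circular, source=p.source)
        shifts[sp] = (e, delta)

    if manifest is not None:
        for sp in species:
            if sp in manifest.species:
                e, delta = shifts[sp]
                tr = manifest.species[sp]
                tr.boundaries = {k: (v + delta if v >= e else v)
                                 for k, v in tr.boundaries.items()}
                tr.diagnostic_sites = [dict(st) for st in sites]
    return out, sites


# ---------------------------------------------------------------------------
# Scenario assembly
# ---------------------------------------------------------------------------


def simulate_bundle(cfg: SimulationConfig
                    ) -> tuple[AnnotatedPlastome, dict[str, AnnotatedPlastome],
                               TruthManifest]:
    """Reference + degraded species genomes + truth manifest."""
    ref, layout = make_reference(cfg)
    manifest = TruthManifest(layout=layout)
    genomes: dict[str, AnnotatedPlastome] = {}
    for spec in cfg.species:
        genome, truth = degrade(ref, layout, spec, cfg.seed)
        genomes[spec.name] = genome
        manifest.species[spec.name] = truth
    if cfg.marker is not None and genomes:
        for spec in cfg.species:
            clash = set(spec.deleted_genes) & set(layout.marker_flanks)
            if clash:
                raise ValueError(
                    f"{spec.name}: deletion of {sorted(clash)} removes a flank "
                    "of the spacer reserved for the planted marker")
        k, m, flank = cfg.marker
        genomes, sites = plant_marker(
            genomes, k, m, flank, cfg.seed,
            region=layout.marker_flanks, manifest=manifest)
    return ref, genomes, manifest


def default_scenario(seed: int = 0, n_species: int = 4,
                     igs_sub_rate: float = 0.02, kappa: float = 2.0,
                     marker: tuple[int, int, int] | None = None
                     ) -> SimulationConfig:
    """Study-shaped conditions: four heavily degraded congeners.

    Loss fractions ~0.3-0.45 of the reference gene complement and
    pseudogene fractions ~0.16-0.29 mirror the degradation range reported
    for holoparasite plastomes; kappa=2 is a typical plastid
    transition/transversion ratio.
    """
    base = [
        dict(deletion_rate=0.35, pseudo_rate=0.20, ir_delta=40, invert_ssc=False),
        dict(deletion_rate=0.40, pseudo_rate=0.29, ir_delta=25, invert_ssc=False),
        dict(deletion_rate=0.30, pseudo_rate=0.16, ir_delta=-30, invert_ssc=True),
        dict(deletion_rate=0.45, pseudo_rate=0.24, ir_delta=-45, invert_ssc=False),
        dict(deletion_rate=0.38, pseudo_rate=0.26, ir_delta=15, invert_ssc=False),
    ]
    species = tuple(
        SpeciesSpec(name=f"sp{chr(65 + i)}", igs_sub_rate=igs_sub_rate,
                    kappa=kappa, hypervariable_igs=("auto", 10.0), **base[i % len(base)])
        for i in range(n_species))
    return SimulationConfig(seed=seed, species=species, marker=marker)


def realistic_config(seed: int = 0, n_species: int = 4) -> SimulationConfig:
    """Plastome-scale build (~120 kb, 80 protein-coding genes)."""
    cfg = default_scenario(seed, n_species)
    return SimulationConfig(seed=seed, n_pcg=80, n_trna=20, lsc_len=82000,
                            ssc_len=16000, ir_len=11000, species=cfg.species,
                            marker=cfg.marker)
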
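"""Reading and writing annotated plastomes.

Internal coordinates are 0-based half-open throughout; GenBank's 1-based
inclusive convention is converted at the file boundary.  Plastomes are
circular by default, and a feature may wrap the origin: such a feature is
represented either by two explicit intervals ``[(s, n), (0, e)]`` or by a
single interval with ``start > end`` (normalized on extraction).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneFeature",
    "AnnotatedPlastome",
    "revcomp",
    "gc_content",
    "normalize_gene_name",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "extract_feature_sequence",
    "write_region_table",
]

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """G+C fraction over unambiguous bases."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


_SUFFIX_RE = re.compile(r"(_\d+|-fragment|_fragment|-copy\d*)$", re.IGNORECASE)


def normalize_gene_name(name: str) -> str:
    """Collapse duplicate-copy naming so IR copies share one symbol.

    Case-insensitive; trailing ``_1``-style copy suffixes and
    ``-fragment`` markers are stripped.  ``trnA-UGC`` style anticodon
    suffixes are kept (they distinguish distinct genes).
    """
    return _SUFFIX_RE.sub("", name.strip()).casefold()


@dataclass(frozen=True)
class GeneFeature:
    """A gene-level feature on a plastome.

    intervals are 0-based half-open, in transcription order along the
    annotated strand's forward coordinates; a '-' strand feature's
    sequence is the reverse complement of the concatenated intervals.
    """

    name: str
    kind: str  # CDS | tRNA | rRNA | pseudo
    intervals: tuple[tuple[int, int], ...]
    strand: str  # '+' | '-'

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError(f"feature {self.name}: empty interval list")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.name}: bad strand {self.strand!r}")
        object.__setattr__(self, "intervals", tuple(tuple(iv) for iv in self.intervals))

    @property
    def start(self) -> int:
        return min(s for s, _ in self.intervals)

    @property
    def end(self) -> int:
        return max(e for _, e in self.intervals)

    @property
    def span(self) -> tuple[int, int]:
        """Smallest single interval covering every part (no wrap handling)."""
        return (self.start, self.end)

    def length(self, genome_length: int | None = None) -> int:
        total = 0
        for s, e in self.intervals:
            if e > s:
                total += e - s
            elif genome_length is not None:
                total += genome_length - s + e
            else:
                raise ValueError(f"feature {self.name}: wrapping interval on linear sequence")
        return total


@dataclass
class AnnotatedPlastome:
    """A circular (by default) plastid genome with gene features."""

    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = True
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"plastome {self.id}: empty sequence")
        self.sequence = self.sequence.upper()
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.intervals:
                if not (0 <= s < n and 0 < e <= n):
                    raise ValueError(
                        f"plastome {self.id}: feature {f.name} interval ({s},{e}) "
                        f"outside [0,{n})")
        self.features = sorted(self.features, key=lambda f: (f.start, f.end, f.name))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        return gc_content(self.sequence)

    def features_of_kind(self, *kinds: str) -> list[GeneFeature]:
        return [f for f in self.features if f.kind in kinds]

    def feature_sequence(self, f: GeneFeature) -> str:
        return extract_feature_sequence(self, f)


def extract_feature_sequence(p: AnnotatedPlastome, f: GeneFeature) -> str:
    """Concatenated interval sequences, reverse-complemented for '-' strand.

    An interval with start > end wraps the circular origin.
    """
    n = len(p.sequence)
    parts: list[str] = []
    for s, e in f.intervals:
        if e > s:
            parts.append(p.sequence[s:e])
        else:
            if not p.circular:
                raise ValueError(
                    f"feature {f.name}: interval ({s},{e}) wraps origin on linear sequence")
            parts.append(p.sequence[s:] + p.sequence[:e])
    seq = "".join(parts)
    if len(seq) > n:
        raise ValueError(f"feature {f.name}: intervals exceed genome length")
    return revcomp(seq) if f.strand == "-" else seq


# ---------------------------------------------------------------------------
# GenBank / FASTA I/O
# ---------------------------------------------------------------------------

_FEATURE_KINDS = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


def _feature_name(feat: SeqFeature) -> str | None:
    for key in ("gene", "locus_tag", "product"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return None


def _location_to_intervals(loc) -> tuple[tuple[tuple[int, int], ...], str]:
    parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    strand = "-" if (loc.strand or 1) < 0 else "+"
    ivs = tuple((int(p.start), int(p.end)) for p in parts)
    if strand == "-":
        # Biopython lists complement-join parts in transcription order for
        # CompoundLocation; store in forward-coordinate order.
        ivs = tuple(sorted(ivs))
    return ivs, strand


def read_genbank(path: str | Path) -> AnnotatedPlastome:
    """Read a GenBank flat file into an AnnotatedPlastome.

    Gene/CDS/tRNA/rRNA features are captured; coordinates become 0-based
    half-open; join() and complement() honored.  Features carrying a
    /pseudo or /pseudogene qualifier get kind='pseudo'.  Plain `gene`
    features are used only when no typed feature shares their symbol.
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError on bad records
        raise ValueError(f"malformed GenBank record in {path}: {exc}") from exc
    if len(record.seq) == 0:
        raise ValueError(f"record {record.id} in {path} has no sequence")
    circular = record.annotations.get("topology", "circular") == "circular"

    feats: list[GeneFeature] = []
    typed_names: set[tuple[str, int]] = set()
    gene_feats: list[GeneFeature] = []
    for feat in record.features:
        name = _feature_name(feat)
        if name is None:
            continue
        pseudo = "pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers
        if feat.type in _FEATURE_KINDS:
            ivs, strand = _location_to_intervals(feat.location)
            kind = "pseudo" if pseudo else _FEATURE_KINDS[feat.type]
            gf = GeneFeature(name, kind, ivs, strand)
            feats.append(gf)
            typed_names.add((normalize_gene_name(name), gf.start))
        elif feat.type == "gene":
            ivs, strand = _location_to_intervals(feat.location)
            kind = "pseudo" if pseudo else "CDS"
            gene_feats.append(GeneFeature(name, kind, ivs, strand))
    for gf in gene_feats:
        key = (normalize_gene_name(gf.name), gf.start)
        near = any(k == key[0] and abs(s - gf.start) < 50 for k, s in typed_names)
        if not near:
            feats.append(gf)
    return AnnotatedPlastome(
        id=record.id or record.name, sequence=str(record.seq),
        features=feats, circular=circular, source=str(path))


def write_genbank(p: AnnotatedPlastome, path: str | Path) -> None:
    """Write an AnnotatedPlastome as a GenBank flat file (round-trip safe)."""
    record = SeqRecord(Seq(p.sequence), id=p.id, name=p.id[:16].replace(" ", "_"),
                       description=f"{p.id} plastome")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if p.circular else "linear"
    for f in p.features:
        strand = -1 if f.strand == "-" else 1
        locs = [SimpleLocation(s, e, strand) for s, e in f.intervals]
        if strand < 0:
            locs = locs[::-1]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        ftype = f.kind if f.kind in ("CDS", "tRNA", "rRNA") else "CDS"
        quals = {"gene": [f.name]}
        if f.kind == "pseudo":
            quals["pseudo"] = [""]
        record.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    SeqIO.write([record], str(path), "genbank")


def read_fasta(path: str | Path) -> AnnotatedPlastome:
    record = SeqIO.read(str(path), "fasta")
    if len(record.seq) == 0:
        raise ValueError(f"record {record.id} in {path} has no sequence")
    return AnnotatedPlastome(id=record.id, sequence=str(record.seq),
                             features=[], source=str(path))


def write_fasta(p: AnnotatedPlastome, path: str | Path) -> None:
    SeqIO.write([SeqRecord(Seq(p.sequence), id=p.id, description="")],
                str(path), "fasta")


def write_region_table(regions: Iterable[tuple[str, int, int, str]],
                       path: str | Path) -> None:
    """Write named intervals as BED (0-based half-open, tab-separated).

    Each region is (chrom, start, end, name).
    """
    with open(path, "w") as fh:
        for chrom, start, end, name in regions:
            if end < start:
                raise ValueError(f"region {name}: end {end} < start {start}")
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def rotate_plastome(p: AnnotatedPlastome, offset: int, new_id: str | None = None
                    ) -> AnnotatedPlastome:
    """Rotate a circular plastome so original position `offset` becomes 0."""
    if not p.circular:
        raise ValueError("cannot rotate a linear sequence")
    n = len(p.sequence)
    offset %= n
    seq = p.sequence[offset:] + p.sequence[:offset]
    feats = []
    for f in p.features:
        ivs = []
        for s, e in f.intervals:
            s2, e2 = (s - offset) % n, (e - offset) % n
            if e2 == 0:
                e2 = n
            if s2 < e2:
                ivs.append((s2, e2))
            else:  # interval now wraps the origin: split
                ivs.append((s2, n))
                ivs.append((0, e2))
        if f.strand == "-":
            # keep intervals in forward-coordinate order except the wrap split
            pass
        feats.append(replace(f, intervals=tuple(ivs)))
    return AnnotatedPlastome(id=new_id or p.id, sequence=seq, features=feats,
                             circular=True, source=p.source)
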
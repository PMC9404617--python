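"""Species-diagnostic sites and conserved primer pairs.

A *diagnostic site* is an alignment column (or maximal private gap run,
counted as one indel locus) where exactly one species differs from an
otherwise unanimous background.  Primer windows are enumerated from
maximal runs of fully conserved, gap-free columns (18-27 nt, GC fraction
0.3-0.7, zero mismatches in any species) and paired so that every
species' product length lies within the requested bounds; candidates are
scored by the number of enclosed diagnostic sites and emitted greedily,
non-overlapping, best first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import progressive_msa
from .io import gc_content, revcomp

__all__ = ["DiagnosticSite", "MarkerCandidate", "build_msa", "diagnostic_sites",
           "primer_search", "discrimination_matrix"]


@dataclass
class DiagnosticSite:
    column: int  # MSA coordinate (start of the run for indels)
    kind: str  # SNP | indel
    species: str  # the single species distinguished
    state: str  # residue, inserted bases, or '-'*run for a deletion
    background_state: str


@dataclass
class MarkerCandidate:
    name: str
    region: str
    forward_primer: str
    forward_pos: int  # MSA column of the forward primer start
    reverse_primer: str  # reverse-complemented, as synthesized
    reverse_pos: int  # MSA column of the reverse window start
    product_lengths: dict = field(default_factory=dict)  # species -> nt
    sites: list = field(default_factory=list)
    score: int = 0

    def separates(self, a: str, b: str) -> bool:
        return any(s.species in (a, b) for s in self.sites)


def build_msa(seqs: dict[str, str], **params) -> dict[str, str]:
    """Progressive multiple alignment of region sequences (deterministic)."""
    if not seqs:
        raise ValueError("no sequences")
    return progressive_msa(seqs, kind="dna", **params)


def diagnostic_sites(msa: dict[str, str]) -> list[DiagnosticSite]:
    """Strict one-vs-rest diagnostic columns.

    SNP: one species carries a different base, all others share one base.
    Indel: a maximal run of columns privately gapped in one species (the
    others unanimous), or privately inserted (bases in one species, gaps
    in all others) -- each run is ONE site.  Columns containing an
    ambiguous base are skipped.
    """
    species = list(msa)
    if len(species) < 3:
        raise ValueError("diagnostic sites need at least three species")
    rows = [msa[sp] for sp in species]
    ncols = len(rows[0])
    if any(len(r) != ncols for r in rows):
        raise ValueError("ragged alignment")

    sites: list[DiagnosticSite] = []
    run: tuple[str, str, int] | None = None  # (kind, species, start)
    run_state: list[str] = []
    run_bg: list[str] = []

    def close_run() -> None:
        nonlocal run
        if run is not None:
            kind, sp, start = run
            sites.append(DiagnosticSite(
                column=start, kind="indel", species=sp,
                state="".join(run_state), background_state="".join(run_bg)))
        run = None

    for col in range(ncols):
        chars = [r[col] for r in rows]
        if any(c not in "ACGT-" for c in chars):
            close_run()
            continue
        gapped = [i for i, c in enumerate(chars) if c == "-"]
        if len(gapped) == 1 and len(set(chars) - {"-"}) == 1:
            sp = species[gapped[0]]
            bg = next(c for c in chars if c != "-")
            if run is not None and run[0] == "del" and run[1] == sp:
                run_state.append("-")
                run_bg.append(bg)
            else:
                close_run()
                run = ("del", sp, col)
                run_state, run_bg = ["-"], [bg]
            continue
        if len(gapped) == len(species) - 1:
            ins_idx = next(i for i in range(len(species)) if i not in gapped)
            sp = species[ins_idx]
            if run is not None and run[0] == "ins" and run[1] == sp:
                run_state.append(chars[ins_idx])
                run_bg.append("-")
            else:
                close_run()
                run = ("ins", sp, col)
                run_state, run_bg = [chars[ins_idx]], ["-"]
            continue
        close_run()
        if "-" in chars:
            continue
        counts: dict[str, list[int]] = {}
        for i, c in enumerate(chars):
            counts.setdefault(c, []).append(i)
        if len(counts) == 2:
            (minor, minor_rows), (major, major_rows) = sorted(
                counts.items(), key=lambda kv: len(kv[1]))
            if len(minor_rows) == 1 and len(major_rows) == len(species) - 1:
                sites.append(DiagnosticSite(
                    column=col, kind="SNP", species=species[minor_rows[0]],
                    state=minor, background_state=major))
    close_run()
    return sites


def _conserved_runs(rows: list[str]) -> list[tuple[int, int]]:
    """Maximal runs of columns where every species shares one ACGT base."""
    ncols = len(rows[0])
    runs = []
    start = None
    for col in range(ncols):
        chars = {r[col] for r in rows}
        ok = len(chars) == 1 and chars <= set("ACGT")
        if ok and start is None:
            start = col
        elif not ok and start is not None:
            runs.append((start, col))
            start = None
    if start is not None:
        runs.append((start, ncols))
    return runs


def primer_search(msa: dict[str, str], region: str = "region",
                  min_len: int = 100, max_len: int = 1000,
                  primer_min: int = 18, primer_max: int = 27,
                  gc_range: tuple[float, float] = (0.3, 0.7),
                  max_candidates: int = 10) -> list[MarkerCandidate]:
    """Conserved primer pairs bounding length-constrained products.

    Primers must match every species exactly (no substitutions, no gaps);
    each species' product (primers included) must span [min_len, max_len].
    Candidates are ranked by enclosed diagnostic-site count and emitted
    greedily without overlap.
    """
    species = list(msa)
    rows = [msa[sp] for sp in species]
    if any(len(r) != len(rows[0]) for r in rows):
        raise ValueError("ragged alignment")
    template = rows[0]
    runs = [r for r in _conserved_runs(rows) if r[1] - r[0] >= primer_min]
    if not runs:
        warnings.warn("no conserved primer window")
        return []
    sites = diagnostic_sites(msa) if len(species) >= 3 else []

    def window_ok(s: int, e: int) -> bool:
        seq = template[s:e]
        return gc_range[0] <= gc_content(seq) <= gc_range[1]

    def product_lengths(f_start: int, r_end: int) -> dict[str, int] | None:
        out = {}
        for sp, row in zip(species, rows):
            L = sum(1 for c in row[f_start:r_end] if c != "-")
            if not (min_len <= L <= max_len):
                return None
            out[sp] = L
        return out

    raw: list[MarkerCandidate] = []
    for ia, (sa, ea) in enumerate(runs):
        for sb, eb in runs[ia:]:
            if (sa, ea) == (sb, eb):
                # one long conserved run: primers at its two ends
                plen = min(primer_max, ea - sa)
                f_start, f_end = sa, sa + plen
                r_start, r_end = ea - plen, ea
                if r_start < f_end:
                    continue
            else:
                plen_f = min(primer_max, ea - sa)
                f_start, f_end = ea - plen_f, ea  # forward primer abuts product
                plen_r = min(primer_max, eb - sb)
                r_start, r_end = sb, sb + plen_r
            if not (window_ok(f_start, f_end) and window_ok(r_start, r_end)):
                continue
            lengths = product_lengths(f_start, r_end)
            if lengths is None:
                continue
            enclosed = [s for s in sites
                        if f_end <= s.column and
                        s.column + max(1, len(s.state)) <= r_start]
            raw.append(MarkerCandidate(
                name="", region=region,
                forward_primer=template[f_start:f_end], forward_pos=f_start,
                reverse_primer=revcomp(template[r_start:r_end]), reverse_pos=r_start,
                product_lengths=lengths, sites=enclosed, score=len(enclosed)))

    raw.sort(key=lambda c: (-c.score, c.forward_pos, c.reverse_pos))
    chosen: list[MarkerCandidate] = []
    for cand in raw:
        span = (cand.forward_pos, cand.reverse_pos + len(cand.reverse_primer))
        if any(not (span[1] <= c.forward_pos or
                    c.reverse_pos + len(c.reverse_primer) <= span[0])
               for c in chosen):
            continue
        cand.name = f"{region}-mk{len(chosen) + 1:02d}"
        chosen.append(cand)
        if len(chosen) >= max_candidates:
            break

    # primers must occur verbatim in every species' ungapped sequence
    for cand in chosen:
        fwd = cand.forward_primer
        rev_window = revcomp(cand.reverse_primer)
        for sp in species:
            ungapped = msa[sp].replace("-", "")
            if fwd not in ungapped or rev_window not in ungapped:
                raise AssertionError(
                    f"primer not exactly conserved in {sp} (internal error)")
    return chosen


def discrimination_matrix(candidates: list[MarkerCandidate], species: list[str]
                          ) -> tuple[pd.DataFrame, bool]:
    """Pairwise discrimination: True when some candidate holds a site
    separating the pair; success means every pair is separated."""
    if not candidates:
        raise ValueError("no candidates")
    k = len(species)
    mat = np.eye(k, dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            sep = any(c.separates(species[i], species[j]) for c in candidates)
            mat[i, j] = mat[j, i] = sep
    df = pd.DataFrame(mat, index=species, columns=species)
    return df, bool(mat.all())
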
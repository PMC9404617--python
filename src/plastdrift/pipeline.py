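"""End-to-end orchestration: one call runs every stage and writes the
tabular outputs (partition.bed, junctions.tsv, census.tsv, ratios.tsv,
cluster.nwk, igs_divergence.tsv, omega.tsv, markers.tsv,
discrimination.tsv) into an output directory."""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

from . import barcode, census, dnds, igs, quadripartite
from .io import AnnotatedPlastome, read_genbank, write_region_table
from .simulate import default_scenario, simulate_bundle

__all__ = ["RunConfig", "run_all", "OUTPUT_FILES"]

log = logging.getLogger("plastdrift")

OUTPUT_FILES = ("partition.bed", "junctions.tsv", "census.tsv", "ratios.tsv",
                "cluster.nwk", "igs_divergence.tsv", "omega.tsv", "markers.tsv",
                "discrimination.tsv")


@dataclass
class RunConfig:
    """Inputs and knobs for a full pipeline run."""

    inputs: list[str] = field(default_factory=list)  # target GenBank paths
    reference: str | None = None  # reference GenBank path
    outdir: str = "plastdrift_out"
    seed: int = 0
    simulate: bool = False  # generate a synthetic bundle instead of reading
    n_species: int = 4
    min_ir_len: int = 1000
    marker_min_len: int = 100
    marker_max_len: int = 1000
    census_thresholds: census.CensusThresholds = field(
        default_factory=census.CensusThresholds)

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a TOML config; keyword overrides (CLI flags) win over the
        file, which wins over the defaults."""
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        unknown = set(data) - {f.name for f in fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        if not 0 < self.marker_min_len < self.marker_max_len:
            raise ValueError("marker bounds must satisfy 0 < min < max")
        if not self.simulate:
            if self.reference is None:
                raise ValueError("a --reference record is required")
            missing = [p for p in [self.reference, *self.inputs]
                       if not Path(p).exists()]
            if missing:
                raise FileNotFoundError(f"input paths not found: {missing}")
            if not self.inputs:
                raise ValueError("no target plastomes given")


def _load(cfg: RunConfig) -> tuple[AnnotatedPlastome, dict[str, AnnotatedPlastome]]:
    if cfg.simulate:
        sim = default_scenario(seed=cfg.seed, n_species=cfg.n_species,
                               marker=(9, 3, 30))
        reference, genomes, _ = simulate_bundle(sim)
        return reference, genomes
    reference = read_genbank(cfg.reference)
    genomes = {}
    for path in cfg.inputs:
        p = read_genbank(path)
        genomes[p.id] = p
    return reference, genomes


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            log.info("stage %s ...", name)
            try:
                out = fn(*args, **kwargs)
            except Exception:
                log.error("stage %s FAILED", name)
                raise
            log.info("stage %s done (%.2fs)", name, time.time() - t0)
            return out
        return wrapped
    return deco


@_stage("partition")
def _run_partition(genomes, outdir, min_ir_len):
    rows, junc_rows = [], []
    partitions = {}
    for sp, p in genomes.items():
        q = quadripartite.detect_inverted_repeat(p, min_len=min_ir_len)
        partitions[sp] = q
        if not q.has_quadripartite:
            log.warning("%s: no quadripartite structure", sp)
            continue
        rows.extend(quadripartite.partition_regions(p, q))
        for ctx in quadripartite.junction_report(p, q):
            junc_rows.append({
                "species": sp, "junction": ctx.junction,
                "position": q.junctions[ctx.junction],
                "left_gene": ctx.left_gene, "left_strand": ctx.left_strand,
                "left_distance": ctx.left_distance,
                "right_gene": ctx.right_gene, "right_strand": ctx.right_strand,
                "right_distance": ctx.right_distance,
                "spanning_gene": ctx.spanning_gene or "."})
    write_region_table(rows, outdir / "partition.bed")
    pd.DataFrame(junc_rows).to_csv(outdir / "junctions.tsv", sep="\t", index=False)
    return partitions


@_stage("census")
def _run_census(genomes, reference, outdir, thresholds):
    m = census.census_matrix(list(genomes.values()), reference, thresholds)
    df = m.to_dataframe()
    glyphs = df.replace(census.STATUS_GLYPHS)
    glyphs.columns = [f"{c}_glyph" for c in glyphs.columns]
    table = pd.concat([glyphs, df], axis=1)
    table.index.name = "gene"
    table.to_csv(outdir / "census.tsv", sep="\t")
    profiles = census.degradation_ratios(m)
    pd.DataFrame([{
        "species": p.species, "n_lost": p.n_lost, "n_pseudo": p.n_pseudo,
        "n_ref_pcg": p.n_ref_pcg, "ratio_lost": p.ratio_lost,
        "ratio_pseudo": p.ratio_pseudo} for p in profiles
    ]).to_csv(outdir / "ratios.tsv", sep="\t", index=False)
    if len(profiles) >= 2:
        newick, _ = census.cluster_species(profiles)
    else:
        newick = f"({profiles[0].species});"
    (outdir / "cluster.nwk").write_text(newick + "\n")
    return m


@_stage("igs-scan")
def _run_igs(genomes, outdir):
    regions = igs.extract_shared_igs(list(genomes.values()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, _ = igs.rank_igs(regions)
    table.to_csv(outdir / "igs_divergence.tsv", sep="\t", index=False)
    return regions, table


@_stage("dnds")
def _run_dnds(genomes, matrix, outdir):
    gene_seqs = dnds.collect_present_cds(genomes, census=matrix)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, _ = dnds.omega_table(gene_seqs)
    table.to_csv(outdir / "omega.tsv", sep="\t", index=False)
    return table


@_stage("markers")
def _run_markers(genomes, regions, outdir, min_len, max_len):
    species = list(genomes)
    marker_rows, all_candidates = [], []
    for region in regions:
        seqs = {sp: region.per_species[sp][2] for sp in species}
        if any(not s for s in seqs.values()):
            continue
        msa = barcode.build_msa(seqs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cands = barcode.primer_search(msa, region=region.name,
                                          min_len=min_len, max_len=max_len)
        for c in cands:
            all_candidates.append(c)
            marker_rows.append({
                "name": c.name, "region": c.region, "score": c.score,
                "forward_primer": c.forward_primer,
                "reverse_primer": c.reverse_primer,
                "n_snp": sum(1 for s in c.sites if s.kind == "SNP"),
                "n_indel": sum(1 for s in c.sites if s.kind == "indel"),
                **{f"product_{sp}": c.product_lengths[sp] for sp in species}})
    pd.DataFrame(marker_rows).to_csv(outdir / "markers.tsv", sep="\t", index=False)
    if all_candidates:
        dm, success = barcode.discrimination_matrix(all_candidates, species)
    else:
        dm = pd.DataFrame(False, index=species, columns=species)
        success = False
    dm.index.name = "species"
    dm.to_csv(outdir / "discrimination.tsv", sep="\t")
    return all_candidates, success


def run_all(cfg: RunConfig) -> dict:
    """Run every stage; returns a summary dict (also written as
    run_summary.json).  Raises on the first failing stage; files written
    before the failure are retained."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(min(log.level or logging.INFO, logging.INFO))
    try:
        reference, genomes = _load(cfg)
        log.info("loaded %d target plastomes (reference %s)",
                 len(genomes), reference.id)

        partitions = _run_partition(genomes, outdir, cfg.min_ir_len)
        matrix = _run_census(genomes, reference, outdir, cfg.census_thresholds)
        regions, igs_table = _run_igs(genomes, outdir)
        omega = _run_dnds(genomes, matrix, outdir)
        candidates, success = _run_markers(genomes, regions, outdir,
                                           cfg.marker_min_len, cfg.marker_max_len)
    finally:
        log.removeHandler(handler)
        handler.close()

    summary = {
        "seed": cfg.seed,
        "species": list(genomes),
        "reference": reference.id,
        "n_ref_pcg": matrix.n_ref_pcg,
        "quadripartite": {sp: q.region_lengths() for sp, q in partitions.items()},
        "shared_igs": len(regions),
        "top_igs": igs_table.iloc[0]["region"] if len(igs_table) else None,
        "n_omega_genes": int(len(omega)),
        "positive_selection_candidates":
            omega.loc[omega.positive_selection_candidate, "gene"].tolist(),
        "n_marker_candidates": len(candidates),
        "discrimination_success": bool(success),
    }
    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary
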
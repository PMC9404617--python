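"""The synthetic generator: determinism, validity, planted-truth fidelity."""

import dataclasses
import math

import numpy as np
import pytest
from Bio.Seq import Seq

from plastdrift.io import extract_feature_sequence, read_genbank, revcomp, write_genbank
from plastdrift.simulate import (SimulationConfig, SpeciesSpec, default_scenario,
                                 degrade, make_reference, plant_marker,
                                 simulate_bundle)


def test_same_seed_byte_identical():
    cfg = default_scenario(seed=7, marker=(9, 3, 30))
    ref1, gen1, man1 = simulate_bundle(cfg)
    ref2, gen2, man2 = simulate_bundle(default_scenario(seed=7, marker=(9, 3, 30)))
    assert ref1.sequence == ref2.sequence
    assert ref1.features == ref2.features
    for sp in gen1:
        assert gen1[sp].sequence == gen2[sp].sequence
        assert gen1[sp].features == gen2[sp].features
    assert man1.to_dict() == man2.to_dict()


def test_different_seeds_differ():
    r1, _ = make_reference(SimulationConfig(seed=1))
    r2, _ = make_reference(SimulationConfig(seed=2))
    assert r1.sequence != r2.sequence


def test_adding_a_species_never_perturbs_others():
    cfg3 = default_scenario(seed=9, n_species=3)
    cfg4 = default_scenario(seed=9, n_species=4)
    _, gen3, _ = simulate_bundle(cfg3)
    _, gen4, _ = simulate_bundle(cfg4)
    for sp in gen3:
        assert gen3[sp].sequence == gen4[sp].sequence


def test_reference_structure_and_orfs():
    cfg = SimulationConfig(seed=4)
    ref, layout = make_reference(cfg)
    assert len(ref) == cfg.lsc_len + 2 * cfg.ir_len + cfg.ssc_len
    jlb, jsb = cfg.lsc_len, cfg.lsc_len + cfg.ir_len
    jsa = jsb + cfg.ssc_len
    assert ref.sequence[jsa:] == revcomp(ref.sequence[jlb:jsb])
    n_cds = 0
    for f in ref.features:
        if f.kind != "CDS":
            continue
        n_cds += 1
        cds = extract_feature_sequence(ref, f)
        assert len(cds) % 3 == 0
        prot = str(Seq(cds).translate())
        assert prot.endswith("*") and "*" not in prot[:-1]
        assert cds.startswith("ATG")
    assert n_cds == cfg.n_pcg


def test_infeasible_packing_rejected():
    with pytest.raises(ValueError, match="infeasible packing"):
        make_reference(SimulationConfig(seed=0, n_pcg=60, lsc_len=2000,
                                        ssc_len=500, ir_len=800))


def test_null_degradation_identical_except_id():
    cfg = SimulationConfig(seed=5, species=(SpeciesSpec(name="null"),))
    ref, layout = make_reference(cfg)
    genome, truth = degrade(ref, layout, cfg.species[0], cfg.seed)
    assert genome.id == "null"
    assert genome.sequence == ref.sequence
    assert [(f.name, f.intervals, f.strand) for f in genome.features] == \
           [(f.name, f.intervals, f.strand) for f in ref.features]
    assert truth.lost == [] and truth.pseudo == {}


def test_explicit_deletion_set_reflected_in_genome():
    cfg = SimulationConfig(seed=6, species=(
        SpeciesSpec(name="d", deleted_genes=("g3", "g7")),))
    ref, layout = make_reference(cfg)
    genome, truth = degrade(ref, layout, cfg.species[0], cfg.seed)
    names = {f.name for f in genome.features}
    assert "g3" not in names and "g7" not in names
    assert truth.lost == ["g3", "g7"]
    removed = sum(e - s for (n2, k, r, s, e, st) in layout.genes if n2 in ("g3", "g7"))
    assert len(genome) == len(ref) - removed


def test_pseudogenization_mechanisms_alter_cds_as_specified():
    cfg = SimulationConfig(seed=8, species=(
        SpeciesSpec(name="p", pseudo_genes={"g2": "frameshift",
                                            "g4": "premature_stop",
                                            "g6": "truncation"}),))
    ref, layout = make_reference(cfg)
    genome, truth = degrade(ref, layout, cfg.species[0], cfg.seed)
    by_name = {f.name: f for f in genome.features}
    ref_by_name = {f.name: f for f in ref.features}

    fs = extract_feature_sequence(genome, by_name["g2"])
    ref_fs = extract_feature_sequence(ref, ref_by_name["g2"])
    assert abs(len(fs) - len(ref_fs)) in (1, 2)  # 1-2 nt indel

    ps = extract_feature_sequence(genome, by_name["g4"])
    prot = str(Seq(ps).translate())
    first_stop = prot.index("*")
    assert first_stop < 0.7 * (len(ps) // 3)

    tr = extract_feature_sequence(genome, by_name["g6"])
    ref_tr = extract_feature_sequence(ref, ref_by_name["g6"])
    assert len(tr) % 3 == 0
    assert len(tr) <= 0.9 * len(ref_tr)
    assert tr == ref_tr[: len(tr)]  # prefix preserved, tail removed


def test_ir_delta_moves_jsb_and_keeps_mirror():
    for delta in (40, -40):
        cfg = SimulationConfig(seed=10, species=(
            SpeciesSpec(name="s", ir_delta=delta),))
        ref, layout = make_reference(cfg)
        genome, truth = degrade(ref, layout, cfg.species[0], cfg.seed)
        b = truth.boundaries
        assert b["JSB"] - b["JLB"] == cfg.ir_len + delta
        assert b["length"] == len(ref) + delta
        irb = genome.sequence[b["JLB"]:b["JSB"]]
        ira = genome.sequence[b["JSA"]:]
        assert ira == revcomp(irb)


def test_ssc_inversion_flips_strands_and_sequence():
    cfg = SimulationConfig(seed=12, species=(
        SpeciesSpec(name="s", invert_ssc=True),))
    ref, layout = make_reference(cfg)
    genome, truth = degrade(ref, layout, cfg.species[0], cfg.seed)
    b = truth.boundaries
    jsb, jsa = b["JSB"], b["JSA"]
    assert genome.sequence[jsb:jsa] == revcomp(ref.sequence[jsb:jsa])
    ref_ssc = {f.name: f.strand for f in ref.features
               if jsb <= f.start and f.end <= jsa}
    new_ssc = {f.name: f.strand for f in genome.features
               if jsb <= f.start and f.end <= jsa}
    assert ref_ssc.keys() == new_ssc.keys()
    assert all(new_ssc[k] != ref_ssc[k] for k in ref_ssc)


def test_igs_transition_transversion_ratio_matches_kappa():
    """Realized ts/tv across seeds ~ kappa/2 within 3 SE (binomial)."""
    kappa = 2.0
    p_ts = kappa / (kappa + 2.0)
    ts = tv = 0
    for seed in range(30):
        cfg = SimulationConfig(seed=seed, species=(
            SpeciesSpec(name="m", igs_sub_rate=0.08, kappa=kappa),))
        ref, layout = make_reference(cfg)
        _, truth = degrade(ref, layout, cfg.species[0], cfg.seed)
        for t, v in truth.igs_substitutions.values():
            ts += t
            tv += v
    n = ts + tv
    assert n > 500
    se = math.sqrt(p_ts * (1 - p_ts) / n)
    assert abs(ts / n - p_ts) <= 3 * se


def test_degraded_genomes_roundtrip_through_genbank(tmp_path, bundle):
    _, genomes, _ = bundle
    for sp, g in genomes.items():
        path = tmp_path / f"{sp}.gb"
        write_genbank(g, path)
        back = read_genbank(path)
        assert back.sequence == g.sequence
        assert {(f.name, f.intervals, f.strand, f.kind) for f in back.features} \
            == {(f.name, f.intervals, f.strand, f.kind) for f in g.features}


def test_plant_marker_truth_structure(bundle):
    _, genomes, manifest = bundle
    sites = next(iter(manifest.species.values())).diagnostic_sites
    assert sum(1 for s in sites if s["kind"] == "SNP") == 9
    assert sum(1 for s in sites if s["kind"] == "indel") == 3
    by_species = {}
    for s in sites:
        by_species.setdefault(s["species"], 0)
        by_species[s["species"]] += 1
    assert set(by_species) == set(genomes)  # round-robin reaches everyone
    assert max(by_species.values()) - min(by_species.values()) <= 1


def test_plant_marker_insufficient_spacer_rejected(bundle):
    _, genomes, _ = bundle
    with pytest.raises(ValueError, match="insufficient spacer length"):
        plant_marker(dict(genomes), k_snps=200, m_indels=100, flank_len=50,
                     seed=0)


def test_marker_flank_deletion_conflict_rejected():
    cfg0 = default_scenario(seed=13)
    ref, layout = make_reference(cfg0)
    flank = layout.marker_flanks[0]
    bad_species = tuple(
        dataclasses.replace(s, deleted_genes=(flank,)) for s in cfg0.species)
    cfg = dataclasses.replace(cfg0, species=bad_species, marker=(2, 1, 20))
    with pytest.raises(ValueError, match="flank"):
        simulate_bundle(cfg)


def test_invalid_rates_rejected():
    with pytest.raises(ValueError):
        SpeciesSpec(name="x", deletion_rate=1.5)
    with pytest.raises(ValueError):
        SpeciesSpec(name="x", kappa=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(seed=0, species=(SpeciesSpec(name="x", ir_delta=99999),))
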
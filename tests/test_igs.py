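"""Shared spacer extraction and K2p divergence ranking."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plastdrift.align import global_align
from plastdrift.igs import extract_shared_igs, k2p_distance, rank_igs
from plastdrift.io import AnnotatedPlastome, GeneFeature
from plastdrift.simulate import SpeciesSpec, default_scenario, simulate_bundle


def _toy(id_, gene_order, spacer_seqs, rng):
    """Plastome with named 30-nt genes separated by the given spacers."""
    parts, feats, pos = [], [], 0
    genes = {g: "".join("ACGT"[i] for i in rng.integers(0, 4, size=30))
             for g in set(gene_order)}
    for gene, spacer in zip(gene_order, spacer_seqs):
        feats.append(GeneFeature(gene, "CDS", ((pos, pos + 30),), "+"))
        parts.append(genes[gene])
        parts.append(spacer)
        pos += 30 + len(spacer)
    return AnnotatedPlastome(id_, "".join(parts), features=feats)


def test_single_plastome_all_spacers_shared():
    rng = np.random.default_rng(0)
    p = _toy("a", ["g1", "g2", "g3"], ["AAAA", "CCCC", "GGGG"], rng)
    regions = extract_shared_igs([p])
    names = {r.name for r in regions}
    assert names == {"g1-g2", "g2-g3", "g3-g1"}  # wrap spacer included


def test_rearrangement_breaks_shared_adjacency():
    rng = np.random.default_rng(1)
    a = _toy("a", ["g1", "g2", "g3", "g4"], ["AAAA"] * 4, rng)
    b = _toy("b", ["g1", "g3", "g2", "g4"], ["AAAA"] * 4, rng)
    names = {r.name for r in extract_shared_igs([a, b])}
    assert "g1-g2" not in names
    assert "g2-g3" in names  # unordered pair still adjacent in both


def test_fewer_than_two_features_rejected():
    p = AnnotatedPlastome("x", "ACGT" * 50,
                          features=[GeneFeature("g", "CDS", ((0, 12),), "+")])
    with pytest.raises(ValueError):
        extract_shared_igs([p])


def test_reversed_flank_order_is_reverse_complemented():
    rng = np.random.default_rng(2)
    spacer = "AACCGGTTAACCGGTTACGT"
    a = _toy("a", ["g1", "g2", "g9"], [spacer, "TTTT", "CCCC"], rng)
    b = _toy("b", ["g2", "g1", "g9"], [spacer, "TTTT", "CCCC"], rng)
    # in b the g1-g2 adjacency runs g2->g1, so its spacer must come back
    # reverse-complemented to align with a's orientation
    regions = {r.name: r for r in extract_shared_igs([a, b])}
    region = regions["g1-g2"]
    from plastdrift.io import revcomp
    assert region.per_species["a"][2] == spacer
    assert region.per_species["b"][2] == revcomp(spacer)


def test_k2p_identical_sequences():
    res = k2p_distance(("ACGTACGT", "ACGTACGT"))
    assert (res.P, res.Q, res.d) == (0.0, 0.0, 0.0)
    assert res.sites == 8


def test_k2p_closed_form_evaluation():
    # 100 sites, exactly 10 transitions, 5 transversions
    a = "A" * 100
    b = "G" * 10 + "C" * 5 + "A" * 85
    res = k2p_distance((a, b))
    assert res.P == 0.1 and res.Q == 0.05
    expected = -0.5 * math.log((1 - 2 * 0.1 - 0.05) * math.sqrt(1 - 2 * 0.05))
    assert res.d == pytest.approx(expected, abs=1e-12)


def test_k2p_transitions_only_closed_form():
    a = "A" * 100
    b = "G" * 10 + "A" * 90
    res = k2p_distance((a, b))
    assert res.P == 0.1 and res.Q == 0.0
    assert res.d == pytest.approx(-0.5 * math.log(0.8), abs=1e-12)
    assert res.d == pytest.approx(0.11157177565710485, abs=1e-9)


def test_k2p_gap_and_ambiguity_columns_excluded():
    res = k2p_distance(("ACG-TN", "ACGCTA"))
    assert res.sites == 4


def test_k2p_saturation_and_empty_errors():
    with pytest.raises(ValueError, match="saturation"):
        k2p_distance(("A" * 10, "G" * 10))
    with pytest.raises(ValueError):
        k2p_distance(("----", "AC-G"))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=20, max_size=40))
def test_k2p_symmetry(seq):
    rng = np.random.default_rng(len(seq))
    other = list(seq)
    for i in rng.integers(0, len(seq), size=3):
        other[i] = "ACGT"[int(rng.integers(0, 4))]
    other = "".join(other)
    try:
        d_ab = k2p_distance((seq, other)).d
        d_ba = k2p_distance((other, seq)).d
    except ValueError:
        return
    assert d_ab == pytest.approx(d_ba)


def _evolve_k2p(rng, seq, p_ts, p_tv):
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    transversions = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
    out = []
    for ch in seq:
        u = rng.random()
        if u < p_ts:
            out.append(transitions[ch])
        elif u < p_ts + p_tv:
            out.append(transversions[ch][int(rng.integers(0, 2))])
        else:
            out.append(ch)
    return "".join(out)


def test_k2p_estimator_consistency_under_simulation():
    """Mean estimate within 3 SE of the closed-form value at 10 kb sites."""
    rng = np.random.default_rng(123)
    kappa = 2.0
    for m in (0.01, 0.05, 0.1):
        p_ts = m * kappa / (kappa + 2)
        p_tv = m * 2 / (kappa + 2)
        expected = -0.5 * math.log((1 - 2 * p_ts - p_tv) * math.sqrt(1 - 2 * p_tv))
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, size=10_000))
        est = [k2p_distance((base, _evolve_k2p(rng, base, p_ts, p_tv))).d
               for _ in range(12)]
        mean = float(np.mean(est))
        se = float(np.std(est, ddof=1) / math.sqrt(len(est)))
        assert abs(mean - expected) <= 3 * max(se, 1e-6), (m, mean, expected)


def test_rate_ordering_under_k2p_simulation():
    """Sequences evolved at rate 2r are on average more divergent than at r."""
    rng = np.random.default_rng(7)
    wins = 0
    for _ in range(20):
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, size=2000))
        d1 = k2p_distance((base, _evolve_k2p(rng, base, 0.01, 0.005))).d
        d2 = k2p_distance((base, _evolve_k2p(rng, base, 0.02, 0.01))).d
        wins += d2 > d1
    assert wins >= 15


def test_identical_regions_rank_zero_sorted_by_name():
    rng = np.random.default_rng(3)
    a = _toy("a", ["g1", "g2", "g3"], ["AAAACC", "CCCCAA", "GGGGTT"], rng)
    b = _toy("b", ["g1", "g2", "g3"], ["AAAACC", "CCCCAA", "GGGGTT"], rng)
    df, _ = rank_igs(extract_shared_igs([a, b]))
    assert (df.d_mean == 0).all()
    assert list(df.region) == sorted(df.region)


def test_planted_hypervariable_spacer_ranks_first():
    cfg = default_scenario(seed=5, n_species=4)
    # noise-free structure, divergence only in spacers
    species = tuple(
        SpeciesSpec(name=s.name, igs_sub_rate=0.01, kappa=2.0,
                    hypervariable_igs=("auto", 12.0))
        for s in cfg.species)
    cfg = type(cfg)(seed=5, species=species)
    _, genomes, manifest = simulate_bundle(cfg)
    hyper_names = set()
    for sp in genomes:
        subs = manifest.species[sp].igs_substitutions
        hyper_names.add(max(subs, key=lambda k: sum(subs[k])))
    assert len(hyper_names) == 1  # same spacer hypervariable in all species
    regions = extract_shared_igs(list(genomes.values()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        df, _ = rank_igs(regions)
    assert df.iloc[0]["region"] == hyper_names.pop()
    assert df.iloc[0]["d_mean"] > df.iloc[1]["d_mean"]


def test_rank_igs_distmat_scaling_column():
    rng = np.random.default_rng(4)
    a = _toy("a", ["g1", "g2"], ["AAAAAAAATT", "CCCC"], rng)
    b = _toy("b", ["g1", "g2"], ["AAAAAAAAGT", "CCCC"], rng)
    df, results = rank_igs(extract_shared_igs([a, b]))
    assert np.allclose(df.d_mean_pct, df.d_mean * 100)
    for r in results:
        assert r.d >= 0
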
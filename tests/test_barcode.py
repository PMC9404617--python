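"""Diagnostic sites, conserved primer search and discrimination."""

import numpy as np
import pytest

from plastdrift.barcode import (build_msa, diagnostic_sites,
                                discrimination_matrix, primer_search)
from plastdrift.igs import extract_shared_igs
from plastdrift.simulate import default_scenario, plant_marker, simulate_bundle


def test_msa_of_identical_sequences_is_gap_free():
    msa = build_msa({"a": "ACGTACGTT", "b": "ACGTACGTT", "c": "ACGTACGTT"})
    assert all(r == "ACGTACGTT" for r in msa.values())


def test_all_identical_msa_yields_no_sites():
    msa = {"a": "ACGTACGT", "b": "ACGTACGT", "c": "ACGTACGT"}
    assert diagnostic_sites(msa) == []


def test_planted_private_snps_and_deletion():
    base = "ACGTTACGGATCCATTGGCAACGATCGGATA"
    a = base[:5] + "T" + base[6:20] + "G" + base[21:]  # two private SNPs
    assert base[5] != "T" and base[20] != "G"
    b = base[:10] + base[13:]  # private 3-nt deletion
    msa = build_msa({"A": a, "B": b, "C": base, "D": base})
    sites = diagnostic_sites(msa)
    snps = [s for s in sites if s.kind == "SNP"]
    indels = [s for s in sites if s.kind == "indel"]
    assert len(snps) == 2 and all(s.species == "A" for s in snps)
    assert len(indels) == 1 and indels[0].species == "B"
    assert indels[0].state == "---"


def test_shared_variant_is_not_diagnostic():
    msa = {"a": "ACGTA", "b": "ACTTA", "c": "ACTTA", "d": "ACGTA"}
    assert diagnostic_sites(msa) == []


def test_ambiguous_columns_skipped():
    msa = {"a": "ACNTA", "b": "ACNTA", "c": "ACNTG"}
    sites = diagnostic_sites(msa)
    assert [s.column for s in sites] == [4]


def test_diagnostic_needs_three_species():
    with pytest.raises(ValueError):
        diagnostic_sites({"a": "ACGT", "b": "ACTT"})


def _marker_toy(rng, private_for=("w", "x", "y")):
    """Exactly one conserved 20-mer pair ~300 nt apart enclosing private
    SNPs.  Every 12th core column carries 2-vs-2 variation (neither
    conserved nor diagnostic), so no other conserved window reaches
    primer length."""
    def rand(n):
        return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))

    fwd = "ATGCATGCATACGTACGTAC"  # GC 0.5
    rev = "GTCAGTCAGTGACTGACTGA"
    core = rand(260)
    snp_cols = {"w": 41, "x": 121, "y": 201, "z": 231}
    rows = {sp: list(core) for sp in ("w", "x", "y", "z")}
    for col in list(range(0, 260, 12)) + [259]:
        base = core[col]
        alt = "A" if base != "A" else "G"
        rows["w"][col] = rows["x"][col] = base
        rows["y"][col] = rows["z"][col] = alt
    for sp in private_for:
        col = snp_cols[sp]
        base = rows[sp][col]
        rows[sp][col] = "A" if base != "A" else "C"
    seqs = {sp: fwd + "".join(r) + rev for sp, r in rows.items()}
    return seqs, fwd, rev


def test_constructed_primer_pair_recovered_with_score_3():
    rng = np.random.default_rng(21)
    seqs, fwd, rev = _marker_toy(rng)
    msa = build_msa(seqs)
    cands = primer_search(msa, region="toy", min_len=100, max_len=1000)
    assert len(cands) >= 1
    top = cands[0]
    assert top.score == 3
    assert top.forward_primer == fwd
    from plastdrift.io import revcomp
    assert top.reverse_primer == revcomp(rev)
    assert all(100 <= L <= 1000 for L in top.product_lengths.values())


def test_product_length_bounds_enforced():
    rng = np.random.default_rng(22)
    seqs, _, _ = _marker_toy(rng)
    msa = build_msa(seqs)
    assert primer_search(msa, min_len=100, max_len=250) == [] or all(
        L <= 250 for c in primer_search(msa, min_len=100, max_len=250)
        for L in c.product_lengths.values())
    # the 300-nt product is rejected when max_len is 250 and recovered at 1000
    long_ok = primer_search(msa, min_len=100, max_len=1000)
    assert any(c.score == 3 for c in long_ok)


def test_single_species_candidates_bounded_only_by_length():
    seq = "ATGC" * 100  # 400 nt, one fully conserved "alignment"
    cands = primer_search({"only": seq}, min_len=100, max_len=1000)
    assert len(cands) >= 1
    for c in cands:
        assert 100 <= c.product_lengths["only"] <= 1000
        assert c.score == 0


def test_gc_filter_rejects_extreme_primers():
    # conserved runs exist but are AT-only: no primer passes the GC filter
    seqs = {sp: "AT" * 40 + "ACGG" + "AT" * 40 for sp in "abc"}
    assert primer_search(build_msa(seqs), min_len=100, max_len=1000) == []


def test_no_conserved_window_warns():
    rng = np.random.default_rng(30)
    seqs = {sp: "".join("ACGT"[i] for i in rng.integers(0, 4, size=120))
            for sp in "abc"}
    with pytest.warns(UserWarning, match="no conserved"):
        cands = primer_search(build_msa(seqs), min_len=20, max_len=1000)
    assert cands == []


def test_discrimination_matrix_partial_coverage():
    # only species w carries a private site: pairs among x, y, z are
    # indistinguishable, pairs involving w are separated
    rng = np.random.default_rng(23)
    seqs, _, _ = _marker_toy(rng, private_for=("w",))
    msa = build_msa(seqs)
    cands = primer_search(msa, min_len=100, max_len=1000)
    species = list(seqs)
    dm, success = discrimination_matrix(cands, species)
    assert not success
    assert dm.loc["w", "x"] and dm.loc["w", "y"] and dm.loc["w", "z"]
    assert not dm.loc["x", "y"] and not dm.loc["x", "z"] and not dm.loc["y", "z"]
    assert (dm.values == dm.values.T).all()
    assert dm.values.diagonal().all()


def test_sites_for_all_but_one_species_still_separate_every_pair():
    # one-vs-rest semantics: a site private to w separates w from z too,
    # so three private sites across four species already discriminate all
    rng = np.random.default_rng(24)
    seqs, _, _ = _marker_toy(rng, private_for=("w", "x", "y"))
    cands = primer_search(build_msa(seqs), min_len=100, max_len=1000)
    _, success = discrimination_matrix(cands, list(seqs))
    assert success


def test_every_species_with_private_site_gives_full_discrimination(bundle):
    _, genomes, manifest = bundle
    regions = extract_shared_igs(list(genomes.values()))
    truth_sites = next(iter(manifest.species.values())).diagnostic_sites
    region_name = truth_sites[0]["region"]
    region = next(r for r in regions if r.name == region_name)
    msa = build_msa({sp: region.per_species[sp][2] for sp in genomes})
    sites = diagnostic_sites(msa)
    assert sum(1 for s in sites if s.kind == "SNP") == 9
    assert sum(1 for s in sites if s.kind == "indel") == 3
    found = {(s.kind, s.species) for s in sites}
    planted = {(t["kind"], t["species"]) for t in truth_sites}
    assert found == planted
    cands = primer_search(msa, region=region_name, min_len=100, max_len=1000)
    dm, success = discrimination_matrix(cands, list(genomes))
    assert success


@pytest.mark.parametrize("seed", [3, 4, 5])
def test_planted_marker_recovery_across_seeds(seed):
    cfg = default_scenario(seed=seed, marker=(9, 3, 30))
    _, genomes, manifest = simulate_bundle(cfg)
    regions = extract_shared_igs(list(genomes.values()))
    region_name = next(iter(manifest.species.values())).diagnostic_sites[0]["region"]
    region = next(r for r in regions if r.name == region_name)
    msa = build_msa({sp: region.per_species[sp][2] for sp in genomes})
    sites = diagnostic_sites(msa)
    assert sum(1 for s in sites if s.kind == "SNP") == 9
    assert sum(1 for s in sites if s.kind == "indel") == 3


def test_primers_rescanned_in_raw_sequences(bundle):
    _, genomes, manifest = bundle
    regions = extract_shared_igs(list(genomes.values()))
    region_name = next(iter(manifest.species.values())).diagnostic_sites[0]["region"]
    region = next(r for r in regions if r.name == region_name)
    seqs = {sp: region.per_species[sp][2] for sp in genomes}
    cands = primer_search(build_msa(seqs), min_len=100, max_len=1000)
    from plastdrift.io import revcomp
    for c in cands:
        for sp, raw in seqs.items():
            assert c.forward_primer in raw
            assert revcomp(c.reverse_primer) in raw


def test_discrimination_requires_candidates():
    with pytest.raises(ValueError):
        discrimination_matrix([], ["a", "b"])
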
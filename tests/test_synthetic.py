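"""Generator guarantees: determinism, GC targets, planted truth integrity."""

import numpy as np
import pytest

from paravirome import synthetic as syn
from paravirome.screen import gc_content


def test_host_genome_is_deterministic_and_hits_gc_target():
    spec = syn.HostGenomeSpec(length=50_000, gc_target=63.0)
    seq1, feats1 = syn.generate_host_genome(spec, 42)
    seq2, feats2 = syn.generate_host_genome(spec, 42)
    assert seq1 == seq2
    assert feats1 == feats2
    assert len(seq1) == 50_000
    assert 61.5 <= gc_content(seq1) <= 64.5


def test_gc_target_zero_yields_pure_at():
    seq, _ = syn.generate_host_genome(syn.HostGenomeSpec(length=2_000, gc_target=0.0), 1)
    assert set(seq) <= {"A", "T"}


def test_host_features_are_non_overlapping_and_in_bounds():
    spec = syn.HostGenomeSpec(length=20_000, gc_target=60.0, trna_genes=((9_000, 76, "t1"), (15_000, 80, "t2")))
    _, feats = syn.generate_host_genome(spec, 5)
    ordered = sorted(feats, key=lambda f: f.start)
    assert all(f.start >= 1 and f.end <= 20_000 for f in ordered)
    assert all(a.end < b.start for a, b in zip(ordered, ordered[1:]))
    assert sum(f.feature_type == "tRNA" for f in ordered) == 2


def test_infeasible_cds_density_raises():
    with pytest.raises(RuntimeError, match="cds_density"):
        syn.generate_host_genome(syn.HostGenomeSpec(length=3_000, gc_target=60.0, cds_density=10.0), 0)


def test_integration_duplicates_att_core_at_trna_3_prime_end():
    spec = syn.HostGenomeSpec(length=15_000, gc_target=63.0, trna_genes=((7_000, 76, "tRNA-Met(CAT)"),))
    host, feats = syn.generate_host_genome(spec, 11)
    trna = next(f for f in feats if f.feature_type == "tRNA")
    pspec = syn.ProphageSpec(length=3_000, gc_target=58.0, att_core_length=20)
    lys, lfeats, truth = syn.simulate_integration(host, feats, pspec, "trna_1", 12)
    assert len(lys) == len(host) + 3_000 + 20
    # attL ends exactly at the original tRNA 3' terminus
    assert truth.attL_interval[1] == trna.end
    for iv in (truth.attL_interval, truth.attR_interval):
        assert lys[iv[0] - 1 : iv[1]] == truth.att_core
    assert truth.att_core == host[trna.end - 20 : trna.end]
    assert truth.site_class == "tRNA"
    # all five hallmark modules are present among the planted genes
    assert {"integration", "lysogeny_switch", "packaging", "head_tail", "lysis"} <= set(
        truth.gene_modules.values()
    )


def test_cds_target_is_flagged_disrupted():
    spec = syn.HostGenomeSpec(length=15_000, gc_target=63.0)
    host, feats = syn.generate_host_genome(spec, 21)
    cds = next(f for f in feats if f.feature_type == "CDS" and f.length > 600)
    pspec = syn.ProphageSpec(length=3_000, gc_target=58.0, att_core_length=15)
    _, lfeats, truth = syn.simulate_integration(host, feats, pspec, cds.id, 22)
    assert truth.site_class == "gene_disruption"
    disrupted = [f for f in lfeats if f.disrupted]
    assert [f.id for f in disrupted] == [cds.id]


def test_zero_length_core_intergenic_insertion_has_no_repeats():
    spec = syn.HostGenomeSpec(length=15_000, gc_target=63.0)
    host, feats = syn.generate_host_genome(spec, 31)
    pspec = syn.ProphageSpec(length=3_000, gc_target=58.0, att_core_length=0)
    lys, _, truth = syn.simulate_integration(host, feats, pspec, "intergenic", 32)
    assert truth.att_core == ""
    assert truth.attL_interval is None and truth.attR_interval is None
    assert len(lys) == len(host) + 3_000


def test_target_shorter_than_core_raises():
    spec = syn.HostGenomeSpec(length=15_000, gc_target=63.0, trna_genes=((7_000, 40, "t"),))
    host, feats = syn.generate_host_genome(spec, 41)
    pspec = syn.ProphageSpec(length=3_000, gc_target=58.0, att_core_length=60)
    with pytest.raises(ValueError, match="shorter than att core"):
        syn.simulate_integration(host, feats, pspec, "trna_1", 42)


def test_mutate_to_identity_is_exact_by_position_count():
    rng = np.random.default_rng(0)
    base = syn.random_protein(300, rng)
    assert syn.mutate_to_identity(base, 100.0, 1) == base
    mutated = syn.mutate_to_identity(base, 85.0, 2)
    assert len(mutated) == len(base)
    identity = 100.0 * sum(a == b for a, b in zip(base, mutated)) / len(base)
    assert 83.0 <= identity <= 87.0


def test_mutate_to_identity_zero_forces_full_divergence():
    rng = np.random.default_rng(3)
    base = "".join(rng.choice(["A", "B"], size=200))
    mutated = syn.mutate_to_identity(base, 0.0, 4, alphabet="AB")
    # substitutions always pick a different symbol, so identity collapses
    identity = sum(a == b for a, b in zip(base, mutated)) / len(base)
    assert identity == 0.0


def test_proteome_clusters_plant_exactly_the_shared_matrix():
    shared = np.array([[0, 3, 0], [3, 0, 1], [0, 1, 0]])
    proteomes, truth = syn.generate_proteome_clusters(3, shared, 100.0, seed=9, n_background=2)
    by_pair = {}
    for rec in truth:
        key = tuple(sorted((rec["phage_a"], rec["phage_b"])))
        by_pair[key] = by_pair.get(key, 0) + 1
    assert by_pair == {("phage1", "phage2"): 3, ("phage2", "phage3"): 1}
    assert len(proteomes["phage1"]) == 3 + 2  # planted + background
    none, truth0 = syn.generate_proteome_clusters(2, np.zeros((2, 2), int), seed=1)
    assert truth0 == []


def test_proteome_clusters_reject_asymmetric_matrix():
    with pytest.raises(ValueError, match="symmetric"):
        syn.generate_proteome_clusters(2, np.array([[0, 1], [2, 0]]))
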
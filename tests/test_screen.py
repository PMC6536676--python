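"""Completeness screen, GC content/boundaries, MTase locus context."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from paravirome import synthetic as syn
from paravirome.features import GeneFeature, categorize_product
from paravirome.screen import (
    REQUIRED_MODULES,
    assess_completeness,
    classify_mtase_locus,
    gc_content,
    refine_boundaries_by_gc,
)


def _genes(categories, strand="+"):
    return [
        GeneFeature(f"g{i}", "c", 1 + i * 1000, 900 + i * 1000, strand, "CDS", cat)
        for i, cat in enumerate(categories)
    ]


def test_all_five_modules_present_is_complete():
    report = assess_completeness(_genes(sorted(REQUIRED_MODULES)))
    assert report.complete
    assert report.missing_modules == frozenset()


def test_missing_lysis_reported():
    report = assess_completeness(_genes(["integration", "lysogeny_switch", "packaging", "head_tail"]))
    assert not report.complete
    assert report.missing_modules == {"lysis"}


def test_empty_region_misses_everything():
    report = assess_completeness([])
    assert report.missing_modules == REQUIRED_MODULES


def test_completeness_is_monotone_under_added_features():
    base = _genes(["integration", "lysis"])
    extra = _genes(["packaging", "head_tail", "lysogeny_switch"])
    before = assess_completeness(base).present_modules
    after = assess_completeness(base + extra).present_modules
    assert before <= after


def test_gc_content_extremes_and_counting_oracle():
    assert gc_content("GCGC") == 100.0
    assert gc_content("ATAT") == 0.0
    seq = syn.random_sequence(10_000, 58.0, np.random.default_rng(17))
    brute = 100.0 * sum(c in "GC" for c in seq) / len(seq)
    assert gc_content(seq) == pytest.approx(brute)


def test_gc_content_skips_ambiguity_codes():
    assert gc_content("GCNN") == 100.0
    with pytest.raises(ValueError):
        gc_content("NNNN")


@given(st.integers(0, 2**31 - 1))
def test_gc_of_concatenation_is_between_parts(seed):
    rng = np.random.default_rng(seed)
    a = syn.random_sequence(int(rng.integers(50, 500)), float(rng.uniform(10, 90)), rng)
    b = syn.random_sequence(int(rng.integers(50, 500)), float(rng.uniform(10, 90)), rng)
    lo, hi = sorted((gc_content(a), gc_content(b)))
    assert lo - 1e-9 <= gc_content(a + b) <= hi + 1e-9


def _gc_fixture(seed, host_gc=65.0, phage_gc=58.0):
    spec = syn.HostGenomeSpec(length=12_000, gc_target=host_gc, trna_genes=((6_000, 76, "t"),))
    host, feats = syn.generate_host_genome(spec, seed)
    pspec = syn.ProphageSpec(length=4_000, gc_target=phage_gc, att_core_length=20)
    return syn.simulate_integration(host, feats, pspec, "trna_1", seed + 1)


def test_planted_gc_island_is_recovered_within_one_window():
    lys, _, truth = _gc_fixture(101)
    refined, flagged, profile = refine_boundaries_by_gc(lys, truth.prophage_interval)
    assert flagged
    assert abs(refined[0] - truth.prophage_interval[0]) <= profile.window
    assert abs(refined[1] - truth.prophage_interval[1]) <= profile.window


def test_no_contrast_returns_rough_interval_with_flag():
    lys, _, truth = _gc_fixture(102, host_gc=63.0, phage_gc=63.0)
    refined, flagged, _ = refine_boundaries_by_gc(lys, truth.prophage_interval)
    assert not flagged
    assert refined == truth.prophage_interval


def test_degenerate_refinement_parameters_rejected():
    lys, _, truth = _gc_fixture(103)
    with pytest.raises(ValueError, match="min_contrast"):
        refine_boundaries_by_gc(lys, truth.prophage_interval, min_contrast=0.0)
    with pytest.raises(ValueError, match="window"):
        refine_boundaries_by_gc(lys, (5_000, 5_400), window=1_000)
    with pytest.raises(ValueError, match="outside"):
        refine_boundaries_by_gc(lys, (0, 100))


def test_mtase_between_parb_and_large_terminase_is_parb_tls():
    genes = _genes(["other", "parB_like", "mtase", "other", "terminase_large", "packaging"])
    assert classify_mtase_locus(genes[2], genes) == "ParB_Tls"


def test_mtase_next_to_replication_module():
    genes = _genes(["other", "replication", "mtase", "other", "other"])
    assert classify_mtase_locus(genes[2], genes) == "near_replication"


def test_mtase_integrase_orientation_rules():
    down = _genes(["integration", "mtase", "other", "other"])
    assert classify_mtase_locus(down[1], down) == "downstream_integrase"
    up = _genes(["other", "other", "mtase", "integration"])
    assert classify_mtase_locus(up[2], up) == "upstream_integrase"
    after_lysis = _genes(["lysis", "mtase", "other"])
    assert classify_mtase_locus(after_lysis[1], after_lysis) == "downstream_lysis"


def test_mtase_with_no_module_in_window_is_other():
    # three intervening genes exceed the default two-gene proximity window
    genes = _genes(["other", "other", "mtase", "other", "other", "other", "integration"])
    assert classify_mtase_locus(genes[2], genes, proximity_genes=2) == "other"


def test_minus_strand_mtase_mirrors_downstream_logic():
    # on the minus strand "downstream" runs toward lower coordinates
    genes = _genes(["other", "mtase", "integration"], strand="-")
    assert classify_mtase_locus(genes[1], genes) == "downstream_integrase"


def test_product_keyword_mapping_is_overridable():
    assert categorize_product("site-specific tyrosine integrase") == "integration"
    assert categorize_product("terminase large subunit") == "terminase_large"
    assert categorize_product("hypothetical protein") == "other"
    assert categorize_product("weird protein", [("weird", "lysis")]) == "lysis"
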
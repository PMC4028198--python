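from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mzgroupnet.formula import ElementalComposition, delta_mass, parse_formula
from mzgroupnet.matching import (
    detect_transformations,
    discover_unlisted,
    rank_rule_frequencies,
)
from mzgroupnet.rules import TransformationRule, rule_by_name

from conftest import make_feature

EC = ElementalComposition


def naive_detect(features, rules, time_filter=True):
    """Independent oracle: quadruple loop over (pair, candidate pair, rule)."""
    edges = set()
    for fa, fb in itertools.permutations(features, 2):
        if time_filter and fa.first_time > fb.first_time:
            continue
        for ca in fa.candidates:
            for cb in fb.candidates:
                diff = cb.composition - ca.composition
                for rule in rules:
                    if diff == rule.delta:
                        edges.add((fa.id, fb.id, rule.name))
    return edges


# ---------------------------------------------------------------------------
# worked examples
# ---------------------------------------------------------------------------

def test_flavonol_hydroxylation_pair(all_rules):
    kaempferol = make_feature("kaempferol", ["C15H11O6"], time_points=(0,))
    quercetin = make_feature("quercetin", ["C15H11O7"], time_points=(0,))
    edges = detect_transformations([kaempferol, quercetin], all_rules)
    hits = [e for e in edges if e.rule == "mono-oxygenation"]
    assert len(hits) == 1
    assert (hits[0].source, hits[0].target) == ("kaempferol", "quercetin")


def test_hexosylation_between_tabulated_glycosides(all_rules):
    a13 = make_feature("A13", ["C35H35O17"], time_points=(4,))
    a3 = make_feature("A3", ["C41H45O22"], time_points=(4,))
    edges = detect_transformations([a13, a3], all_rules)
    assert [(e.source, e.target, e.rule) for e in edges] == [("A13", "A3", "hexosylation")]


def test_time_filter_discards_backward_edges(all_rules):
    late = make_feature("late", ["C15H11O6"], time_points=(2,))
    early = make_feature("early", ["C15H11O7"], time_points=(1,))
    filtered = detect_transformations([late, early], all_rules, time_filter=True)
    # the backward mono-oxygenation late->early is discarded; the forward
    # early->late deoxygenation (-O is its own rule) survives
    assert [(e.source, e.target, e.rule) for e in filtered] == [
        ("early", "late", "deoxygenation")
    ]
    unfiltered = detect_transformations([late, early], all_rules, time_filter=False)
    assert ("late", "early", "mono-oxygenation") in {
        (e.source, e.target, e.rule) for e in unfiltered
    }


def test_equal_first_time_is_allowed(all_rules):
    a = make_feature("a", ["C15H11O6"], time_points=(3,))
    b = make_feature("b", ["C15H11O7"], time_points=(3,))
    edges = detect_transformations([a, b], all_rules)
    assert [(e.source, e.target, e.rule) for e in edges] == [
        ("a", "b", "mono-oxygenation"),
        ("b", "a", "deoxygenation"),
    ]


def test_candidate_pairs_collapse_to_one_edge():
    rules = [TransformationRule("mono-oxygenation", EC({"O": 1}))]
    a = make_feature("a", ["C15H11O6", "C20H20O5"])
    b = make_feature("b", ["C15H11O7", "C20H20O6"])
    edges = detect_transformations([a, b], rules)
    assert len(edges) == 1
    assert len(edges[0].support) == 2
    # best-ranked supporting pair is recorded on the edge itself
    assert edges[0].source_formula == parse_formula("C15H11O6")


def test_directed_deltas_no_free_reverse():
    rules = [TransformationRule("hexosylation", EC({"C": 6, "H": 10, "O": 5}))]
    a = make_feature("a", ["C15H11O6"])
    b = make_feature("b", ["C21H21O11"])
    edges = detect_transformations([a, b], rules)
    assert [(e.source, e.target) for e in edges] == [("a", "b")]


def test_feature_without_candidates_skipped(all_rules, caplog):
    a = make_feature("a", ["C15H11O6"])
    bare = make_feature("bare", ["C15H11O7"])
    bare.candidates = []
    with caplog.at_level("WARNING"):
        edges = detect_transformations([a, bare], all_rules)
    assert edges == []
    assert "bare" in caplog.text


def test_empty_rule_set_is_error():
    with pytest.raises(ValueError):
        detect_transformations([make_feature("a", ["C2H4"])], [])


def test_duplicate_feature_ids_rejected(all_rules):
    with pytest.raises(ValueError):
        detect_transformations(
            [make_feature("x", ["C2H4"]), make_feature("x", ["C2H4O"])], all_rules
        )


# ---------------------------------------------------------------------------
# rule frequency ranking
# ---------------------------------------------------------------------------

def test_rank_rule_frequencies_counts_and_order(all_rules):
    feats = [
        make_feature("a", ["C15H11O6"]),
        make_feature("b", ["C15H11O7"]),
        make_feature("c", ["C15H11O8"]),
        make_feature("d", ["C16H13O8"]),
    ]
    edges = detect_transformations(feats, all_rules)
    table = rank_rule_frequencies(edges, all_rules)
    counts = dict(table)
    assert counts["mono-oxygenation"] == 2  # a->b, b->c
    assert counts["methylation"] == 1  # c->d
    assert table[0][0] == "mono-oxygenation"
    assert sum(counts.values()) == len(edges)


def test_rank_rule_frequencies_empty():
    assert rank_rule_frequencies([]) == []


def test_rank_ties_follow_rule_file_order(all_rules):
    from mzgroupnet.matching import TransformationEdge

    comp = parse_formula("C15H11O6")
    mk = lambda rule: TransformationEdge("a", "b", rule, comp, comp)
    # hydration (row 3) precedes methylation (row 5) in the default file
    edges = [mk("methylation"), mk("hydration")]
    table = rank_rule_frequencies(edges, all_rules)
    assert table == [("hydration", 1), ("methylation", 1)]


# ---------------------------------------------------------------------------
# unlisted-difference mining
# ---------------------------------------------------------------------------

def test_discover_unlisted_constructed_case():
    rules = [TransformationRule("mono-oxygenation", EC({"O": 1}))]
    feats = [
        make_feature("a1", ["C10H10O2"]),
        make_feature("a2", ["C12H12O3"]),  # +C2H2O1 from a1 (acetylation, unlisted)
        make_feature("b1", ["C20H20O5"]),
        make_feature("b2", ["C22H22O6"]),  # +C2H2O1 from b1
    ]
    found = discover_unlisted(feats, rules, min_count=2, max_delta_mass=300.0)
    acetyl = [u for u in found if u.delta == EC({"C": 2, "H": 2, "O": 1})]
    assert len(acetyl) == 1
    assert acetyl[0].occurrence_count == 2
    assert set(acetyl[0].example_pairs) == {("a1", "a2"), ("b1", "b2")}


def test_discover_unlisted_excludes_listed_rules(all_rules):
    feats = [make_feature("a", ["C15H11O6"]), make_feature("b", ["C15H11O7"])]
    found = discover_unlisted(feats, all_rules, min_count=1, max_delta_mass=300.0)
    assert all(u.delta != EC({"O": 1}) for u in found)
    assert found == []  # the only difference is a listed rule


def test_discover_unlisted_finds_removed_rule(all_rules):
    without_pentosylation = [r for r in all_rules if r.name != "pentosylation"]
    feats = [
        make_feature("m595", ["C30H27O13"], time_points=(0,)),
        make_feature("m727", ["C35H35O17"], time_points=(0,)),
    ]
    found = discover_unlisted(feats, without_pentosylation, min_count=1, max_delta_mass=300.0)
    deltas = {u.delta for u in found}
    assert EC({"C": 5, "H": 8, "O": 4}) in deltas


def test_discover_unlisted_respects_mass_cap():
    feats = [make_feature("a", ["C10H10O2"]), make_feature("b", ["C30H30O10"])]
    rules = [TransformationRule("mono-oxygenation", EC({"O": 1}))]
    assert discover_unlisted(feats, rules, min_count=1, max_delta_mass=100.0) == []


def test_discover_unlisted_min_count_validation():
    with pytest.raises(ValueError):
        discover_unlisted([], [], min_count=0)


# ---------------------------------------------------------------------------
# properties / oracle equivalence
# ---------------------------------------------------------------------------

def test_antisymmetry_single_candidates(all_rules):
    a = make_feature("a", ["C15H11O6"])
    b = make_feature("b", ["C15H11O7"])
    edges = detect_transformations([a, b], all_rules, time_filter=False)
    pairs = {(e.source, e.target, e.rule) for e in edges}
    assert ("a", "b", "mono-oxygenation") in pairs
    assert ("b", "a", "mono-oxygenation") not in pairs
    # the reverse direction appears exactly because -O is its own rule
    assert ("b", "a", "deoxygenation") in pairs


def test_time_filtered_edges_are_subset(all_rules):
    rng = np.random.default_rng(7)
    feats = _random_features(rng, n=10)
    filtered = detect_transformations(feats, all_rules, time_filter=True)
    unfiltered = detect_transformations(feats, all_rules, time_filter=False)
    keyed = lambda edges: {(e.source, e.target, e.rule) for e in edges}
    assert keyed(filtered) <= keyed(unfiltered)
    by_id = {f.id: f for f in feats}
    for e in filtered:
        assert by_id[e.source].first_time <= by_id[e.target].first_time


def _random_features(rng, n=8, max_candidates=3):
    feats = []
    for i in range(n):
        n_cands = int(rng.integers(1, max_candidates + 1))
        formulas = []
        for _ in range(n_cands):
            c = int(rng.integers(5, 25))
            h = int(rng.integers(4, 30))
            o = int(rng.integers(0, 12))
            formulas.append(f"C{c}H{h}O{o}" if o else f"C{c}H{h}")
        feats.append(
            make_feature(f"f{i}", formulas, time_points=(int(rng.integers(0, 4)),))
        )
    return feats


@pytest.mark.parametrize("seed", range(12))
def test_oracle_equivalence_random_features(all_rules, seed):
    rng = np.random.default_rng(seed)
    feats = _random_features(rng, n=int(rng.integers(4, 15)))
    got = {
        (e.source, e.target, e.rule)
        for e in detect_transformations(feats, all_rules, time_filter=True)
    }
    assert got == naive_detect(feats, all_rules, time_filter=True)


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=20, deadline=None)
def test_oracle_equivalence_property(all_rules, seed):
    rng = np.random.default_rng(seed)
    feats = _random_features(rng, n=int(rng.integers(2, 10)))
    for tf in (True, False):
        got = {
            (e.source, e.target, e.rule)
            for e in detect_transformations(feats, all_rules, time_filter=tf)
        }
        assert got == naive_detect(feats, all_rules, time_filter=tf)
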
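"""Target-map assembly and inverse-expression concordance."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cryptvillus.datasets import (
    load_reference_target_map,
    reference_case_with_decoys,
    reference_profiles,
)
from cryptvillus.differential import GradientProfile
from cryptvillus.errors import ConfigurationError, InputError
from cryptvillus.integration import (
    build_target_map,
    integrate,
    inverse_concordance,
    relation_of,
)

AXES = frozenset({"wt_axis", "ko_axis"})
LEVEL = {"up": 2.0, "down": 0.5, "same": 1.0}


def _axis_profile(name, wt, ko, tau=1.45):
    """Profile whose two axis directions are exactly (wt, ko)."""
    return GradientProfile(
        feature=name,
        levels={"WTV": 1.0, "WTC": LEVEL[wt], "KOV": 1.0, "KOC": LEVEL[ko]},
        comparable=AXES, tau=tau,
    )


# ---------------------------------------------------------------------------
# Target-map assembly

def test_single_source_map_equals_that_source():
    tm = build_target_map({"s1": [("m1", "G1"), ("m1", "G2")]})
    assert tm.pairs() == [("m1", "G1"), ("m1", "G2")]
    assert tm.sources("m1", "G1") == frozenset({"s1"})


def test_combine_rules_union_vs_intersection():
    sources = {
        "s1": [("m1", "G1"), ("m1", "G2")],
        "s2": [("m1", "G1")],
        "s3": [("m1", "G1")],
    }
    union = build_target_map(sources, "union")
    assert ("m1", "G2") in union
    strict = build_target_map(sources, "intersection-of-3")
    assert ("m1", "G1") in strict and ("m1", "G2") not in strict
    two = build_target_map(sources, "intersection-of-2")
    assert two.pairs() == [("m1", "G1")]


def test_unknown_combine_rule_rejected():
    with pytest.raises(ConfigurationError):
        build_target_map({"s1": [("m", "G")]}, "majority")


def test_empty_sources_rejected_and_empty_map_yields_no_candidates():
    with pytest.raises(ConfigurationError):
        build_target_map({})
    tm = build_target_map({"s1": []})
    report = integrate({}, {}, tm)
    assert report.verdicts == [] and report.qualifying == []


# ---------------------------------------------------------------------------
# Concordance rule

def _oracle_verdict(pairs):
    """Brute-force restatement: >=1 opposite and no concordant movement."""
    opposite = any(
        {m, p} == {"up", "down"} for m, p in pairs
    )
    concordant = any(m == p != "same" for m, p in pairs)
    return "qualifies" if opposite and not concordant else "rejected"


@pytest.mark.parametrize(
    ("m_wt", "m_ko", "p_wt", "p_ko"),
    list(itertools.product(("up", "same", "down"), repeat=4)),
)
def test_verdict_matches_enumeration_oracle(m_wt, m_ko, p_wt, p_ko):
    """All 3^2 x 3^2 axis-direction combinations agree with the rule."""
    v = inverse_concordance(
        _axis_profile("m", m_wt, m_ko), _axis_profile("P", p_wt, p_ko))
    assert v.verdict == _oracle_verdict([(m_wt, p_wt), (m_ko, p_ko)])


def test_relation_taxonomy():
    assert relation_of("up", "down") == "opposite"
    assert relation_of("down", "down") == "same"
    assert relation_of("same", "up") == "one-sided"
    assert relation_of("same", "same") == "both-same"


def test_no_comparable_comparison_is_rejected_with_reason():
    m = GradientProfile("m", {g: 1.0 for g in ("WTV", "WTC", "KOV", "KOC")},
                        comparable=frozenset({"wt_axis"}))
    p = GradientProfile("P", {g: 1.0 for g in ("WTV", "WTC", "KOV", "KOC")},
                        comparable=frozenset({"ko_axis"}))
    v = inverse_concordance(m, p)
    assert v.verdict == "rejected" and v.reason == "incomparable scales"


def test_flat_profiles_rejected_for_lack_of_opposition():
    v = inverse_concordance(_axis_profile("m", "same", "same"),
                            _axis_profile("P", "same", "same"))
    assert v.verdict == "rejected" and "no opposite" in v.reason


def test_link_must_exist_in_supplied_map():
    tm = build_target_map({"s1": [("m1", "G1")]})
    with pytest.raises(InputError):
        inverse_concordance(_axis_profile("m2", "up", "same"),
                            _axis_profile("G1", "down", "same"), target_map=tm)


@given(
    c_wt=st.floats(0.05, 20), c_ko=st.floats(0.05, 20),
    dirs=st.tuples(*[st.sampled_from(("up", "same", "down"))] * 4),
)
def test_verdict_invariant_under_per_block_rescaling(c_wt, c_ko, dirs):
    """Scaling each genotype's scale block jointly cannot change verdicts."""
    m_wt, m_ko, p_wt, p_ko = dirs
    m = _axis_profile("m", m_wt, m_ko)
    p = _axis_profile("P", p_wt, p_ko)
    scaled_levels = {
        "WTV": p.levels["WTV"] * c_wt, "WTC": p.levels["WTC"] * c_wt,
        "KOV": p.levels["KOV"] * c_ko, "KOC": p.levels["KOC"] * c_ko,
    }
    p_scaled = GradientProfile("P", scaled_levels, comparable=AXES)
    assert (inverse_concordance(m, p).verdict
            == inverse_concordance(m, p_scaled).verdict)


@pytest.mark.parametrize(
    ("m_wt", "m_ko", "p_wt", "p_ko"),
    list(itertools.product(("up", "same", "down"), repeat=4)),
)
def test_verdict_symmetric_under_joint_direction_negation(m_wt, m_ko, p_wt, p_ko):
    flip = {"up": "down", "down": "up", "same": "same"}
    v1 = inverse_concordance(_axis_profile("m", m_wt, m_ko),
                             _axis_profile("P", p_wt, p_ko))
    v2 = inverse_concordance(_axis_profile("m", flip[m_wt], flip[m_ko]),
                             _axis_profile("P", flip[p_wt], flip[p_ko]))
    assert v1.verdict == v2.verdict


# ---------------------------------------------------------------------------
# The published four pairs

def test_reference_pairs_all_qualify():
    mirna, protein = reference_profiles()
    tm = load_reference_target_map()
    report = integrate(mirna, protein, tm)
    assert sorted((v.mirna, v.gene) for v in report.qualifying) == [
        ("miR-200c-5p", "Rpsa"), ("miR-212-3p", "Actb"),
        ("miR-221-3p", "Serpinb1a"), ("miR-33-5p", "Gyk"),
    ]


def test_gyk_pair_opposite_on_both_axes():
    mirna, protein = reference_profiles()
    v = inverse_concordance(mirna["miR-33-5p"], protein["Gyk"])
    rel = {d.comparison: d.relation for d in v.details if d.comparable}
    assert rel == {"wt_axis": "opposite", "ko_axis": "opposite"}


def test_actb_pair_qualifies_through_cross_genotype_comparisons():
    mirna, protein = reference_profiles()
    v = inverse_concordance(mirna["miR-212-3p"], protein["Actb"])
    rel = {d.comparison: d.relation for d in v.details if d.comparable}
    assert v.qualifies
    assert rel["wt_axis"] == "both-same" and rel["ko_axis"] == "both-same"
    assert rel["villi"] == "opposite" and rel["crypts"] == "opposite"


def test_constructed_decoys_all_rejected():
    mirna, protein, tm = reference_case_with_decoys()
    report = integrate(mirna, protein, tm)
    rejected = {(v.mirna, v.gene) for v in report.verdicts if not v.qualifies}
    assert len(report.verdicts) == 10
    assert len(report.qualifying) == 4
    assert all("decoy" in m.lower() or "decoy" in g.lower()
               for m, g in rejected)


def test_links_without_profiles_are_skipped_and_logged():
    mirna, protein = reference_profiles()
    tm = build_target_map({"s1": [("miR-33-5p", "Gyk"), ("miR-33-5p", "NoSuch")]})
    report = integrate(mirna, protein, tm)
    assert len(report.verdicts) == 1
    assert report.skipped == [("miR-33-5p", "NoSuch", "no protein profile")]
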
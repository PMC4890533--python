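"""Four-group differential expression, gradient calls, PCA overview."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cryptvillus.design import COMPARISONS, COMPARISON_ORDER
from cryptvillus.differential import (
    GradientProfile,
    classify_axis_direction,
    gradient_change_category,
    pairwise_de,
    pca_overview,
    run_comparisons,
)
from cryptvillus.errors import InputError
from cryptvillus.qpcr import global_mean_normalize, to_linear_signal


def _student_t_p(a, b):
    """Independent equal-variance two-sided t-test, from the formula."""
    from scipy.stats import t as t_dist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return 2 * t_dist.sf(abs(t), na + nb - 2)


def test_identical_groups_not_selected():
    r = pairwise_de([500.0, 600.0, 700.0], [500.0, 600.0, 700.0])
    assert r.fold == pytest.approx(1.0)
    assert r.p_value == pytest.approx(1.0)
    assert not r.selected


def test_constant_equal_groups_are_an_exact_null():
    r = pairwise_de([600.0] * 4, [600.0] * 4)
    assert r.p_value == 1.0 and not r.selected


def test_clear_separation_selected_and_p_matches_independent_t():
    a, b = [1000.0, 1100.0, 900.0, 1000.0], [400.0, 380.0, 420.0, 400.0]
    r = pairwise_de(a, b)
    assert r.fold == pytest.approx(2.5)
    assert r.direction == "down"
    assert r.p_value == pytest.approx(_student_t_p(a, b), rel=1e-12)
    assert r.p_value < 0.05 and r.selected


def test_low_signal_blocks_selection_regardless_of_p():
    a, b = [300.0, 310.0, 290.0, 300.0], [100.0, 95.0, 105.0, 100.0]
    r = pairwise_de(a, b)
    assert r.p_value < 0.05
    assert r.mean_signal == pytest.approx(300.0)
    assert not r.selected


def test_single_detected_replicate_flagged_not_erred():
    r = pairwise_de([1000.0, np.nan, np.nan, np.nan], [400.0] * 4)
    assert r.insufficient_replication and not r.selected


def test_vectorized_comparisons_match_scalar_brute_force(default_bundle):
    """The tabulated selection equals feature-by-feature recomputation."""
    m = default_bundle.cp_matrix
    signal = to_linear_signal(global_mean_normalize(m).values, 32768.0)
    table = run_comparisons(signal, m.groups)
    idx = {(r.feature, r.comparison): r for r in table.itertuples()}
    rng = np.random.default_rng(0)
    features = rng.choice(signal.index, size=40, replace=False)
    for label in COMPARISON_ORDER:
        first, second = COMPARISONS[label]
        ca = m.groups.index[m.groups == first]
        cb = m.groups.index[m.groups == second]
        for feat in features:
            ref = pairwise_de(signal.loc[feat, ca], signal.loc[feat, cb])
            row = idx[(str(feat), label)]
            assert row.insufficient_replication == ref.insufficient_replication
            if not ref.insufficient_replication:
                assert row.p_value == pytest.approx(ref.p_value, abs=1e-12)
                assert row.fold == pytest.approx(ref.fold, rel=1e-12)
                assert row.selected == ref.selected


@pytest.mark.parametrize(
    ("villus", "crypt", "expected"),
    [
        (1.0, 0.20, "down"),   # strongly depleted in the crypt
        (1.0, 2.58, "up"),     # crypt-enriched
        (1.0, 1.06, "same"),   # inside the 1.45-fold band
        (1.0, 1.45, "up"),     # the threshold itself crosses
        (3.0, 3.0, "same"),
    ],
)
def test_axis_direction_calls(villus, crypt, expected):
    assert classify_axis_direction(villus, crypt, tau=1.45) == expected


@given(
    a=st.floats(0.01, 100), b=st.floats(0.01, 100),
    c=st.floats(0.01, 100), tau=st.floats(1.01, 3.0),
)
def test_axis_direction_antisymmetric_and_scale_free(a, b, c, tau):
    d1 = classify_axis_direction(a, b, tau)
    d2 = classify_axis_direction(b, a, tau)
    assert {"up": "down", "down": "up", "same": "same"}[d1] == d2
    assert classify_axis_direction(a * c, b * c, tau) == d1


def test_axis_direction_rejects_bad_inputs():
    with pytest.raises(InputError):
        classify_axis_direction(0.0, 1.0)
    with pytest.raises(InputError):
        classify_axis_direction(1.0, 1.0, tau=1.0)


@pytest.mark.parametrize(
    ("wt", "ko", "category"),
    [
        ("up", "down", "reversed"),
        ("down", "up", "reversed"),
        ("up", "same", "lost"),
        ("down", "same", "lost"),
        ("same", "up", "gained"),
        ("same", "down", "gained"),
        ("down", "down", "preserved"),
        ("up", "up", "preserved"),
        ("same", "same", "preserved-null"),
    ],
)
def test_gradient_change_taxonomy(wt, ko, category):
    assert gradient_change_category(wt, ko).category == category


def test_gradient_change_rejects_undefined_call():
    with pytest.raises(InputError):
        gradient_change_category("up", "flat")


def test_profile_direction_uses_comparison_order():
    p = GradientProfile("x", {"WTV": 1.0, "WTC": 2.0, "KOV": 1.0, "KOC": 0.5})
    assert p.direction("wt_axis") == "up"
    assert p.direction("ko_axis") == "down"
    assert p.direction("villi") == "same"
    restricted = GradientProfile("x", p.levels, comparable=frozenset({"wt_axis"}))
    assert restricted.direction("ko_axis") is None


# ---------------------------------------------------------------------------
# PCA overview

def _cluster_matrix():
    rng = np.random.default_rng(5)
    base = rng.normal(0, 0.2, size=(60, 12))
    base[:, 6:] += 4.0  # two well-separated sample clusters
    return pd.DataFrame(base, index=[f"f{i:02d}" for i in range(60)],
                        columns=[f"s{j}" for j in range(12)])


def test_pca_separates_clusters_sign_agnostic():
    coords, feats = pca_overview(_cluster_matrix(), k=50)
    assert len(feats) == 50
    left, right = coords.iloc[:6, 0], coords.iloc[6:, 0]
    assert (left.max() < right.min()) or (right.max() < left.min())


def test_pca_duplicated_sample_gets_identical_coordinates():
    m = _cluster_matrix()
    m["s_dup"] = m["s0"]
    coords, _ = pca_overview(m, k=50)
    assert np.allclose(coords.loc["s0"], coords.loc["s_dup"])


def test_two_components_reconstruct_no_worse_than_one():
    m = _cluster_matrix().to_numpy()
    x = m - m.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    resid = [np.linalg.norm(x - (u[:, :k] * s[:k]) @ vt[:k]) for k in (1, 2)]
    assert resid[1] <= resid[0]


def test_pca_warns_and_uses_all_when_k_exceeds_features():
    m = _cluster_matrix().iloc[:10]
    with pytest.warns(UserWarning):
        coords, feats = pca_overview(m, k=50)
    assert len(feats) == 10 and coords.shape == (12, 2)
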
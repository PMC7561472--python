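"""Thresholding, hierarchical clustering, correlations and group tests."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom
from sklearn.metrics import adjusted_rand_score

import blastomorph as bm
from blastomorph.clusterstats import _min_size_tree_cut, dunn_test


# ---------------------------------------------------------------------------
# yap threshold
# ---------------------------------------------------------------------------
def test_threshold_symmetric_midpoint():
    thr, is_high = bm.yap_threshold([1, 1, 1, 3, 3, 3])
    assert thr == pytest.approx(2.0)
    assert list(is_high) == [False] * 3 + [True] * 3


def test_threshold_decision_rule_is_strictly_greater():
    """A cell at 1.7 with threshold 1.6 is classified high."""
    values = [1.0, 1.1, 1.2, 2.0, 2.1, 2.2, 1.7]
    thr, is_high = bm.yap_threshold(values)
    assert 1.2 < thr < 2.0
    assert is_high[-1] == (values[-1] > thr)
    assert is_high[-1]


def test_threshold_requires_spread():
    with pytest.raises(ValueError, match="identical"):
        bm.yap_threshold([2.0, 2.0, 2.0, 2.0])
    with pytest.raises(ValueError, match="at least 4"):
        bm.yap_threshold([1.0, 2.0])


@settings(deadline=None, max_examples=20)
@given(
    scale=st.floats(0.1, 50.0),
    shift=st.floats(-10.0, 10.0),
)
def test_threshold_affine_equivariance(scale, shift):
    """Standardisation makes the split equivariant under x -> a*x + b."""
    rng = np.random.default_rng(0)
    x = np.r_[rng.normal(1.0, 0.15, 60), rng.normal(2.2, 0.25, 60)]
    thr, labels = bm.yap_threshold(x)
    thr2, labels2 = bm.yap_threshold(scale * x + shift)
    assert thr2 == pytest.approx(scale * thr + shift, rel=1e-6, abs=1e-6)
    assert np.array_equal(labels, labels2)


def test_threshold_on_bimodal_mixture_lands_between_modes():
    rng = np.random.default_rng(1)
    x = np.r_[rng.normal(1.0, 0.15, 250), rng.normal(2.2, 0.25, 250)]
    thr, _ = bm.yap_threshold(x)
    assert 1.3 < thr < 1.9


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------
ARCHETYPES = {
    # (prop_exposed, nc_yap) centroids of the three blastomere states
    "inside-like": (0.08, 1.05),
    "outside-like": (0.45, 2.0),
    "undefined": (0.80, 1.5),
}


def _planted(n_per=60, sd=(0.05, 0.08), seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for name, (p, y) in ARCHETYPES.items():
        for _ in range(n_per):
            rows.append(
                {
                    "prop_exposed": rng.normal(p, sd[0]),
                    "nc_yap": rng.normal(y, sd[1]),
                    "truth": name,
                }
            )
    return pd.DataFrame(rows)


def test_planted_archetypes_recovered():
    df = _planted()
    model = bm.hier_cluster(df)
    assert model.k == 3
    assert adjusted_rand_score(df["truth"], model.labels) >= 0.9
    named = model.named_labels()
    # majority name of each planted group matches its archetype
    for name in ARCHETYPES:
        sub = named[(df["truth"] == name).to_numpy()]
        assert (sub == name).mean() > 0.9


def test_duplicate_rows_get_identical_labels():
    df = _planted(n_per=20)
    df2 = pd.concat([df, df.iloc[:5]], ignore_index=True)
    model = bm.hier_cluster(df2)
    for i in range(5):
        assert model.labels[len(df) + i] == model.labels[i]


def test_ambiguous_centroids_leave_names_unset():
    """One cluster extreme in both variables cannot be named."""
    rng = np.random.default_rng(0)
    rows = []
    for p, y in [(0.1, 1.0), (0.5, 1.5), (0.9, 2.0)]:  # yap increases with p
        for _ in range(30):
            rows.append({"prop_exposed": rng.normal(p, 0.04), "nc_yap": rng.normal(y, 0.06)})
    with pytest.warns(UserWarning, match="names unset"):
        model = bm.hier_cluster(pd.DataFrame(rows))
    assert model.names is None


def test_tree_cut_fallback_on_unimodal_data():
    rng = np.random.default_rng(3)
    df = pd.DataFrame(
        {"prop_exposed": rng.normal(0.5, 0.01, 40), "nc_yap": rng.normal(1.5, 0.01, 40)}
    )
    model = bm.hier_cluster(df)  # falls back to k=3 with a warning in the log
    assert model.k == 3
    assert len(np.unique(model.labels)) == 3


def test_min_records_enforced():
    df = _planted(n_per=2)
    with pytest.raises(ValueError, match="at least"):
        bm.hier_cluster(df, k=3)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------
def test_perfect_monotone_pair_gives_rho_one():
    df = pd.DataFrame({"a": np.arange(10.0), "b": np.exp(np.arange(10.0)), "stage": 8})
    rep = bm.correlate(df, ["a", "b"])
    assert rep.rho.loc["a", "b"] == pytest.approx(1.0)
    assert rep.rho.equals(rep.rho.T)
    assert np.allclose(np.diag(rep.rho), 1.0)


def test_constant_column_reports_nan():
    df = pd.DataFrame({"a": np.arange(10.0), "b": np.ones(10), "stage": 8})
    rep = bm.correlate(df, ["a", "b"])
    assert np.isnan(rep.rho.loc["a", "b"])


def test_independent_columns_near_zero():
    rng = np.random.default_rng(0)
    hits = 0
    for seed in range(20):
        r = np.random.default_rng(seed)
        df = pd.DataFrame({"a": r.normal(size=200), "b": r.normal(size=200), "stage": 8})
        rho = bm.correlate(df, ["a", "b"]).rho.loc["a", "b"]
        hits += abs(rho) < 0.15
    assert hits >= 18  # ~95% of null draws


def test_stage_restriction():
    df = pd.DataFrame(
        {
            "a": np.r_[np.arange(10.0), np.arange(10.0)],
            "b": np.r_[np.arange(10.0), -np.arange(10.0)],
            "stage": [16] * 10 + [32] * 10,
        }
    )
    rep = bm.correlate(df, ["a", "b"], stages=[16])
    assert rep.n == 10
    assert rep.rho.loc["a", "b"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------
def test_identical_groups_not_significant():
    rng = np.random.default_rng(0)
    vals = rng.normal(size=30)
    df = pd.DataFrame({"g": ["a"] * 30 + ["b"] * 30, "v": np.r_[vals, vals]})
    res = bm.group_tests(df, "g", "v")
    assert res.p_value > 0.05


def test_normality_gate_selects_anova_then_kruskal():
    rng = np.random.default_rng(1)
    normal = pd.DataFrame(
        {"g": ["a"] * 40 + ["b"] * 40, "v": np.r_[rng.normal(0, 1, 40), rng.normal(1, 1, 40)]}
    )
    res_n = bm.group_tests(normal, "g", "v")
    assert res_n.test == "anova"
    assert {"group_a", "group_b", "p_adj"} <= set(res_n.posthoc.columns)
    skewed = pd.DataFrame(
        {
            "g": ["a"] * 40 + ["b"] * 40,
            "v": np.r_[rng.lognormal(0, 1, 40), rng.lognormal(1, 1, 40)],
        }
    )
    res_k = bm.group_tests(skewed, "g", "v")
    assert res_k.test == "kruskal"
    assert {"p_raw", "p_adj"} <= set(res_k.posthoc.columns)
    assert res_k.p_value < 0.01


def test_shifted_lognormal_detected_by_gated_test():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "g": ["a"] * 30 + ["b"] * 30,
                "v": np.r_[rng.lognormal(0, 1, 30), rng.lognormal(1, 1, 30)],
            }
        )
        res = bm.group_tests(df, "g", "v")
        hits += res.p_value < 0.01
    assert hits >= 18  # ≥90% power at Δ = 1 sd


def test_small_group_skips_omnibus_with_warning():
    df = pd.DataFrame({"g": ["a"] * 10 + ["b"] * 2, "v": np.arange(12.0)})
    res = bm.group_tests(df, "g", "v")
    assert res.test == "skipped"
    assert res.warnings


def test_dunn_matches_kruskal_for_two_groups():
    """With two groups, Dunn's z² equals the Kruskal-Wallis H statistic."""
    from scipy.stats import kruskal

    rng = np.random.default_rng(2)
    a, b = rng.normal(0, 1, 25), rng.normal(0.8, 1, 30)
    d = dunn_test({"a": a, "b": b})
    H = kruskal(a, b).statistic
    assert d["z"].iloc[0] ** 2 == pytest.approx(H, rel=1e-9)
    assert d["p_adj"].iloc[0] >= d["p_raw"].iloc[0] - 1e-12


def test_fisher_exact_matches_hypergeometric_oracle():
    """p for (10,0 / 0,10) computed exactly by hypergeometric enumeration."""
    table = [[10, 0], [0, 10]]
    _, p = bm.fisher_test(table)
    # P(X = 10) + P(X = 0) under Hypergeom(N=20, K=10, n=10)
    oracle = hypergeom.pmf(10, 20, 10, 10) + hypergeom.pmf(0, 20, 10, 10)
    assert p == pytest.approx(oracle, rel=1e-9)
    assert p < 1e-4


# ---------------------------------------------------------------------------
# confinement comparison
# ---------------------------------------------------------------------------
def test_identical_cohorts_show_no_shift():
    df = _planted(n_per=40, seed=5)[["prop_exposed", "nc_yap"]]
    out = bm.confinement_compare(df, df.copy())
    for v in ("prop_exposed", "nc_yap"):
        assert out["medians"][v]["control"] == out["medians"][v]["confined"]
        assert out["tests"][v].p_value > 0.05
    comp = out["cluster_composition_pct"]
    assert np.allclose(comp.sum(axis=1), 100.0)


def test_confinement_compare_rejects_empty():
    df = _planted(n_per=10)
    with pytest.raises(ValueError, match="non-empty"):
        bm.confinement_compare(df, df.iloc[:0])
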
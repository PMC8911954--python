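import itertools
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wineomics.differential_analysis import (
    bh_adjust,
    fold_change,
    median_baseline_transform,
    moderated_t_test,
    pca,
    presence_venn,
    significance_stars,
    two_way_anova,
    venn_summary,
)
from wineomics.entities import EntityTable


def _presence_table(sets: dict[str, set[str]]):
    universe = sorted(set().union(*sets.values())) or ["x"]
    idx = pd.Index(universe, name="entity")
    ab = pd.DataFrame(
        {g: [1.0 if e in s else np.nan for e in universe] for g, s in sets.items()},
        index=idx,
    )
    entities = pd.DataFrame(
        {"rt_min": 1.0, "ri": 1000.0, "id_level": 2, "cas": "", "formula": ""}, index=idx
    )
    return EntityTable(entities=entities, abundance=ab,
                       sample_groups={g: g for g in sets})


# --------------------------------------------------------------------------
# Venn partition
# --------------------------------------------------------------------------

def test_identical_sets_all_in_intersection():
    s = {"a", "b", "c"}
    table = _presence_table({f"g{i}": set(s) for i in range(4)})
    regions = presence_venn(table)
    full = frozenset(f"g{i}" for i in range(4))
    assert regions[full] == 3
    assert sum(v for k, v in regions.items() if k != full) == 0


@pytest.mark.parametrize("seed", range(5))
def test_venn_matches_exhaustive_membership_enumeration(seed):
    rng = np.random.default_rng(seed)
    universe = [f"e{i}" for i in range(25)]
    sets = {
        g: {e for e in universe if rng.random() < 0.5}
        for g in ["A", "B", "C", "D"]
    }
    if not set().union(*sets.values()):
        sets["A"] = {"e0"}
    table = _presence_table(sets)
    regions = presence_venn(table)
    # brute-force oracle over all 2^4 membership patterns
    for r in range(1, 5):
        for combo in itertools.combinations(sets, r):
            members = frozenset(combo)
            expected = sum(
                1
                for e in set().union(*sets.values())
                if {g for g in sets if e in sets[g]} == set(combo)
            )
            assert regions[members] == expected
    # regions partition the union
    assert sum(regions.values()) == len(set().union(*sets.values()))


def test_venn_summary_headline_numbers():
    sets = {"A": {"x", "y"}, "B": {"y"}, "C": {"y", "z"}, "D": {"y"}}
    summary = venn_summary(_presence_table(sets))
    assert summary["universe"] == 3
    assert summary["shared_all"] == 1
    assert summary["exclusive"] == {"A": 1, "B": 0, "C": 1, "D": 0}


# --------------------------------------------------------------------------
# transform
# --------------------------------------------------------------------------

def test_transform_centres_per_entity():
    idx = pd.Index(["a", "b"], name="entity")
    ab = pd.DataFrame({"s1": [4.0, 7.0], "s2": [16.0, 7.0]}, index=idx)
    table = EntityTable(
        entities=pd.DataFrame(index=idx, columns=["rt_min", "ri", "id_level", "cas", "formula"]),
        abundance=ab,
        sample_groups={"s1": "g1", "s2": "g2"},
    )
    out = median_baseline_transform(table)
    np.testing.assert_allclose(out.loc["a"], [-1.0, 1.0])  # log2(4),log2(16) centred
    np.testing.assert_allclose(out.loc["b"], [0.0, 0.0])  # identical values -> zeros


def test_transform_imputes_nd_and_never_emits_nan():
    idx = pd.Index(["a", "gone"], name="entity")
    ab = pd.DataFrame({"s1": [8.0, np.nan], "s2": [np.nan, np.nan], "s3": [2.0, np.nan]},
                      index=idx)
    table = EntityTable(
        entities=pd.DataFrame(index=idx, columns=["rt_min", "ri", "id_level", "cas", "formula"]),
        abundance=ab,
        sample_groups={c: c for c in ab.columns},
    )
    with pytest.warns(UserWarning, match="no detection"):
        out = median_baseline_transform(table)
    assert list(out.index) == ["a"]
    assert out.notna().all().all()
    # ND imputed at half the smallest detected abundance (here 1.0)
    assert out.loc["a", "s2"] == pytest.approx(np.log2(1.0) - np.log2(2.0))


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

def test_pca_variance_fractions_sum_to_one_and_loadings_orthonormal():
    rng = np.random.default_rng(0)
    mat = pd.DataFrame(rng.normal(size=(10, 8)))
    res = pca(mat)
    assert res.explained_fraction.sum() == pytest.approx(1.0)
    gram = res.loadings.to_numpy().T @ res.loadings.to_numpy()
    np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-9)


def test_pca_two_entity_toy_matches_closed_form_eigenvalues():
    # samples drawn exactly along a dominant direction plus a small one
    x = np.array([[3.0, 1.0], [-3.0, -1.0], [1.0, -1.0], [-1.0, 1.0]]).T
    mat = pd.DataFrame(x, index=["e1", "e2"], columns=list("abcd"))
    res = pca(mat)
    cov = np.cov(x)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    np.testing.assert_allclose(res.explained_fraction, eig / eig.sum(), atol=1e-12)


def test_pca_separates_planted_group_structure():
    from sklearn.metrics import silhouette_score

    rng = np.random.default_rng(5)
    n_e = 40
    groups = ["LC17", "LC18", "LD17", "LD18"]
    effects = {g: rng.normal(0, 1.0, n_e) for g in groups}
    cols, labels = {}, []
    for g in groups:
        for r in range(3):
            cols[f"{g}_r{r}"] = effects[g] + rng.normal(0, 0.25, n_e)
            labels.append(g)
    mat = pd.DataFrame(cols, index=[f"e{i}" for i in range(n_e)])
    res = pca(mat)
    score = silhouette_score(res.scores.iloc[:, :2], labels)
    assert score > 0.3


def test_rank_zero_matrix_rejected():
    mat = pd.DataFrame(np.ones((4, 4)))
    with pytest.raises(ValueError, match="rank 0"):
        pca(mat)


# --------------------------------------------------------------------------
# fold change
# --------------------------------------------------------------------------

def test_fold_change_examples():
    assert fold_change(10.0, 10.0) == (1.0, "-")
    fc, direction = fold_change(2.5e7, 5.3e6)
    assert fc == pytest.approx(4.8, rel=0.05) and direction == "down"
    fc, direction = fold_change(np.nan, 5.0)
    assert np.isnan(fc) and direction == "-"


def test_fold_change_rejects_non_positive_means():
    with pytest.raises(ValueError):
        fold_change(0.0, 5.0)


# --------------------------------------------------------------------------
# moderated t-test
# --------------------------------------------------------------------------

def _two_groups(seed=0, n_entities=50, shift=None):
    rng = np.random.default_rng(seed)
    a = pd.DataFrame(rng.normal(0, 1, (n_entities, 3)))
    b = pd.DataFrame(rng.normal(0, 1, (n_entities, 3)))
    if shift is not None:
        b.iloc[0] += shift
    return a, b


def test_d0_zero_limit_equals_ordinary_t():
    from scipy import stats

    a, b = _two_groups(seed=1)
    res = moderated_t_test(a, b, d0_override=0.0)
    ref = stats.ttest_ind(a, b, axis=1)
    np.testing.assert_allclose(res["t"], ref.statistic, rtol=1e-9)
    np.testing.assert_allclose(res["p"], ref.pvalue, rtol=1e-9)


def test_d0_infinite_limit_shares_one_variance():
    a, b = _two_groups(seed=2)
    res = moderated_t_test(a, b, d0_override=np.inf)
    assert res["s2_post"].nunique() == 1


def test_moderated_t_matches_limma_oracle(tmp_path):
    """Independent cross-check against the reference empirical-Bayes
    implementation in R (limma), on a fixed small matrix."""
    rng = np.random.default_rng(7)
    n = 40
    a = pd.DataFrame(rng.normal(0, 1, (n, 3)))
    b = pd.DataFrame(rng.normal(0.5, 1.2, (n, 3)))
    mat = pd.concat([a, b], axis=1)
    mat.columns = [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]
    csv = tmp_path / "mat.csv"
    mat.to_csv(csv, index=False)
    out = tmp_path / "limma.csv"
    script = textwrap.dedent(f"""
        suppressMessages(library(limma))
        m <- as.matrix(read.csv("{csv}"))
        design <- cbind(Intercept=1, B=c(0,0,0,1,1,1))
        fit <- eBayes(lmFit(m, design))
        write.csv(data.frame(t=fit$t[,2], p=fit$p.value[,2],
                             d0=fit$df.prior, s02=fit$s2.prior),
                  "{out}", row.names=FALSE)
    """)
    r = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
    assert r.returncode == 0, r.stderr
    ref = pd.read_csv(out)
    res = moderated_t_test(b, a)  # limma's coefficient is B - A
    np.testing.assert_allclose(res["d0"].iloc[0], ref["d0"].iloc[0], rtol=1e-4)
    np.testing.assert_allclose(res["s0_sq"].iloc[0], ref["s02"].iloc[0], rtol=1e-4)
    np.testing.assert_allclose(res["t"], ref["t"], rtol=1e-6)
    np.testing.assert_allclose(res["p"], ref["p"], rtol=1e-6)


def test_planted_shift_detected():
    a, b = _two_groups(seed=3, shift=3.0)
    res = moderated_t_test(a, b)
    p_adj = bh_adjust(res["p"].to_numpy())
    assert p_adj[0] < 0.01
    assert (p_adj[1:] < 0.05).mean() < 0.1


# --------------------------------------------------------------------------
# Benjamini-Hochberg
# --------------------------------------------------------------------------

def _bh_brute_force(p):
    """Textbook step-up definition: adj_i = min over j>=rank(i) of m*p_j/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for pos, i in enumerate(order):
        candidates = [m * p[order[j]] / (j + 1) for j in range(pos, m)]
        adj[i] = min(1.0, min(candidates))
    return adj


def test_bh_hand_example():
    np.testing.assert_allclose(
        bh_adjust([0.005, 0.01, 0.03, 0.04]), [0.02, 0.02, 0.04, 0.04]
    )


def test_bh_trivial_cases():
    np.testing.assert_allclose(bh_adjust([0.3]), [0.3])
    np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=6))
def test_bh_matches_brute_force_definition(p):
    np.testing.assert_allclose(bh_adjust(p), _bh_brute_force(p), atol=1e-12)


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(11)
    p = rng.uniform(size=100)
    ref = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)


# --------------------------------------------------------------------------
# two-way ANOVA
# --------------------------------------------------------------------------

def test_anova_hand_toy_matches_direct_ss_arithmetic():
    y = np.array([[[1.0, 2.0], [3.0, 4.0]], [[5.0, 6.0], [7.0, 8.0]]])
    out = two_way_anova(y)
    # direct arithmetic: grand=4.5; A means 2.5/6.5; B means 3.5/5.5
    assert out.loc["factor_a", "ss"] == pytest.approx(32.0)
    assert out.loc["factor_b", "ss"] == pytest.approx(8.0)
    assert out.loc["interaction", "ss"] == pytest.approx(0.0)
    assert out.loc["residual", "ss"] == pytest.approx(2.0)
    assert out.loc["factor_a", "F"] == pytest.approx(32.0 / 0.5)


def test_anova_matches_statsmodels():
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    rng = np.random.default_rng(4)
    y = rng.normal(0, 1, (2, 2, 3)) + np.array([[0.0, 1.0], [2.0, 3.5]])[:, :, None]
    out = two_way_anova(y)
    rows = [
        {"y": y[i, j, k], "a": f"a{i}", "b": f"b{j}"}
        for i in range(2) for j in range(2) for k in range(3)
    ]
    df = pd.DataFrame(rows)
    ref = sm.stats.anova_lm(ols("y ~ C(a) * C(b)", data=df).fit(), typ=2)
    assert out.loc["factor_a", "F"] == pytest.approx(ref.loc["C(a)", "F"], rel=1e-9)
    assert out.loc["factor_b", "p"] == pytest.approx(ref.loc["C(b)", "PR(>F)"], rel=1e-9)
    assert out.loc["interaction", "F"] == pytest.approx(ref.loc["C(a):C(b)", "F"], rel=1e-9)


def test_zero_noise_additive_effects_have_zero_interaction():
    a_eff = np.array([0.0, 2.0])
    b_eff = np.array([0.0, 1.0])
    y = a_eff[:, None, None] + b_eff[None, :, None] + np.zeros((2, 2, 3))
    out = two_way_anova(y)
    assert out.loc["interaction", "ss"] == pytest.approx(0.0, abs=1e-12)


def test_planted_vintage_effect_detected_vineyard_not():
    rng = np.random.default_rng(9)
    sd = 0.5
    p_a, p_b = [], []
    for _ in range(50):
        y = rng.normal(0, sd, (2, 2, 3))
        y[1] += 2 * sd  # vintage (factor A) effect of 2 x s.d.
        out = two_way_anova(y)
        p_a.append(out.loc["factor_a", "p"])
        p_b.append(out.loc["factor_b", "p"])
    assert np.median(p_a) < 0.01  # the planted factor is typically detected
    assert np.median(p_b) > 0.1  # the null factor typically is not


def test_unbalanced_design_rejected():
    y = np.full((2, 2, 3), np.nan)
    y[:, :, :] = 1.0
    y[0, 0, 2] = np.nan
    with pytest.raises(ValueError, match="unbalanced"):
        two_way_anova(y)


def test_significance_star_legend():
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.2) == ""
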
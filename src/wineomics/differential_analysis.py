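"""Group-level statistics on the entity table.

Covers the downstream analysis of a 2 vineyards x 2 vintages wine study:
presence/Venn partitions over the four wine groups, the log2
median-baseline transform, covariance-method PCA, fold changes against a
baseline wine, an empirical-Bayes moderated t-test with Benjamini-Hochberg
correction, and classical balanced two-way ANOVA.

The moderated t-test follows the standard empirical-Bayes variance
moderation: per-entity sample variances s2_g (d_g df) share strength
through a scaled-inverse-chi-square prior (d0, s0^2) fitted by matching the
moments of log s2_g (digamma/trigamma inversion), giving posterior
variances s2_post = (d0 s0^2 + d_g s2_g) / (d0 + d_g) and t-statistics with
d0 + d_g degrees of freedom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import polygamma

from .entities import EntityTable

__all__ = [
    "presence_venn",
    "venn_summary",
    "median_baseline_transform",
    "PCAResult",
    "pca",
    "fold_change",
    "moderated_t_test",
    "bh_adjust",
    "two_way_anova",
    "significance_stars",
    "differential_report",
]


# --------------------------------------------------------------------------
# presence / Venn
# --------------------------------------------------------------------------

def presence_venn(table: EntityTable) -> dict[frozenset, int]:
    """Counts of every non-empty membership region over the group presence
    sets. The regions partition the union: an entity counts in exactly the
    region of the groups it is present in.
    """
    sets = table.presence_sets()
    groups = list(sets)
    universe = set().union(*sets.values())
    regions = {}
    for entity in universe:
        member = frozenset(g for g in groups if entity in sets[g])
        regions[member] = regions.get(member, 0) + 1
    # include empty regions for completeness (all 2^k - 1 patterns)
    from itertools import combinations

    for r in range(1, len(groups) + 1):
        for combo in combinations(groups, r):
            regions.setdefault(frozenset(combo), 0)
    return regions


def venn_summary(table: EntityTable) -> dict:
    """Headline Venn numbers: per-group totals, the all-groups intersection
    and per-group exclusive counts."""
    sets = table.presence_sets()
    groups = list(sets)
    regions = presence_venn(table)
    return {
        "universe": len(set().union(*sets.values())),
        "per_group": {g: len(sets[g]) for g in groups},
        "shared_all": regions.get(frozenset(groups), 0),
        "exclusive": {g: regions.get(frozenset([g]), 0) for g in groups},
    }


# --------------------------------------------------------------------------
# transform and PCA
# --------------------------------------------------------------------------

def median_baseline_transform(table: EntityTable) -> pd.DataFrame:
    """log2 abundances, median-centred per entity across all samples.

    ND cells are imputed as half the entity's smallest detected abundance
    (minimum substitution) *for this numeric matrix only* — presence/Venn
    logic always uses the raw ND flags. Entities detected nowhere are
    dropped with a warning. The output contains no NaN.
    """
    ab = table.abundance
    all_nd = ab.isna().all(axis=1)
    if all_nd.any():
        warnings.warn(
            f"dropping {int(all_nd.sum())} entities with no detection", stacklevel=2
        )
        ab = ab.loc[~all_nd]
    filled = ab.apply(lambda row: row.fillna(row.min() / 2.0), axis=1)
    log2 = np.log2(filled)
    return log2.sub(log2.median(axis=1), axis=0)


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # entities x components (orthonormal)
    explained_fraction: np.ndarray  # sums to 1


def pca(matrix: pd.DataFrame, method: str = "covariance") -> PCAResult:
    """PCA of samples over entity variables.

    ``matrix`` is entities x samples (e.g. the median-baseline transform).
    The covariance method decomposes the sample covariance of the centred
    data without variable scaling; ``method="correlation"`` standardises
    each entity first.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 entities and 2 samples")
    x = matrix.T.to_numpy(dtype=float)  # samples x entities
    x = x - x.mean(axis=0)
    if method == "correlation":
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    elif method != "covariance":
        raise ValueError(f"unknown PCA method {method!r}")
    if not np.any(x):
        raise ValueError("matrix has rank 0 after centring")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    keep = s > 1e-12 * s[0]
    u, s, vt = u[:, keep], s[keep], vt[keep]
    var = s**2
    scores = pd.DataFrame(
        u * s,
        index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(len(s))],
    )
    loadings = pd.DataFrame(
        vt.T, index=matrix.index, columns=scores.columns
    )
    return PCAResult(scores=scores, loadings=loadings, explained_fraction=var / var.sum())


# --------------------------------------------------------------------------
# fold change
# --------------------------------------------------------------------------

def fold_change(mean_baseline: float, mean_other: float) -> tuple[float, str]:
    """Fold change >= 1 with a direction relative to the baseline.

    Returns ``(fc, direction)`` with direction ``"up"`` when the other group
    exceeds the baseline, ``"down"`` when below, ``"-"`` when equal or when
    either mean is missing (ND), in which case fc is NaN.
    """
    if (
        mean_baseline is None
        or mean_other is None
        or not np.isfinite(mean_baseline)
        or not np.isfinite(mean_other)
    ):
        return float("nan"), "-"
    if mean_baseline <= 0 or mean_other <= 0:
        raise ValueError("fold change needs positive means")
    if mean_other == mean_baseline:
        return 1.0, "-"
    if mean_other > mean_baseline:
        return mean_other / mean_baseline, "up"
    return mean_baseline / mean_other, "down"


# --------------------------------------------------------------------------
# moderated t-test
# --------------------------------------------------------------------------

def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return math.inf
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(polygamma(1, x))
        diff = (tri - y) / float(polygamma(2, x))
        x -= diff
        if x <= 0:
            x = 1e-8
        if abs(diff) < tol * x:
            break
    return x


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching fit of the scaled-inverse-chi-square variance prior.

    Returns (d0, s0^2); d0 = inf means complete shrinkage to s0^2.
    """
    z = np.log(np.clip(s2, 1e-300, None))
    e = z - float(polygamma(0, df / 2.0)) + math.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = math.exp(emean + float(polygamma(0, d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s02 = math.exp(emean)
    return d0, s02


def moderated_t_test(
    group_a: pd.DataFrame | np.ndarray,
    group_b: pd.DataFrame | np.ndarray,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t-test, jointly over entities.

    ``group_a`` / ``group_b`` are entities x replicates matrices of log2
    abundances. Returns a DataFrame with columns ``mean_a``, ``mean_b``,
    ``t``, ``p``, ``df``, ``s2``, ``s2_post``, ``d0``, ``s0_sq``.

    ``d0_override`` forces the prior degrees of freedom (0 recovers the
    ordinary t-test per entity; inf pools a single variance across
    entities); by default the prior is fitted from the data. With fewer
    than 2 entities, moderation is impossible and the ordinary t-test is
    used with a warning.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[0] != b.shape[0]:
        raise ValueError("groups must cover the same entities")
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("need at least two observations per group")
    df = na + nb - 2
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    s2 = ((na - 1) * va + (nb - 1) * vb) / df
    if d0_override is not None:
        d0 = float(d0_override)
        s02 = float(np.exp(np.mean(np.log(np.clip(s2, 1e-300, None))))) if d0 > 0 else 0.0
        if math.isinf(d0):
            _, s02 = _fit_variance_prior(s2, df)
    elif a.shape[0] < 2:
        warnings.warn("fewer than 2 entities: falling back to ordinary t", stacklevel=2)
        d0, s02 = 0.0, 0.0
    else:
        d0, s02 = _fit_variance_prior(s2, df)
    if math.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / se
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    index = group_a.index if isinstance(group_a, pd.DataFrame) else pd.RangeIndex(len(t))
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "t": t,
            "p": p,
            "df": df_total,
            "s2": s2,
            "s2_post": s2_post,
            "d0": d0,
            "s0_sq": s02,
        },
        index=index,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / (np.arange(m) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# --------------------------------------------------------------------------
# two-way ANOVA (balanced 2x2xr)
# --------------------------------------------------------------------------

def two_way_anova(cells: np.ndarray) -> pd.DataFrame:
    """Classical sums-of-squares two-way ANOVA on a balanced 2 x 2 x r array.

    ``cells[i, j, :]`` holds the replicates of factor-A level i and
    factor-B level j. Returns a DataFrame indexed by ``factor_a``,
    ``factor_b``, ``interaction`` with columns ``ss``, ``df``, ``F``, ``p``.
    """
    y = np.asarray(cells, dtype=float)
    if y.ndim != 3 or y.shape[0] != 2 or y.shape[1] != 2:
        raise ValueError("expected a 2 x 2 x r array")
    r = y.shape[2]
    if r < 2:
        raise ValueError("need at least 2 replicates per cell")
    if np.any(~np.isfinite(y)):
        raise ValueError("unbalanced design (missing cells) is not supported")
    grand = y.mean()
    mean_a = y.mean(axis=(1, 2))
    mean_b = y.mean(axis=(0, 2))
    mean_cell = y.mean(axis=2)
    ss_a = 2 * r * float(np.sum((mean_a - grand) ** 2))
    ss_b = 2 * r * float(np.sum((mean_b - grand) ** 2))
    ss_cells = r * float(np.sum((mean_cell - grand) ** 2))
    ss_int = ss_cells - ss_a - ss_b
    ss_err = float(np.sum((y - mean_cell[:, :, None]) ** 2))
    df_err = 4 * (r - 1)
    ms_err = ss_err / df_err
    rows = []
    for name, ss in (("factor_a", ss_a), ("factor_b", ss_b), ("interaction", ss_int)):
        if ms_err == 0:
            f = math.inf if ss > 0 else 0.0
            p = 0.0 if ss > 0 else 1.0
        else:
            f = (ss / 1.0) / ms_err
            p = float(stats.f.sf(f, 1, df_err))
        rows.append({"ss": ss, "df": 1, "F": f, "p": p})
    out = pd.DataFrame(rows, index=["factor_a", "factor_b", "interaction"])
    out.loc["residual"] = {"ss": ss_err, "df": df_err, "F": np.nan, "p": np.nan}
    return out


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# --------------------------------------------------------------------------
# study-level report
# --------------------------------------------------------------------------

def differential_report(
    replicate_table: EntityTable,
    vintage_of: dict[str, str] | None = None,
    baseline: str = "LaChanga2017",
    fallback_baseline: str = "LaChanga2018",
    fc_min: float = 1.1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Vintage comparison over the replicate-level entity table.

    Entities detected in all replicates of both vintages are tested with the
    moderated t-test (2017 vs 2018, vineyards pooled) on the
    median-baseline-transformed data, BH-adjusted; significance additionally
    requires FC > ``fc_min``. Fold changes and directions are reported
    against ``baseline`` (or ``fallback_baseline`` for entities ND there).
    """
    groups = replicate_table.groups
    if vintage_of is None:
        vintage_of = {g: ("2017" if g.endswith("2017") else "2018") for g in groups}
    mat = median_baseline_transform(replicate_table)
    cols17 = [s for s in replicate_table.samples
              if vintage_of[replicate_table.sample_groups[s]] == "2017"]
    cols18 = [s for s in replicate_table.samples
              if vintage_of[replicate_table.sample_groups[s]] == "2018"]
    pres = replicate_table.presence()
    tested = pres[cols17].all(axis=1) & pres[cols18].all(axis=1)
    tested = tested.reindex(mat.index, fill_value=False)
    mt = moderated_t_test(mat.loc[tested, cols17], mat.loc[tested, cols18])
    mt["p_adj"] = bh_adjust(mt["p"].to_numpy())
    group_means = pd.DataFrame(index=replicate_table.abundance.index)
    for g in groups:
        cols = replicate_table.samples_of(g)
        all_present = pres[cols].all(axis=1)
        group_means[g] = np.where(
            all_present, replicate_table.abundance[cols].mean(axis=1), np.nan
        )
    fc17 = group_means[[g for g in groups if vintage_of[g] == "2017"]].mean(axis=1)
    fc18 = group_means[[g for g in groups if vintage_of[g] == "2018"]].mean(axis=1)
    rows = []
    for name in mat.index:
        base = baseline if np.isfinite(group_means.loc[name, baseline]) else fallback_baseline
        base_mean = group_means.loc[name, base]
        fcs = {}
        for g in groups:
            if g == base:
                continue
            other = group_means.loc[name, g]
            if np.isfinite(base_mean) and np.isfinite(other):
                fc, direction = fold_change(base_mean, other)
            else:
                fc, direction = float("nan"), "-"
            fcs[f"fc_{g}"] = fc
            fcs[f"dir_{g}"] = direction
        if name in mt.index:
            p = mt.loc[name, "p"]
            p_adj = mt.loc[name, "p_adj"]
            t = mt.loc[name, "t"]
            a, bmean = fc17[name], fc18[name]
            vintage_fc = (
                fold_change(a, bmean)[0] if np.isfinite(a) and np.isfinite(bmean) else np.nan
            )
            significant = bool(p_adj < alpha and np.isfinite(vintage_fc) and vintage_fc > fc_min)
            stars = significance_stars(p) if significant else ""
        else:
            p = p_adj = t = vintage_fc = np.nan
            significant = False
            stars = ""
        rows.append(
            {
                "entity": name,
                "baseline": base,
                **fcs,
                "vintage_fc": vintage_fc,
                "t": t,
                "p": p,
                "p_adj": p_adj,
                "significant": significant,
                "stars": stars,
            }
        )
    return pd.DataFrame(rows).set_index("entity")
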
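"""Shared statistical tests used across the pipeline.

Mann-Whitney U (exact enumeration for small samples, tie-corrected normal
approximation otherwise) and the Monte-Carlo Dunnett adjustment are
implemented here; Levene's test, one-way ANOVA and Pearson correlation
are delegated to scipy.stats behind a uniform dict-returning surface.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, sqrt

import numpy as np
from scipy import stats

__all__ = [
    "mann_whitney_u",
    "levene_test",
    "anova_dunnett",
    "pearson",
]

EXACT_U_LIMIT = 14  # exact enumeration when n_a + n_b <= this


def _as_clean_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def mann_whitney_u(a, b, method: str = "auto") -> dict[str, float]:
    """Two-sided Mann-Whitney U test of group ``a`` against group ``b``.

    For ``n_a + n_b <= 14`` (``method="auto"``) the null distribution of U
    is enumerated exhaustively over all C(n_a+n_b, n_a) group labelings of
    the pooled midranks (exact even under ties).  For larger samples a
    normal approximation with tie-corrected variance and 0.5 continuity
    correction is used; ``method`` may force either path.  Returns
    ``{"U": ..., "p_two_sided": ..., "exact": ...}`` with U the statistic
    of group ``a``.
    """
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    a = _as_clean_array(a, "a")
    b = _as_clean_array(b, "b")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    if method == "exact" or (method == "auto" and n1 + n2 <= EXACT_U_LIMIT):
        total = comb(n1 + n2, n1)
        obs_dev = abs(u1 - mu)
        hits = 0
        offset = n1 * (n1 + 1) / 2.0
        for idx in combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - offset
            if abs(u - mu) >= obs_dev - 1e-9:
                hits += 1
        return {"U": u1, "p_two_sided": hits / total, "exact": True}
    # tie-corrected normal approximation
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:  # all values tied
        return {"U": u1, "p_two_sided": 1.0, "exact": False}
    z = (abs(u1 - mu) - 0.5) / sqrt(sigma2)
    p = 2.0 * stats.norm.sf(max(z, 0.0))
    return {"U": u1, "p_two_sided": min(p, 1.0), "exact": False}


def levene_test(groups, center: str = "mean") -> dict[str, float]:
    """Levene's test of variance homogeneity across ``groups``.

    ``center="mean"`` is the classical Levene statistic on |x - group
    mean| deviations; ``center="median"`` gives the Brown-Forsythe
    variant.  The statistic is referred to an F(k-1, N-k) distribution.
    A ``degenerate`` flag marks inputs whose deviations are all zero in
    every group (constant groups), for which the statistic is undefined.
    """
    groups = [_as_clean_array(g, "group") for g in groups]
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    centre = np.mean if center == "mean" else np.median
    devs = [np.abs(g - centre(g)) for g in groups]
    if all(np.all(d == 0) for d in devs):
        return {"W": np.nan, "df": (k - 1, n_total - k), "p": np.nan, "degenerate": True}
    w, p = stats.levene(*groups, center=center)
    return {"W": float(w), "df": (k - 1, n_total - k), "p": float(p), "degenerate": False}


def _dunnett_mc_null(lams: np.ndarray, df: int, n_draws: int, seed: int) -> np.ndarray:
    """Monte-Carlo sample of max_i |T_i| under the Dunnett null.

    The null contrasts (treatment mean - control mean)/SE are
    equicorrelated multivariate t with corr(T_i, T_j) = lam_i * lam_j,
    lam_i = sqrt(n_i / (n_i + n_0)); this factor structure lets each
    draw be built from one shared and k-1 independent normals plus a
    chi-square denominator.
    """
    rng = np.random.default_rng(seed)
    z0 = rng.standard_normal(n_draws)
    eps = rng.standard_normal((n_draws, len(lams)))
    z = lams * z0[:, None] + np.sqrt(1.0 - lams**2) * eps
    s = np.sqrt(rng.chisquare(df, n_draws) / df)
    return np.max(np.abs(z / s[:, None]), axis=1)


def anova_dunnett(
    groups: dict[str, np.ndarray],
    control_label: str,
    n_mc: int = 100_000,
    mc_seed: int = 20210617,
) -> dict[str, object]:
    """One-way ANOVA plus Dunnett many-to-one comparisons against a control.

    The ANOVA F statistic and p-value follow the classical decomposition;
    Dunnett-adjusted two-sided p-values are computed by Monte-Carlo
    sampling (``n_mc`` draws, fixed ``mc_seed``) from the equicorrelated
    multivariate-t null of the max-|T| statistic.
    """
    if control_label not in groups:
        raise ValueError(f"control group {control_label!r} missing")
    labels = list(groups)
    data = {lab: _as_clean_array(groups[lab], lab) for lab in labels}
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    k = len(labels)
    n_total = sum(len(v) for v in data.values())
    f_stat, f_p = stats.f_oneway(*data.values())
    df_between, df_within = k - 1, n_total - k
    # pooled within-group variance
    ss_within = sum(np.sum((v - v.mean()) ** 2) for v in data.values())
    s2 = ss_within / df_within
    ctrl = data[control_label]
    others = [lab for lab in labels if lab != control_label]
    lams = np.array([sqrt(len(data[lab]) / (len(data[lab]) + len(ctrl))) for lab in others])
    null_max = _dunnett_mc_null(lams, df_within, n_mc, mc_seed)
    dunnett_p = {}
    t_stats = {}
    for lab in others:
        g = data[lab]
        se = sqrt(s2 * (1.0 / len(g) + 1.0 / len(ctrl)))
        t = (g.mean() - ctrl.mean()) / se
        t_stats[lab] = float(t)
        dunnett_p[lab] = float(np.mean(null_max >= abs(t)))
    return {
        "F": float(f_stat),
        "df": (df_between, df_within),
        "p": float(f_p),
        "t_vs_control": t_stats,
        "dunnett_p": dunnett_p,
    }


def pearson(x, y) -> dict[str, float]:
    """Pearson product-moment correlation with two-sided t-test p-value."""
    x = _as_clean_array(x, "x")
    y = _as_clean_array(y, "y")
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        return {"r": np.nan, "p": np.nan, "n": len(x), "degenerate": True}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": len(x), "degenerate": False}
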
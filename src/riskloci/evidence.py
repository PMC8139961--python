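"""Corroborating evidence: differential-expression meta-analysis,
differential-methylation screening, and co-expression.

Per-study differential expression is summarized as Hedges g (standardized
mean difference with the small-sample correction J = 1 - 3/(4(n1+n2-2)-1))
and pooled with the DerSimonian–Laird random-effects model:

    Q    = sum w_i (g_i - g_fixed)^2,            w_i = 1/v_i
    tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))
    g_RE = sum w*_i g_i / sum w*_i,              w*_i = 1/(v_i + tau2)

with a normal reference for the pooled p (standard DL, no t correction).
The pooling code is scale-agnostic given (effect, variance) pairs.

The methylation scan regresses each probe's beta value on the binary group
indicator plus covariates and screens probes at p < 1e-6; methylation stays
on the beta scale by default, with an optional logit (M-value) transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StudyEffect",
    "MetaResult",
    "study_effect",
    "meta_random_effects",
    "dmp_scan",
    "coexpression",
    "forest_plot",
]


@dataclass
class StudyEffect:
    """Hedges g and its sampling variance for one case/control study."""

    study_id: str
    g: float
    v: float
    n_case: int
    n_control: int


@dataclass
class MetaResult:
    """DerSimonian–Laird random-effects pooling across studies."""

    pooled: float
    se_pooled: float
    ci95: tuple
    tau2: float
    q: float
    p_meta: float
    k: int


def study_effect(case_values, control_values, study_id: str = "study") -> StudyEffect:
    """Hedges g (small-sample corrected SMD) for one study.

    ``g = J * (mean_case - mean_control) / s_pooled`` with
    ``J = 1 - 3/(4(n1+n2-2)-1)``; the variance is
    ``v = (n1+n2)/(n1*n2) + g^2/(2(n1+n2))``.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    n1, n2 = len(case), len(control)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    s2 = ((n1 - 1) * case.var(ddof=1) + (n2 - 1) * control.var(ddof=1)) / (n1 + n2 - 2)
    if s2 <= 0:
        raise ValueError(f"degenerate study {study_id}: zero pooled variance")
    j = 1.0 - 3.0 / (4.0 * (n1 + n2 - 2) - 1.0)
    g = j * (case.mean() - control.mean()) / np.sqrt(s2)
    v = (n1 + n2) / (n1 * n2) + g**2 / (2.0 * (n1 + n2))
    return StudyEffect(study_id=study_id, g=float(g), v=float(v), n_case=n1, n_control=n2)


def meta_random_effects(effects) -> MetaResult:
    """DerSimonian–Laird random-effects pooling of (effect, variance) pairs.

    Accepts a sequence of :class:`StudyEffect` or of ``(g, v)`` pairs.
    With a single study the pooled estimate is that study's effect with
    ``tau2 = 0``.
    """
    pairs = [(e.g, e.v) if isinstance(e, StudyEffect) else (float(e[0]), float(e[1]))
             for e in effects]
    k = len(pairs)
    if k == 0:
        raise ValueError("meta-analysis requires at least one study")
    g = np.array([p[0] for p in pairs])
    v = np.array([p[1] for p in pairs])
    if np.any(v <= 0):
        raise ValueError("study variances must be > 0")

    w = 1.0 / v
    g_fixed = float((w * g).sum() / w.sum())
    q = float((w * (g - g_fixed) ** 2).sum())
    if k == 1:
        tau2 = 0.0
    else:
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q - (k - 1)) / denom)
    w_star = 1.0 / (v + tau2)
    pooled = float((w_star * g).sum() / w_star.sum())
    se = float(1.0 / np.sqrt(w_star.sum()))
    p = float(np.clip(2.0 * stats.norm.sf(abs(pooled) / se), 1e-300, 1.0))
    return MetaResult(
        pooled=pooled,
        se_pooled=se,
        ci95=(pooled - 1.96 * se, pooled + 1.96 * se),
        tau2=float(tau2),
        q=q,
        p_meta=p,
        k=k,
    )


def dmp_scan(
    beta_matrix: pd.DataFrame,
    group,
    covariates=None,
    p_screen: float = 1e-6,
    m_values: bool = False,
):
    """Differential-methylation probe scan with covariate adjustment.

    Each probe (row of ``beta_matrix``, probes x samples) is regressed on
    the binary group indicator plus covariates via OLS; the two-sided
    t-based p on the group coefficient is screened at ``p_screen``.
    ``m_values=True`` applies a logit transform first.  Constant probes get
    p = NA and are excluded from the screen (counted).

    Returns ``(stats_df, screened_ids, n_constant)``.
    """
    group = np.asarray(group, dtype=float)
    if set(np.unique(group)) - {0.0, 1.0}:
        raise ValueError("group labels must be binary 0/1")
    Y = beta_matrix.to_numpy(dtype=float)
    if m_values:
        eps = 1e-9
        Yc = np.clip(Y, eps, 1 - eps)
        Y = np.log2(Yc / (1 - Yc))
    n = Y.shape[1]
    if len(group) != n:
        raise ValueError("group labels must align with samples")

    X = np.column_stack([np.ones(n), group])
    if covariates is not None and len(covariates.columns):
        X = np.hstack([X, covariates.to_numpy(dtype=float)])
    k = X.shape[1]
    df = n - k
    if df < 1:
        raise ValueError("not enough samples for the design")

    XtX_inv = np.linalg.pinv(X.T @ X)
    B = XtX_inv @ X.T @ Y.T  # k x probes
    resid = Y.T - X @ B
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    coef = B[1]

    constant = Y.std(axis=1) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, coef / se, np.nan)
    p = 2.0 * stats.t.sf(np.abs(tval), df)
    p[constant] = np.nan

    out = pd.DataFrame(
        {
            "probe": beta_matrix.index,
            "coef": coef,
            "se": se,
            "t": tval,
            "p": p,
        }
    )
    out["screened"] = out["p"] < p_screen
    screened = out.loc[out["screened"], "probe"].tolist()
    return out, screened, int(constant.sum())


def coexpression(expr: pd.DataFrame, gene_a: str, gene_b: str, log2_transform: bool = False):
    """Pearson co-expression of two genes over shared samples.

    ``expr`` is genes x samples; ``log2_transform`` applies
    ``log2(x + 1)`` first (the convention for count-scale RNA-seq input).
    Returns ``(r, p, n)`` with the p from the t transform on n-2 df.
    """
    x = expr.loc[gene_a].to_numpy(dtype=float)
    y = expr.loc[gene_b].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 shared samples")
    if log2_transform:
        x, y = np.log2(x + 1.0), np.log2(y + 1.0)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(len(x))


def forest_plot(effects, meta: MetaResult, path) -> None:
    """Minimal forest plot of per-study effects with the pooled diamond."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 0.5 * (len(effects) + 2) + 1))
    for i, e in enumerate(effects):
        half = 1.96 * np.sqrt(e.v)
        ax.errorbar(e.g, i, xerr=half, fmt="s", color="k", capsize=3)
        ax.text(-0.02, i, e.study_id, transform=ax.get_yaxis_transform(),
                ha="right", va="center")
    y = len(effects) + 0.5
    lo, hi = meta.ci95
    ax.plot([lo, meta.pooled, hi, meta.pooled, lo],
            [y, y - 0.25, y, y + 0.25, y], color="firebrick")
    ax.text(-0.02, y, "RE pooled", transform=ax.get_yaxis_transform(),
            ha="right", va="center")
    ax.axvline(0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("standardized mean difference (Hedges g)")
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
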
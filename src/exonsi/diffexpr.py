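"""Differential expression and exon-usage statistics.

Three test families operate on feature × sample matrices:

* :func:`paired_t_test` — per-row paired t on tumor−normal differences
  (gene-level expression, or qPCR log-ratios).
* :func:`exon_usage_test` — per-exon comparison of splicing-index values
  between two groups, paired or unpaired (Welch by default), optionally
  with empirical-Bayes variance moderation: per-exon variances are shrunk
  towards a common prior whose scale s0² and weight d0 are estimated from
  the across-exon spread of log variances by method of moments, and the
  moderated t gains d0 extra degrees of freedom.
* :func:`ptm_match` — Pavlidis template matching: Pearson correlation of
  each row against a template profile, with correlation-based p-values.

Multiple-testing correction (Benjamini–Hochberg step-up or Bonferroni) is in
:func:`adjust_pvalues`.  Rows whose variance is exactly zero cannot be
tested; they are reported with a ``degenerate`` flag, never silently
assigned p = 0.
"""

from __future__ import annotations

import logging
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .matrices import IntensityMatrix, SIMatrix

log = logging.getLogger(__name__)

RESULT_COLUMNS = ["feature_id", "effect", "t", "df", "p", "p_adj", "degenerate", "method"]
_ZERO_VAR_TOL = 1e-12


def _finish(
    feature_ids, effect, t, df, p, degenerate, method: str, correction: str | None
) -> pd.DataFrame:
    res = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "effect": effect,
            "t": t,
            "df": df,
            "p": p,
            "degenerate": degenerate,
            "method": method,
        }
    )
    res["p_adj"] = np.nan
    ok = res["p"].notna()
    if correction is not None and ok.any():
        res.loc[ok, "p_adj"] = adjust_pvalues(res.loc[ok, "p"].to_numpy(), method=correction)
    return res[RESULT_COLUMNS]


# ---------------------------------------------------------------------------
# paired t
# ---------------------------------------------------------------------------

def paired_t_test(
    matrix: IntensityMatrix | pd.DataFrame,
    pairing: Mapping[str, tuple[str, str]],
    correction: str | None = "BH",
) -> pd.DataFrame:
    """Row-wise paired t-test of case minus control.

    ``pairing`` maps subject → (control sample, case sample); the effect is
    the mean within-pair difference, t = mean(d) / (sd(d)/√n) with n−1
    degrees of freedom and a two-sided p.  Rows with zero within-pair
    variance are flagged degenerate (p and t undefined).
    """
    values = matrix.values if isinstance(matrix, IntensityMatrix) else matrix
    pairs = list(pairing.values())
    if len(pairs) < 3:
        raise ValueError("paired t-test needs at least 3 complete pairs")
    control = values[[p[0] for p in pairs]].to_numpy(dtype=float)
    case = values[[p[1] for p in pairs]].to_numpy(dtype=float)
    d = case - control
    n = d.shape[1]
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    degenerate = sd < _ZERO_VAR_TOL
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(np.abs(t), df)
    t[degenerate] = np.nan
    p[degenerate] = np.nan
    return _finish(values.index, mean, t, float(df), p, degenerate, "paired_t", correction)


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        step = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += step
        if abs(step) < tol * x:
            break
    return x


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0²) from log sample variances.

    Under the hierarchical model s² ~ s0² · F(df, d0), the log variances have
    known digamma/trigamma moments; matching the observed mean and variance
    of log s² yields the prior degrees of freedom d0 and scale s0².  When the
    observed spread is no larger than the sampling spread, d0 = ∞ and all
    variances shrink completely to s0².
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = np.var(e, ddof=1) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        # no excess spread: complete shrinkage to the common variance
        return np.inf, float(np.mean(s2))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0 = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Posterior variances s²_post = (d0·s0² + df·s²) / (d0 + df)."""
    d0, s0 = estimate_variance_prior(s2, df)
    if np.isinf(d0):
        return np.full_like(np.asarray(s2, dtype=float), s0), d0, s0
    post = (d0 * s0 + df * s2) / (d0 + df)
    return post, d0, s0


# ---------------------------------------------------------------------------
# exon usage
# ---------------------------------------------------------------------------

def exon_usage_test(
    si: SIMatrix | IntensityMatrix | pd.DataFrame,
    groups: pd.Series | Mapping[str, str],
    paired: bool = False,
    pairing: Mapping[str, tuple[str, str]] | None = None,
    shrink_variance: bool = True,
    equal_var: bool = False,
    correction: str | None = "BH",
) -> pd.DataFrame:
    """Differential exon usage on splicing-index values between two groups.

    Unpaired comparisons use Welch's t by default (``equal_var=True`` for the
    pooled-variance form); paired comparisons require ``pairing``.  With
    ``shrink_variance``, per-exon variances are moderated empirical-Bayes
    style (pooled variances are used for the unpaired case, since moderation
    assumes a common per-exon variance) and the t degrees of freedom become
    df + d0.  Exons with zero variance in both groups are flagged degenerate.
    """
    values = si.values if isinstance(si, (SIMatrix, IntensityMatrix)) else si
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    a_label, b_label = labels

    if paired:
        if pairing is None:
            raise ValueError("paired test requires a subject → (A, B) pairing")
        pairs = list(pairing.values())
        if len(pairs) < 3:
            raise ValueError("paired test needs at least 3 pairs")
        A = values[[p[0] for p in pairs]].to_numpy(dtype=float)
        B = values[[p[1] for p in pairs]].to_numpy(dtype=float)
        d = B - A
        n = d.shape[1]
        effect = d.mean(axis=1)
        s2 = d.var(axis=1, ddof=1)
        df = float(n - 1)
        sem_factor = 1.0 / n
        method = "paired"
    else:
        a_cols = groups.index[groups == a_label]
        b_cols = groups.index[groups == b_label]
        if len(a_cols) < 2 or len(b_cols) < 2:
            raise ValueError("each group needs at least 2 samples")
        A = values[list(a_cols)].to_numpy(dtype=float)
        B = values[list(b_cols)].to_numpy(dtype=float)
        na, nb = A.shape[1], B.shape[1]
        effect = B.mean(axis=1) - A.mean(axis=1)
        va, vb = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)
        if shrink_variance or equal_var:
            s2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            df = float(na + nb - 2)
            sem_factor = 1.0 / na + 1.0 / nb
            method = "pooled"
        else:
            s2 = va / na + vb / nb  # Welch: s2 is already the squared SEM
            with np.errstate(divide="ignore", invalid="ignore"):
                df_w = s2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            df = df_w
            sem_factor = 1.0
            method = "welch"

    degenerate = np.asarray(s2) < _ZERO_VAR_TOL
    if shrink_variance and method != "welch":
        s2_post, d0, _ = squeeze_variances(np.where(degenerate, np.nan, s2), df)
        total_df = df + d0
        method += "_moderated"
    else:
        s2_post, total_df = s2, df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(s2_post * sem_factor)
    t = np.asarray(t, dtype=float)
    if np.isscalar(total_df) or np.ndim(total_df) == 0:
        dist_df = np.inf if np.isinf(total_df) else total_df
        p = 2.0 * (stats.norm.sf(np.abs(t)) if np.isinf(dist_df) else stats.t.sf(np.abs(t), dist_df))
        df_out = float(total_df)
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
        df_out = total_df
    t[degenerate] = np.nan
    p = np.asarray(p, dtype=float)
    p[degenerate] = np.nan
    if degenerate.any():
        log.info("%d degenerate (zero-variance) exon(s) flagged", int(degenerate.sum()))
    return _finish(values.index, effect, t, df_out, p, degenerate, method, correction)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def adjust_pvalues(p, method: Literal["BH", "bonferroni"] = "BH") -> np.ndarray:
    """Benjamini–Hochberg step-up or Bonferroni adjustment, input order kept."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    key = {"BH": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown correction method {method!r}")
    return multipletests(p, method=key)[1]


# ---------------------------------------------------------------------------
# Pavlidis template matching
# ---------------------------------------------------------------------------

def ptm_match(
    matrix: IntensityMatrix | pd.DataFrame,
    template,
    r_min: float | None = None,
    p_max: float | None = None,
) -> pd.DataFrame:
    """Correlate every row against a template expression profile.

    ``template`` is either a feature id (a row of the matrix) or an explicit
    vector over the samples.  Pearson r is converted to a two-sided p-value
    via t = r·√((n−2)/(1−r²)) with n−2 degrees of freedom.  Rows with zero
    variance have undefined correlation and are excluded (their count is
    logged).  Rows passing the supplied threshold (r ≥ r_min or p ≤ p_max)
    are flagged.
    """
    values = matrix.values if isinstance(matrix, IntensityMatrix) else matrix
    if isinstance(template, str):
        if template not in values.index:
            raise KeyError(f"template feature {template!r} not in matrix")
        tvec = values.loc[template].to_numpy(dtype=float)
    else:
        tvec = np.asarray(template, dtype=float)
        if tvec.shape[0] != values.shape[1]:
            raise ValueError("template length does not match sample count")
    n = tvec.size
    if n < 4:
        raise ValueError("template must span at least 4 samples")
    tc = tvec - tvec.mean()
    t_norm = np.sqrt((tc**2).sum())
    if t_norm < _ZERO_VAR_TOL:
        raise ValueError("template has zero variance")

    X = values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    row_norm = np.sqrt((Xc**2).sum(axis=1))
    constant = row_norm < _ZERO_VAR_TOL
    if constant.any():
        log.info("excluded %d constant row(s) from template matching", int(constant.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ tc) / (row_norm * t_norm)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    p[np.isinf(tstat)] = 0.0

    res = pd.DataFrame({"feature_id": values.index, "r": r, "p": p})
    res = res.loc[~constant].reset_index(drop=True)
    if r_min is not None:
        res["passes"] = res["r"] >= r_min
    elif p_max is not None:
        res["passes"] = res["p"] <= p_max
    else:
        res["passes"] = False
    return res
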
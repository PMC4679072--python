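"""Model fitting, tests, and the corrected null distribution for adjusted data.

A one-way ANOVA run on batch-adjusted data assumes ``F ~ F_{M-1, n-M}``.
After covariate-preserving adjustment the samples are no longer independent
(each batch shares its batch-effect estimation error), and under the null
the between-group sum of squares is a weighted sum of chi-squares,

    SSB ~ sum_i lambda_i chi2_1,

with eigenvalue weights ``lambda_i`` fixed by the batch-group design.  The
one-way F statistic is then approximately

    F ~ inflation * df_correction * F_{q_tilde, n-M-m+1}

where ``q_tilde = (sum lambda)^2 / sum lambda^2`` (Satterthwaite effective
degrees of freedom), ``inflation = sum lambda / ((M-1) sigma^2)`` and
``df_correction = 1 + (m-1)/(n-M-m+1)``.  Both factors depend only on the
design's imbalance, not on the sample size, so growing the study does not
repair the miscalibration.  ``corrected_p`` inverts this law to restore
calibrated p-values; for two groups (a single lambda) the law is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from ._model import ModelOperators, build_operators, solve
from .adjust import AdjustedMatrix, ExpressionMatrix, _reordered_values
from .design import BatchGroupDesign, DesignError, effective_sample_size

__all__ = [
    "TwoWayFit",
    "GroupDiffEstimate",
    "NullFApprox",
    "fit_two_way",
    "group_diff_estimate",
    "group_means_with_ci",
    "oneway_f_test",
    "blocked_f_test",
    "null_f_approx",
    "corrected_p",
    "bh_fdr",
    "two_step_test",
]


@dataclass(frozen=True)
class TwoWayFit:
    """Per-feature least-squares fit of ``Y = alpha + beta_j + gamma_i + eps``.

    Group and batch effects are expressed with sample-weighted means zero, so
    ``alpha`` is the grand mean, and ``fitted + resid`` reconstructs the data
    exactly.  ``sigma2`` is the residual variance on ``n - M - m + 1`` df.
    """

    design: BatchGroupDesign
    feature_ids: tuple[str, ...]
    alpha: np.ndarray  # (features,)
    beta: np.ndarray  # (features, M)
    gamma: np.ndarray  # (features, m)
    sigma2: np.ndarray  # (features,)
    df_resid: int
    fitted: np.ndarray  # (features, n) in design sample order
    resid: np.ndarray
    _ops: ModelOperators
    _coef: np.ndarray

    def contrast_se(self, group_a: str, group_b: str) -> np.ndarray:
        """Standard error of the group contrast ``beta_a - beta_b`` per feature.

        For a two-group contrast this equals ``sigma_hat / sqrt(nu)`` with
        ``nu`` the effective sample size of the pair.
        """
        ja, jb = self._group_pos(group_a, group_b)
        c = self._ops.t_beta[ja] - self._ops.t_beta[jb]
        var_unit = float(c @ self._ops.xtx_inv @ c)
        return np.sqrt(self.sigma2 * var_unit)

    def contrast(self, group_a: str, group_b: str) -> np.ndarray:
        ja, jb = self._group_pos(group_a, group_b)
        return self.beta[:, ja] - self.beta[:, jb]

    def _group_pos(self, group_a: str, group_b: str) -> tuple[int, int]:
        for g in (group_a, group_b):
            if g not in self.design.groups:
                raise DesignError(f"unknown group label: {g!r}")
        return self.design.groups.index(group_a), self.design.groups.index(group_b)


def fit_two_way(Y: ExpressionMatrix, design: BatchGroupDesign) -> TwoWayFit:
    """Fit the additive two-way batch/group model per feature."""
    ops = build_operators(design)
    values, _ = _reordered_values(Y, design)
    fit = solve(ops, values)
    return TwoWayFit(
        design=design,
        feature_ids=Y.feature_ids,
        alpha=fit["alpha"],
        beta=fit["beta"],
        gamma=fit["gamma"],
        sigma2=fit["sigma2"],
        df_resid=ops.df_resid,
        fitted=fit["fitted"],
        resid=fit["resid"],
        _ops=ops,
        _coef=fit["coef"],
    )


@dataclass(frozen=True)
class GroupDiffEstimate:
    """Within-batch group differences and their precision-weighted pool.

    ``delta_per_batch[i] = Ybar_iA - Ybar_iB`` with weight ``nu_i``; the
    pooled estimate ``delta = sum nu_i delta_i / nu`` has variance
    ``sigma^2 / nu`` and coincides with the two-way least-squares contrast.
    A naive analysis would instead assume variance ``sigma^2 / nu0``.
    """

    group_a: str
    group_b: str
    delta_per_batch: np.ndarray  # (features, m); nan where a group is absent
    nu_per_batch: tuple[float, ...]
    delta: np.ndarray  # (features,)
    nu: float
    nu0: float


def group_diff_estimate(
    Y: ExpressionMatrix, design: BatchGroupDesign, group_a: str, group_b: str
) -> GroupDiffEstimate:
    """Per-batch and pooled group-difference estimates, direct from batch means."""
    ess = effective_sample_size(design, group_a, group_b)
    values, _ = _reordered_values(Y, design)
    ja = design.groups.index(group_a)
    jb = design.groups.index(group_b)
    m = design.m
    delta_i = np.full((values.shape[0], m), np.nan)
    for i in range(m):
        in_a = (design.batch_index == i) & (design.group_index == ja)
        in_b = (design.batch_index == i) & (design.group_index == jb)
        if in_a.any() and in_b.any():
            delta_i[:, i] = values[:, in_a].mean(axis=1) - values[:, in_b].mean(axis=1)
    nu_i = np.array(ess.nu_per_batch)
    if ess.nu == 0:
        pooled = np.full(values.shape[0], np.nan)
    else:
        pooled = np.nansum(delta_i * nu_i, axis=1) / ess.nu
    return GroupDiffEstimate(
        group_a=group_a,
        group_b=group_b,
        delta_per_batch=delta_i,
        nu_per_batch=ess.nu_per_batch,
        delta=pooled,
        nu=ess.nu,
        nu0=ess.nu0,
    )


def group_means_with_ci(fit: TwoWayFit, level: float = 0.95) -> pd.DataFrame:
    """Least-squares group means with t confidence intervals.

    Means are evaluated at the sample-weighted average batch (so for a
    single feature they are ``alpha + beta_j``); intervals use the two-way
    residual df and propagate the batch-effect estimation uncertainty
    through the full contrast covariance.  Fully analogous to least-squares
    (adjusted) means from a linear model with batch blocking.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    ops = fit._ops
    tcrit = st.t.ppf(0.5 + level / 2.0, fit.df_resid)
    rows = []
    for j, g in enumerate(fit.design.groups):
        c = ops.t_alpha + ops.t_beta[j]
        var_unit = float(c @ ops.xtx_inv @ c)
        est = fit.alpha + fit.beta[:, j]
        half = tcrit * np.sqrt(fit.sigma2 * var_unit)
        for k, feat in enumerate(fit.feature_ids):
            rows.append(
                {
                    "feature": feat,
                    "group": g,
                    "estimate": est[k],
                    "se": np.sqrt(fit.sigma2[k] * var_unit),
                    "lower": est[k] - half[k],
                    "upper": est[k] + half[k],
                    "df": fit.df_resid,
                    "level": level,
                }
            )
    return pd.DataFrame(rows)


def _group_layout(Y: ExpressionMatrix, design: BatchGroupDesign):
    values, _ = _reordered_values(Y, design)
    return values, design.group_index


def oneway_f_test(
    Yadj: ExpressionMatrix | AdjustedMatrix, design: BatchGroupDesign
) -> pd.DataFrame:
    """Standard one-way ANOVA across groups, per feature.

    Returns the F statistic and its naive p-value from ``F_{M-1, n-M}`` —
    the reference distribution a user unaware of the batch adjustment would
    apply.  On covariate-adjusted unbalanced data this p-value is
    anti-conservative; see :func:`null_f_approx` / :func:`corrected_p`.
    """
    if design.M < 2:
        raise DesignError("one-way test needs at least 2 groups")
    n, M = design.n, design.M
    if n - M < 1:
        raise DesignError("no residual degrees of freedom for the one-way test")
    values, gidx = _group_layout(Yadj, design)
    grand = values.mean(axis=1, keepdims=True)
    ssb = np.zeros(values.shape[0])
    ssw = np.zeros(values.shape[0])
    for j in range(M):
        sel = gidx == j
        nj = sel.sum()
        gm = values[:, sel].mean(axis=1)
        ssb += nj * (gm - grand[:, 0]) ** 2
        ssw += ((values[:, sel] - gm[:, None]) ** 2).sum(axis=1)
    F = (ssb / (M - 1)) / (ssw / (n - M))
    p = st.f.sf(F, M - 1, n - M)
    return pd.DataFrame({"feature": list(Yadj.feature_ids), "F": F, "p": p})


def blocked_f_test(Y: ExpressionMatrix, design: BatchGroupDesign) -> pd.DataFrame:
    """Group F test from the two-way model with batch as a blocking factor.

    This is the recommended analysis: the extra-sum-of-squares F comparing
    the full model (batch + group) against batch alone, on
    ``(M-1, n-M-m+1)`` df.  Calibrated for any connected design.
    """
    ops = build_operators(design)
    values, _ = _reordered_values(Y, design)
    full = solve(ops, values)
    sse_full = (full["resid"] ** 2).sum(axis=1)
    # reduced model: batch effects only
    Xr = np.column_stack([np.ones(design.n), ops.batch_onehot[:, 1:]])
    pr = np.linalg.pinv(Xr)
    resid_r = values - (values @ pr.T) @ Xr.T
    sse_red = (resid_r**2).sum(axis=1)
    M = design.M
    F = ((sse_red - sse_full) / (M - 1)) / (sse_full / ops.df_resid)
    p = st.f.sf(F, M - 1, ops.df_resid)
    return pd.DataFrame({"feature": list(Y.feature_ids), "F": F, "p": p})


@dataclass(frozen=True)
class NullFApprox:
    """Null law of the one-way F statistic on covariate-adjusted data.

    ``lambdas`` are the nonzero eigenvalues (in units of sigma^2) of the
    between-group quadratic form applied to adjusted data; ``q_tilde`` and
    ``sigma_tilde_sq`` are the Satterthwaite moment-matched effective df and
    scale; ``inflation = q_tilde sigma_tilde_sq / (M-1)`` is the systematic
    F inflation factor and ``df_correction = 1 + (m-1)/(n-M-m+1)`` accounts
    for the residual df consumed by the batch adjustment.  All quantities
    except the df correction depend only on the design's proportions.
    """

    design: BatchGroupDesign
    lambdas: np.ndarray
    q_tilde: float
    sigma_tilde_sq: float
    df_denom: int
    df_correction: float
    inflation: float

    def to_dict(self) -> dict:
        return {
            "lambdas": [float(v) for v in self.lambdas],
            "q_tilde": self.q_tilde,
            "sigma_tilde_sq": self.sigma_tilde_sq,
            "df_denom": self.df_denom,
            "df_correction": self.df_correction,
            "inflation": self.inflation,
        }


def null_f_approx(design: BatchGroupDesign) -> NullFApprox:
    """Construct the corrected null F law for a design, by explicit matrices.

    Under the null the adjusted data are ``(I - Gamma) y`` with ``Gamma`` the
    linear smoother that assembles the centered batch-effect estimates, and
    the between-group numerator is the quadratic form with matrix
    ``(I - Gamma)' A (I - Gamma)`` where ``A`` projects onto group means
    minus the grand mean.  Its nonzero eigenvalues are the ``lambda_i``.
    Brute-force eigendecomposition keeps the construction auditable; cost is
    O(n^3) in the number of samples.
    """
    if design.M < 2:
        raise DesignError("null F approximation needs at least 2 groups")
    ops = build_operators(design)
    n, M, m = design.n, design.M, design.m
    I = np.eye(n)
    adjust_map = I - ops.gamma_smoother
    G = ops.group_onehot
    P_group = G @ np.diag(1.0 / design.col_totals) @ G.T
    A = P_group - np.full((n, n), 1.0 / n)
    N = adjust_map.T @ A @ adjust_map
    eig = np.linalg.eigvalsh((N + N.T) / 2.0)
    lambdas = np.clip(np.sort(eig)[::-1][: M - 1], 0.0, None)
    s1 = float(lambdas.sum())
    s2 = float((lambdas**2).sum())
    q_tilde = s1**2 / s2
    sigma_tilde_sq = s2 / s1
    df_denom = n - M - m + 1
    df_correction = 1.0 + (m - 1) / df_denom
    inflation = s1 / (M - 1)
    return NullFApprox(
        design=design,
        lambdas=lambdas,
        q_tilde=q_tilde,
        sigma_tilde_sq=sigma_tilde_sq,
        df_denom=df_denom,
        df_correction=df_correction,
        inflation=inflation,
    )


def corrected_p(F, approx: NullFApprox):
    """Calibrated upper-tail p-value for one-way F on covariate-adjusted data.

    ``p = P(F_{q_tilde, n-M-m+1} > F / (inflation * df_correction))``.
    Exact for two groups (single eigenvalue); Satterthwaite-approximate for
    ``M > 2`` unbalanced designs.
    """
    F = np.asarray(F, dtype=float)
    if (F < 0).any():
        raise ValueError("F statistics must be non-negative")
    scaled = F / (approx.inflation * approx.df_correction)
    return st.f.sf(scaled, approx.q_tilde, approx.df_denom)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def two_step_test(
    Y: ExpressionMatrix,
    design: BatchGroupDesign,
    method: str = "anova",
    shrink: float | str = "auto",
) -> pd.DataFrame:
    """The two-step pipeline with both naive and corrected p-values.

    Adjusts for batch (``method`` in {'center', 'anova', 'eb'}), runs the
    one-way F test per feature, and reports the naive p (reference
    ``F_{M-1, n-M}``), the corrected p from the design's null F law, and BH
    q-values for both.  Columns: feature, F, p_naive, p_corrected, q_naive,
    q_corrected.
    """
    from .adjust import anova_adjust, center_batches, eb_adjust

    if method == "center":
        Yadj = center_batches(Y, design, target="grand_mean")
    elif method == "anova":
        Yadj = anova_adjust(Y, design)
    elif method == "eb":
        Yadj = eb_adjust(Y, design, shrink=shrink)
    else:
        raise ValueError(f"unknown adjustment method: {method!r}")
    res = oneway_f_test(Yadj, design)
    approx = null_f_approx(design)
    p_corr = corrected_p(res["F"].to_numpy(), approx)
    return pd.DataFrame(
        {
            "feature": res["feature"],
            "F": res["F"],
            "p_naive": res["p"],
            "p_corrected": p_corr,
            "q_naive": bh_fdr(res["p"].to_numpy()),
            "q_corrected": bh_fdr(p_corr),
        }
    )
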
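"""Shared least-squares machinery for the additive two-way batch/group model.

The model per feature is ``Y_ijr = alpha + beta_j + gamma_i + eps_ijr`` with
``eps ~ N(0, sigma^2)``.  Internally a reference-cell design matrix is used
(first group and first batch absorbed into the intercept); estimates are then
re-expressed under sum-to-zero-with-sample-weights constraints so that the
``n_i-``-weighted mean of the batch effects and the ``n_-j``-weighted mean of
the group effects are both zero.  Subtracting batch effects in that
parameterization leaves the grand mean of the data unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import BatchGroupDesign, DesignError


class IdentifiabilityError(DesignError):
    """Two-way model not identifiable (disconnected batch-group design)."""


class ReplicationError(DesignError):
    """Not enough residual degrees of freedom to estimate the error variance."""


@dataclass(frozen=True)
class ModelOperators:
    """Precomputed linear operators for a batch-group design.

    Attributes
    ----------
    X : (n, p) reference-cell design matrix, p = 1 + (M-1) + (m-1).
    pinv : (p, n) Moore-Penrose inverse of ``X`` (full column rank verified).
    xtx_inv : (p, p) inverse of the normal matrix, for contrast variances.
    t_alpha, t_beta, t_gamma : rows mapping the reference-cell coefficient
        vector to the weighted-centered intercept, group effects (M rows)
        and batch effects (m rows).
    gamma_smoother : (n, n) matrix ``Gamma`` with ``Gamma @ y`` = per-sample
        centered batch-effect estimate; batch adjustment is ``(I - Gamma) y``.
    df_resid : residual degrees of freedom n - M - m + 1.
    """

    design: BatchGroupDesign
    X: np.ndarray
    pinv: np.ndarray
    xtx_inv: np.ndarray
    t_alpha: np.ndarray
    t_beta: np.ndarray
    t_gamma: np.ndarray
    batch_onehot: np.ndarray
    group_onehot: np.ndarray
    df_resid: int

    @property
    def gamma_smoother(self) -> np.ndarray:
        return self.batch_onehot @ self.t_gamma @ self.pinv


def check_fittable(design: BatchGroupDesign) -> None:
    """Raise if the two-way model cannot be fit on this design."""
    comps = design.connected_components()
    if len(comps) > 1:
        desc = "; ".join(
            f"component {k+1}: batches {b} with groups {g}"
            for k, (b, g) in enumerate(comps)
        )
        raise IdentifiabilityError(
            "batch-group design is disconnected; group differences across "
            f"components are not estimable within batches ({desc})"
        )
    df = design.n - design.M - design.m + 1
    if df < 1:
        raise ReplicationError(
            f"insufficient replication: residual df n - M - m + 1 = {df} < 1"
        )


def build_operators(design: BatchGroupDesign) -> ModelOperators:
    check_fittable(design)
    n, m, M = design.n, design.m, design.M
    B = np.zeros((n, m))
    B[np.arange(n), design.batch_index] = 1.0
    G = np.zeros((n, M))
    G[np.arange(n), design.group_index] = 1.0
    X = np.column_stack([np.ones(n), G[:, 1:], B[:, 1:]])
    p = 1 + (M - 1) + (m - 1)

    rank = np.linalg.matrix_rank(X)
    if rank != p:  # connectivity was checked, so this is a genuine defect
        raise IdentifiabilityError(
            f"design matrix rank {rank} < expected {p}; model not identifiable"
        )
    pinv = np.linalg.pinv(X)
    xtx_inv = np.linalg.inv(X.T @ X)

    # reference-cell extractors: beta_full (M, p), gamma_full (m, p)
    e_beta = np.zeros((M, p))
    for j in range(1, M):
        e_beta[j, j] = 1.0
    e_gamma = np.zeros((m, p))
    for i in range(1, m):
        e_gamma[i, M - 1 + i] = 1.0
    w_batch = design.row_totals / n
    w_group = design.col_totals / n
    t_gamma = (np.eye(m) - np.outer(np.ones(m), w_batch)) @ e_gamma
    t_beta = (np.eye(M) - np.outer(np.ones(M), w_group)) @ e_beta
    e0 = np.zeros(p)
    e0[0] = 1.0
    t_alpha = e0 + w_group @ e_beta + w_batch @ e_gamma

    return ModelOperators(
        design=design,
        X=X,
        pinv=pinv,
        xtx_inv=xtx_inv,
        t_alpha=t_alpha,
        t_beta=t_beta,
        t_gamma=t_gamma,
        batch_onehot=B,
        group_onehot=G,
        df_resid=n - M - m + 1,
    )


def solve(ops: ModelOperators, values: np.ndarray) -> dict[str, np.ndarray]:
    """Least-squares fit of the two-way model for all features at once.

    Parameters
    ----------
    values : (n_features, n_samples) data aligned to the design's sample order.

    Returns
    -------
    dict with ``alpha`` (features,), ``beta`` (features, M), ``gamma``
    (features, m) in the weighted-centered parameterization, ``fitted``,
    ``resid`` and the residual variance ``sigma2`` on ``df_resid`` df.
    """
    coef = values @ ops.pinv.T  # (features, p)
    alpha = coef @ ops.t_alpha
    beta = coef @ ops.t_beta.T
    gamma = coef @ ops.t_gamma.T
    fitted = coef @ ops.X.T
    resid = values - fitted
    sigma2 = (resid**2).sum(axis=1) / ops.df_resid
    return {
        "coef": coef,
        "alpha": alpha,
        "beta": beta,
        "gamma": gamma,
        "fitted": fitted,
        "resid": resid,
        "sigma2": sigma2,
    }
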
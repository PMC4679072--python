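"""Batch-adjustment methods for expression-style matrices.

Three adjustment families are provided:

* per-batch centering (``center_batches``), the one-way approach: subtract
  each batch's mean, optionally re-adding the grand mean.  In unbalanced
  designs the batch mean absorbs part of the group differences
  (the composition-weighted contamination term ``beta_bar_i``), so
  centering shrinks and can distort group contrasts;
* covariate-preserving adjustment (``anova_adjust``): estimate batch and
  group effects jointly in the additive two-way model and subtract only the
  estimated batch effects.  Group contrasts are preserved exactly, but the
  shared estimation error per batch induces cross-sample dependence that
  downstream one-way analyses ignore;
* a location-shrinkage variant (``eb_adjust``) that moderates the per-feature
  batch-effect estimates toward the cross-feature mean, in the spirit of
  empirical-Bayes batch correction.

None of these make adjusted data safe for naive downstream testing on
unbalanced designs; see :mod:`batchaudit.inference` for the corrected null
distribution.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from ._model import build_operators, solve
from .design import BatchGroupDesign, DesignError

__all__ = [
    "ExpressionMatrix",
    "AdjustedMatrix",
    "CenteringDecomposition",
    "center_batches",
    "anova_adjust",
    "eb_adjust",
    "centering_decomposition",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Features x samples numeric matrix with identifiers.

    Missing or non-finite values are rejected on construction: the additive
    model assumes complete data, and silently masking cells would change the
    per-feature design.
    """

    values: np.ndarray
    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_ids", tuple(map(str, self.feature_ids)))
        object.__setattr__(self, "sample_ids", tuple(map(str, self.sample_ids)))
        if values.ndim != 2:
            raise DesignError("expression values must be a 2-D matrix")
        if values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise DesignError("values shape does not match feature/sample ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise DesignError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DesignError("duplicate sample ids")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise DesignError(
                "missing/non-finite value at feature "
                f"{self.feature_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class AdjustedMatrix(ExpressionMatrix):
    """Batch-adjusted matrix with adjustment provenance.

    ``batch_effects[g, i]`` is the constant actually subtracted from every
    sample of batch ``i`` for feature ``g``; ``method`` names the adjustment;
    ``provenance`` records a design hash and parameters.
    """

    method: str = "unknown"
    batch_effects: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)


def design_hash(design: BatchGroupDesign) -> str:
    payload = repr((design.batches, design.groups, design.counts.tolist())).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def sample_batch_index(Y: ExpressionMatrix, design: BatchGroupDesign) -> np.ndarray:
    """Batch index for each matrix column, by sample id."""
    lookup = dict(zip(design.sample_ids, design.batch_index))
    missing = [s for s in Y.sample_ids if s not in lookup]
    extra = set(design.sample_ids) - set(Y.sample_ids)
    if missing or extra:
        raise DesignError(
            f"sample mismatch between matrix and annotation: matrix-only={missing}, "
            f"annotation-only={sorted(extra)}"
        )
    return np.array([lookup[s] for s in Y.sample_ids], dtype=int)


def _reordered_values(Y: ExpressionMatrix, design: BatchGroupDesign) -> tuple[np.ndarray, np.ndarray]:
    """Values with columns permuted into the design's sample order.

    Returns (values_in_design_order, inverse permutation back to matrix order).
    """
    sample_batch_index(Y, design)  # validates id sets match
    pos = {s: k for k, s in enumerate(Y.sample_ids)}
    order = np.array([pos[s] for s in design.sample_ids], dtype=int)
    inverse = np.empty_like(order)
    inverse[order] = np.arange(len(order))
    return Y.values[:, order], inverse


def center_batches(
    Y: ExpressionMatrix, design: BatchGroupDesign, target: str = "zero"
) -> AdjustedMatrix:
    """Center each batch per feature, to zero or to the grand mean.

    ``target='zero'`` subtracts the batch mean ``Ybar_i``; ``target='grand_mean'``
    additionally adds back the overall mean ``Ybar`` so the data keep their
    location.  Group contrasts are identical between the two targets.
    """
    if target not in ("zero", "grand_mean"):
        raise ValueError(f"unknown centering target: {target!r}")
    b = sample_batch_index(Y, design)
    m = design.m
    batch_means = np.empty((Y.n_features, m))
    for i in range(m):
        batch_means[:, i] = Y.values[:, b == i].mean(axis=1)
    subtracted = batch_means.copy()
    if target == "grand_mean":
        subtracted -= Y.values.mean(axis=1, keepdims=True)
    adjusted = Y.values - subtracted[:, b]
    return AdjustedMatrix(
        values=adjusted,
        feature_ids=Y.feature_ids,
        sample_ids=Y.sample_ids,
        method="center_zero" if target == "zero" else "center_grand_mean",
        batch_effects=subtracted,
        provenance={"design": design_hash(design), "target": target},
    )


def anova_adjust(Y: ExpressionMatrix, design: BatchGroupDesign) -> AdjustedMatrix:
    """Covariate-preserving batch adjustment via the two-way additive model.

    Per feature, batch and group effects are estimated jointly by least
    squares and only the batch effects are subtracted, re-expressed so their
    ``n_i-``-weighted mean is zero (the grand mean of the data is preserved).
    Group-mean differences of the adjusted data equal the two-way contrast
    estimates exactly, and every within-batch pairwise sample difference is
    untouched.
    """
    ops = build_operators(design)
    values, inverse = _reordered_values(Y, design)
    fit = solve(ops, values)
    gamma = fit["gamma"]  # (features, m), weighted-centered
    adjusted = values - gamma[:, design.batch_index]
    return AdjustedMatrix(
        values=adjusted[:, inverse],
        feature_ids=Y.feature_ids,
        sample_ids=Y.sample_ids,
        method="anova_covariate",
        batch_effects=gamma,
        provenance={"design": design_hash(design)},
    )


def eb_adjust(
    Y: ExpressionMatrix, design: BatchGroupDesign, shrink: float | str = "auto"
) -> AdjustedMatrix:
    """Covariate-preserving adjustment with batch effects shrunk across features.

    The per-feature batch-effect estimates ``gamma_hat[g, i]`` from the
    two-way fit are pulled toward their cross-feature mean per batch with a
    normal-prior location-shrinkage weight

        w[g, i] = tau2[i] / (tau2[i] + s2[g, i])

    where ``tau2[i]`` is the method-of-moments cross-feature variance of the
    estimates (in excess of their sampling noise) and ``s2[g, i]`` the
    per-feature sampling variance of ``gamma_hat[g, i]``.  With no true batch
    effects, ``tau2`` is near zero and the adjustment is strongly moderated;
    with large shared batch effects the weight approaches 1 and the result
    approaches :func:`anova_adjust`.  ``shrink`` may also be a fixed weight
    in [0, 1]: 1 reproduces ``anova_adjust``, 0 subtracts only the
    cross-feature mean effect.
    """
    ops = build_operators(design)
    values, inverse = _reordered_values(Y, design)
    fit = solve(ops, values)
    gamma = fit["gamma"]  # (features, m)
    n_feat = gamma.shape[0]
    center = gamma.mean(axis=0)  # cross-feature mean batch effect

    if shrink == "auto":
        if n_feat < 2:
            raise DesignError("shrink='auto' needs at least 2 features to pool across")
        # sampling variance of centered gamma_hat: sigma2_g * diag(T (X'X)^-1 T')
        c = np.einsum(
            "ip,pq,iq->i", ops.t_gamma, ops.xtx_inv, ops.t_gamma
        )  # (m,)
        s2 = np.outer(fit["sigma2"], c)  # (features, m)
        emp_var = gamma.var(axis=0, ddof=1)  # (m,)
        tau2 = np.maximum(emp_var - s2.mean(axis=0), 0.0)
        weight = tau2 / (tau2 + s2)
    else:
        shrink = float(shrink)
        if not 0.0 <= shrink <= 1.0:
            raise ValueError("shrink must be in [0, 1] or 'auto'")
        weight = np.full_like(gamma, shrink)

    shrunk = center + weight * (gamma - center)
    # re-center so the weighted mean of subtracted effects stays zero
    w_batch = design.row_totals / design.n
    shrunk = shrunk - (shrunk @ w_batch)[:, None]
    adjusted = values - shrunk[:, design.batch_index]
    return AdjustedMatrix(
        values=adjusted[:, inverse],
        feature_ids=Y.feature_ids,
        sample_ids=Y.sample_ids,
        method="eb_covariate",
        batch_effects=shrunk,
        provenance={"design": design_hash(design), "shrink": shrink},
    )


@dataclass(frozen=True)
class CenteringDecomposition:
    """Analytic decomposition of what per-batch centering subtracts.

    For true group effects ``beta`` and errors ``eps``, centering batch ``i``
    subtracts ``beta_bar_i + eps_bar_i`` (plus any true batch effect), where
    ``beta_bar_i = sum_j w_ij beta_j`` is the group-composition contamination
    and ``eps_bar_i`` the batch mean error.  In a proportional design all
    ``beta_bar_i`` coincide and group contrasts are unharmed.
    """

    beta_bar: np.ndarray  # (features, m)
    eps_bar: np.ndarray  # (features, m)


def centering_decomposition(
    design: BatchGroupDesign, beta: np.ndarray, eps: np.ndarray
) -> CenteringDecomposition:
    """Compute the contamination terms of per-batch centering.

    Parameters
    ----------
    beta : (features, M) true group effects.
    eps : (features, n) error terms aligned to the design's sample order.
    """
    beta = np.atleast_2d(beta)
    eps = np.atleast_2d(eps)
    beta_bar = beta @ design.weights.T  # (features, m)
    m = design.m
    eps_bar = np.empty((eps.shape[0], m))
    for i in range(m):
        eps_bar[:, i] = eps[:, design.batch_index == i].mean(axis=1)
    return CenteringDecomposition(beta_bar=beta_bar, eps_bar=eps_bar)
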
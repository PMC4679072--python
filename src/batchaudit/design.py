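"""Batch-group design objects and effective-sample-size diagnostics.

The central combinatorial object is the m x M contingency table ``n_ij`` of
samples per (batch, group).  All reliability diagnostics for two-step batch
adjustment are functions of this table alone: the effective sample size

    nu = sum_i 1 / (1/n_iA + 1/n_iB)

of the within-batch pooled group-difference estimator, the nominal sample
size ``nu0 = 1 / (1/n_A + 1/n_B)`` assumed by an analysis that ignores
batches, and their ratio ``nu0/nu >= 1`` which quantifies by how much a
two-step pipeline (adjust for batch, then test ignoring batch) overstates
the information in the data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BatchGroupDesign",
    "EffectiveSampleSize",
    "DesignError",
    "build_design",
    "design_from_counts",
    "effective_sample_size",
    "balance_report",
]


class DesignError(ValueError):
    """Invalid or inconsistent batch-group design / annotation."""


@dataclass(frozen=True)
class BatchGroupDesign:
    """Cross-tabulation of samples by batch and study group.

    Parameters
    ----------
    batches, groups
        Labels in first-appearance order (no lexical sorting is imposed).
    counts
        Integer table of shape ``(m, M)`` with entry ``n_ij`` = number of
        samples in batch ``i`` and group ``j``.
    sample_ids, batch_index, group_index
        Per-sample membership aligned to the annotation order.  Present when
        the design was built from an annotation table; synthetic designs
        built from a bare counts table get generated sample ids.
    """

    batches: tuple[str, ...]
    groups: tuple[str, ...]
    counts: np.ndarray
    sample_ids: tuple[str, ...]
    batch_index: np.ndarray = field(repr=False)
    group_index: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "batch_index", np.asarray(self.batch_index))
        object.__setattr__(self, "group_index", np.asarray(self.group_index))
        if counts.ndim != 2 or counts.shape != (len(self.batches), len(self.groups)):
            raise DesignError("counts shape does not match batch/group labels")
        if (counts < 0).any():
            raise DesignError("negative cell counts")
        if (counts.sum(axis=1) < 1).any():
            raise DesignError("every batch must contain at least one sample")
        if (counts.sum(axis=0) < 1).any():
            raise DesignError("every group must contain at least one sample")

    @property
    def m(self) -> int:
        return len(self.batches)

    @property
    def M(self) -> int:
        return len(self.groups)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        """Per-batch totals n_i-."""
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        """Per-group totals n_-j."""
        return self.counts.sum(axis=0)

    @property
    def weights(self) -> np.ndarray:
        """Group-composition weights w_ij = n_ij / n_i- (rows sum to 1)."""
        return self.counts / self.row_totals[:, None]

    def is_proportional(self, tol: float = 1e-12) -> bool:
        """True when every batch has the same group composition.

        Equivalent to ``n_ij = n_i- * n_-j / n`` for all cells, the equality
        case of the Jensen bound ``nu <= nu0``.
        """
        expected = np.outer(self.row_totals, self.col_totals) / self.n
        return bool(np.abs(self.counts - expected).max() <= tol * max(1, self.n))

    def is_connected(self) -> bool:
        """Whether the bipartite batch-group graph on nonzero cells is connected.

        A disconnected design means some group contrasts are never observed
        within a batch, so the two-way model is not identifiable.
        """
        return len(self.connected_components()) <= 1

    def connected_components(self) -> list[tuple[list[str], list[str]]]:
        """Connected components as (batch labels, group labels) pairs.

        Union-find over the nonzero cells of the contingency table.
        """
        m, M = self.counts.shape
        parent = list(range(m + M))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j in zip(*np.nonzero(self.counts)):
            ri, rj = find(int(i)), find(int(j) + m)
            if ri != rj:
                parent[rj] = ri
        comps: dict[int, tuple[list[str], list[str]]] = {}
        for i in range(m):
            comps.setdefault(find(i), ([], []))[0].append(self.batches[i])
        for j in range(M):
            comps.setdefault(find(j + m), ([], []))[1].append(self.groups[j])
        return list(comps.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.batches), columns=list(self.groups))


@dataclass(frozen=True)
class EffectiveSampleSize:
    """Effective vs nominal precision of a two-group comparison.

    ``nu_per_batch[i] = 1/(1/n_iA + 1/n_iB)`` (0 when either count is 0),
    ``nu = sum(nu_per_batch)``, ``nu0 = 1/(1/n_A + 1/n_B)``, and
    ``ratio = nu0/nu`` (+inf for fully confounded pairs with nu = 0).
    """

    group_a: str
    group_b: str
    nu_per_batch: tuple[float, ...]
    nu: float
    nu0: float
    ratio: float
    n_a: int
    n_b: int

    def to_dict(self) -> dict:
        return {
            "group_a": self.group_a,
            "group_b": self.group_b,
            "nu_per_batch": list(self.nu_per_batch),
            "nu": self.nu,
            "nu0": self.nu0,
            "ratio": self.ratio,
            "n_a": self.n_a,
            "n_b": self.n_b,
        }


def build_design(annotation: pd.DataFrame) -> BatchGroupDesign:
    """Cross-tabulate a sample annotation table into a :class:`BatchGroupDesign`.

    Parameters
    ----------
    annotation
        Table with columns ``sample``, ``batch``, ``group`` (one row per
        sample).  Label order is first appearance; sample ids must be unique.
    """
    required = {"sample", "batch", "group"}
    missing = required - set(annotation.columns)
    if missing:
        raise DesignError(f"annotation missing required column(s): {sorted(missing)}")
    if len(annotation) < 1:
        raise DesignError("annotation is empty")
    samples = annotation["sample"].astype(str)
    dup = samples[samples.duplicated()]
    if len(dup):
        raise DesignError(f"duplicate sample id(s): {sorted(set(dup))}")
    batch = annotation["batch"].astype(str)
    group = annotation["group"].astype(str)
    if (batch.str.len() == 0).any() or (group.str.len() == 0).any():
        raise DesignError("batch and group labels must be non-empty")

    batches = tuple(dict.fromkeys(batch))  # first-appearance order
    groups = tuple(dict.fromkeys(group))
    b_idx = {b: i for i, b in enumerate(batches)}
    g_idx = {g: j for j, g in enumerate(groups)}
    batch_index = batch.map(b_idx).to_numpy()
    group_index = group.map(g_idx).to_numpy()
    counts = np.zeros((len(batches), len(groups)), dtype=int)
    np.add.at(counts, (batch_index, group_index), 1)
    return BatchGroupDesign(
        batches=batches,
        groups=groups,
        counts=counts,
        sample_ids=tuple(samples),
        batch_index=batch_index,
        group_index=group_index,
    )


def design_from_counts(counts, batches=None, groups=None) -> BatchGroupDesign:
    """Build a design (with generated sample ids) from a bare n_ij table.

    Samples are laid out batch-major then group-major, which fixes a
    deterministic sample order for simulation.
    """
    counts = np.asarray(counts, dtype=int)
    m, M = counts.shape
    batches = tuple(batches) if batches is not None else tuple(f"batch{i+1}" for i in range(m))
    groups = tuple(groups) if groups is not None else tuple(f"group{j+1}" for j in range(M))
    rows = []
    for i in range(m):
        for j in range(M):
            rows.extend([(i, j)] * counts[i, j])
    batch_index = np.array([r[0] for r in rows], dtype=int)
    group_index = np.array([r[1] for r in rows], dtype=int)
    sample_ids = tuple(f"s{k+1:04d}" for k in range(len(rows)))
    return BatchGroupDesign(
        batches=batches,
        groups=groups,
        counts=counts,
        sample_ids=sample_ids,
        batch_index=batch_index,
        group_index=group_index,
    )


def annotation_frame(design: BatchGroupDesign) -> pd.DataFrame:
    """Per-sample annotation table for a design (inverse of build_design)."""
    return pd.DataFrame(
        {
            "sample": list(design.sample_ids),
            "batch": [design.batches[i] for i in design.batch_index],
            "group": [design.groups[j] for j in design.group_index],
        }
    )


def effective_sample_size(
    design: BatchGroupDesign, group_a: str, group_b: str
) -> EffectiveSampleSize:
    """Effective sample size nu, nominal nu0 and over-confidence ratio nu0/nu.

    Per batch, ``nu_i = 1/(1/n_iA + 1/n_iB)`` is the precision contributed by
    the within-batch comparison of groups A and B; a batch missing either
    group contributes ``nu_i = 0`` (it adds nominal but not effective sample
    size).  ``nu0 = 1/(1/n_A + 1/n_B)`` is the precision a one-way analysis
    would assume.  Jensen's inequality gives ``nu <= nu0`` with equality iff
    ``n_iA : n_iB`` is constant across batches.
    """
    for g in (group_a, group_b):
        if g not in design.groups:
            raise DesignError(f"unknown group label: {g!r}")
    ja = design.groups.index(group_a)
    jb = design.groups.index(group_b)
    na_i = design.counts[:, ja].astype(float)
    nb_i = design.counts[:, jb].astype(float)
    with np.errstate(divide="ignore"):
        nu_i = np.where((na_i > 0) & (nb_i > 0), 1.0 / (1.0 / na_i + 1.0 / nb_i), 0.0)
    nu = float(nu_i.sum())
    n_a, n_b = int(na_i.sum()), int(nb_i.sum())
    nu0 = 1.0 / (1.0 / n_a + 1.0 / n_b)
    ratio = nu0 / nu if nu > 0 else math.inf
    return EffectiveSampleSize(
        group_a=group_a,
        group_b=group_b,
        nu_per_batch=tuple(float(v) for v in nu_i),
        nu=nu,
        nu0=nu0,
        ratio=ratio,
        n_a=n_a,
        n_b=n_b,
    )


def balance_report(design: BatchGroupDesign) -> dict:
    """Design-level reliability audit.

    Returns the effective-sample-size diagnostics for every unordered group
    pair, plus a ``proportional`` flag (all batches share the group
    composition; all ratios are then exactly 1) and a ``connected`` flag
    (two-way model identifiable).  Fully confounded pairs are reported with
    ``ratio = +inf`` rather than raising.
    """
    pairs = [
        effective_sample_size(design, a, b)
        for a, b in itertools.combinations(design.groups, 2)
    ]
    return {
        "batches": list(design.batches),
        "groups": list(design.groups),
        "counts": design.counts.tolist(),
        "n": design.n,
        "pairs": [p.to_dict() for p in pairs],
        "proportional": design.is_proportional(),
        "connected": design.is_connected(),
        "max_ratio": max((p.ratio for p in pairs), default=1.0),
    }
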
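"""Readers and writers for matrices, annotations and reports.

Matrices are delimited text, features in rows: first column feature id,
header row of sample ids.  Annotations need columns ``sample``, ``batch``,
``group`` (case-insensitive; extra columns are ignored with a warning).
Tab is the default delimiter; comma is auto-detected.  Values round-trip at
10 significant digits.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .adjust import ExpressionMatrix
from .design import DesignError

log = logging.getLogger("batchaudit")

__all__ = ["read_matrix", "write_matrix", "read_annotation", "write_report"]


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_matrix(path) -> ExpressionMatrix:
    """Read a features x samples matrix from delimited text.

    Raises on duplicate feature/sample ids, missing cells (named by feature
    and sample) and non-numeric cells.
    """
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    feature_ids = [str(v) for v in df.index]
    sample_ids = [str(v) for v in df.columns]
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                feat = df.index[np.flatnonzero(bad.to_numpy())[0]]
                raise DesignError(
                    f"non-numeric value at feature {feat!r}, sample {col!r} in {path.name}"
                ) from None
        raise
    if np.isnan(values).any():
        g, s = np.argwhere(np.isnan(values))[0]
        raise DesignError(
            f"missing value at feature {feature_ids[g]!r}, sample {sample_ids[s]!r} "
            f"in {path.name}"
        )
    return ExpressionMatrix(values=values, feature_ids=feature_ids, sample_ids=sample_ids)


def write_matrix(Y: ExpressionMatrix, path, sep: str = "\t") -> None:
    """Write a matrix as delimited text with 10 significant digits."""
    df = pd.DataFrame(Y.values, index=list(Y.feature_ids), columns=list(Y.sample_ids))
    df.index.name = "feature"
    df.to_csv(path, sep=sep, float_format="%.10g")


def read_annotation(path, matrix: ExpressionMatrix | None = None) -> pd.DataFrame:
    """Read a sample annotation table (columns sample, batch, group).

    Column matching is case-insensitive; order of rows is preserved.  When
    ``matrix`` is given, the sample sets must match exactly and the error
    lists any difference.
    """
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    rename = {c: c.strip().lower() for c in df.columns}
    df = df.rename(columns=rename)
    required = ["sample", "batch", "group"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DesignError(f"annotation {path.name} missing column(s): {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        log.warning("annotation %s: ignoring extra column(s) %s", path.name, extra)
    ann = df[required].astype(str)
    if matrix is not None:
        ann_set = set(ann["sample"])
        mat_set = set(matrix.sample_ids)
        if ann_set != mat_set:
            raise DesignError(
                "annotation/matrix sample mismatch: "
                f"matrix-only={sorted(mat_set - ann_set)}, "
                f"annotation-only={sorted(ann_set - mat_set)}"
            )
    return ann


def write_report(results: dict, path, fmt: str = "json", seed: int | None = None) -> None:
    """Write a diagnostics/test/sanity-check report.

    JSON reports are stamped with the package version and seed and use
    sorted keys for byte-stable output; ``fmt='tsv'`` expects a tabular
    payload (list of records or DataFrame).
    """
    path = Path(path)
    if fmt == "json":
        doc = {"version": __version__, "seed": seed, "results": _json_safe(results)}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif fmt == "tsv":
        df = results if isinstance(results, pd.DataFrame) else pd.DataFrame(results)
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    else:
        raise ValueError(f"unknown report format: {fmt!r}")


def _json_safe(obj):
    """Recursively convert numpy scalars/arrays; encode non-finite as strings."""
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_json_safe(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return repr(obj)
    return obj
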
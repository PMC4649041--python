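"""Delimited-text I/O for matrices, time series, parcellations and reports.

All tabular files are tab-delimited with optional ``#``-prefixed metadata
lines; infinite distances are serialized as the literal token ``inf``.
Matrix files carry a header row of node ids and a leading id column, so a
round trip preserves node identity as well as values (floats are written
with 17 significant digits, enough for bit-faithful float64 round trips).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .connectivity import RegionTimeSeriesSet
from .graph import (
    ClosureResult,
    DistanceGraph,
    GraphValidationError,
    LABEL_NAMES,
    ProximityGraph,
)
from .group import SMPTestRow, BackboneResult
from .parcellation import Parcellation

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_proximity",
    "read_distance",
    "read_parcellation",
    "write_parcellation",
    "read_timeseries_table",
    "write_timeseries_table",
    "write_edge_classification",
    "write_smp_table",
    "write_backbone",
    "write_node_scores",
]

_FLOAT_FMT = "%.17g"


def _write_lines(path: Path, lines: Iterable[str], comments: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        for line in lines:
            fh.write(line + "\n")


def write_matrix(
    matrix: np.ndarray | ProximityGraph | DistanceGraph,
    path: str | Path,
    node_ids: Sequence[str] | None = None,
    comments: Sequence[str] = (),
) -> None:
    """Write a square matrix as TSV with a node-id header row and column."""
    if isinstance(matrix, ProximityGraph):
        node_ids, matrix = matrix.node_ids, matrix.weights
    elif isinstance(matrix, DistanceGraph):
        node_ids, matrix = matrix.node_ids, matrix.distances
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    ids = list(node_ids) if node_ids is not None else [f"n{i}" for i in range(n)]
    lines = ["id\t" + "\t".join(ids)]
    for i in range(n):
        cells = ["inf" if np.isinf(v) else _FLOAT_FMT % v for v in matrix[i]]
        lines.append(ids[i] + "\t" + "\t".join(cells))
    _write_lines(Path(path), lines, comments)


def read_matrix(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    """Read a square TSV matrix; ``inf`` tokens parse to infinity."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0,
                     float_precision="round_trip")
    ids = tuple(str(v) for v in df.index)
    if tuple(str(c) for c in df.columns) != ids:
        raise GraphValidationError(f"{path}: row and column ids differ")
    mat = df.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise GraphValidationError(f"{path}: matrix is not square")
    finite = np.isfinite(mat) & np.isfinite(mat.T)
    with np.errstate(invalid="ignore"):
        asym = np.abs(np.where(finite, mat - mat.T, 0.0))
    if (np.isfinite(mat) != np.isfinite(mat.T)).any() or asym.max() > 1e-8:
        raise GraphValidationError(
            f"{path}: matrix asymmetric (max asymmetry {asym.max():.3g})"
        )
    return mat, ids


def read_proximity(path: str | Path) -> ProximityGraph:
    mat, ids = read_matrix(path)
    return ProximityGraph(weights=mat, node_ids=ids)


def read_distance(path: str | Path) -> DistanceGraph:
    mat, ids = read_matrix(path)
    return DistanceGraph(distances=mat, node_ids=ids)


def write_parcellation(p: Parcellation, path: str | Path,
                       comments: Sequence[str] = ()) -> None:
    df = p.to_frame()
    lines = ["\t".join(df.columns)]
    for _, row in df.iterrows():
        lines.append("\t".join(str(v) for v in row))
    _write_lines(Path(path), lines, comments)


def read_parcellation(path: str | Path) -> Parcellation:
    df = pd.read_csv(path, sep="\t", comment="#")
    return Parcellation.from_frame(df)


def write_timeseries_table(ts: RegionTimeSeriesSet, path: str | Path,
                           comments: Sequence[str] = ()) -> None:
    lines = []
    for rid, row in zip(ts.node_ids, ts.series):
        lines.append(rid + "\t" + "\t".join(_FLOAT_FMT % v for v in row))
    _write_lines(Path(path), lines,
                 list(comments) + [f"tr_seconds={ts.tr_seconds}"])


def read_timeseries_table(
    path: str | Path,
    tr_seconds: float | None = None,
    parcellation: Parcellation | None = None,
) -> RegionTimeSeriesSet:
    """Read a regions x time table (first column region id, no header row).

    If a parcellation is given, rows are aligned to its region order;
    missing or unexpected region ids are reported by id.  The TR may come
    from a ``# tr_seconds=...`` comment or the argument (argument wins).
    """
    path = Path(path)
    ids: list[str] = []
    rows: list[list[float]] = []
    file_tr = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                stripped = line.lstrip("# ").strip()
                if stripped.startswith("tr_seconds="):
                    file_tr = float(stripped.split("=", 1)[1])
                continue
            cells = line.split("\t")
            rid = cells[0].strip()
            try:
                vals = [float(v) for v in cells[1:]]
            except ValueError as exc:
                raise GraphValidationError(
                    f"{path}:{lineno}: non-numeric cell in row {rid!r}: {exc}"
                ) from None
            ids.append(rid)
            rows.append(vals)
    if len(set(ids)) != len(ids):
        dupes = sorted({r for r in ids if ids.count(r) > 1})
        raise GraphValidationError(f"{path}: duplicated region id(s): {dupes}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise GraphValidationError(f"{path}: rows have unequal lengths {sorted(lengths)}")
    series = np.asarray(rows, dtype=float)
    if parcellation is not None:
        want = list(parcellation.ids)
        missing = [r for r in want if r not in ids]
        extra = [r for r in ids if r not in want]
        if missing or extra:
            raise GraphValidationError(
                f"{path}: region mismatch vs parcellation "
                f"(missing: {missing[:5]}, unexpected: {extra[:5]})"
            )
        order = [ids.index(r) for r in want]
        series = series[order]
        ids = want
    tr = tr_seconds if tr_seconds is not None else file_tr
    if tr is None:
        raise GraphValidationError(f"{path}: TR not given and not in file header")
    return RegionTimeSeriesSet(series=series, tr_seconds=tr, node_ids=tuple(ids))


def write_edge_classification(c: ClosureResult, path: str | Path,
                              comments: Sequence[str] = ()) -> None:
    """Edge list: node_i, node_j, w, d_direct, d_closed, label, distortion."""
    lines = ["node_i\tnode_j\tw\td_direct\td_closed\tlabel\tdistortion"]
    n = c.n_nodes
    for i in range(n):
        for j in range(i + 1, n):
            d = c.direct_distances[i, j]
            w = 0.0 if np.isinf(d) else 1.0 / (d + 1.0)
            s = c.distortion[i, j]
            lines.append(
                "\t".join(
                    [
                        c.node_ids[i],
                        c.node_ids[j],
                        _FLOAT_FMT % w,
                        "inf" if np.isinf(d) else _FLOAT_FMT % d,
                        "inf" if np.isinf(c.closed_distances[i, j])
                        else _FLOAT_FMT % c.closed_distances[i, j],
                        LABEL_NAMES[int(c.labels[i, j])],
                        "nan" if np.isnan(s) else
                        ("inf" if np.isinf(s) else _FLOAT_FMT % s),
                    ]
                )
            )
    _write_lines(Path(path), lines, comments)


def _fmt_opt(v: float | None) -> str:
    return "NA" if v is None else "%.6g" % v


def write_smp_table(rows: Sequence[SMPTestRow], path: str | Path,
                    comments: Sequence[str] = ()) -> None:
    """Tab-delimited hierarchical SMP comparison table plus a JSON mirror."""
    path = Path(path)
    lines = ["region_set\tn_a\tn_b\tmean_a\tmean_b\tdifference\t"
             "ci_low\tci_high\tp_value\ttested\tnote"]
    for r in rows:
        lines.append(
            "\t".join(
                [
                    r.name, str(r.n_a), str(r.n_b), _fmt_opt(r.mean_a),
                    _fmt_opt(r.mean_b), _fmt_opt(r.difference),
                    _fmt_opt(r.ci_low), _fmt_opt(r.ci_high),
                    _fmt_opt(r.p_value), str(r.tested).lower(), r.note,
                ]
            )
        )
    _write_lines(path, lines, comments)
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump([asdict(r) for r in rows], fh, indent=1)


def write_backbone(b: BackboneResult, node_ids: Sequence[str],
                   path: str | Path, comments: Sequence[str] = ()) -> None:
    lines = ["node_i\tnode_j\tconsensus"]
    for i, j, c in b.edges:
        lines.append(f"{node_ids[i]}\t{node_ids[j]}\t{c:.6g}")
    _write_lines(Path(path), lines,
                 list(comments) + [f"group={b.group_label}",
                                   f"threshold={b.threshold}"])


def write_node_scores(scores: np.ndarray, node_ids: Sequence[str],
                      path: str | Path, comments: Sequence[str] = ()) -> None:
    lines = ["node\tscore"]
    for rid, v in zip(node_ids, scores):
        lines.append(f"{rid}\t{_FLOAT_FMT % v}")
    _write_lines(Path(path), lines, comments)
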
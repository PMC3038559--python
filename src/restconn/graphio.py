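"""Readers and writers for the pipeline's on-disk formats.

Cohorts are stored as one TSV per subject (header row = ROI labels, one
row per time point) with a JSON sidecar carrying the sampling interval
and provenance; matrices as labelled CSV; edge lists as TSV; and graphs
as Pajek ``.net`` files for network visualisation.  All numeric output
uses 12 significant digits so re-runs are byte-reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CausalGraphSpec
from .dataset import ROITimeSeriesSet
from .edges import Edge, SignificantEdgeList

__all__ = [
    "write_cohort_tsv",
    "read_cohort_tsv",
    "write_matrix_csv",
    "read_matrix_csv",
    "write_edges_tsv",
    "read_edges_tsv",
    "write_pajek",
]

SIDECAR_NAME = "cohort.json"
#: fixed precision for derived outputs (matrices, edge weights)
FLOAT_FMT = "%.12g"
#: full precision for raw cohort data, so write -> read is lossless
DATA_FMT = "%.17g"


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


def write_cohort_tsv(
    ts: ROITimeSeriesSet,
    directory: str | Path,
    spec: CausalGraphSpec | None = None,
    seed: int | None = None,
) -> Path:
    """Write one TSV per subject plus a JSON sidecar.

    If the generating :class:`CausalGraphSpec` is given, its ground
    truth (directed edge list with signs and lags) is stored in the
    sidecar so a cohort on disk is self-describing.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sid, mat in ts:
        lines = ["\t".join(ts.roi_labels)]
        for row in mat:
            lines.append("\t".join(DATA_FMT % v for v in row))
        (directory / f"{sid}.tsv").write_text("\n".join(lines) + "\n")
    sidecar: dict = {
        "tr_seconds": ts.tr_seconds,
        "roi_labels": list(ts.roi_labels),
        "subject_ids": list(ts.subject_ids),
    }
    if seed is not None:
        sidecar["seed"] = seed
    if spec is not None:
        edges = []
        for k in range(spec.lag_order):
            for j in range(spec.n_rois):
                for i in range(spec.n_rois):
                    w = spec.coeff[k, j, i]
                    if i != j and abs(w) > 1e-12:
                        edges.append(
                            {
                                "source": spec.roi_labels[i],
                                "target": spec.roi_labels[j],
                                "lag": k + 1,
                                "weight": float(w),
                                "sign": int(np.sign(w)),
                            }
                        )
        sidecar["ground_truth"] = {
            "lag_order": spec.lag_order,
            "directed_edges": edges,
            "seed": spec.seed,
        }
    (directory / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=2) + "\n")
    return directory


def read_cohort_tsv(directory: str | Path) -> ROITimeSeriesSet:
    """Read a cohort directory written by :func:`write_cohort_tsv`.

    Columns are realigned by header name, so files with shuffled column
    order load correctly; malformed cells are reported with file, row
    and column.
    """
    directory = Path(directory)
    sidecar_path = directory / SIDECAR_NAME
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing cohort sidecar {sidecar_path}; cannot determine tr_seconds"
        )
    sidecar = json.loads(sidecar_path.read_text())
    labels = list(sidecar["roi_labels"])
    subject_ids = sidecar.get("subject_ids")
    if subject_ids is None:
        subject_ids = sorted(p.stem for p in directory.glob("*.tsv"))
    data = []
    for sid in subject_ids:
        path = directory / f"{sid}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"subject file {path} listed in sidecar is missing")
        frame = pd.read_csv(path, sep="\t", dtype=str)
        if sorted(frame.columns) != sorted(labels):
            raise ValueError(
                f"{path.name}: ROI columns {sorted(frame.columns)} do not match "
                f"the cohort's ROI set"
            )
        frame = frame[labels]  # realign by header name, not position
        values = np.empty(frame.shape, dtype=float)
        for cj, col in enumerate(labels):
            for ri, cell in enumerate(frame[col]):
                try:
                    values[ri, cj] = float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path.name}: non-numeric value {cell!r} at row "
                        f"{ri + 2}, column {col!r}"
                    ) from None
        data.append(values)
    return ROITimeSeriesSet(
        data, labels, float(sidecar["tr_seconds"]), subject_ids
    )


def write_matrix_csv(
    matrix: np.ndarray, roi_labels: Sequence[str], path: str | Path
) -> Path:
    """Labelled square matrix as CSV (header row and index column)."""
    path = Path(path)
    labels = list(roi_labels)
    lines = ["," + ",".join(labels)]
    for lab, row in zip(labels, np.asarray(matrix)):
        lines.append(lab + "," + ",".join(_fmt(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_matrix_csv(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    frame = pd.read_csv(path, index_col=0)
    labels = tuple(frame.columns)
    if tuple(frame.index) != labels:
        raise ValueError(f"{path}: row and column labels disagree")
    return frame.to_numpy(dtype=float), labels


EDGE_COLUMNS = ("source", "target", "weight", "sign", "p_corrected", "tier")


def write_edges_tsv(edge_list: SignificantEdgeList, path: str | Path) -> Path:
    """Edge list as TSV with a metadata comment line."""
    path = Path(path)
    lines = [
        f"# directed={edge_list.directed} family_alpha={_fmt(edge_list.family_alpha)} "
        f"n_comparisons={edge_list.n_comparisons}",
        "\t".join(EDGE_COLUMNS),
    ]
    for e in edge_list:
        lines.append(
            "\t".join(
                [e.source, e.target, _fmt(e.weight), str(e.sign),
                 _fmt(e.p_corrected), str(e.tier)]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_edges_tsv(path: str | Path) -> SignificantEdgeList:
    path = Path(path)
    lines = path.read_text().splitlines()
    meta = dict(item.split("=") for item in lines[0].lstrip("# ").split())
    frame = pd.read_csv(path, sep="\t", skiprows=1)
    edges = tuple(
        Edge(
            source=str(row.source),
            target=str(row.target),
            weight=float(row.weight),
            sign=int(row.sign),
            p_corrected=float(row.p_corrected),
            tier=int(row.tier),
        )
        for row in frame.itertuples()
    )
    return SignificantEdgeList(
        directed=meta["directed"] == "True",
        edges=edges,
        family_alpha=float(meta["family_alpha"]),
        n_comparisons=int(meta["n_comparisons"]),
    )


def write_pajek(
    edge_list: SignificantEdgeList, roi_labels: Sequence[str], path: str | Path
) -> Path:
    """Minimal Pajek ``.net`` file: quoted vertex labels, 1-based ids.

    Directed lists use an ``*Arcs`` section, undirected ``*Edges``;
    weights are the third column.
    """
    labels = list(roi_labels)
    index = {lab: i + 1 for i, lab in enumerate(labels)}
    for e in edge_list:
        for endpoint in (e.source, e.target):
            if endpoint not in index:
                raise ValueError(
                    f"edge endpoint {endpoint!r} is not among the vertex labels"
                )
    lines = [f"*Vertices {len(labels)}"]
    for lab, i in index.items():
        lines.append(f'{i} "{lab}"')
    lines.append("*Arcs" if edge_list.directed else "*Edges")
    for e in edge_list:
        lines.append(f"{index[e.source]} {index[e.target]} {_fmt(e.weight)}")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path
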
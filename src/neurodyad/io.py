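"""Readers and writers for every exchange format the pipeline touches.

One unambiguous CSV dialect throughout: comma-separated, UTF-8, "."
decimal, mandatory header row, NA encoded as an empty field.  Graphs are
additionally exportable as GraphML and plain edge lists; results and
configurations travel as JSON.  Every writer's output is re-readable by
the matching reader (closed round trip).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .network import NominationMatrix
from .similarity import RoiTimeSeriesSet

__all__ = [
    "read_nominations",
    "write_nominations",
    "read_timeseries_dir",
    "write_timeseries_dir",
    "read_demographics",
    "write_demographics",
    "read_volumes",
    "write_volumes",
    "read_dyad_table",
    "write_dyad_table",
    "write_graph",
    "write_json",
    "read_json",
]


# -- nominations -------------------------------------------------------------

EDGE_COLS = ["nominator_id", "nominee_id"]


def read_nominations(path, subject_ids: Sequence[str] | None = None) -> NominationMatrix:
    """Read a nomination matrix from an edge-list or square-adjacency CSV.

    Edge lists have columns ``nominator_id,nominee_id``; adjacency files
    have subject ids as both the header row and the first column.  For
    edge lists the subject set defaults to the sorted union of ids seen;
    pass ``subject_ids`` to include isolated subjects.  Self-edges are an
    error (named by row); duplicate directed edges are deduplicated with a
    warning.
    """
    path = Path(path)
    head = pd.read_csv(path, nrows=0)
    if list(head.columns) == EDGE_COLS:
        edges = pd.read_csv(path, dtype=str)
        selfies = edges[edges[EDGE_COLS[0]] == edges[EDGE_COLS[1]]]
        if not selfies.empty:
            raise ValueError(
                f"self-nomination at data row(s) {list(selfies.index + 2)} of {path}"
            )
        dup = edges.duplicated()
        if dup.any():
            warnings.warn(f"{int(dup.sum())} duplicate directed edges in {path}; "
                          "deduplicated", stacklevel=2)
            edges = edges[~dup]
        if subject_ids is None:
            subject_ids = sorted(set(edges[EDGE_COLS[0]]) | set(edges[EDGE_COLS[1]]))
        ids = list(subject_ids)
        pos = {s: k for k, s in enumerate(ids)}
        unknown = [s for s in pd.concat([edges[c] for c in EDGE_COLS]) if s not in pos]
        if unknown:
            raise KeyError(f"edge references unknown subject id(s): {sorted(set(unknown))}")
        m = np.zeros((len(ids), len(ids)), dtype=np.int8)
        m[[pos[s] for s in edges[EDGE_COLS[0]]],
          [pos[s] for s in edges[EDGE_COLS[1]]]] = 1
        return NominationMatrix(entries=m, subject_ids=tuple(ids))
    adj = pd.read_csv(path, index_col=0)
    adj.index = adj.index.astype(str)
    adj.columns = adj.columns.astype(str)
    if list(adj.index) != list(adj.columns):
        raise ValueError(f"adjacency file {path} must have matching row/column ids")
    return NominationMatrix(
        entries=adj.to_numpy(dtype=np.int8), subject_ids=tuple(adj.index)
    )


def write_nominations(nm: NominationMatrix, path, fmt: str = "edgelist") -> None:
    path = Path(path)
    if fmt == "edgelist":
        ii, jj = np.nonzero(nm.entries)
        pd.DataFrame(
            {
                EDGE_COLS[0]: [nm.subject_ids[i] for i in ii],
                EDGE_COLS[1]: [nm.subject_ids[j] for j in jj],
            }
        ).to_csv(path, index=False)
    elif fmt == "adjacency":
        pd.DataFrame(
            nm.entries, index=list(nm.subject_ids), columns=list(nm.subject_ids)
        ).to_csv(path)
    else:
        raise ValueError(f"unknown nomination format {fmt!r}")


# -- ROI time series ---------------------------------------------------------


def write_timeseries_dir(ts: RoiTimeSeriesSet, directory) -> None:
    """One ``<subject_id>.csv`` per subject, T rows x R columns, header =
    ROI names; an absent (subject, ROI) series is written as all-empty."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k, sid in enumerate(ts.subject_ids):
        frame = pd.DataFrame(ts.series[k].T, columns=list(ts.roi_names))
        for r, present in enumerate(ts.present_mask[k]):
            if not present:
                frame.iloc[:, r] = np.nan
        # %.17g keeps float64 round trips bit-exact
        frame.to_csv(directory / f"{sid}.csv", index=False, float_format="%.17g")


def read_timeseries_dir(directory) -> RoiTimeSeriesSet:
    """Assemble a :class:`RoiTimeSeriesSet` from per-subject CSV files.

    Subject ids come from file stems (sorted).  All files must share T and
    the same ROI set; a differing column order is reordered by name with a
    warning.  An all-NA column marks that (subject, ROI) as absent.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.csv"))
    if not files:
        raise FileNotFoundError(f"no .csv time-series files in {directory}")
    frames = {f.stem: pd.read_csv(f, float_precision="round_trip") for f in files}
    first = files[0].stem
    roi_names = list(frames[first].columns)
    t = len(frames[first])
    series, masks, ids = [], [], []
    for sid, frame in frames.items():
        if len(frame) != t:
            raise ValueError(
                f"subject {sid} has {len(frame)} time points, expected {t}"
            )
        if list(frame.columns) != roi_names:
            if sorted(frame.columns) != sorted(roi_names):
                raise ValueError(f"subject {sid} has a different ROI set")
            warnings.warn(f"subject {sid}: ROI columns reordered by name",
                          stacklevel=2)
            frame = frame[roi_names]
        vals = frame.to_numpy(dtype=float).T  # [R x T]
        present = ~np.isnan(vals).all(axis=1)
        if np.isnan(vals[present]).any():
            raise ValueError(f"subject {sid}: partially missing ROI series")
        vals = np.nan_to_num(vals)
        series.append(vals)
        masks.append(present)
        ids.append(sid)
    return RoiTimeSeriesSet(
        series=np.stack(series),
        present_mask=np.stack(masks),
        roi_names=tuple(roi_names),
        subject_ids=tuple(ids),
    )


# -- small tables ------------------------------------------------------------


def write_demographics(demo: pd.DataFrame, path) -> None:
    demo.to_csv(path)


def read_demographics(path) -> pd.DataFrame:
    demo = pd.read_csv(path, index_col="subject_id", dtype={"subject_id": str})
    required = {"gender", "ethnicity", "nationality", "age", "handedness"}
    missing = required - set(demo.columns)
    if missing:
        raise ValueError(f"demographics file lacks column(s): {sorted(missing)}")
    return demo


def write_volumes(volumes: pd.DataFrame, path) -> None:
    volumes.to_csv(path)


def read_volumes(path) -> pd.DataFrame:
    vols = pd.read_csv(path, index_col="roi")
    if "volume_mm3" not in vols.columns:
        raise ValueError("volumes file needs a volume_mm3 column")
    if (vols["volume_mm3"] < 0).any():
        raise ValueError("negative ROI volume")
    return vols


def write_dyad_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_dyad_table(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject_i": str, "subject_j": str})


# -- graphs & JSON -----------------------------------------------------------


def write_graph(graph: nx.Graph, path, fmt: str = "graphml") -> None:
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "edgelist":
        with open(path, "w") as fh:
            for u, v in graph.edges:
                fh.write(f"{u},{v}\n")
    else:
        raise ValueError(f"unknown graph format {fmt!r}")


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
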
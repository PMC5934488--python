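"""Delimited-text I/O for adjacency matrices, epochs and results.

Adjacency matrices travel as square delimited tables (CSV/TSV) with the
atlas labels as row and column headers; epochs as samples x ROI tables with
a label header row; spanning trees as two-column edge lists.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from restnet.atlas import ROIAtlas, build_roi_atlas
from restnet.mst import SpanningTree

SYMMETRY_TOL = 1e-8


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def read_adjacency(path, atlas: ROIAtlas | None = None) -> np.ndarray:
    """Read and validate an adjacency matrix from delimited text.

    Checks square shape against the atlas, header labels, symmetry (within
    1e-8), the coherence range [0, 1] and a zero diagonal.
    """
    path = Path(path)
    atlas = atlas or build_roi_atlas()
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    n = len(atlas)
    if df.shape != (n, n):
        raise ValueError(
            f"{path.name}: expected a {n}x{n} matrix, got "
            f"{df.shape[0]}x{df.shape[1]}"
        )
    cols = tuple(str(c) for c in df.columns)
    rows = tuple(str(r) for r in df.index)
    for kind, labels in (("column", cols), ("row", rows)):
        unknown = [lb for lb in labels if lb not in atlas.labels]
        if unknown:
            raise ValueError(
                f"{path.name}: unknown {kind} label(s): {unknown[:5]}"
            )
        if labels != atlas.labels:
            raise ValueError(
                f"{path.name}: {kind} labels are not in canonical atlas order"
            )
    W = df.to_numpy(dtype=float)
    asym = np.abs(W - W.T).max()
    if asym > SYMMETRY_TOL:
        i, j = np.unravel_index(np.argmax(np.abs(W - W.T)), W.shape)
        raise ValueError(
            f"{path.name}: matrix asymmetric beyond {SYMMETRY_TOL:g} "
            f"(max |W-W'| = {asym:.3g} at row {atlas.labels[i]!r}, "
            f"column {atlas.labels[j]!r})"
        )
    if np.any((W < 0) | (W > 1)):
        i, j = np.unravel_index(np.argmax(np.abs(W - 0.5)), W.shape)
        bad = W[(W < 0) | (W > 1)][0]
        raise ValueError(
            f"{path.name}: coherence entries must lie in [0, 1]; found {bad}"
        )
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0.0)
    return W


def write_adjacency(W: np.ndarray, path, atlas: ROIAtlas | None = None) -> None:
    """Write an adjacency matrix with atlas labels as headers."""
    path = Path(path)
    atlas = atlas or build_roi_atlas()
    df = pd.DataFrame(W, index=atlas.labels, columns=atlas.labels)
    df.to_csv(path, sep=_sep_for(path))


def read_epochs(paths, fs: float = 250.0, atlas: ROIAtlas | None = None):
    """Read one epoch per file (samples x ROIs with a label header row)."""
    from restnet.connectivity import EpochSet

    atlas = atlas or build_roi_atlas()
    epochs = []
    for p in paths:
        p = Path(p)
        df = pd.read_csv(p, sep=_sep_for(p))
        labels = tuple(str(c) for c in df.columns)
        if labels != atlas.labels:
            raise ValueError(f"{p.name}: header labels do not match the atlas")
        epochs.append(df.to_numpy(dtype=float))
    return EpochSet(epochs=epochs, fs=fs)


def write_tree(tree: SpanningTree, path) -> None:
    """Write a spanning tree as a two-column edge list."""
    path = Path(path)
    labels = tree.node_labels or tuple(str(i) for i in range(tree.n))
    rows = [(labels[i], labels[j]) for i, j in tree.edges]
    pd.DataFrame(rows, columns=["node_a", "node_b"]).to_csv(
        path, sep=_sep_for(path), index=False
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
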
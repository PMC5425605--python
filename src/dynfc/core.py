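"""Shared containers and small utilities used across the pipeline.

The pipeline operates on node-level (ROI-level) BOLD time series: one
matrix per subject with one row per TR and one column per node.  A few
nodes play designated roles — an amygdala node inside the limbic module,
an mPFC node inside the default-mode module, and bilateral caudate nodes
used for specificity contrasts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RoiTimeSeries", "derive_seed", "read_matrix", "write_matrix"]


@dataclass
class RoiTimeSeries:
    """A subject's time-by-node signal matrix.

    Parameters
    ----------
    data : ndarray, shape (n_timepoints, n_nodes)
        One row per TR, one column per node.
    tr_seconds : float
        Sampling interval (repetition time) in seconds.
    subject_id : str
        Identifier used in output tables.
    node_ids : ndarray of str, optional
        One label per node; defaults to ``n000, n001, ...``.
    roles : dict, optional
        Designated node roles.  Recognised keys: ``"amygdala"`` and
        ``"mpfc"`` (single node index each), ``"caudate"`` (list of node
        indices).
    """

    data: np.ndarray
    tr_seconds: float = 2.0
    subject_id: str = "sub-000"
    node_ids: np.ndarray | None = None
    roles: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time series data must be 2-D (time x nodes)")
        if self.node_ids is None:
            self.node_ids = np.array([f"n{i:03d}" for i in range(self.n_nodes)])

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


def derive_seed(root: int, *path: int) -> int:
    """Derive a child seed deterministically from a root seed and a path.

    Seeds are derived hierarchically (global -> subject -> window -> run)
    so any stage can be re-run in isolation and reproduce its outputs.
    The result is a non-negative int below 2**31.
    """
    ss = np.random.SeedSequence([int(root), *[int(p) for p in path]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def write_matrix(path: str | Path, data: np.ndarray, header: list[str] | None = None,
                 sidecar: dict | None = None) -> None:
    """Write a numeric matrix as whitespace-delimited text.

    ``header`` becomes a single leading line of column ids.  ``sidecar``
    is written next to the matrix as ``<path>.json``.
    """
    path = Path(path)
    hdr = " ".join(header) if header is not None else ""
    np.savetxt(path, np.asarray(data, dtype=float), fmt="%.10g",
               header=hdr, comments="")
    if sidecar is not None:
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_matrix(path: str | Path, header: bool = True):
    """Read a matrix written by :func:`write_matrix`.

    Returns ``(data, column_ids)``; ``column_ids`` is None when
    ``header`` is False.
    """
    path = Path(path)
    cols = None
    if header:
        with open(path) as fh:
            cols = fh.readline().split()
    data = np.loadtxt(path, skiprows=1 if header else 0, ndmin=2)
    return data, cols
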
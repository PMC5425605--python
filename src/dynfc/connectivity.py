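"""Fisher-z connectivity matrices at subject, group, and window level.

Two variants exist.  The *signed* variant keeps negative weights and is
used for bi-nodal and module-pair FC, which genuinely fluctuate around
zero.  The *graph-ready* variant zeroes the diagonal and all negative
entries and is the only form accepted by the community-detection code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import RoiTimeSeries

__all__ = [
    "ConnectivityMatrix",
    "fisher_z",
    "correlation_matrix",
    "make_graph_ready",
    "group_matrix",
]

#: correlations are clipped to this magnitude before atanh so perfectly
#: (anti)correlated series map to a large finite z rather than +/-inf.
R_CLIP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    """Symmetric node-by-node matrix of Fisher-z weights."""

    z: np.ndarray
    variant: str = "signed"  # "signed" | "graph_ready"
    n_valid_timepoints: int = 0
    node_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2 or self.z.shape[0] != self.z.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if self.variant not in ("signed", "graph_ready"):
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]


def fisher_z(r):
    """Variance-stabilising r-to-z transform, atanh(r).

    Accepts scalars or arrays.  |r| is clipped to ``1 - 1e-7`` before the
    transform; |r| > 1 (beyond numerical noise) is an input error.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1 + 1e-9):
        raise ValueError("correlation magnitude exceeds 1")
    out = np.arctanh(np.clip(arr, -R_CLIP, R_CLIP))
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def _masked_data(ts: RoiTimeSeries, mask=None) -> np.ndarray:
    data = ts.data if isinstance(ts, RoiTimeSeries) else np.asarray(ts, float)
    if mask is not None:
        retained = np.asarray(getattr(mask, "retained", mask), dtype=bool)
        if retained.size != data.shape[0]:
            raise ValueError("censor mask length does not match time series")
        data = data[retained]
    return data


def correlation_matrix(ts, mask=None) -> ConnectivityMatrix:
    """Pairwise Pearson correlation over retained TRs, Fisher-z transformed.

    The diagonal is set to 0.  Nodes with zero variance over the retained
    TRs get an all-zero row/column (with a warning) rather than NaNs.
    Requires at least 3 retained TRs.
    """
    data = _masked_data(ts, mask)
    if data.shape[0] < 3:
        raise ValueError("need at least 3 retained timepoints to correlate")
    sd = data.std(axis=0)
    # relative tolerance: a constant column's std is rounding noise, not 0
    flat = sd <= 1e-12 * (np.abs(data).max(axis=0) + 1.0)
    if flat.any():
        warnings.warn(f"{int(flat.sum())} node(s) with zero variance; "
                      "their connectivity rows are set to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data, rowvar=False)
    r[flat, :] = 0.0
    r[:, flat] = 0.0
    z = fisher_z(np.clip(r, -1.0, 1.0))
    np.fill_diagonal(z, 0.0)
    node_ids = ts.node_ids if isinstance(ts, RoiTimeSeries) else None
    return ConnectivityMatrix(z=z, variant="signed",
                              n_valid_timepoints=data.shape[0],
                              node_ids=node_ids)


def make_graph_ready(cm: ConnectivityMatrix) -> ConnectivityMatrix:
    """Zero the diagonal and all negative entries; keep everything else."""
    if cm.variant != "signed":
        raise ValueError("make_graph_ready expects the signed variant")
    z = np.maximum(cm.z, 0.0)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z=z, variant="graph_ready",
                              n_valid_timepoints=cm.n_valid_timepoints,
                              node_ids=cm.node_ids)


def group_matrix(cohort, masks=None) -> ConnectivityMatrix:
    """Group-level graph-ready matrix from temporally concatenated subjects.

    Each subject's retained TRs are z-scored per node (so between-subject
    mean/variance differences cannot masquerade as correlation), stacked
    in time, correlated once, Fisher-z transformed and made graph-ready.
    """
    if masks is None:
        masks = [None] * len(cohort)
    if len(masks) != len(cohort):
        raise ValueError("one censor mask per subject required")
    n_nodes = cohort[0].data.shape[1]
    bad = [getattr(ts, "subject_id", i) for i, ts in enumerate(cohort)
           if ts.data.shape[1] != n_nodes]
    if bad:
        raise ValueError(f"node-set mismatch for subjects: {bad}")
    blocks = []
    for ts, mask in zip(cohort, masks):
        data = _masked_data(ts, mask)
        sd = data.std(axis=0)
        sd[sd <= 0] = 1.0
        blocks.append((data - data.mean(axis=0)) / sd)
    stacked = np.vstack(blocks)
    cm = correlation_matrix(RoiTimeSeries(stacked, tr_seconds=cohort[0].tr_seconds,
                                          subject_id="group",
                                          node_ids=cohort[0].node_ids))
    return make_graph_ready(cm)
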
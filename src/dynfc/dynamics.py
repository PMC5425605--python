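"""Sliding-window machinery: the window grid, per-window connectivity,
per-window modularity Q, module-pair FC, and node-pair FC series.

Windows are half-open index ranges ``[start, start + length)`` laid out
at ``0, step, 2*step, ...``; a window exists iff it fits entirely inside
the scan, giving ``floor((T - L)/s) + 1`` windows.  Censored TRs are
excluded within each window (never interpolated); a window with too few
retained TRs is flagged invalid and kept in place so series stay
aligned across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .community import Partition, best_partition
from .connectivity import ConnectivityMatrix, correlation_matrix, fisher_z, make_graph_ready
from .core import RoiTimeSeries, derive_seed

__all__ = [
    "WindowSpec",
    "WindowSeries",
    "make_windows",
    "window_connectivity",
    "window_modularity",
    "module_pair_fc",
    "node_pair_fc",
]


@dataclass
class WindowSpec:
    """Sliding-window layout: 22 TRs stepped by 5 by default (44 s at
    TR = 2 s), with a window valid only when at least
    ``min_valid_fraction`` of its TRs survive censoring."""

    length_trs: int = 22
    step_trs: int = 5
    min_valid_fraction: float = 2.0 / 3.0

    def validate(self, n_timepoints: int | None = None) -> None:
        if self.length_trs < 1 or self.step_trs < 1:
            raise ValueError("window length and step must be positive")
        if not 0.0 <= self.min_valid_fraction <= 1.0:
            raise ValueError("min_valid_fraction must be in [0, 1]")
        if n_timepoints is not None and self.length_trs > n_timepoints:
            raise ValueError("window length exceeds the series length")


@dataclass
class WindowSeries:
    """A per-window scalar trajectory with validity flags."""

    values: np.ndarray
    valid: np.ndarray
    starts: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.starts = np.asarray(self.starts, dtype=int)
        if not (self.values.size == self.valid.size == self.starts.size):
            raise ValueError("values, valid and starts must have equal length")

    @property
    def n_windows(self) -> int:
        return self.values.size

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]


def make_windows(n_timepoints: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open [start, stop) window ranges covering the scan."""
    spec.validate(n_timepoints)
    starts = range(0, n_timepoints - spec.length_trs + 1, spec.step_trs)
    return [(s, s + spec.length_trs) for s in starts]


def _retained(ts: RoiTimeSeries, mask) -> np.ndarray:
    if mask is None:
        return np.ones(ts.n_timepoints, dtype=bool)
    retained = np.asarray(getattr(mask, "retained", mask), dtype=bool)
    if retained.size != ts.n_timepoints:
        raise ValueError("censor mask length does not match time series")
    return retained


def window_connectivity(ts: RoiTimeSeries, mask=None,
                        spec: WindowSpec | None = None):
    """Signed Fisher-z connectivity matrix at each window.

    Returns ``(matrices, valid, starts)`` where ``matrices[k]`` is None
    for invalid windows (retained fraction below ``min_valid_fraction``
    or fewer than 3 retained TRs).
    """
    spec = spec or WindowSpec()
    windows = make_windows(ts.n_timepoints, spec)
    retained = _retained(ts, mask)
    need = max(3, int(np.ceil(spec.min_valid_fraction * spec.length_trs)))
    matrices, valid, starts = [], [], []
    for start, stop in windows:
        keep = retained[start:stop]
        starts.append(start)
        if keep.sum() < need:
            matrices.append(None)
            valid.append(False)
            continue
        sub = RoiTimeSeries(ts.data[start:stop][keep], tr_seconds=ts.tr_seconds,
                            subject_id=ts.subject_id, node_ids=ts.node_ids)
        matrices.append(correlation_matrix(sub))
        valid.append(True)
    return matrices, np.array(valid), np.array(starts)


def window_modularity(window_matrices, valid, starts, gamma: float = 1.7,
                      n_runs: int = 25, seed: int = 0) -> WindowSeries:
    """Per-window modularity Q from repeated-restart Louvain.

    Each valid window's signed matrix is made graph-ready and clustered
    with ``n_runs`` restarts at resolution ``gamma``; the best Q is
    stored.  Window-level seeds are derived from ``seed`` and the window
    index so reruns reproduce the series exactly.
    """
    values = np.full(len(window_matrices), np.nan)
    for k, cm in enumerate(window_matrices):
        if cm is None or not valid[k]:
            continue
        ready = make_graph_ready(cm)
        part = best_partition(ready, gamma=gamma, n_runs=n_runs,
                              seed=derive_seed(seed, k))
        values[k] = part.q_value
    return WindowSeries(values=values, valid=np.asarray(valid, bool),
                        starts=starts, name="Q")


def _windowed_pair_series(a: np.ndarray, b: np.ndarray, retained: np.ndarray,
                          spec: WindowSpec, name: str) -> WindowSeries:
    """Per-window Fisher-z correlation of two 1-D courses."""
    windows = make_windows(a.size, spec)
    need = max(3, int(np.ceil(spec.min_valid_fraction * spec.length_trs)))
    values = np.full(len(windows), np.nan)
    valid = np.zeros(len(windows), dtype=bool)
    starts = np.array([w[0] for w in windows])
    for k, (start, stop) in enumerate(windows):
        keep = retained[start:stop]
        if keep.sum() < need:
            continue
        x, y = a[start:stop][keep], b[start:stop][keep]
        if x.std() <= 0 or y.std() <= 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if not np.isfinite(r):
            continue
        values[k] = fisher_z(np.clip(r, -1.0, 1.0))
        valid[k] = True
    return WindowSeries(values=values, valid=valid, starts=starts, name=name)


def module_pair_fc(ts: RoiTimeSeries, partition: Partition, mask=None,
                   spec: WindowSpec | None = None) -> dict:
    """Between-module FC series for every unordered module pair.

    The module time course is the mean time course of all nodes the
    partition assigns to the module; K modules yield K(K-1)/2 series.
    """
    spec = spec or WindowSpec()
    labels = np.asarray(getattr(partition, "labels", partition))
    if labels.size != ts.n_nodes:
        raise ValueError("partition does not cover the node set")
    k_mod = int(labels.max()) + 1
    for m in range(k_mod):
        if not (labels == m).any():
            raise ValueError(f"module {m} is empty")
    retained = _retained(ts, mask)
    courses = np.column_stack([ts.data[:, labels == m].mean(axis=1)
                               for m in range(k_mod)])
    out = {}
    for a in range(k_mod):
        for b in range(a + 1, k_mod):
            out[(a, b)] = _windowed_pair_series(
                courses[:, a], courses[:, b], retained, spec, f"module_{a}-{b}")
    return out


def node_pair_fc(ts: RoiTimeSeries, node_set_a, node_set_b, mask=None,
                 spec: WindowSpec | None = None) -> WindowSeries:
    """Windowed FC between the mean courses of two disjoint node sets.

    Supports singleton sets (amygdala vs mPFC) and multi-node sets
    (bilateral caudate collapsed into one mean course).
    """
    spec = spec or WindowSpec()
    set_a = np.atleast_1d(np.asarray(node_set_a, dtype=int))
    set_b = np.atleast_1d(np.asarray(node_set_b, dtype=int))
    if set_a.size == 0 or set_b.size == 0:
        raise ValueError("node sets must be nonempty")
    if np.intersect1d(set_a, set_b).size:
        raise ValueError("node sets must be disjoint")
    retained = _retained(ts, mask)
    a = ts.data[:, set_a].mean(axis=1)
    b = ts.data[:, set_b].mean(axis=1)
    return _windowed_pair_series(a, b, retained, spec, "node_pair")
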
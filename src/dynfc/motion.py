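"""Head-motion handling: framewise displacement, censoring, nuisance
regression, and bandpass filtering of node time series.

Framewise displacement (FD) at TR t is the sum of the absolute temporal
differences of the six rigid-body parameters,

    FD_t = sum_{i=1..6} | R_i(t) - R_i(t-1) |,     FD_0 = 0,

with rotations treated in the units supplied.  Censoring applies three
rules: (1) any TR with FD above threshold is removed together with the
immediately following TR; (2) a retained TR whose two temporal
neighbours are both censored is removed as well; (3) a run in which more
than half the TRs end up censored is flagged unusable as a whole.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import RoiTimeSeries

__all__ = [
    "MotionTrace",
    "CensorMask",
    "framewise_displacement",
    "censor_mask",
    "nuisance_regress",
    "bandpass",
]


@dataclass
class MotionTrace:
    """Per-TR six rigid-body parameters (3 translations, 3 rotations)."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion trace must have six columns")

    @property
    def n_timepoints(self) -> int:
        return self.params.shape[0]


@dataclass
class CensorMask:
    """Per-TR retention flags plus the whole-run usability verdict."""

    retained: np.ndarray
    usable: bool = True

    def __post_init__(self) -> None:
        self.retained = np.asarray(self.retained, dtype=bool)

    @property
    def retained_fraction(self) -> float:
        return float(self.retained.mean()) if self.retained.size else 0.0


def framewise_displacement(motion: MotionTrace) -> np.ndarray:
    """Per-TR FD; zero at the first TR by convention."""
    params = motion.params if isinstance(motion, MotionTrace) else np.asarray(motion, float)
    if params.shape[0] < 2:
        raise ValueError("need at least 2 TRs to compute FD")
    if not np.isfinite(params).all():
        raise ValueError("non-finite motion parameter values")
    fd = np.zeros(params.shape[0])
    fd[1:] = np.abs(np.diff(params, axis=0)).sum(axis=1)
    return fd


def censor_mask(fd: np.ndarray, threshold: float = 0.5,
                run_fraction: float = 0.5) -> CensorMask:
    """Apply the three censoring rules to an FD series."""
    fd = np.asarray(fd, dtype=float)
    if (fd < 0).any():
        raise ValueError("FD must be nonnegative")
    n = fd.size
    censored = fd > threshold
    # rule 1: the TR after a supra-threshold TR is censored too
    censored[1:] |= censored[:-1].copy()
    # rule 2: retained TRs isolated between censored neighbours; repeat to
    # a fixed point so cascades resolve (the rule is idempotent after that)
    changed = True
    while changed:
        iso = ~censored[1:-1] & censored[:-2] & censored[2:]
        changed = bool(iso.any())
        censored[1:-1] |= iso
    usable = censored.mean() <= run_fraction
    return CensorMask(retained=~censored, usable=usable)


def _volterra_design(params: np.ndarray) -> np.ndarray:
    """24 motion regressors: [R, R^2, R_{t-1}, R^2_{t-1}].

    The lagged rows are padded by replicating the first sample so the
    design has the same length as the series.
    """
    lag = np.vstack([params[:1], params[:-1]])
    return np.hstack([params, params**2, lag, lag**2])


def nuisance_regress(ts: RoiTimeSeries, motion: MotionTrace,
                     csf: np.ndarray | None = None,
                     wm: np.ndarray | None = None) -> RoiTimeSeries:
    """OLS residualisation of every node on motion + tissue regressors.

    The design is intercept + 24 Volterra motion regressors + optional
    CSF and WM mean-signal columns.  Collinear columns are dropped with a
    warning; residuals are exactly orthogonal to every retained column.
    """
    params = motion.params if isinstance(motion, MotionTrace) else np.asarray(motion, float)
    n = ts.n_timepoints
    if params.shape[0] != n:
        raise ValueError("motion trace length does not match time series")
    cols = [np.ones((n, 1)), _volterra_design(params)]
    for name, series in (("csf", csf), ("wm", wm)):
        if series is not None:
            series = np.asarray(series, float).reshape(-1, 1)
            if series.shape[0] != n:
                raise ValueError(f"{name} regressor length does not match time series")
            cols.append(series)
    X = np.hstack(cols)
    # drop collinear columns via pivoted QR
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        from scipy.linalg import qr
        _, _, piv = qr(X, mode="economic", pivoting=True)
        keep = np.sort(piv[:rank])
        warnings.warn(f"rank-deficient nuisance design: dropping "
                      f"{X.shape[1] - rank} collinear column(s)", stacklevel=2)
        X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
    resid = ts.data - X @ beta
    return RoiTimeSeries(resid, tr_seconds=ts.tr_seconds, subject_id=ts.subject_id,
                         node_ids=ts.node_ids, roles=dict(ts.roles))


def bandpass(ts: RoiTimeSeries, low_hz: float = 0.01, high_hz: float = 0.1,
             order: int = 4) -> RoiTimeSeries:
    """Zero-phase Butterworth bandpass of every node series.

    Forward-backward (filtfilt) application avoids the phase distortion
    that would corrupt windowed correlations.  ``order`` is the analog
    prototype order; the effective attenuation is doubled by the two
    passes.
    """
    fs = 1.0 / ts.tr_seconds
    nyq = fs / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(f"band ({low_hz}, {high_hz}) Hz must lie inside "
                         f"(0, {nyq}) Hz at TR {ts.tr_seconds} s")
    sos = signal.butter(order, [low_hz, high_hz], btype="band", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, ts.data, axis=0)
    return RoiTimeSeries(filtered, tr_seconds=ts.tr_seconds, subject_id=ts.subject_id,
                         node_ids=ts.node_ids, roles=dict(ts.roles))
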
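"""Within-subject linear support vector regression: which network-network
interactions predict the bi-nodal amygdala-mPFC trajectory?

For each subject, the 45 module-pair FC window series are the features
and the bi-nodal FC series is the target.  An epsilon-insensitive linear
SVR (cost C = 1) is fit per subject; performance is the Pearson r
between observed and leave-one-window-out predicted values.  Feature
weights from the full-data fit are carried to group level, where
one-sample t-tests identify interactions consistently predictive across
subjects (screened at p < 0.01, with BH-FDR flags alongside).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .inference import fdr_adjust, one_sample_t

__all__ = ["fit_linear_svr", "loocv_performance", "group_weight_tests",
           "MIN_WINDOWS"]

#: minimum number of jointly valid windows for a within-subject fit.
MIN_WINDOWS = 10


def _zscore_train(train: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd <= 0, 1.0, sd)
    return mu, sd


def _clean(features, target):
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("features must be windows x pairs, target a window vector")
    keep = np.isfinite(y) & np.isfinite(X).all(axis=1)
    X, y = X[keep], y[keep]
    if y.size < MIN_WINDOWS:
        raise ValueError(f"need at least {MIN_WINDOWS} valid windows, got {y.size}")
    return X, y


def fit_linear_svr(features, target, cost: float = 1.0, epsilon: float = 0.1):
    """Full-data linear SVR fit on z-scored variables.

    Returns ``(weights, intercept)`` on the z-scored scale; each weight
    is the feature's signed contribution to the decision function.
    """
    X, y = _clean(features, target)
    mu_x, sd_x = _zscore_train(X)
    mu_y, sd_y = _zscore_train(y[:, None])
    Xz = (X - mu_x) / sd_x
    yz = (y - mu_y[0]) / sd_y[0]
    model = SVR(kernel="linear", C=cost, epsilon=epsilon)
    model.fit(Xz, yz)
    return model.coef_.ravel().copy(), float(model.intercept_[0])


def loocv_performance(features, target, cost: float = 1.0,
                      epsilon: float = 0.1, global_z: bool = False) -> float:
    """Leave-one-window-out Pearson r between observed and predicted.

    By default z-scoring is re-estimated on each training fold and
    applied to the held-out window (fold-safe).  ``global_z=True``
    z-scores once over all windows before cross-validation instead, for
    comparison with analyses that standardise up front.
    """
    X, y = _clean(features, target)
    n = y.size
    if global_z:
        mu_x, sd_x = _zscore_train(X)
        mu_y, sd_y = _zscore_train(y[:, None])
        X = (X - mu_x) / sd_x
        y = (y - mu_y[0]) / sd_y[0]
    preds = np.empty(n)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        Xtr, ytr = X[tr], y[tr]
        if global_z:
            Xtr_z, ytr_z, Xte_z = Xtr, ytr, X[i:i + 1]
            y_mu, y_sd = 0.0, 1.0
        else:
            mu_x, sd_x = _zscore_train(Xtr)
            mu_y, sd_y = _zscore_train(ytr[:, None])
            Xtr_z = (Xtr - mu_x) / sd_x
            ytr_z = (ytr - mu_y[0]) / sd_y[0]
            Xte_z = (X[i:i + 1] - mu_x) / sd_x
            y_mu, y_sd = mu_y[0], sd_y[0]
        model = SVR(kernel="linear", C=cost, epsilon=epsilon)
        model.fit(Xtr_z, ytr_z)
        preds[i] = model.predict(Xte_z)[0] * y_sd + y_mu
    if preds.std() <= 0 or y.std() <= 0:
        warnings.warn("constant predictions; LOOCV performance defined as 0",
                      stacklevel=2)
        return 0.0
    return float(np.corrcoef(y, preds)[0, 1])


def group_weight_tests(per_subject_weights, pair_labels=None) -> pd.DataFrame:
    """One-sample t-tests of each feature weight across subjects.

    ``per_subject_weights`` is subjects x pairs.  Returns a pair-labeled
    table with ``t``, ``p``, mean weight, a ``sig_p01`` flag at the
    exploratory p < 0.01 screen and a ``sig_fdr05`` flag at BH-FDR 0.05.
    """
    W = np.asarray(per_subject_weights, dtype=float)
    if W.ndim != 2:
        raise ValueError("weights must be a subjects x pairs matrix")
    if W.shape[0] < 3:
        raise ValueError("need at least 3 subjects for group weight tests")
    n_pairs = W.shape[1]
    if pair_labels is None:
        pair_labels = [f"pair{j}" for j in range(n_pairs)]
    if len(pair_labels) != n_pairs:
        raise ValueError("one label per pair required")
    ts, ps = [], []
    for j in range(n_pairs):
        t, _, p = one_sample_t(W[:, j])
        ts.append(t)
        ps.append(p)
    ps = np.array(ps)
    return pd.DataFrame({
        "pair": list(pair_labels),
        "mean_weight": W.mean(axis=0),
        "t": ts,
        "p": ps,
        "p_fdr": fdr_adjust(ps),
        "sig_p01": ps < 0.01,
        "sig_fdr05": fdr_adjust(ps) < 0.05,
    })
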
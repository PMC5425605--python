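"""Within-subject cross-level statistics.

Each subject contributes three aligned window trajectories — bi-nodal
(amygdala-mPFC) FC, limbic-DMN module-pair FC, and modularity Q.  The
trajectories are correlated pairwise within the subject and Fisher-z
transformed, giving per-subject effect sizes whose group distribution is
tested downstream.  Per-subject medians of each trajectory are the
static-like summaries entering the trauma regressions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .connectivity import fisher_z
from .dynamics import WindowSeries

__all__ = ["cross_level_correlate", "series_median", "cross_level_row",
           "MIN_JOINT_WINDOWS"]

#: below this many jointly valid windows a within-subject correlation is
#: reported as missing rather than estimated.
MIN_JOINT_WINDOWS = 10


def cross_level_correlate(a: WindowSeries, b: WindowSeries) -> float:
    """Fisher-z Pearson correlation of two window series.

    Windows invalid in either series are dropped pairwise; fewer than
    ``MIN_JOINT_WINDOWS`` joint windows yields NaN with a warning.
    """
    if a.n_windows != b.n_windows or not np.array_equal(a.starts, b.starts):
        raise ValueError("window grids are not aligned")
    joint = a.valid & b.valid
    if joint.sum() < MIN_JOINT_WINDOWS:
        warnings.warn("fewer than %d jointly valid windows; correlation "
                      "reported missing" % MIN_JOINT_WINDOWS, stacklevel=2)
        return float("nan")
    x, y = a.values[joint], b.values[joint]
    if x.std() <= 0 or y.std() <= 0:
        warnings.warn("constant series; correlation reported missing", stacklevel=2)
        return float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    return fisher_z(np.clip(r, -1.0, 1.0))


def series_median(a: WindowSeries) -> float:
    """Median over valid windows only; NaN when no window is valid."""
    vals = a.valid_values()
    return float(np.median(vals)) if vals.size else float("nan")


def cross_level_row(subject_id: str, binodal: WindowSeries,
                    module_pair: WindowSeries, q: WindowSeries) -> dict:
    """One subject's cross-level summary (a row of the cohort table)."""
    return {
        "subject_id": subject_id,
        "z_binodal_modpair": cross_level_correlate(binodal, module_pair),
        "z_binodal_q": cross_level_correlate(binodal, q),
        "z_modpair_q": cross_level_correlate(module_pair, q),
        "median_binodal_fc": series_median(binodal),
        "median_modpair_fc": series_median(module_pair),
        "median_q": series_median(q),
        "n_valid_windows": int((binodal.valid & module_pair.valid & q.valid).sum()),
    }


def cross_level_table(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows)
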
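"""End-to-end orchestration: simulate (or load) -> preprocess -> group
partition -> window dynamics -> cross-level -> group statistics -> SVR.

Every stage is a pure function of (inputs, config, seed); seeds are
derived hierarchically (global -> stage -> subject -> window -> run) so
any stage can be re-run in isolation and reproduce its outputs exactly.
All tables are written as TSV, the manifest as JSON.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community import Partition, consensus_partition, gamma_sweep
from .connectivity import group_matrix
from .core import RoiTimeSeries, derive_seed
from .cross_level import cross_level_row, cross_level_table
from .dynamics import (WindowSeries, WindowSpec, module_pair_fc, node_pair_fc,
                       window_connectivity, window_modularity)
from .inference import build_design, ols_fit, one_sample_t
from .motion import bandpass, censor_mask, framewise_displacement, nuisance_regress
from .svr import fit_linear_svr, group_weight_tests, loocv_performance
from .synthetic import CohortConfig, generate_cohort, write_cohort

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "prep_subject",
           "subject_dynamics"]


@dataclass
class PipelineConfig:
    """Settings for a full run; defaults match the emulated protocol:
    22-TR windows stepped by 5, gamma 1.7 chosen from a 1-2 sweep in 0.1
    steps with 250 runs per gamma, 300-run consensus, 25 restarts per
    window, FD threshold 0.5, SVR cost 1."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    window: WindowSpec = field(default_factory=WindowSpec)
    gamma: float = 1.7
    sweep_gammas: tuple = tuple(np.round(np.arange(1.0, 2.0001, 0.1), 10))
    sweep_runs: int = 250
    run_sweep: bool = False
    consensus_runs: int = 300
    window_restarts: int = 25
    fd_threshold: float = 0.5
    run_fraction: float = 0.5
    apply_nuisance: bool = True
    apply_bandpass: bool = True
    svr_cost: float = 1.0
    svr_epsilon: float = 0.1
    run_svr_loocv: bool = True
    log_ctq: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sweep_gammas"] = list(self.sweep_gammas)
        return d


@dataclass
class PipelineResult:
    """In-memory artifacts of one run."""

    partition: Partition
    sweep: pd.DataFrame | None
    cross_level: pd.DataFrame
    covariates: pd.DataFrame
    group_tests: pd.DataFrame
    regressions: dict
    svr_subjects: pd.DataFrame
    svr_group: pd.DataFrame
    manifest: dict
    truth: object = None


def prep_subject(ts: RoiTimeSeries, motion, config: PipelineConfig):
    """FD, censor mask, nuisance regression and bandpass for one subject.

    Returns ``(prepped series, mask, mean FD)``; the mask's ``usable``
    flag implements the whole-run censoring rule.
    """
    fd = framewise_displacement(motion)
    mask = censor_mask(fd, threshold=config.fd_threshold,
                       run_fraction=config.run_fraction)
    out = ts
    if config.apply_nuisance:
        out = nuisance_regress(out, motion)
    if config.apply_bandpass:
        out = bandpass(out)
    return out, mask, float(fd.mean())


def _pair_key(partition: Partition, ts: RoiTimeSeries) -> tuple[int, int]:
    """The (limbic, DMN) module pair: the consensus modules holding the
    designated amygdala and mPFC nodes."""
    a = int(partition.labels[ts.roles["amygdala"]])
    b = int(partition.labels[ts.roles["mpfc"]])
    if a == b:
        raise ValueError("amygdala and mPFC fell into the same consensus "
                         "module; the limbic-DMN pair is undefined")
    return (min(a, b), max(a, b))


def subject_dynamics(ts: RoiTimeSeries, mask, partition: Partition,
                     config: PipelineConfig, seed: int):
    """All window series for one subject.

    Returns a dict with the bi-nodal series, the module-pair series
    dict, the limbic-DMN pair key, and the Q series.
    """
    spec = config.window
    binodal = node_pair_fc(ts, [ts.roles["amygdala"]], [ts.roles["mpfc"]],
                           mask, spec)
    binodal.name = "binodal"
    pairs = module_pair_fc(ts, partition, mask, spec)
    mats, valid, starts = window_connectivity(ts, mask, spec)
    q = window_modularity(mats, valid, starts, gamma=config.gamma,
                          n_runs=config.window_restarts, seed=seed)
    return {"binodal": binodal, "pairs": pairs, "q": q,
            "limbic_dmn": _pair_key(partition, ts)}


def _svr_features(dyn: dict):
    """Stack module-pair series into a windows x pairs matrix."""
    keys = sorted(dyn["pairs"])
    cols, labels = [], []
    for key in keys:
        ws = dyn["pairs"][key]
        vals = np.where(ws.valid, ws.values, np.nan)
        cols.append(vals)
        labels.append(f"module_{key[0]}-{key[1]}")
    target = np.where(dyn["binodal"].valid, dyn["binodal"].values, np.nan)
    return np.column_stack(cols), target, labels


def run_pipeline(config: PipelineConfig, out_dir=None,
                 cohort=None) -> PipelineResult:
    """Execute every stage on a synthetic (or supplied) cohort.

    ``cohort`` may pre-supply ``(series, motions, covariates, truth)``;
    otherwise the cohort is generated from ``config.cohort``.  When
    ``out_dir`` is given, all tables plus a manifest are written there.
    """
    seed = config.seed
    if cohort is None:
        series, motions, covariates, truth = generate_cohort(config.cohort)
    else:
        series, motions, covariates, truth = cohort
    covariates = covariates.copy()

    # --- preprocessing & censoring -------------------------------------
    prepped, masks, mean_fd, usable = [], [], [], []
    for ts, mot in zip(series, motions):
        p, m, fd_bar = prep_subject(ts, mot, config)
        prepped.append(p)
        masks.append(m)
        mean_fd.append(fd_bar)
        usable.append(m.usable)
    covariates["mean_fd"] = mean_fd
    covariates["usable"] = usable
    keep = [i for i, u in enumerate(usable) if u]
    kept_series = [prepped[i] for i in keep]
    kept_masks = [masks[i] for i in keep]
    kept_cov = covariates.iloc[keep].reset_index(drop=True)

    # --- group partition ------------------------------------------------
    gm = group_matrix(kept_series, kept_masks)
    partition = consensus_partition(gm, gamma=config.gamma,
                                    n_runs=config.consensus_runs,
                                    seed=derive_seed(seed, 100))
    sweep = None
    if config.run_sweep:
        sweep = gamma_sweep(gm, gammas=config.sweep_gammas,
                            n_runs=config.sweep_runs,
                            seed=derive_seed(seed, 101))

    # --- per-subject dynamics, cross-level, SVR ------------------------
    rows, svr_rows, weight_stack = [], [], []
    pair_labels = None
    n_windows = None
    for i, (ts, mask) in enumerate(zip(kept_series, kept_masks)):
        dyn = subject_dynamics(ts, mask, partition, config,
                               seed=derive_seed(seed, 200, i))
        modpair = dyn["pairs"][dyn["limbic_dmn"]]
        rows.append(cross_level_row(ts.subject_id, dyn["binodal"],
                                    modpair, dyn["q"]))
        X, y, labels = _svr_features(dyn)
        pair_labels = labels
        n_windows = dyn["q"].n_windows
        w, _ = fit_linear_svr(X, y, cost=config.svr_cost,
                              epsilon=config.svr_epsilon)
        perf = (loocv_performance(X, y, cost=config.svr_cost,
                                  epsilon=config.svr_epsilon)
                if config.run_svr_loocv else np.nan)
        weight_stack.append(w)
        svr_rows.append({"subject_id": ts.subject_id, "performance": perf,
                         **{lab: wv for lab, wv in zip(labels, w)}})
    xl = cross_level_table(rows).merge(kept_cov, on="subject_id")

    # --- group statistics ----------------------------------------------
    group_tests = []
    for col in ("z_binodal_modpair", "z_binodal_q", "z_modpair_q"):
        t, df, p = one_sample_t(xl[col])
        group_tests.append({"measure": col, "t": t, "df": df, "p": p,
                            "mean": float(np.nanmean(xl[col]))})
    group_tests = pd.DataFrame(group_tests)

    regressions = {}
    X_ctq = build_design(xl, model="ctq", log_ctq=config.log_ctq)
    X_grp = build_design(xl, model="group")
    for outcome in ("median_binodal_fc", "median_q"):
        regressions[f"ctq:{outcome}"] = ols_fit(xl[outcome], X_ctq, outcome)
    for outcome in ("z_binodal_modpair", "z_binodal_q", "z_modpair_q"):
        regressions[f"group:{outcome}"] = ols_fit(xl[outcome], X_grp, outcome)

    svr_subjects = pd.DataFrame(svr_rows)
    svr_group = group_weight_tests(np.vstack(weight_stack), pair_labels)

    manifest = {
        "version": __version__,
        "seed": seed,
        "config_sha1": hashlib.sha1(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
        "n_subjects_input": len(series),
        "n_subjects_retained": len(keep),
        "n_windows": n_windows,
        "n_modules": partition.n_modules,
        "n_module_pairs": len(pair_labels) if pair_labels else 0,
        "consensus_q": partition.q_value,
        "limbic_dmn_pair": list(dyn["limbic_dmn"]),
    }
    result = PipelineResult(partition=partition, sweep=sweep, cross_level=xl,
                            covariates=covariates, group_tests=group_tests,
                            regressions=regressions, svr_subjects=svr_subjects,
                            svr_group=svr_group, manifest=manifest, truth=truth)
    if out_dir is not None:
        _write_result(Path(out_dir), config, result,
                      (series, motions, covariates, truth))
    return result


def _write_result(out: Path, config: PipelineConfig, res: PipelineResult,
                  cohort) -> None:
    out.mkdir(parents=True, exist_ok=True)
    series, motions, covariates, truth = cohort
    write_cohort(out / "cohort", series, motions, covariates, truth,
                 config=config.cohort)
    pd.DataFrame({"node": np.arange(res.partition.labels.size),
                  "module": res.partition.labels}).to_csv(
        out / "partition.tsv", sep="\t", index=False)
    (out / "partition.json").write_text(json.dumps(
        {"gamma": res.partition.gamma, "q": res.partition.q_value,
         "n_modules": res.partition.n_modules}))
    if res.sweep is not None:
        res.sweep.to_csv(out / "gamma_sweep.tsv", sep="\t", index=False)
    res.cross_level.to_csv(out / "cross_level.tsv", sep="\t", index=False)
    res.group_tests.to_csv(out / "group_tests.tsv", sep="\t", index=False)
    for name, reg in res.regressions.items():
        fname = "regression_" + name.replace(":", "_") + ".tsv"
        reg.table.to_csv(out / fname, sep="\t", index=False)
    res.svr_subjects.to_csv(out / "svr_subjects.tsv", sep="\t", index=False)
    res.svr_group.to_csv(out / "svr_group.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(json.dumps(res.manifest, indent=1))
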
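"""Synthetic resting-state cohorts with planted ground truth.

The generator emulates a two-group adolescent cohort (controls and
assault-exposed participants) scanned for 450 s at TR = 2 s, parcellated
into ~10 large-scale modules.  No generative model is implied by real
resting-state data; the distributional choices here are explicit
stand-ins built so every downstream stage of the pipeline has a known
recovery target:

* each module m has a latent unit-variance Gaussian time course s_m(t);
  node signals are ``loading * s_m(t) + noise``;
* all module pairs share a global factor giving a common between-module
  correlation b_i per subject;
* the limbic (module 0) and default-mode (module 1) pair additionally
  follows a *time-varying* coupling c_t realised through a shared factor
  with signed loading, so corr(s_0, s_1) equals c_t exactly at the
  latent level.  c_t comes from a bounded AR(1) state at sliding-window
  resolution, interpolated to TRs;
* the designated amygdala (limbic) and mPFC (DMN) nodes receive an extra
  shared component with amplitude ``binodal_gain * c_t``, tying bi-nodal
  FC to the limbic-DMN coupling; caudate nodes carry module signal only,
  giving the specificity contrast;
* childhood-trauma severity (emotional-abuse score) shifts the subject
  mean of c_t by ``trauma_effect_fc`` and the global between-module
  coupling by ``trauma_effect_mod`` per standard deviation of the
  log-transformed score, so modular segregation (Q) rises while bi-nodal
  FC falls with abuse when both effects are negative;
* motion traces are smooth random-walk drifts plus step displacements
  whose framewise displacement exceeds the 0.5 censoring threshold.
  Censoring ground truth is emergent from the spikes, never planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .core import RoiTimeSeries, derive_seed, write_matrix
from .motion import MotionTrace

__all__ = ["CohortConfig", "GroundTruth", "generate_cohort",
           "generate_motion_trace", "write_cohort"]

#: fixed loading of every node on its module's latent time course.
NODE_LOADING = 0.8
#: reduced module loading of the designated amygdala/mPFC nodes, so
#: their mutual FC is dominated by the coupling-scaled shared component
#: and its tracking fidelity genuinely varies across subjects.
BINODAL_LOADING = 0.5
#: AR(1) coefficient of the window-level latent coupling state.
AR_PHI = 0.8
#: Table-1-style covariate distributions (mean, sd) per group.
AGE_DIST = {"control": (14.7, 1.92), "assaulted": (15.2, 1.52)}
VIQ_DIST = {"control": (107.5, 19.1), "assaulted": (99.4, 13.7)}
#: CTQ subscale score distributions; controls sit near the floor of 5,
#: the assaulted group is shifted upward (Table-1 direction).
CTQ_DIST = {"control": (7.5, 2.0), "assaulted": (11.5, 3.5)}
CTQ_SUBSCALES = ["emotional_abuse", "physical_abuse", "sexual_abuse",
                 "emotional_neglect", "physical_neglect"]


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort.

    Defaults reproduce the emulated study conditions: 30 + 26 subjects,
    225 TRs at 2 s, 215 nodes in 10 modules.  Effect parameters are on
    the correlation scale per SD of the (log) emotional-abuse score.
    """

    n_control: int = 30
    n_assaulted: int = 26
    n_nodes: int = 215
    n_modules: int = 10
    n_timepoints: int = 225
    tr_seconds: float = 2.0
    coupling_base: float = 0.25
    coupling_volatility: float = 0.15
    binodal_gain: float = 0.8
    trauma_effect_fc: float = -0.15
    trauma_effect_mod: float = -0.08
    noise_sd: float = 0.5
    motion_spike_prob: float = 0.02
    seed: int = 0
    window_length_trs: int = 22
    window_step_trs: int = 5

    @property
    def n_subjects(self) -> int:
        return self.n_control + self.n_assaulted

    @property
    def n_windows(self) -> int:
        return (self.n_timepoints - self.window_length_trs) // self.window_step_trs + 1

    def validate(self) -> None:
        for name in ("n_control", "n_assaulted", "n_nodes", "n_modules",
                     "n_timepoints", "window_length_trs", "window_step_trs"):
            if getattr(self, name) < 1:
                raise ValueError(f"CohortConfig.{name} must be positive")
        if self.n_modules < 2:
            raise ValueError("CohortConfig.n_modules must be >= 2 so the "
                             "amygdala and mPFC nodes lie in distinct modules")
        if self.n_timepoints < self.window_length_trs:
            raise ValueError("CohortConfig.n_timepoints must be >= window_length_trs")
        if self.n_nodes < 3 * self.n_modules:
            raise ValueError("CohortConfig.n_nodes too small: need >= 3 nodes "
                             "per module for the designated-node roles")
        if not 0.0 <= self.motion_spike_prob <= 1.0:
            raise ValueError("CohortConfig.motion_spike_prob must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("CohortConfig.noise_sd must be nonnegative")
        if self.coupling_volatility < 0:
            raise ValueError("CohortConfig.coupling_volatility must be nonnegative")
        if not 0.0 < self.coupling_base < 0.9:
            raise ValueError("CohortConfig.coupling_base must be in (0, 0.9)")


@dataclass
class GroundTruth:
    """Planted quantities used as recovery targets by the tests."""

    module_labels: np.ndarray
    #: shape (n_subjects, n_windows): true limbic-DMN coupling per window.
    latent_coupling: np.ndarray
    #: per-subject true effects: abuse score, its z, mean bi-nodal
    #: coupling, and between-module coupling.
    subject_effects: pd.DataFrame
    module_names: list = field(default_factory=list)


def _module_labels(n_nodes: int, n_modules: int) -> np.ndarray:
    """Contiguous near-even blocks of nodes; module 0 = limbic, 1 = DMN."""
    return np.sort(np.arange(n_nodes) % n_modules)


def generate_motion_trace(n_timepoints: int, spike_prob: float,
                          seed: int = 0) -> MotionTrace:
    """Six-column motion trace: smooth drift plus supra-threshold steps.

    Each spiked TR adds a persistent offset of magnitude 0.15 (random
    sign) to every parameter, so its FD is 0.9 > 0.5 while neighbouring
    TRs stay at drift level (FD ~ 0.02).
    """
    if not 0.0 <= spike_prob <= 1.0:
        raise ValueError("spike_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    drift = np.cumsum(rng.normal(0.0, 0.004, size=(n_timepoints, 6)), axis=0)
    spikes = rng.random(n_timepoints) < spike_prob
    spikes[0] = False  # FD is undefined-at-0 by convention
    offsets = np.zeros((n_timepoints, 6))
    for t in np.flatnonzero(spikes):
        offsets[t:] += rng.choice([-0.15, 0.15], size=6)
    return MotionTrace(params=drift + offsets)


def _ctq_scores(rng: np.random.Generator, group: str, n: int) -> np.ndarray:
    """Five correlated subscale scores per subject, clipped to [5, 25]."""
    mean, sd = CTQ_DIST[group]
    shared = rng.normal(0.0, 1.0, size=(n, 1))
    unique = rng.normal(0.0, 1.0, size=(n, 5))
    raw = mean + sd * (0.6 * shared + 0.8 * unique)
    return np.clip(np.round(raw), 5, 25)


def generate_cohort(config: CohortConfig):
    """Generate one cohort: time series, motion, covariates, ground truth.

    Deterministic for a fixed ``config.seed``.  Returns
    ``(list[RoiTimeSeries], list[MotionTrace], covariates DataFrame,
    GroundTruth)``.
    """
    config.validate()
    labels = _module_labels(config.n_nodes, config.n_modules)
    # designated nodes: amygdala = first limbic node, mPFC = first DMN
    # node, caudate = next two limbic nodes (bilateral pair)
    amygdala = int(np.flatnonzero(labels == 0)[0])
    mpfc = int(np.flatnonzero(labels == 1)[0])
    caudate = [int(i) for i in np.flatnonzero(labels == 0)[1:3]]
    roles = {"amygdala": amygdala, "mpfc": mpfc, "caudate": caudate}

    n_sub, t_len = config.n_subjects, config.n_timepoints
    groups = ["control"] * config.n_control + ["assaulted"] * config.n_assaulted

    cov_rng = np.random.default_rng(derive_seed(config.seed, 0))
    rows = []
    for i, grp in enumerate(groups):
        rows.append({
            "subject_id": f"sub-{i:03d}",
            "group": grp,
            "age": round(float(np.clip(cov_rng.normal(*AGE_DIST[grp]), 11, 17.9)), 1),
            "verbal_iq": float(np.round(np.clip(cov_rng.normal(*VIQ_DIST[grp]), 60, 160))),
        })
    covariates = pd.DataFrame(rows)
    ctq_c = _ctq_scores(cov_rng, "control", config.n_control)
    ctq_a = _ctq_scores(cov_rng, "assaulted", config.n_assaulted)
    ctq = np.vstack([ctq_c, ctq_a])
    for j, name in enumerate(CTQ_SUBSCALES):
        covariates[f"ctq_{name}"] = ctq[:, j]

    abuse = covariates["ctq_emotional_abuse"].to_numpy(float)
    log_abuse = np.log(abuse)
    abuse_z = (log_abuse - log_abuse.mean()) / log_abuse.std()

    n_win = config.n_windows
    centers = (np.arange(n_win) * config.window_step_trs
               + (config.window_length_trs - 1) / 2.0)

    series, motions = [], []
    latent = np.zeros((n_sub, n_win))
    effects = []
    for i in range(n_sub):
        rng = np.random.default_rng(derive_seed(config.seed, 1, i))
        b_i = float(np.clip(config.coupling_base
                            + config.trauma_effect_mod * abuse_z[i], 0.02, 0.85))
        mu_i = config.coupling_base + config.trauma_effect_fc * abuse_z[i]
        # stationary AR(1) state at window resolution
        v = np.zeros(n_win)
        v[0] = rng.normal(0.0, config.coupling_volatility)
        innov_sd = config.coupling_volatility * np.sqrt(1.0 - AR_PHI**2)
        for w in range(1, n_win):
            v[w] = AR_PHI * v[w - 1] + rng.normal(0.0, innov_sd)
        c_lo = max(0.02, 2.0 * b_i - 0.95)  # keeps factor variances valid
        c_w = np.clip(mu_i + v, c_lo, 0.92)
        latent[i] = c_w
        c_t = np.interp(np.arange(t_len), centers, c_w)

        g = rng.normal(0.0, 1.0, t_len)        # global between-module factor
        xi = rng.normal(0.0, 1.0, t_len)       # limbic-DMN coupling factor
        eta = rng.normal(0.0, 1.0, (t_len, config.n_modules))
        l_t = np.sqrt(np.abs(c_t - b_i))
        sgn = np.sign(c_t - b_i)
        s = np.sqrt(b_i) * g[:, None] + np.sqrt(1.0 - b_i) * eta
        resid_01 = np.sqrt(np.clip(1.0 - b_i - l_t**2, 0.0, None))
        s[:, 0] = np.sqrt(b_i) * g + l_t * xi + resid_01 * eta[:, 0]
        s[:, 1] = np.sqrt(b_i) * g + sgn * l_t * xi + resid_01 * eta[:, 1]

        x = (NODE_LOADING * s[:, labels]
             + config.noise_sd * rng.normal(0.0, 1.0, (t_len, config.n_nodes)))
        # the designated nodes share an extra component proportional to the
        # current coupling: the limbic-DMN coupling factor itself, so the
        # bi-nodal channel co-moves with the realized module coupling and
        # its tracking fidelity scales with the subject's coupling level
        binodal = config.binodal_gain * c_t * xi
        x[:, amygdala] = (BINODAL_LOADING * s[:, 0] + binodal
                          + config.noise_sd * rng.normal(0.0, 1.0, t_len))
        x[:, mpfc] = (BINODAL_LOADING * s[:, 1] + binodal
                      + config.noise_sd * rng.normal(0.0, 1.0, t_len))

        series.append(RoiTimeSeries(x, tr_seconds=config.tr_seconds,
                                    subject_id=f"sub-{i:03d}", roles=dict(roles)))
        motions.append(generate_motion_trace(t_len, config.motion_spike_prob,
                                             seed=derive_seed(config.seed, 2, i)))
        effects.append({"subject_id": f"sub-{i:03d}",
                        "abuse_score": abuse[i], "abuse_z": abuse_z[i],
                        "mean_binodal_coupling": float(c_w.mean()),
                        "between_coupling": b_i})

    truth = GroundTruth(module_labels=labels, latent_coupling=latent,
                        subject_effects=pd.DataFrame(effects),
                        module_names=["limbic", "DMN"] +
                        [f"module{m}" for m in range(2, config.n_modules)])
    return series, motions, covariates, truth


def write_cohort(out_dir, series, motions, covariates, truth,
                 config: CohortConfig | None = None) -> None:
    """Serialize a cohort: matrices and motion as numeric text,
    covariates as TSV, ground truth (and config) as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ts, mot in zip(series, motions):
        write_matrix(out / f"{ts.subject_id}_ts.txt", ts.data,
                     header=list(ts.node_ids))
        np.savetxt(out / f"{ts.subject_id}_motion.txt", mot.params, fmt="%.8g")
    covariates.to_csv(out / "covariates.tsv", sep="\t", index=False)
    payload = {
        "module_labels": truth.module_labels.tolist(),
        "module_names": truth.module_names,
        "latent_coupling": truth.latent_coupling.tolist(),
        "subject_effects": truth.subject_effects.to_dict(orient="list"),
        "roles": series[0].roles if series else {},
    }
    if config is not None:
        payload["config"] = asdict(config)
    (out / "ground_truth.json").write_text(json.dumps(payload))
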
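# Methods

This note documents the models, algorithms, numerical choices, and the
synthetic-cohort generator behind `dynfc`, in the order the pipeline runs.

## Motion preprocessing

Framewise displacement at TR t is FD_t = Σ_{i=1..6} |R_i(t) − R_i(t−1)|
over the six rigid-body parameters, with FD_0 = 0 by convention and
rotations taken in the units supplied (no conversion to mm is attempted,
since the convention of the source traces is unknowable downstream).
Censoring applies three rules in order: any TR with FD > 0.5 is censored
together with the immediately following TR; retained TRs whose two
temporal neighbours are both censored are removed, iterated to a fixed
point so cascades resolve; and a run whose censored fraction exceeds 50 %
is flagged unusable as a whole.  The package assumes single-run data (one
450-s scan), so the third rule drops whole subjects.

Nuisance regression residualises each node on an intercept, 24 Volterra
motion regressors [R, R², R_{t−1}, R²_{t−1}] (the lagged rows padded by
replicating the first sample so the design matches the series length), and
optional CSF/WM mean-signal columns.  Collinear columns are dropped via
pivoted QR with a warning; residuals are exactly orthogonal to every
retained column.  Temporal filtering uses a zero-phase forward–backward
Butterworth bandpass (order 4, 0.01–0.1 Hz at TR = 2 s).  The filter
family is a design choice: zero-phase application avoids the phase
distortion that would corrupt windowed correlations.  The stage order is
nuisance regression → bandpass → censoring applied only at correlation
time (censored TRs are excluded, never interpolated), keeping the temporal
grid intact for windowing.

## Connectivity

Correlations are Pearson over retained TRs and Fisher-z transformed with
|r| clipped to 1 − 1e−7 so degenerate perfect correlations stay finite.
Zero-variance nodes (detected with a relative tolerance, since a constant
column's sample std is rounding noise) get zeroed rows with a warning.
Two variants exist deliberately: bi-nodal and module-pair FC use the
*signed* matrices — these quantities genuinely fluctuate around zero —
while all community detection uses the *graph-ready* variant (diagonal and
negative weights zeroed), including the per-window matrices.  The group
matrix z-scores each subject's retained TRs per node before concatenating,
so between-subject mean and variance differences cannot masquerade as
correlation.

## Community detection

Modularity is the standard weighted form with resolution parameter γ:
Q = (1/2m) Σ_ij [W_ij − γ k_i k_j/2m] δ(c_i, c_j).  The Louvain
implementation is two-phase greedy maximisation: node visit order is
shuffled from the run's seed, a move is accepted only for strictly
positive gain with first-best tie-breaking, and converged local moves are
followed by module aggregation until neither phase improves Q.  The inner
loop is JIT-compiled (numba), which makes the repeated-restart protocols
(250-run stability sweeps, 300-run consensus, 25 restarts per window per
subject) practical on a single core.  `best_partition` keeps the maximum-Q
restart, breaking exact ties toward fewer modules and earlier runs.

Partition similarity is the z-scored Rand pair count
z = (w − M₁M₂/M)/σ_w, where M is the number of node pairs, M₁ and M₂ the
within-module pair counts, and w the pairs co-assigned in both.  Printed
forms of σ_w vary across the literature, so the package derives the exact
permutation-null variance from first principles by splitting pair-of-pairs
into identical, sharing-one-node, and disjoint configurations:

    E[w²] = M₁M₂/M + T₁T₂ / n(n−1)(n−2)
            + 4(M₁²−M₁−T₁)(M₂²−M₂−T₂) / n(n−1)(n−2)(n−3),

with T = Σ_groups s(s−1)(s−2).  The test suite validates this against a
10⁵-draw Monte-Carlo permutation estimate; degenerate pairs (all
singletons vs one module) have σ_w = 0 and score 0 by definition.

Consensus clustering runs n Louvain partitions, forms the agreement matrix
(entry = fraction of partitions co-assigning the pair), and re-clusters it
with the diagonal zeroed, iterating until partitions are unanimous or mean
off-diagonal agreement stops increasing (cap: 50 rounds).  Consensus
rounds use γ = 1 regardless of the working resolution — agreement matrices
have near-binary weights, and re-applying a high resolution there
fragments stable structure; this is configurable.  The returned partition
carries its Q re-computed on the original matrix at the original γ.  The
working resolution defaults to γ = 1.7; `gamma_sweep` reproduces the
selection protocol (γ from 1 to 2 in 0.1 steps, 250 runs each, mean
pairwise z-Rand subsampled to at most 1000 partition pairs for
tractability).

## Sliding-window dynamics

Windows are half-open ranges of 22 TRs stepped by 5 (41 windows over 225
TRs), included iff they fit inside the scan.  A window is valid when at
least 2/3 of its TRs survive censoring (and at least 3 in absolute terms);
invalid windows are flagged in place rather than dropped, keeping grids
aligned across subjects and series.  Per-window Q uses graph-ready
matrices with 25 restarts by default, seeded deterministically from
(stage, subject, window, run) so any stage re-runs bit-identically.
Module-pair FC uses the group-level consensus partition for every subject,
with the module time course defined as the mean course of its nodes;
node-pair FC supports singleton sets (amygdala–mPFC) and multi-node sets
(bilateral caudate collapsed to one mean course).  Both are Fisher-z
transformed per window, matching the bi-nodal series.

## Cross-level and group statistics

Within each subject the three trajectories (bi-nodal FC, limbic–DMN FC,
Q) are correlated pairwise — Pearson, over jointly valid windows, with
fewer than 10 joint windows reported missing — and Fisher-z transformed.
Group-level inference uses one-sample t-tests on the z distributions and
OLS regressions: the *ctq* model enters all five CTQ subscales
simultaneously (log-transformed, then z-scored; subscale minimums of 5
keep the log defined) plus z-scored age, verbal IQ, and mean FD; the
*group* model replaces the subscales with a 0/1 assault dummy.  The log
transform is applied to all five subscales for symmetry and is a config
flag.  Tests are two-sided; Benjamini–Hochberg FDR is available and used
alongside the exploratory p < 0.01 screen on SVR weights.

## SVR attribution

Per subject, a linear ε-insensitive SVR (libsvm engine, C = 1, ε = 0.1
default) predicts the bi-nodal series from the 45 module-pair series, all
z-scored.  Reported weights come from the full-data fit; performance is
the Pearson r between observed and leave-one-window-out predictions, with
z-scoring re-estimated inside each training fold by default (a
`global_z` flag reproduces the simpler standardise-once variant).  ε is
not prescribed by the protocol this emulates; 0.1 is the common default
and the acceptance checks also pass at 0.01.  Invalid windows are dropped
listwise across features and target.

## The synthetic cohort

No generative model is implied by real resting-state data; the generator
is an explicit stand-in built so that every downstream stage has a known
recovery target.  Its structure:

* Each module m has a unit-variance latent Gaussian course s_m(t); node
  signals are 0.8·s_m + 0.5·noise (within-module r ≈ 0.72).  All module
  pairs share a global factor giving between-module correlation b_i per
  subject.
* The limbic–DMN pair follows a time-varying coupling c_t: a stationary
  AR(1) state (φ = 0.8, sd = `coupling_volatility` = 0.15) at window
  resolution, interpolated to TRs, around a subject mean
  μ_i = `coupling_base` (0.25) + `trauma_effect_fc`·z_i, where z_i is the
  z-scored log emotional-abuse score.  A signed loading on the shared
  factor realises corr(s_limbic, s_DMN) = c_t exactly, above or below b_i.
* The designated amygdala and mPFC nodes carry a reduced module loading
  (0.5) plus an extra shared component `binodal_gain`·c_t·ξ, where ξ is
  the limbic–DMN coupling factor itself.  Tying the bi-nodal channel to
  the same factor that carries the module coupling makes the bi-nodal
  window series co-move with the *realized* module coupling, and makes its
  tracking fidelity scale with the subject's coupling level — which is
  what produces the weaker cross-level correspondence in the
  higher-trauma group.  Caudate nodes carry module signal only, providing
  the specificity contrast.
* Trauma severity shifts the bi-nodal mean by `trauma_effect_fc` = −0.15
  and the global between-module coupling by `trauma_effect_mod` = −0.08
  per SD of log emotional abuse, so bi-nodal FC falls and modular
  segregation (Q) rises with abuse.
* Covariates follow the emulated sample: ages ~N(14.7, 1.9)/N(15.2, 1.5),
  verbal IQ ~N(107.5, 19.1)/N(99.4, 13.7), CTQ subscales correlated
  within subject, controls near the floor (mean ≈ 7.5) and the assaulted
  group shifted upward (mean ≈ 11.5), clipped to the 5–25 score range.
* Motion traces are smooth random-walk drifts plus step displacements of
  0.15 per parameter (FD = 0.9 > 0.5) at `motion_spike_prob` = 0.02 per
  TR.  Censoring ground truth is emergent from the spikes, never planted,
  and the signal model is independent of motion.

Effect sizes were fixed once, during generator design, so that the planted
effects are detectable at the emulated sample size (n = 56) the way the
emulated findings are — i.e. moderate standardized effects — and are
documented here rather than tuned per analysis.

What the generator does *not* emulate: hemodynamics (latent factors are
temporally white before the pipeline's own bandpass), voxel-level
structure, scanner/protocol heterogeneity, spatially varying noise, or
genuine network reconfiguration beyond the single time-varying coupling.
Passing recovery tests therefore demonstrates the correctness and
statistical calibration of the pipeline, not the truth of any claim about
real brains.

## Problem sizes and numerical choices

Tests and the acceptance script run at a desk-scale parcellation of 60
nodes (10 or 6 modules) with the full temporal protocol (225 TRs, 41
windows) and sample size (56); the parcellation is the only dimension
scaled down, chosen so that planted communities are still comfortably
recoverable.  Louvain move acceptance requires a gain above 1e−12;
exact-tie handling is documented above.  Correlations are clipped before
atanh; zero-variance guards are relative.  Seeds derive hierarchically
from a single root via `numpy.random.SeedSequence`, and every reported
number is reproducible bit for bit from that root.

## Known limitations

* Negative weights are discarded for community detection (no
  negative-weight modularity variants), matching the emulated protocol.
* No tapered windows or state-space dynamic-connectivity estimators; the
  windowing is rectangular with listwise censoring.
* The consensus procedure's stopping rule (mean off-diagonal agreement
  non-increase) can in principle stop early on adversarial graphs; the
  cap and fallback return the best-agreement partition with a warning.
* `rand_z_score` requires ≥ 4 nodes (the permutation variance involves
  4-node configurations).
* The CLI ingests node-level numeric text only — no NIfTI/BIDS.
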
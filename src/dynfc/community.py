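"""Community detection: Louvain with a resolution parameter, partition
similarity, resolution selection, and agreement-matrix consensus.

All routines operate on "graph-ready" connectivity matrices: symmetric,
nonnegative, zero diagonal (see :mod:`dynfc.connectivity`).  Modularity
follows the standard weighted Newman definition with resolution
parameter gamma,

    Q = (1/2m) * sum_ij [ w_ij - gamma * k_i k_j / (2m) ] * delta(c_i, c_j)

where k_i is the weighted degree and 2m the total weight.  Larger gamma
penalises large modules and yields finer partitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .core import derive_seed

__all__ = [
    "Partition",
    "modularity_q",
    "louvain",
    "best_partition",
    "rand_z_score",
    "gamma_sweep",
    "agreement",
    "consensus_partition",
]

#: gamma used when re-clustering agreement matrices during consensus.
#: Agreement matrices have near-binary weights; unit resolution keeps the
#: consensus rounds from shattering them.
CONSENSUS_GAMMA = 1.0

#: safety cap on consensus iterations.
MAX_CONSENSUS_ITER = 50


@dataclass
class Partition:
    """A node -> module assignment together with the settings that made it.

    Labels are contiguous integers ``0..n_modules-1`` ordered by first
    appearance along the node axis, so two partitions are identical iff
    their label arrays are equal element-wise.
    """

    labels: np.ndarray
    gamma: float = 1.0
    q_value: float = np.nan

    def __post_init__(self) -> None:
        self.labels = canonical_labels(np.asarray(self.labels, dtype=np.int64))

    @property
    def n_modules(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def module_nodes(self, module: int) -> np.ndarray:
        return np.flatnonzero(self.labels == module)


def canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel modules as 0..K-1 in order of first appearance."""
    labels = np.asarray(labels)
    uniq, inv = np.unique(labels, return_inverse=True)
    first = np.full(uniq.size, labels.size, dtype=np.int64)
    np.minimum.at(first, inv, np.arange(labels.size))
    rank = np.empty(uniq.size, dtype=np.int64)
    rank[np.argsort(first)] = np.arange(uniq.size)
    return rank[inv]


def _as_weight_array(w) -> np.ndarray:
    """Accept a ConnectivityMatrix or a bare ndarray; return float ndarray."""
    arr = getattr(w, "z", w)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("weight matrix must be square")
    if (arr < 0).any():
        raise ValueError("community routines require nonnegative weights; "
                         "apply make_graph_ready first")
    return arr


def modularity_q(w, partition, gamma: float = 1.0) -> float:
    """Modularity Q of a partition on a nonnegative weighted graph.

    ``partition`` may be a :class:`Partition` or a bare label array.
    Returns 0 (with a warning) for an all-zero matrix, where Q is not
    defined by the formula.
    """
    arr = _as_weight_array(w)
    labels = np.asarray(getattr(partition, "labels", partition), dtype=np.int64)
    if labels.shape[0] != arr.shape[0]:
        raise ValueError("partition length does not match matrix size")
    k = arr.sum(axis=1)
    two_m = k.sum()
    if two_m <= 0:
        warnings.warn("all-zero graph: modularity defined as 0", stacklevel=2)
        return 0.0
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        q += arr[np.ix_(idx, idx)].sum() - gamma * k[idx].sum() ** 2 / two_m
    return float(q / two_m)


@njit(cache=False)
def _louvain_core(W, gamma, seed):  # pragma: no cover - exercised via louvain()
    np.random.seed(seed)
    n0 = W.shape[0]
    labels = np.arange(n0)
    Wc = W.copy()
    while True:
        m = Wc.shape[0]
        k = np.zeros(m)
        for i in range(m):
            s = 0.0
            for j in range(m):
                s += Wc[i, j]
            k[i] = s
        two_m = k.sum()
        if two_m <= 0.0:
            break
        comm = np.arange(m)
        stot = k.copy()
        lw = np.zeros(m)
        moved = True
        while moved:
            moved = False
            order = np.random.permutation(m)
            for oi in range(m):
                i = order[oi]
                ci = comm[i]
                for c in range(m):
                    lw[c] = 0.0
                for j in range(m):
                    if j != i:
                        lw[comm[j]] += Wc[i, j]
                stot[ci] -= k[i]
                base = lw[ci] - gamma * k[i] * stot[ci] / two_m
                best_c = ci
                best_gain = base
                for c in range(m):
                    if c == ci:
                        continue
                    g = lw[c] - gamma * k[i] * stot[c] / two_m
                    if g > best_gain + 1e-12:
                        best_gain = g
                        best_c = c
                comm[i] = best_c
                stot[best_c] += k[i]
                if best_c != ci:
                    moved = True
        # compact community ids by first appearance
        new_id = np.full(m, -1, dtype=np.int64)
        cnt = 0
        for i in range(m):
            c = comm[i]
            if new_id[c] < 0:
                new_id[c] = cnt
                cnt += 1
            comm[i] = new_id[c]
        if cnt == m:
            break
        W2 = np.zeros((cnt, cnt))
        for i in range(m):
            for j in range(m):
                W2[comm[i], comm[j]] += Wc[i, j]
        Wc = W2
        for v in range(n0):
            labels[v] = comm[labels[v]]
    return labels


def louvain(w, gamma: float = 1.0, seed: int = 0) -> Partition:
    """One seeded run of two-phase greedy modularity maximisation.

    Node visit order is shuffled from ``seed``; a move is accepted only
    for strictly positive modularity gain; the first best candidate wins
    ties.  Local moves alternate with module aggregation until neither
    phase improves Q.  Deterministic for a fixed seed.
    """
    arr = _as_weight_array(w)
    labels = _louvain_core(arr, float(gamma), int(seed) % (2**32))
    part = Partition(labels=labels, gamma=float(gamma))
    part.q_value = modularity_q(arr, part, gamma=gamma) if arr.sum() > 0 else 0.0
    return part


def best_partition(w, gamma: float = 1.0, n_runs: int = 25, seed: int = 0) -> Partition:
    """Best of ``n_runs`` restarts of :func:`louvain`.

    Returns the partition with maximal Q; exact ties go to the partition
    with fewer modules, then to the earlier run.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    arr = _as_weight_array(w)
    best: Partition | None = None
    for r in range(n_runs):
        cand = louvain(arr, gamma=gamma, seed=derive_seed(seed, r))
        if best is None or cand.q_value > best.q_value + 1e-12 or (
            abs(cand.q_value - best.q_value) <= 1e-12
            and cand.n_modules < best.n_modules
        ):
            best = cand
    return best


def _pair_stats(labels: np.ndarray):
    """Within-pair count M1, and the triple count T = sum n_i(n_i-1)(n_i-2)."""
    sizes = np.bincount(labels)
    sizes = sizes[sizes > 0].astype(float)
    m1 = float((sizes * (sizes - 1) / 2).sum())
    t = float((sizes * (sizes - 1) * (sizes - 2)).sum())
    return m1, t


def rand_z_score(p1, p2) -> float:
    """z-scored Rand pair-counting similarity of two partitions.

    The score standardises w, the number of node pairs co-assigned in
    both partitions, under the permutation null in which one partition's
    labels are randomly reassigned to nodes:

        z = (w - M1*M2/M) / sd(w)

    with M the total node-pair count and M1, M2 the within-module pair
    counts of each partition.  The null variance is exact, obtained by
    splitting pair-of-pairs into identical / sharing-one-node / disjoint
    configurations.  Degenerate partitions (all singletons, or a single
    module) have sd(w) = 0; the score is then defined as 0.
    """
    l1 = np.asarray(getattr(p1, "labels", p1), dtype=np.int64)
    l2 = np.asarray(getattr(p2, "labels", p2), dtype=np.int64)
    if l1.shape != l2.shape:
        raise ValueError("partitions must cover the same node set")
    n = l1.size
    if n < 4:
        raise ValueError("need at least 4 nodes for the permutation variance")
    m = n * (n - 1) / 2.0
    m1, t1 = _pair_stats(l1)
    m2, t2 = _pair_stats(l2)
    # observed co-assignment count via the contingency table
    joint = np.bincount(l1 * (l2.max() + 1) + l2).astype(float)
    w_obs = float((joint * (joint - 1) / 2).sum())
    e_w = m1 * m2 / m
    n3 = n * (n - 1.0) * (n - 2.0)
    n4 = n3 * (n - 3.0)
    e_w2 = (
        m1 * m2 / m
        + t1 * t2 / n3
        + 4.0 * (m1 * m1 - m1 - t1) * (m2 * m2 - m2 - t2) / n4
    )
    var_w = e_w2 - e_w * e_w
    if var_w <= 1e-12:
        warnings.warn("degenerate partition pair: Rand z defined as 0", stacklevel=2)
        return 0.0
    return float((w_obs - e_w) / np.sqrt(var_w))


def agreement(partitions) -> np.ndarray:
    """Co-assignment (agreement) matrix of a stack of partitions.

    Entry (i, j) is the fraction of partitions assigning nodes i and j
    to the same module; the diagonal is 1.
    """
    parts = [np.asarray(getattr(p, "labels", p)) for p in partitions]
    if len(parts) < 2:
        raise ValueError("need at least two partitions")
    n = parts[0].size
    acc = np.zeros((n, n))
    for lab in parts:
        if lab.size != n:
            raise ValueError("partitions must cover the same node set")
        acc += lab[:, None] == lab[None, :]
    return acc / len(parts)


def gamma_sweep(w, gammas=None, n_runs: int = 250, seed: int = 0,
                max_pairs: int = 1000) -> pd.DataFrame:
    """Partition-stability profile over a range of resolution parameters.

    For each gamma, ``n_runs`` seeded Louvain partitions are generated;
    stability is the mean pairwise z-scored Rand similarity over all
    unordered partition pairs, subsampled without replacement to at most
    ``max_pairs`` pairs.  Returns a table with one row per gamma:
    ``gamma``, ``mean_rand_z``, ``median_n_modules``.
    """
    if gammas is None:
        gammas = np.round(np.arange(1.0, 2.0001, 0.1), 10)
    gammas = np.asarray(list(gammas), dtype=float)
    if gammas.size < 2:
        raise ValueError("need at least two gammas to sweep")
    arr = _as_weight_array(w)
    rng = np.random.default_rng(derive_seed(seed, 10_001))
    rows = []
    for gi, g in enumerate(gammas):
        parts = [louvain(arr, gamma=g, seed=derive_seed(seed, gi, r))
                 for r in range(n_runs)]
        n_pairs_total = n_runs * (n_runs - 1) // 2
        if n_pairs_total <= max_pairs:
            pair_idx = [(a, b) for a in range(n_runs) for b in range(a + 1, n_runs)]
        else:
            flat = rng.choice(n_pairs_total, size=max_pairs, replace=False)
            pair_idx = []
            for f in flat:
                a = int((2 * n_runs - 1 - np.sqrt((2 * n_runs - 1) ** 2 - 8 * f)) // 2)
                b = int(f - a * (2 * n_runs - a - 1) // 2 + a + 1)
                pair_idx.append((a, b))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sims = [rand_z_score(parts[a], parts[b]) for a, b in pair_idx]
        rows.append({
            "gamma": float(g),
            "mean_rand_z": float(np.mean(sims)),
            "median_n_modules": float(np.median([p.n_modules for p in parts])),
        })
    return pd.DataFrame(rows)


def _unanimous(parts) -> bool:
    first = parts[0].labels
    return all(np.array_equal(first, p.labels) for p in parts[1:])


def consensus_partition(w, gamma: float = 1.7, n_runs: int = 300,
                        seed: int = 0) -> Partition:
    """Stable partition via iterative agreement-matrix re-clustering.

    Each round runs ``n_runs`` seeded Louvain partitions and forms their
    agreement matrix; the next round re-clusters that matrix (diagonal
    zeroed, unit resolution).  Iteration stops at unanimous agreement or
    as soon as mean off-diagonal agreement stops increasing, with a hard
    cap of ``MAX_CONSENSUS_ITER`` rounds.  The returned partition carries
    its Q re-computed on the *original* matrix at the original gamma.
    """
    arr = _as_weight_array(w)
    current = arr
    cur_gamma = float(gamma)
    prev_score = -np.inf
    best_fallback: Partition | None = None
    final: Partition | None = None
    for it in range(MAX_CONSENSUS_ITER):
        parts = [louvain(current, gamma=cur_gamma, seed=derive_seed(seed, it, r))
                 for r in range(n_runs)]
        if _unanimous(parts):
            final = parts[0]
            break
        agree = agreement(parts)
        off = agree[~np.eye(agree.shape[0], dtype=bool)]
        score = float(off.mean())
        # representative of this round: the highest-Q run on the original graph
        rep = max(parts, key=lambda p: modularity_q(arr, p, gamma=gamma))
        if best_fallback is None or score > prev_score:
            best_fallback = rep
        if score <= prev_score:
            final = best_fallback
            break
        prev_score = score
        current = agree.copy()
        np.fill_diagonal(current, 0.0)
        cur_gamma = CONSENSUS_GAMMA
    if final is None:
        warnings.warn("consensus did not converge within the iteration cap; "
                      "returning best-agreement partition", stacklevel=2)
        final = best_fallback
    out = Partition(labels=final.labels, gamma=float(gamma))
    out.q_value = modularity_q(arr, out, gamma=gamma) if arr.sum() > 0 else 0.0
    return out
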
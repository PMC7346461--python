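"""Ancestral fang-state reconstruction.

Two complementary routes:

* an equal-rates (ER / Mk) continuous-time Markov model fitted by maximum
  likelihood, with exact per-node marginal state probabilities computed by
  the up/down (rerooting-equivalent) algorithm; and
* the quantitative-genetic threshold model: an unobserved continuous
  liability evolves by Brownian motion (variance 1 per unit branch
  length) and the discrete state is the interval of the ordered threshold
  vector the liability falls in.  Tip and node liabilities and the free
  thresholds are sampled by a Gibbs/Metropolis MCMC; node state
  posteriors are post-burn-in interval frequencies.

The ER transition probability over time t has the closed form
``P_same(t) = 1/k + (k-1)/k * exp(-k q t)`` and
``P_diff(t) = 1/k * (1 - exp(-k q t))``; the root state prior is uniform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr, ndtri

from .tree import Node, Phylogeny, node_ids

__all__ = [
    "er_log_likelihood",
    "fit_er_rate",
    "ml_asr_marginal",
    "ancthresh_mcmc",
    "ERFit",
    "ASRResult",
    "ThresholdChain",
]


def _resolve_states(tip_states: Mapping[str, str], states: Sequence[str] | None, k: int | None):
    observed = sorted({str(s) for s in tip_states.values()})
    if states is None:
        if k is not None and k != len(observed):
            raise ValueError(
                f"k={k} but {len(observed)} states observed; pass an explicit "
                "state list to include unobserved states"
            )
        states = observed
    states = list(states)
    if k is not None and k != len(states):
        raise ValueError(f"k={k} does not match state list of length {len(states)}")
    unknown = set(observed) - set(states)
    if unknown:
        raise ValueError(f"unknown state labels: {sorted(unknown)}")
    return states


def _check_tips(tree: Phylogeny, tip_states: Mapping[str, str]) -> None:
    missing = [t for t in tree.tip_labels if t not in tip_states]
    if missing:
        raise ValueError(f"states missing for tips: {', '.join(missing)}")


def _er_uppass(tree: Phylogeny, tip_states, q: float, states: list[str]):
    """Scaled pruning partials per node; returns (partials, logfactor)."""
    k = len(states)
    sidx = {s: i for i, s in enumerate(states)}
    partials: dict[Node, np.ndarray] = {}
    logf = 0.0
    for node in tree.postorder():
        if node.is_leaf:
            D = np.zeros(k)
            D[sidx[str(tip_states[node.label])]] = 1.0
        else:
            D = np.ones(k)
            for child in node.children:
                e = np.exp(-k * q * child.length)
                Dc = partials[child]
                D = D * (e * Dc + (1 - e) * Dc.mean())
            s = D.sum()
            if s <= 0:
                raise ValueError("zero likelihood during pruning")
            D = D / s
            logf += np.log(s)
        partials[node] = D
    return partials, logf


def er_log_likelihood(
    tree: Phylogeny,
    tip_states: Mapping[str, str],
    q: float,
    k: int | None = None,
    states: Sequence[str] | None = None,
) -> float:
    """Log-likelihood of tip states under the equal-rates Markov model.

    Felsenstein pruning with the closed-form ER transition probabilities;
    the root partials are combined with a uniform state prior.
    """
    if q < 0:
        raise ValueError("rate q must be non-negative")
    _check_tips(tree, tip_states)
    states = _resolve_states(tip_states, states, k)
    partials, logf = _er_uppass(tree, tip_states, q, states)
    root_like = partials[tree.root].mean()  # uniform prior = mean of partials
    return float(np.log(root_like) + logf)


@dataclass
class ERFit:
    """Maximum-likelihood estimate of the single ER transition rate."""

    q: float
    log_likelihood: float
    at_boundary: bool = False


def fit_er_rate(
    tree: Phylogeny,
    tip_states: Mapping[str, str],
    k: int | None = None,
    states: Sequence[str] | None = None,
) -> ERFit:
    """Bounded 1-D maximum-likelihood fit of the ER rate q."""
    _check_tips(tree, tip_states)
    states = _resolve_states(tip_states, states, k)
    observed = {str(tip_states[t]) for t in tree.tip_labels}
    if len(observed) < 2:
        warnings.warn("all tips share one state: q-hat = 0 at the boundary")
        logL = er_log_likelihood(tree, tip_states, 0.0, states=states)
        return ERFit(q=0.0, log_likelihood=logL, at_boundary=True)
    q_max = 100.0 / max(tree.height, 1e-12)

    def nll(logq: float) -> float:
        return -er_log_likelihood(tree, tip_states, np.exp(logq), states=states)

    res = optimize.minimize_scalar(
        nll,
        bounds=(np.log(1e-8 / tree.height), np.log(q_max)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    q_hat = float(np.exp(res.x))
    return ERFit(q=q_hat, log_likelihood=-float(res.fun))


@dataclass
class ThresholdChain:
    """MCMC trace and settings of a threshold-model run."""

    state_order: list[str]
    thresholds_mean: np.ndarray
    trace: pd.DataFrame = field(repr=False)
    liability_mean: pd.Series = field(repr=False)
    acceptance_rate: float = float("nan")
    rhat_root: float = float("nan")
    ngen: int = 0
    burnin: int = 0
    seed: int | None = None


@dataclass
class ASRResult:
    """Per-internal-node state probabilities plus fitted parameters.

    ``node_probabilities`` is indexed by the deterministic post-order node
    id (see :func:`snakedent.tree.node_ids`); probabilities in each row
    sum to 1.
    """

    states: list[str]
    node_probabilities: pd.DataFrame
    method: str
    q: float | None = None
    log_likelihood: float | None = None
    chain: ThresholdChain | None = None
    warnings: list[str] = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.node_probabilities.to_csv(path, index_label="node")

    def annotated_newick(self, tree: Phylogeny) -> str:
        """Newick with internal labels ``<id>[&state=prob,...]``."""
        ids = node_ids(tree)

        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = node.label
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                nid = ids[node]
                probs = self.node_probabilities.loc[nid]
                ann = ",".join(f"{st}={probs[st]:.4f}" for st in self.states)
                s += f"{nid}[&{ann}]"
            if node.length is not None:
                s += f":{node.length:.12g}"
            return s

        return fmt(tree.root) + ";"


def ml_asr_marginal(
    tree: Phylogeny,
    tip_states: Mapping[str, str],
    k: int | None = None,
    states: Sequence[str] | None = None,
) -> ASRResult:
    """Exact marginal ancestral states under the ML-fitted ER model.

    For each internal node the marginal posterior over states at the
    fitted rate is computed with the up/down algorithm, which is
    equivalent to rerooting the tree at every node.
    """
    _check_tips(tree, tip_states)
    states = _resolve_states(tip_states, states, k)
    fit = fit_er_rate(tree, tip_states, states=states)
    q = fit.q
    kk = len(states)
    partials, _ = _er_uppass(tree, tip_states, q, states)

    down: dict[Node, np.ndarray] = {tree.root: np.full(kk, 1.0 / kk)}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        msgs = {}
        for child in node.children:
            e = np.exp(-kk * q * child.length)
            Dc = partials[child]
            msgs[child] = e * Dc + (1 - e) * Dc.mean()
        for child in node.children:
            W = down[node].copy()
            for other in node.children:
                if other is not child:
                    W = W * msgs[other]
            e = np.exp(-kk * q * child.length)
            U = e * W + (1 - e) * W.mean()
            s = U.sum()
            down[child] = U / s if s > 0 else U

    ids = node_ids(tree)
    rows, index = [], []
    for node in tree.postorder():
        if node.is_leaf:
            continue
        marg = partials[node] * down[node]
        marg = marg / marg.sum()
        rows.append(marg)
        index.append(ids[node])
    probs = pd.DataFrame(rows, index=index, columns=states)
    return ASRResult(
        states=states,
        node_probabilities=probs,
        method="ml-er-marginal",
        q=q,
        log_likelihood=fit.log_likelihood,
    )


def _split_rhat(x: np.ndarray) -> float:
    """Split-R-hat of a single chain (split into two halves)."""
    n = x.size // 2
    if n < 2:
        return float("nan")
    chains = np.stack([x[:n], x[x.size - n :]])
    within = chains.var(axis=1, ddof=1).mean()
    between = n * chains.mean(axis=1).var(ddof=1)
    if within == 0:
        return float("nan")
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))


def ancthresh_mcmc(
    tree: Phylogeny,
    tip_states: Mapping[str, str],
    state_order: Sequence[str],
    ngen: int = 100_000,
    burnin: int = 20_000,
    seed: int | None = None,
) -> ASRResult:
    """Bayesian threshold-model ancestral state reconstruction.

    Liabilities evolve by Brownian motion with variance 1 per unit branch
    length; state s occupies the liability interval between thresholds
    s-1 and s, with the first threshold fixed at 0 for identifiability
    and the remaining thresholds uniform on the ordered set within
    (0, T_max], T_max = 6 * sqrt(tree height).  Internal-node liabilities
    are Gibbs-sampled from their full conditionals, tip liabilities from
    truncated normals on their observed state's interval, and free
    thresholds by random-walk Metropolis with the step adapted toward
    ~30% acceptance during burn-in.
    """
    _check_tips(tree, tip_states)
    states = list(state_order)
    k = len(states)
    if k < 2:
        raise ValueError("need at least 2 states")
    unknown = {str(v) for v in tip_states.values()} - set(states)
    if unknown:
        raise ValueError(f"tip states outside state_order: {sorted(unknown)}")
    if ngen <= burnin:
        raise ValueError("ngen must exceed burnin")
    rng = np.random.default_rng(seed)

    # -- flatten tree to arrays -----------------------------------------
    nodes = list(tree.postorder())
    idx = {nd: i for i, nd in enumerate(nodes)}
    n_nodes = len(nodes)
    is_tip = np.array([nd.is_leaf for nd in nodes])
    tip_idx = np.flatnonzero(is_tip)
    int_idx = np.flatnonzero(~is_tip)
    parent = np.full(n_nodes, -1)
    blen = np.zeros(n_nodes)
    for nd in nodes:
        if nd.parent is not None:
            parent[idx[nd]] = idx[nd.parent]
            blen[idx[nd]] = max(nd.length, 1e-12)
    neighbors: list[list[tuple[int, float]]] = [[] for _ in range(n_nodes)]
    for i in range(n_nodes):
        if parent[i] >= 0:
            neighbors[i].append((parent[i], blen[i]))
            neighbors[parent[i]].append((i, blen[i]))

    sidx = {s: i for i, s in enumerate(states)}
    tip_state_idx = np.array(
        [sidx[str(tip_states[nodes[i].label])] for i in tip_idx]
    )
    t_max = 6.0 * np.sqrt(max(tree.height, 1e-12))

    # thresholds: thr[0] = 0 fixed; thr has k-1 entries
    thr = np.linspace(0.0, t_max / 3.0, k - 1) if k > 2 else np.array([0.0])

    def bounds_for(state_i: np.ndarray, thresholds: np.ndarray):
        lo = np.where(state_i == 0, -np.inf, thresholds[np.maximum(state_i - 1, 0)])
        hi = np.where(state_i == k - 1, np.inf, thresholds[np.minimum(state_i, k - 2)])
        return lo, hi

    # init: tips at interval midpoints (clipped), internals at 0
    lo, hi = bounds_for(tip_state_idx, thr)
    liab = np.zeros(n_nodes)
    liab[tip_idx] = np.clip((np.where(np.isinf(lo), hi - 1.0, lo) +
                             np.where(np.isinf(hi), lo + 1.0, hi)) / 2.0, -t_max, t_max)

    tip_parent = parent[tip_idx]
    tip_sd = np.sqrt(blen[tip_idx])

    # per-boundary tip groups for threshold Metropolis updates
    free_thr = list(range(1, k - 1))
    groups_below = {m: tip_idx[tip_state_idx == m] for m in free_thr}
    groups_above = {m: tip_idx[tip_state_idx == m + 1] for m in free_thr}
    steps = {m: 0.25 * np.sqrt(tree.height) for m in free_thr}
    accepted = {m: 0 for m in free_thr}
    proposed = {m: 0 for m in free_thr}
    win_acc = {m: 0 for m in free_thr}
    win_n = {m: 0 for m in free_thr}

    n_int = int_idx.size
    state_counts = np.zeros((n_int, k))
    trace_rows = []
    tiny = 1e-12

    for gen in range(ngen):
        # 1. Gibbs: internal-node liabilities from full conditionals
        z = rng.standard_normal(n_int)
        for j, i in enumerate(int_idx):
            prec = 0.0
            mean_acc = 0.0
            for nb, t in neighbors[i]:
                w = 1.0 / t
                prec += w
                mean_acc += liab[nb] * w
            mu = mean_acc / prec
            liab[i] = mu + z[j] / np.sqrt(prec)

        # 2. tip liabilities: truncated normal given parent (vectorized)
        lo, hi = bounds_for(tip_state_idx, thr)
        mu = liab[tip_parent]
        a = ndtr((lo - mu) / tip_sd)
        b = ndtr((hi - mu) / tip_sd)
        u = a + rng.random(tip_idx.size) * (b - a)
        u = np.clip(u, tiny, 1.0 - tiny)
        liab[tip_idx] = mu + tip_sd * ndtri(u)

        # 3. Metropolis: free thresholds (flat prior on the ordered set)
        for m in free_thr:
            proposed[m] += 1
            win_n[m] += 1
            prop = thr[m] + steps[m] * rng.standard_normal()
            lo_ok = thr[m - 1] if m >= 1 else 0.0
            hi_ok = thr[m + 1] if m + 1 <= k - 2 else t_max
            ok = lo_ok < prop < hi_ok
            if ok and groups_below[m].size:
                ok = liab[groups_below[m]].max() < prop
            if ok and groups_above[m].size:
                ok = liab[groups_above[m]].min() >= prop
            if ok:
                thr[m] = prop
                accepted[m] += 1
                win_acc[m] += 1
            if gen < burnin and win_n[m] == 100:
                rate = win_acc[m] / 100.0
                if rate < 0.2:
                    steps[m] *= 0.8
                elif rate > 0.4:
                    steps[m] *= 1.25
                win_acc[m] = win_n[m] = 0

        if gen >= burnin:
            node_states = np.searchsorted(thr, liab[int_idx], side="right")
            state_counts[np.arange(n_int), node_states] += 1.0
        if gen % 10 == 0:
            trace_rows.append(
                (gen, liab[int_idx[-1]], *thr[1:]) if k > 2 else (gen, liab[int_idx[-1]])
            )

    probs = state_counts / state_counts.sum(axis=1, keepdims=True)
    ids = node_ids(tree)
    index = [ids[nodes[i]] for i in int_idx]
    prob_df = pd.DataFrame(probs, index=index, columns=states)

    trace_cols = ["generation", "root_liability"] + [f"threshold_{m}" for m in free_thr]
    trace = pd.DataFrame(trace_rows, columns=trace_cols)
    post = trace[trace["generation"] >= burnin]["root_liability"].to_numpy()
    rhat = _split_rhat(post)
    warns = []
    if np.isfinite(rhat) and rhat > 1.2:
        msg = f"split R-hat on root liability is {rhat:.3f} (> 1.2): chain may not have converged"
        warnings.warn(msg)
        warns.append(msg)
    total_prop = sum(proposed.values())
    acc_rate = (sum(accepted.values()) / total_prop) if total_prop else float("nan")
    post_trace = trace[trace["generation"] >= burnin]
    thr_mean = np.concatenate(
        [[0.0], [post_trace[f"threshold_{m}"].mean() for m in free_thr]]
    )
    chain = ThresholdChain(
        state_order=states,
        thresholds_mean=thr_mean,
        trace=trace,
        liability_mean=pd.Series(liab[int_idx], index=index),
        acceptance_rate=acc_rate,
        rhat_root=rhat,
        ngen=ngen,
        burnin=burnin,
        seed=seed,
    )
    return ASRResult(
        states=states,
        node_probabilities=prob_df,
        method="threshold-mcmc",
        chain=chain,
        warnings=warns,
    )
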
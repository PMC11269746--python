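"""Continuous-time Markov (Mk) machinery for discrete characters on a tree.

Implements Felsenstein pruning likelihoods for binary and k-state characters,
maximum-likelihood rate fitting, a random-walk Metropolis sampler over binary
gain/loss rates, and joint (Pupko-style dynamic programming) and marginal
(up/down message passing) ancestral state reconstruction.

Characters may be supplied singly (``{tip: state}``) or as a species x
character matrix (pandas DataFrame); all passes are vectorised over
characters.  Missing tip data (state ``-1`` / ``None`` / NaN) enter as
uninformative partial-likelihood vectors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .errors import ConvergenceFailure, InvalidArgumentError, SamplerFailure
from .trees import Phylogeny

__all__ = [
    "BinaryRates",
    "RateMatrixK",
    "NodeStateAssignment",
    "PosteriorSampleSet",
    "MarginalPosteriors",
    "FitResult",
    "prune_loglik",
    "fit_ml",
    "mcmc_sample",
    "autocorrelation",
    "joint_reconstruct",
    "marginal_reconstruct",
]

_RATE_FLOOR = 1e-10


# --------------------------------------------------------------------- models
@dataclass(frozen=True)
class BinaryRates:
    """Gain (0→1) and loss (1→0) rates per unit branch length."""

    q01: float
    q10: float

    def __post_init__(self):
        if self.q01 < 0 or self.q10 < 0:
            raise InvalidArgumentError("rates must be non-negative")

    @property
    def k(self) -> int:
        return 2

    def stationary(self) -> np.ndarray:
        s = self.q01 + self.q10
        if s == 0:
            return np.array([0.5, 0.5])
        return np.array([self.q10 / s, self.q01 / s])

    def transition(self, t: float) -> np.ndarray:
        """Closed-form 2-state transition matrix P(t) = expm(Q t)."""
        if t < 0:
            raise InvalidArgumentError("negative branch length")
        s = self.q01 + self.q10
        if s == 0 or t == 0:
            return np.eye(2)
        e = math.exp(-s * t)
        pi0 = self.q10 / s
        pi1 = self.q01 / s
        return np.array(
            [
                [pi0 + pi1 * e, pi1 * (1.0 - e)],
                [pi0 * (1.0 - e), pi1 + pi0 * e],
            ]
        )

    def transition_stack(self, ts: np.ndarray) -> np.ndarray:
        """Vectorised P(t) for an array of branch lengths; shape (len(ts), 2, 2)."""
        ts = np.asarray(ts, dtype=float)
        s = self.q01 + self.q10
        P = np.empty(ts.shape + (2, 2))
        if s == 0:
            P[...] = np.eye(2)
            return P
        e = np.exp(-s * ts)
        pi0, pi1 = self.q10 / s, self.q01 / s
        P[..., 0, 0] = pi0 + pi1 * e
        P[..., 0, 1] = pi1 * (1.0 - e)
        P[..., 1, 0] = pi0 * (1.0 - e)
        P[..., 1, 1] = pi1 + pi0 * e
        return P


@dataclass(frozen=True)
class RateMatrixK:
    """General k-state rate matrix: non-negative off-diagonals, zero row sums."""

    Q: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        Q = np.asarray(self.Q, dtype=float)
        object.__setattr__(self, "Q", Q)
        if Q.ndim != 2 or Q.shape[0] != Q.shape[1] or Q.shape[0] < 2:
            raise InvalidArgumentError("Q must be square with k >= 2")
        off = Q.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise InvalidArgumentError("off-diagonal rates must be non-negative")
        if np.any(np.abs(Q.sum(axis=1)) > 1e-8 * max(1.0, np.abs(off).max())):
            raise InvalidArgumentError("rows of Q must sum to zero")
        if self.labels is not None and len(self.labels) != Q.shape[0]:
            raise InvalidArgumentError("labels length must equal k")

    @property
    def k(self) -> int:
        return self.Q.shape[0]

    @classmethod
    def from_offdiagonal(cls, rates: np.ndarray, labels=None) -> "RateMatrixK":
        """Build from a k x k array whose off-diagonals are rates (diagonal ignored)."""
        Q = np.asarray(rates, dtype=float).copy()
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return cls(Q, labels)

    def stationary(self) -> np.ndarray:
        k = self.k
        A = np.vstack([self.Q.T, np.ones(k)])
        b = np.zeros(k + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        s = pi.sum()
        if s <= 0:
            return np.full(k, 1.0 / k)
        return pi / s

    def transition(self, t: float) -> np.ndarray:
        if t < 0:
            raise InvalidArgumentError("negative branch length")
        if t == 0:
            return np.eye(self.k)
        return expm(self.Q * t)

    def transition_stack(self, ts: np.ndarray) -> np.ndarray:
        ts = np.asarray(ts, dtype=float)
        return np.stack([self.transition(float(t)) for t in ts])


# ----------------------------------------------------------------- utilities
def _resolve_prior(root_prior, model) -> np.ndarray:
    if isinstance(root_prior, str):
        if root_prior == "stationary":
            return np.asarray(model.stationary(), dtype=float)
        if root_prior == "flat":
            return np.full(model.k, 1.0 / model.k)
        raise InvalidArgumentError(f"unknown root prior {root_prior!r}")
    prior = np.asarray(root_prior, dtype=float)
    if prior.shape != (model.k,) or np.any(prior < 0):
        raise InvalidArgumentError("root prior must be a length-k non-negative vector")
    s = prior.sum()
    if s <= 0:
        raise InvalidArgumentError("root prior must not be all zero")
    return prior / s


def _states_matrix(tree: Phylogeny, tip_states, k: int) -> tuple[np.ndarray, bool]:
    """Normalise tip states to an int array (n_chars, n_tips); -1 = missing.

    Returns (matrix, single) where `single` marks scalar-per-tip input.
    """
    tips = tree.tip_indices()
    tip_names = [tree.names[v] for v in tips]
    if isinstance(tip_states, pd.DataFrame):
        missing = [n for n in tip_names if n not in tip_states.index]
        if missing:
            raise KeyError(f"tips absent from state table: {missing[:5]}")
        arr = tip_states.loc[tip_names].to_numpy()
        arr = np.where(pd.isna(arr), -1, arr).astype(np.int64).T
        single = False
    elif isinstance(tip_states, Mapping):
        vals = []
        for n in tip_names:
            if n not in tip_states:
                raise KeyError(f"tip {n!r} has no state")
            v = tip_states[n]
            vals.append(-1 if v is None else int(v))
        arr = np.asarray(vals, dtype=np.int64)[None, :]
        single = True
    else:
        raise InvalidArgumentError("tip_states must be a mapping or DataFrame")
    if np.any(arr >= k) or np.any(arr < -1):
        raise InvalidArgumentError(f"tip states must lie in 0..{k - 1} (or -1 missing)")
    return arr, single


def _transition_cache(tree: Phylogeny, model) -> np.ndarray:
    """P(blen_v) for every node (root entry is identity)."""
    if np.any(tree.blen < 0):
        raise InvalidArgumentError("negative branch length")
    return model.transition_stack(tree.blen)


def _partials_up(tree, states, model, Pstack):
    """Scaled pruning pass.

    Returns (L, logscale, U): partials L (C, m, k), per-character log scaling,
    and per-node messages to the parent U[c, v, i] = sum_j P_v[i, j] L[c, v, j].
    """
    C, _ = states.shape
    m, k = len(tree), model.k
    L = np.zeros((C, m, k))
    U = np.zeros((C, m, k))
    logscale = np.zeros(C)
    tipset = {v for v in tree.tip_indices()}
    tip_pos = {v: i for i, v in enumerate(tree.tip_indices())}
    for v in tree.postorder():
        if v in tipset:
            s = states[:, tip_pos[v]]
            Lv = np.zeros((C, k))
            Lv[s < 0] = 1.0
            obs = s >= 0
            Lv[np.nonzero(obs)[0], s[obs]] = 1.0
            L[:, v, :] = Lv
        else:
            Lv = np.ones((C, k))
            for c in tree.children[v]:
                Lv = Lv * U[:, c, :]
            mx = Lv.max(axis=1)
            bad = mx <= 0
            if np.any(bad):
                # impossible data under the model; keep zeros, loglik -> -inf
                mx = np.where(bad, 1.0, mx)
            Lv = Lv / mx[:, None]
            logscale += np.where(bad, -np.inf, np.log(mx))
            L[:, v, :] = Lv
        if v != tree.root:
            U[:, v, :] = L[:, v, :] @ Pstack[v].T
    return L, logscale, U


# --------------------------------------------------------------- public API
def prune_loglik(tree: Phylogeny, tip_states, rate_model, root_prior="stationary"):
    """Felsenstein pruning log-likelihood.

    Returns a float for single-character input, else one value per character
    column.  Order of tip enumeration does not matter; missing states are
    integrated over.
    """
    prior = _resolve_prior(root_prior, rate_model)
    states, single = _states_matrix(tree, tip_states, rate_model.k)
    Pstack = _transition_cache(tree, rate_model)
    L, logscale, _ = _partials_up(tree, states, rate_model, Pstack)
    lik = L[:, tree.root, :] @ prior
    with np.errstate(divide="ignore"):
        ll = np.log(lik) + logscale
    return float(ll[0]) if single else ll


@dataclass
class FitResult:
    """Maximum-likelihood fit of an Mk model."""

    rates: BinaryRates | RateMatrixK
    loglik: float
    converged: bool
    boundary: bool = False
    identifiable: bool = True
    n_starts: int = 1
    message: str = ""


def _fit_binary(tree, states, root_prior, starts=None) -> FitResult:
    C = states.shape[0]
    observed = states[states >= 0]
    identifiable = len(np.unique(observed)) >= 2
    if not identifiable:
        # likelihood ridge: put the unobserved transition at the boundary
        warnings.warn("fewer than 2 distinct tip states; MLE lies on a boundary")
        if observed.size and observed[0] == 1:
            rates = BinaryRates(1.0, _RATE_FLOOR)
        elif observed.size:
            rates = BinaryRates(_RATE_FLOOR, 1.0)
        else:
            rates = BinaryRates(1.0, 1.0)
        frame = pd.DataFrame(states.T, index=tree.tip_names, columns=range(C))
        ll = float(np.sum(prune_loglik(tree, frame, rates, root_prior)))
        return FitResult(rates=rates, loglik=ll, converged=True, boundary=True,
                         identifiable=False, n_starts=0,
                         message="degenerate data; boundary MLE returned")

    def negll(x):
        rates = BinaryRates(math.exp(x[0]), math.exp(x[1]))
        ll = prune_loglik(tree, pd.DataFrame(states.T, index=tree.tip_names,
                                             columns=range(C)), rates, root_prior)
        return -float(np.sum(ll))

    lo, hi = math.log(_RATE_FLOOR), math.log(1e4)
    if starts is None:
        p1 = float(np.mean(observed == 1)) if observed.size else 0.5
        p1 = min(max(p1, 0.02), 0.98)
        starts = [(0.0, 0.0), (math.log(p1 / (1 - p1)), 0.0)]
    best = None
    for x0 in starts:
        res = minimize(negll, x0, method="L-BFGS-B", bounds=[(lo, hi)] * 2)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceFailure("binary rate optimisation failed")
    q01, q10 = math.exp(best.x[0]), math.exp(best.x[1])
    boundary = bool(min(best.x) <= lo + 1e-6)
    return FitResult(
        rates=BinaryRates(q01, q10),
        loglik=-float(best.fun),
        converged=bool(best.success),
        boundary=boundary,
        identifiable=identifiable,
        n_starts=len(starts),
        message=str(best.message),
    )


def _fit_kstate(tree, states, k, root_prior, seed, n_starts) -> FitResult:
    C = states.shape[0]
    off_idx = [(i, j) for i in range(k) for j in range(k) if i != j]
    n_par = len(off_idx)
    frame = pd.DataFrame(states.T, index=tree.tip_names, columns=range(C))

    def build(x):
        R = np.zeros((k, k))
        for p, (i, j) in enumerate(off_idx):
            R[i, j] = math.exp(x[p])
        return RateMatrixK.from_offdiagonal(R)

    def negll(x):
        try:
            model = build(x)
            ll = prune_loglik(tree, frame, model, root_prior)
        except (InvalidArgumentError, FloatingPointError):
            return 1e12
        val = -float(np.sum(ll))
        return val if np.isfinite(val) else 1e12

    rng = np.random.default_rng(seed)
    lo, hi = math.log(_RATE_FLOOR), math.log(1e4)
    uniform = math.log(1.0 / n_par)
    # counts heuristic: overall observed state turnover per unit tree length
    turnover = max(len(np.unique(states[states >= 0])) - 1, 1) / max(tree.total_length(), 1e-6)
    start_list = [np.full(n_par, uniform), np.full(n_par, math.log(max(turnover, 1e-6)))]
    while len(start_list) < n_starts:
        start_list.append(rng.normal(uniform, 1.0, size=n_par))
    best = None
    for x0 in start_list[:n_starts]:
        res = minimize(negll, x0, method="L-BFGS-B", bounds=[(lo, hi)] * n_par)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceFailure("k-state rate optimisation failed")
    return FitResult(
        rates=build(best.x),
        loglik=-float(best.fun),
        converged=bool(best.success),
        boundary=bool(np.min(best.x) <= lo + 1e-6),
        n_starts=n_starts,
        message=str(best.message),
    )


def fit_ml(tree: Phylogeny, tip_states, k: int = 2, root_prior="stationary",
           seed: int = 0, n_starts: int = 3) -> FitResult:
    """Maximise the pruning likelihood over non-negative rates (log-scale box).

    Binary characters use the two-rate gain/loss model; ``k > 2`` fits all
    k(k-1) off-diagonal rates with multi-start L-BFGS-B (uniform, turnover
    heuristic, random starts) because the likelihood surface is multimodal.
    """
    states, _ = _states_matrix(tree, tip_states, k)
    if k == 2:
        return _fit_binary(tree, states, root_prior)
    return _fit_kstate(tree, states, k, root_prior, seed, n_starts)


@dataclass
class PosteriorSampleSet:
    """Ordered MCMC samples of binary gain/loss rates."""

    samples: np.ndarray  # (n_samples, 2) columns q01, q10
    burn_in: int
    thin: int
    seed: int
    acceptance_rate: float
    initial: BinaryRates

    def __len__(self) -> int:
        return self.samples.shape[0]

    def __iter__(self):
        for q01, q10 in self.samples:
            yield BinaryRates(float(q01), float(q10))

    def median(self) -> BinaryRates:
        med = np.median(self.samples, axis=0)
        return BinaryRates(float(med[0]), float(med[1]))


def mcmc_sample(tree: Phylogeny, tip_states, n_samples: int = 500,
                burn_in: int = 500, thin: int = 10, seed: int = 0,
                root_prior="stationary", step: float = 0.5,
                prior_mean_factor: float = 2.0) -> PosteriorSampleSet:
    """Random-walk Metropolis over (log q01, log q10).

    The chain starts at the ML estimate; rates carry independent exponential
    priors with mean ``prior_mean_factor`` x the ML estimate (floored away
    from zero).  Exactly `n_samples` draws are returned after discarding
    `burn_in` iterations and thinning by `thin`.  Deterministic given `seed`.
    """
    if n_samples < 1 or burn_in < 0 or thin < 1:
        raise InvalidArgumentError("n_samples >= 1, burn_in >= 0, thin >= 1 required")
    states, single = _states_matrix(tree, tip_states, 2)
    frame = pd.DataFrame(states.T, index=tree.tip_names, columns=range(states.shape[0]))
    fit = fit_ml(tree, frame, k=2, root_prior=root_prior)
    init = fit.rates
    scale01 = max(prior_mean_factor * init.q01, 1e-6)
    scale10 = max(prior_mean_factor * init.q10, 1e-6)

    def logpost(x):
        q01, q10 = math.exp(x[0]), math.exp(x[1])
        ll = prune_loglik(tree, frame, BinaryRates(q01, q10), root_prior)
        ll = float(np.sum(ll))
        # exponential prior on rates + log-scale Jacobian
        return ll - q01 / scale01 - q10 / scale10 + x[0] + x[1]

    rng = np.random.default_rng(seed)
    x = np.array([math.log(max(init.q01, _RATE_FLOOR)), math.log(max(init.q10, _RATE_FLOOR))])
    lp = logpost(x)
    out = np.empty((n_samples, 2))
    accepted = 0
    total = burn_in + n_samples * thin
    got = 0
    for it in range(total):
        prop = x + rng.normal(0.0, step, size=2)
        lp_prop = logpost(prop)
        if math.log(rng.uniform()) < lp_prop - lp:
            x, lp = prop, lp_prop
            accepted += 1
        if it >= burn_in and (it - burn_in + 1) % thin == 0:
            out[got] = np.exp(x)
            got += 1
    if accepted == 0:
        raise SamplerFailure("no proposal accepted over the full run")
    return PosteriorSampleSet(out, burn_in, thin, seed, accepted / total, init)


def autocorrelation(samples, max_lag: int) -> np.ndarray:
    """Per-lag autocorrelation at lags 0..max_lag (lag 0 is exactly 1).

    Computed as the Pearson correlation between the chain and its lagged
    copy, so a perfectly alternating chain scores exactly -1 at lag 1.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < max_lag + 2:
        raise InvalidArgumentError("need at least max_lag + 2 samples")
    if np.std(x) == 0:
        raise InvalidArgumentError("constant chain has undefined autocorrelation")
    out = np.empty(max_lag + 1)
    out[0] = 1.0
    for lag in range(1, max_lag + 1):
        a, b = x[:-lag], x[lag:]
        if np.std(a) == 0 or np.std(b) == 0:
            raise InvalidArgumentError("constant sub-chain at requested lag")
        out[lag] = np.corrcoef(a, b)[0, 1]
    return np.clip(out, -1.0, 1.0)


@dataclass
class NodeStateAssignment:
    """Single most probable joint assignment of states to all nodes."""

    states: dict[str, int]
    log_prob: float
    tie: bool = False


def joint_reconstruct(tree: Phylogeny, tip_states: Mapping[str, int | None],
                      rate_model, root_prior="stationary") -> NodeStateAssignment:
    """Pupko-style maximum-probability joint reconstruction (single character).

    Ties are broken toward the lowest state index and flagged.
    """
    prior = _resolve_prior(root_prior, rate_model)
    states, single = _states_matrix(tree, tip_states, rate_model.k)
    if not single:
        raise InvalidArgumentError("joint_reconstruct takes one character at a time")
    s = states[0]
    Pstack = _transition_cache(tree, rate_model)
    m, k = len(tree), rate_model.k
    with np.errstate(divide="ignore"):
        logP = np.log(Pstack)
        logprior = np.log(prior)
    NEG = -np.inf
    tip_pos = {v: i for i, v in enumerate(tree.tip_indices())}
    # logS[v, j]: best log-prob of subtree below v given v in state j
    logS = np.zeros((m, k))
    # cost[v, i]: best contribution of branch+subtree of v given parent state i
    cost = np.zeros((m, k))
    ptr = np.zeros((m, k), dtype=np.int64)
    tie_any = False
    for v in tree.postorder():
        if tree.is_tip(v):
            sv = s[tip_pos[v]]
            base = np.zeros(k) if sv < 0 else np.where(np.arange(k) == sv, 0.0, NEG)
        else:
            base = np.zeros(k)
            for c in tree.children[v]:
                base = base + cost[c]
        logS[v] = base
        if v != tree.root:
            scores = logP[v] + base[None, :]  # (parent state, child state)
            ptr[v] = np.argmax(scores, axis=1)
            cost[v] = scores[np.arange(k), ptr[v]]
            finite = np.isfinite(cost[v])
            near = np.abs(scores - cost[v][:, None]) <= 1e-12
            if np.any(near.sum(axis=1)[finite] > 1):
                tie_any = True
    total = logprior + logS[tree.root]
    best_state = int(np.argmax(total))
    best = total[best_state]
    if np.sum(np.abs(total - best) <= 1e-12) > 1:
        tie_any = True
    assign = np.zeros(m, dtype=np.int64)
    assign[tree.root] = best_state
    for v in tree.preorder():
        if v == tree.root:
            continue
        assign[v] = ptr[v, assign[int(tree.parent[v])]]
    return NodeStateAssignment(
        states={tree.names[v]: int(assign[v]) for v in range(m)},
        log_prob=float(best),
        tie=tie_any,
    )


@dataclass
class MarginalPosteriors:
    """Per-node, per-character marginal posterior state probabilities."""

    node_names: list[str]
    probs: np.ndarray  # (n_nodes, n_chars, k)
    char_ids: list = field(default_factory=list)

    def at(self, node: str, char: int = 0) -> np.ndarray:
        return self.probs[self.node_names.index(node), char]


def marginal_reconstruct(tree: Phylogeny, tip_states, rate_model,
                         root_prior="stationary") -> MarginalPosteriors:
    """Marginal posterior of every node's state via up/down message passing."""
    prior = _resolve_prior(root_prior, rate_model)
    states, single = _states_matrix(tree, tip_states, rate_model.k)
    Pstack = _transition_cache(tree, rate_model)
    L, logscale, U = _partials_up(tree, states, rate_model, Pstack)
    C, m, k = L.shape[0], len(tree), rate_model.k
    D = np.zeros((C, m, k))
    D[:, tree.root, :] = prior
    post = np.zeros((C, m, k))
    for v in tree.preorder():
        if v == tree.root:
            numer = D[:, v, :] * L[:, v, :]
        else:
            numer = D[:, v, :] * L[:, v, :]
        z = numer.sum(axis=1, keepdims=True)
        z = np.where(z <= 0, 1.0, z)
        post[:, v, :] = numer / z
        for c in tree.children[v]:
            sib = np.ones((C, k))
            for c2 in tree.children[v]:
                if c2 != c:
                    sib = sib * U[:, c2, :]
            msg = (D[:, v, :] * sib) @ Pstack[c]
            zz = msg.max(axis=1, keepdims=True)
            zz = np.where(zz <= 0, 1.0, zz)
            D[:, c, :] = msg / zz
    probs = np.transpose(post, (1, 0, 2))  # (m, C, k)
    char_ids = list(tip_states.columns) if isinstance(tip_states, pd.DataFrame) else [0]
    return MarginalPosteriors(list(tree.names), probs, char_ids)
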
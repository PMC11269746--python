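"""Independent brute-force oracles for likelihood and reconstruction tests.

These enumerate internal-node state combinations directly from transition
matrices and never call the package's pruning/DP code paths, so they serve
as exhaustive references on small trees.
"""

import itertools
import math

import numpy as np

from convloss.mk import BinaryRates
from convloss.trees import Phylogeny
from convloss.synthetic import simulate_tree


def random_binary_instance(seed):
    """Random 4-6 tip tree with random branch lengths, rates and tip states."""
    r = np.random.default_rng(seed)
    n = int(r.integers(4, 7))
    t = simulate_tree(n, seed)
    blen = t.blen.copy()
    blen[1:] = r.uniform(0.05, 1.0, size=len(blen) - 1)
    tree = Phylogeny(t.names, t.parent, blen)
    rates = BinaryRates(float(r.uniform(0.1, 2.0)), float(r.uniform(0.1, 2.0)))
    states = {name: int(r.integers(0, 2)) for name in tree.tip_names}
    return tree, rates, states


def enumerate_binary(tree, rates, states, prior):
    """(log marginal likelihood, max joint log-prob, per-node marginals)."""
    internals = [v for v in range(len(tree)) if not tree.is_tip(v)]
    P = {v: rates.transition(float(tree.blen[v])) for v in range(len(tree))}
    total = 0.0
    best = -np.inf
    marg = np.zeros((len(tree), 2))
    for combo in itertools.product([0, 1], repeat=len(internals)):
        s = dict(zip(internals, combo))
        for v in tree.tip_indices():
            s[v] = states[tree.names[v]]
        p = prior[s[tree.root]]
        for v in range(len(tree)):
            if v == tree.root:
                continue
            p *= P[v][s[int(tree.parent[v])], s[v]]
        total += p
        if p > 0:
            best = max(best, math.log(p))
        for v in range(len(tree)):
            marg[v, s[v]] += p
    return math.log(total), best, marg / total


def enumerate_aa_marginal_4tip(tree, msa, model, alphabet):
    """Marginal aa posteriors by vectorised enumeration on the fixed
    4-tip topology ((a,b)i1,(c,d)i2)root; internal nodes only."""
    P = {v: model.transition(float(tree.blen[v])) for v in range(len(tree))}
    prior = model.stationary()
    names = tree.names
    root = tree.root
    internals = [v for v in range(len(tree)) if not tree.is_tip(v)]
    i1, i2 = [v for v in internals if v != root]
    k = len(alphabet)
    aaidx = {a: i for i, a in enumerate(alphabet)}
    combos = np.stack(np.meshgrid(*[np.arange(k)] * 3, indexing="ij"), -1).reshape(-1, 3)
    width = len(next(iter(msa.values())))
    out = {}
    for v in internals:
        out[names[v]] = np.zeros((width, k))
    for site in range(width):
        p = prior[combos[:, 0]].copy()
        for col, v in ((1, i1), (2, i2)):
            p = p * P[v][combos[:, 0], combos[:, col]]
        for v in tree.tip_indices():
            ch = msa[names[v]][site]
            if ch in aaidx:
                parent = int(tree.parent[v])
                pcol = 0 if parent == root else (1 if parent == i1 else 2)
                p = p * P[v][combos[:, pcol], aaidx[ch]]
        tot = p.sum()
        for col, v in ((0, root), (1, i1), (2, i2)):
            for s in range(k):
                out[names[v]][site, s] = p[combos[:, col] == s].sum() / tot
    return out
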
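"""Statistical tests used downstream: chi-square, Mann-Whitney U, and a
phylogenetic ANOVA whose null F distribution comes from Brownian-motion
simulation on the tree."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InvalidArgumentError
from .trees import Phylogeny

__all__ = [
    "chi_square",
    "mann_whitney",
    "brownian_simulate",
    "pic_sigma2",
    "phylogenetic_anova",
    "PhyloAnovaResult",
]


def chi_square(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a contingency table (no Yates correction by
    default); p from the chi-square distribution with (r-1)(c-1) df."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0):
        raise InvalidArgumentError("table must be a 2-D non-negative array")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise InvalidArgumentError("zero marginal total")
    stat, p, _, _ = sps.chi2_contingency(t, correction=correction)
    return float(stat), float(p)


def mann_whitney(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U.

    Exact enumeration p for small samples without ties (n + m <= 12); normal
    approximation with tie correction (and continuity correction) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise InvalidArgumentError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def brownian_simulate(tree: Phylogeny, sigma2: float, seed: int = 0,
                      n_traits: int = 1) -> np.ndarray:
    """Brownian-motion tip values: root 0, independent normal increments with
    variance sigma2 x branch length.  Shape (n_tips,) or (n_tips, n_traits)."""
    if sigma2 < 0:
        raise InvalidArgumentError("sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    m = len(tree)
    vals = np.zeros((m, n_traits))
    sd = np.sqrt(sigma2 * np.clip(tree.blen, 0.0, None))
    for v in tree.preorder():
        p = int(tree.parent[v])
        if p >= 0:
            vals[v] = vals[p] + rng.normal(0.0, 1.0, size=n_traits) * sd[v]
    tips = tree.tip_indices()
    out = vals[tips]
    return out[:, 0] if n_traits == 1 else out


def pic_sigma2(tree: Phylogeny, trait: dict[str, float]) -> float:
    """Brownian rate estimate from phylogenetically independent contrasts.

    Standard Felsenstein pruning on a (multifurcations resolved pairwise)
    tree: sigma2 = mean squared standardised contrast.
    """
    value: dict[int, float] = {}
    length: dict[int, float] = {}
    contrasts: list[float] = []
    for v in tree.postorder():
        if tree.is_tip(v):
            name = tree.names[v]
            if name not in trait:
                raise KeyError(f"tip {name!r} has no trait value")
            value[v] = float(trait[name])
            length[v] = float(tree.blen[v])
        else:
            kids = list(tree.children[v])
            # resolve >2 children by sequential pairing
            while len(kids) > 1:
                a, b = kids.pop(), kids.pop()
                va, vb = length[a], length[b]
                denom = va + vb
                if denom <= 0:
                    denom = 1e-12
                contrasts.append((value[a] - value[b]) / np.sqrt(denom))
                merged = -len(contrasts)  # synthetic key
                value[merged] = (vb * value[a] + va * value[b]) / denom
                length[merged] = va * vb / denom
                kids.append(merged)
            u = kids[0]
            value[v] = value[u]
            length[v] = float(tree.blen[v]) + (length[u] if u < 0 else 0.0)
            if u >= 0:  # single child chain: just extend the branch
                length[v] = float(tree.blen[v]) + length[u]
    if not contrasts:
        raise InvalidArgumentError("need at least one contrast (>= 2 tips)")
    c = np.asarray(contrasts)
    return float(np.mean(c**2))


def _f_statistic(values: np.ndarray, group_idx: np.ndarray, n_groups: int) -> np.ndarray:
    """One-way ANOVA F, vectorised over trait columns.  values: (n, T)."""
    n, T = values.shape
    grand = values.mean(axis=0)
    ssb = np.zeros(T)
    ssw = np.zeros(T)
    for g in range(n_groups):
        sel = values[group_idx == g]
        ng = sel.shape[0]
        mg = sel.mean(axis=0)
        ssb += ng * (mg - grand) ** 2
        ssw += ((sel - mg) ** 2).sum(axis=0)
    df1 = n_groups - 1
    df2 = n - n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        return (ssb / df1) / (ssw / df2)


@dataclass
class PhyloAnovaResult:
    """Observed F versus a Brownian-motion simulation null."""

    f_obs: float
    n_sim: int
    null_f: np.ndarray
    p: float
    sigma2: float


def phylogenetic_anova(tree: Phylogeny, groups: dict[str, str],
                       trait: dict[str, float], n_sim: int = 1000,
                       seed: int = 0) -> PhyloAnovaResult:
    """Simulation-null phylogenetic ANOVA.

    The observed one-way ANOVA F is compared with F values computed from
    `n_sim` Brownian-motion trait simulations on the tree (group labels
    fixed, Brownian rate estimated from the data by independent contrasts);
    p is the fraction of null F >= observed F.
    """
    tips = tree.tip_names
    missing = [t for t in tips if t not in groups or t not in trait]
    if missing:
        raise InvalidArgumentError(f"tips without group/trait: {missing[:5]}")
    labels = sorted(set(groups[t] for t in tips))
    if len(labels) < 2:
        raise InvalidArgumentError("need at least 2 groups")
    gidx = np.array([labels.index(groups[t]) for t in tips])
    values = np.array([[trait[t]] for t in tips])
    f_obs = float(_f_statistic(values, gidx, len(labels))[0])
    sigma2 = pic_sigma2(tree, trait)
    sims = brownian_simulate(tree, sigma2, seed=seed, n_traits=n_sim)
    null_f = _f_statistic(sims, gidx, len(labels))
    p = float(np.mean(null_f >= f_obs))
    return PhyloAnovaResult(f_obs, n_sim, null_f, p, sigma2)
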
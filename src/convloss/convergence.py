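"""Convergent gene-loss analysis from replicated ancestral reconstructions.

Given per-replicate presence/absence reconstructions of ortholog groups
(OGs) at ancestral nodes, this module classifies per-OG scenarios at three
focal ancestors (the common ancestor of two convergent clades and each
clade's own ancestor), assigns the best-supported loss branch along each
root-to-clade path, and tests whether the two lineages lost genes in a
significantly similar order via the concordant-pair statistic S with a
label-shuffling permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, InvalidArgumentError, NoSingleLossError
from . import stats as _stats

__all__ = [
    "FocalNodes",
    "classify_scenarios",
    "select_commonly_lost",
    "assign_loss_branch",
    "assign_loss_branches",
    "loss_order_similarity",
    "permutation_pvalue",
    "PermutationResult",
    "overlap_contingency",
    "branch_jaccard",
    "JaccardResult",
    "category_loss_timing",
]

TRIPLETS = [(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)]


@dataclass(frozen=True)
class FocalNodes:
    """The three focal ancestors: shared LCA and each convergent clade's LCA."""

    lca_fa: str
    lca_a: str
    lca_f: str


def classify_scenarios(
    replicate_states: Mapping[str, Sequence[Mapping[str, int]]],
    focal_nodes: FocalNodes,
) -> pd.DataFrame:
    """Per-OG support for the 8 presence triplets at the focal ancestors.

    Each replicate contributes one (LCAfa, LCAa, LCAf) presence triplet; the
    table reports the fraction of replicates per triplet, the majority
    scenario (ties broken toward more presences, i.e. fewer inferred losses,
    and flagged), and its support.
    """
    rows = {}
    keys = ["".join(map(str, t)) for t in TRIPLETS]
    for og, replicates in replicate_states.items():
        counts = dict.fromkeys(keys, 0)
        for rep in replicates:
            try:
                trip = (
                    int(rep[focal_nodes.lca_fa]),
                    int(rep[focal_nodes.lca_a]),
                    int(rep[focal_nodes.lca_f]),
                )
            except KeyError as exc:
                raise DataError(f"replicate for {og!r} misses focal node {exc}") from exc
            counts["".join(map(str, trip))] += 1
        n = len(replicates)
        if n == 0:
            raise DataError(f"no replicates for {og!r}")
        fracs = {k: counts[k] / n for k in keys}
        top = max(fracs.values())
        winners = [k for k in keys if fracs[k] == top]
        # more presences first, then lexicographically larger pattern
        winners.sort(key=lambda k: (k.count("1"), k), reverse=True)
        best = winners[0]
        rows[og] = {**fracs, "majority": tuple(int(c) for c in best),
                    "support": top, "tie": len(winners) > 1}
    table = pd.DataFrame.from_dict(rows, orient="index")
    return table


def select_commonly_lost(majority_table: pd.DataFrame, category_map=None):
    """OGs whose majority scenario is (1, 0, 0): present in the shared
    ancestor, independently absent in both convergent clades' ancestors.

    With a category map (OG -> category), returns ``{category: set}``.
    """
    mask = majority_table["majority"].apply(lambda t: tuple(t) == (1, 0, 0))
    ogs = set(majority_table.index[mask])
    if category_map is None:
        return ogs
    out: dict[str, set] = {}
    for og in ogs:
        cat = category_map.get(og, "unmapped")
        out.setdefault(cat, set()).add(og)
    return out


def _scan_single_loss(seq: Sequence[int]) -> int | None:
    """1-based branch of the single 1->0 transition, or None if not exactly one
    loss (or any gain) along the node-state sequence."""
    loss_at = None
    for i in range(1, len(seq)):
        a, b = seq[i - 1], seq[i]
        if a == 0 and b == 1:
            return None
        if a == 1 and b == 0:
            if loss_at is not None:
                return None
            loss_at = i
    return loss_at


def assign_loss_branch(
    replicates: Sequence[Mapping[str, int]],
    path: Sequence[tuple[str, str]],
) -> tuple[int, float, bool, int]:
    """Plurality loss branch (1-based) along a path for one OG.

    Only replicates whose node-state sequence along the path shows exactly
    one 1->0 transition and no 0->1 qualify to vote.  Returns
    (branch, support, tie_flag, n_qualifying); raises
    :class:`NoSingleLossError` when no replicate qualifies.
    """
    if not path:
        raise InvalidArgumentError("empty path")
    nodes = [path[0][0]] + [c for _, c in path]
    votes: dict[int, int] = {}
    qualifying = 0
    for rep in replicates:
        try:
            seq = [int(rep[n]) for n in nodes]
        except KeyError as exc:
            raise DataError(f"replicate misses path node {exc}") from exc
        branch = _scan_single_loss(seq)
        if branch is None:
            continue
        qualifying += 1
        votes[branch] = votes.get(branch, 0) + 1
    if qualifying == 0:
        raise NoSingleLossError("no replicate shows a single-loss scenario on this path")
    top = max(votes.values())
    winners = sorted(b for b, v in votes.items() if v == top)
    return winners[0], top / qualifying, len(winners) > 1, qualifying


def assign_loss_branches(
    replicate_states: Mapping[str, Sequence[Mapping[str, int]]],
    path: Sequence[tuple[str, str]],
    ogs: Sequence[str] | None = None,
) -> tuple[dict[str, tuple[int, float]], list[str]]:
    """Vectorised convenience wrapper; returns (assignments, excluded OGs)."""
    out: dict[str, tuple[int, float]] = {}
    excluded: list[str] = []
    for og in ogs if ogs is not None else replicate_states:
        try:
            branch, support, _, _ = assign_loss_branch(replicate_states[og], path)
            out[og] = (branch, support)
        except NoSingleLossError:
            excluded.append(og)
    return out, excluded


def _ranks(assign: Mapping[str, int | tuple], ogs: Sequence[str]) -> np.ndarray:
    vals = []
    for og in ogs:
        v = assign[og]
        vals.append(v[0] if isinstance(v, tuple) else v)
    return np.asarray(vals, dtype=np.int64)


def _concordant_count(ra: np.ndarray, rf: np.ndarray, ties: str):
    sa = np.sign(ra[:, None] - ra[None, :])
    sf = np.sign(rf[:, None] - rf[None, :])
    iu = np.triu_indices(len(ra), k=1)
    da, df = sa[iu], sf[iu]
    if ties == "concordant":
        return int(np.sum(da == df)), da.size
    if ties == "exclude":
        keep = (da != 0) & (df != 0)
        return int(np.sum((da == df) & keep)), int(np.sum(keep))
    raise InvalidArgumentError("ties must be 'concordant' or 'exclude'")


def loss_order_similarity(
    rank_a: Mapping[str, int | tuple],
    rank_f: Mapping[str, int | tuple],
    ties: str = "concordant",
) -> float:
    """Fraction of OG pairs lost in the same relative order in both lineages.

    A pair is concordant when sign(rank_a(x) - rank_a(y)) equals
    sign(rank_f(x) - rank_f(y)); with ``ties='concordant'`` same-branch pairs
    (sign 0) count as an order statement, with ``ties='exclude'`` any pair
    tied in either lineage is dropped from the denominator.
    """
    ogs = sorted(rank_a)
    if set(rank_a) != set(rank_f):
        raise InvalidArgumentError("rankings must cover the same OG set")
    if len(ogs) < 2:
        raise InvalidArgumentError("need at least 2 OGs")
    conc, tot = _concordant_count(_ranks(rank_a, ogs), _ranks(rank_f, ogs), ties)
    if tot == 0:
        raise InvalidArgumentError("no untied pairs to compare")
    return conc / tot


@dataclass
class PermutationResult:
    """Observed loss-order similarity and its shuffle-null p value."""

    s_obs: float
    p: float
    p_smoothed: float  # (count + 1) / (n_perm + 1)
    n_perm: int
    null: np.ndarray | None = None


def permutation_pvalue(
    assign_a: Mapping[str, int | tuple],
    assign_f: Mapping[str, int | tuple],
    n_perm: int = 10_000,
    seed: int = 0,
    ties: str = "concordant",
    keep_null: bool = False,
) -> PermutationResult:
    """Permutation test of loss-order similarity.

    Each permutation independently shuffles the OG -> loss-branch
    correspondence within each lineage (preserving both lineages' multisets
    of branch labels, hence their tie structure); p is the plain fraction of
    shuffled S' >= observed S.  Deterministic given `seed`.
    """
    if n_perm < 1:
        raise InvalidArgumentError("n_perm must be >= 1")
    ogs = sorted(assign_a)
    if set(assign_a) != set(assign_f):
        raise InvalidArgumentError("assignments must cover the same OG set")
    n = len(ogs)
    if n < 2:
        raise InvalidArgumentError("need at least 2 OGs")
    ra, rf = _ranks(assign_a, ogs), _ranks(assign_f, ogs)
    sa = np.sign(ra[:, None] - ra[None, :]).astype(np.int8)
    sf = np.sign(rf[:, None] - rf[None, :]).astype(np.int8)
    iu = np.triu_indices(n, k=1)
    obs_conc, obs_tot = _concordant_count(ra, rf, ties)
    s_obs = obs_conc / obs_tot
    rng = np.random.default_rng(seed)
    perm_a = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    perm_f = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    pa = sa[perm_a[:, :, None], perm_a[:, None, :]][:, iu[0], iu[1]]
    pf = sf[perm_f[:, :, None], perm_f[:, None, :]][:, iu[0], iu[1]]
    if ties == "concordant":
        null_s = (pa == pf).sum(axis=1) / obs_tot
        count = int(np.sum((pa == pf).sum(axis=1) >= obs_conc))
    else:
        keep = (pa != 0) & (pf != 0)
        tot = keep.sum(axis=1)
        conc = ((pa == pf) & keep).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            null_s = np.where(tot > 0, conc / np.maximum(tot, 1), np.nan)
        count = int(np.nansum(null_s >= s_obs - 1e-12))
    p = count / n_perm
    return PermutationResult(
        s_obs=float(s_obs),
        p=float(p),
        p_smoothed=float((count + 1) / (n_perm + 1)),
        n_perm=n_perm,
        null=null_s if keep_null else None,
    )


def overlap_contingency(lost_a: set, lost_f: set, universe: set):
    """2x2 contingency of loss membership in the two lineages + chi-square p.

    Cells: [[both, A only], [F only, neither]].
    """
    if not universe:
        raise InvalidArgumentError("empty universe")
    if not (lost_a <= universe and lost_f <= universe):
        raise InvalidArgumentError("lost sets must be subsets of the universe")
    both = len(lost_a & lost_f)
    a_only = len(lost_a - lost_f)
    f_only = len(lost_f - lost_a)
    neither = len(universe) - both - a_only - f_only
    table = np.array([[both, a_only], [f_only, neither]])
    stat, p = _stats.chi_square(table)
    return table, stat, p


@dataclass
class JaccardResult:
    """Branch x branch overlap of lost-OG sets between the two paths."""

    matrix: pd.DataFrame
    empty_union: pd.DataFrame  # True where both branch loss sets were empty


def branch_jaccard(
    assign_a: Mapping[str, tuple[int, float] | int],
    assign_f: Mapping[str, tuple[int, float] | int],
    n_branches_a: int | None = None,
    n_branches_f: int | None = None,
) -> JaccardResult:
    """Jaccard index of OGs lost at each (path-A branch, path-F branch) pair."""

    def by_branch(assign, n):
        branches: dict[int, set] = {}
        for og, v in assign.items():
            b = v[0] if isinstance(v, tuple) else int(v)
            branches.setdefault(b, set()).add(og)
        top = n if n is not None else (max(branches) if branches else 1)
        return {i: branches.get(i, set()) for i in range(1, top + 1)}

    sets_a = by_branch(assign_a, n_branches_a)
    sets_f = by_branch(assign_f, n_branches_f)
    mat = pd.DataFrame(0.0, index=list(sets_a), columns=list(sets_f))
    empty = pd.DataFrame(False, index=list(sets_a), columns=list(sets_f))
    for i, sa_ in sets_a.items():
        for j, sf_ in sets_f.items():
            union = sa_ | sf_
            if not union:
                empty.loc[i, j] = True
                mat.loc[i, j] = 0.0
            else:
                mat.loc[i, j] = len(sa_ & sf_) / len(union)
    return JaccardResult(mat, empty)


def category_loss_timing(
    assign_a: Mapping[str, tuple[int, float] | int],
    assign_f: Mapping[str, tuple[int, float] | int],
    category_map: Mapping[str, str | Sequence[str]],
) -> pd.DataFrame:
    """Mean loss timing (1-based branch index) per functional category.

    Categories are ranked by mean timing within each lineage (average ranks
    on ties); the absolute rank difference highlights categories whose loss
    timing diverges between lineages.  Categories with no member OG in a
    lineage are dropped with a warning.
    """
    from scipy.stats import rankdata

    def timing(assign):
        per_cat: dict[str, list[int]] = {}
        for og, v in assign.items():
            b = v[0] if isinstance(v, tuple) else int(v)
            cats = category_map.get(og)
            if cats is None:
                continue
            if isinstance(cats, str):
                cats = [cats]
            for c in cats:
                per_cat.setdefault(c, []).append(b)
        return {c: float(np.mean(v)) for c, v in per_cat.items()}

    ta, tf = timing(assign_a), timing(assign_f)
    cats = sorted(set(ta) | set(tf))
    keep = [c for c in cats if c in ta and c in tf]
    dropped = [c for c in cats if c not in keep]
    if dropped:
        warnings.warn(f"categories without members in one lineage dropped: {dropped}")
    mean_a = np.array([ta[c] for c in keep])
    mean_f = np.array([tf[c] for c in keep])
    rank_a = rankdata(mean_a)
    rank_f = rankdata(mean_f)
    return pd.DataFrame(
        {
            "mean_timing_a": mean_a,
            "mean_timing_f": mean_f,
            "rank_a": rank_a,
            "rank_f": rank_f,
            "rank_diff": np.abs(rank_a - rank_f),
        },
        index=keep,
    )
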
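"""Amino-acid ancestral reconstruction and fragment-specific substitution mapping.

On a fixed gene tree, reconstructs marginal per-site amino-acid posteriors,
calls ancestral residues above a posterior threshold, maps substitutions to
branches, and measures which alignment sites accumulate substitutions
specifically on branches leading to single-domain fragment genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .mk import MarginalPosteriors, marginal_reconstruct
from . import stats as _stats
from .trees import Phylogeny

__all__ = [
    "AA_ALPHABET",
    "UNCERTAIN",
    "PoissonAAModel",
    "AncestralCalls",
    "SubstitutionEvent",
    "SiteEnrichment",
    "marginal_asr_aa",
    "call_states",
    "map_substitutions",
    "fragment_branch_set",
    "site_fragment_ratio",
    "top_sites",
    "group_enrichment",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
UNCERTAIN = "?"
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}


@dataclass(frozen=True)
class PoissonAAModel:
    """Equal-exchangeability (F81-style) amino-acid model.

    All exchangeabilities are equal; stationary frequencies are free.  The
    transition matrix has the closed form
    ``P_ij(t) = pi_j + exp(-mu t) (delta_ij - pi_j)`` with mu scaled so one
    unit of branch length equals one expected substitution per site.
    """

    freqs: np.ndarray = field(default_factory=lambda: np.full(20, 0.05))

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (20,) or np.any(f < 0):
            raise InvalidArgumentError("freqs must be 20 non-negative values")
        s = f.sum()
        if s <= 0:
            raise InvalidArgumentError("freqs must not be all zero")
        object.__setattr__(self, "freqs", f / s)

    @classmethod
    def from_msa(cls, msa: Mapping[str, str], pseudocount: float = 1.0) -> "PoissonAAModel":
        counts = np.full(20, pseudocount)
        for seq in msa.values():
            for ch in seq:
                i = _AA_INDEX.get(ch)
                if i is not None:
                    counts[i] += 1
        return cls(counts)

    @property
    def k(self) -> int:
        return 20

    @property
    def mu(self) -> float:
        return 1.0 / (1.0 - float(np.sum(self.freqs**2)))

    def stationary(self) -> np.ndarray:
        return self.freqs

    def transition(self, t: float) -> np.ndarray:
        if t < 0:
            raise InvalidArgumentError("negative branch length")
        e = np.exp(-self.mu * t)
        P = (1.0 - e) * np.tile(self.freqs, (20, 1))
        P[np.diag_indices(20)] += e
        return P

    def transition_stack(self, ts: np.ndarray) -> np.ndarray:
        ts = np.asarray(ts, dtype=float)
        e = np.exp(-self.mu * ts)[:, None, None]
        base = np.tile(self.freqs, (20, 1))
        P = (1.0 - e) * base[None, :, :]
        idx = np.arange(20)
        P[:, idx, idx] += e[:, 0, 0][:, None]
        return P


def _msa_to_frame(tree: Phylogeny, msa: Mapping[str, str]) -> pd.DataFrame:
    tips = tree.tip_names
    missing = [t for t in tips if t not in msa]
    if missing:
        raise KeyError(f"tree tips absent from alignment: {missing[:5]}")
    width = len(next(iter(msa.values())))
    if any(len(msa[t]) != width for t in tips):
        raise InvalidArgumentError("alignment rows have unequal width")
    data = np.full((len(tips), width), -1, dtype=np.int64)
    for r, t in enumerate(tips):
        for c, ch in enumerate(msa[t]):
            data[r, c] = _AA_INDEX.get(ch, -1)  # gaps/X -> missing
    return pd.DataFrame(data, index=tips, columns=range(1, width + 1))


def marginal_asr_aa(
    tree: Phylogeny,
    msa: Mapping[str, str],
    model: PoissonAAModel | None = None,
    root_prior="stationary",
) -> MarginalPosteriors:
    """Per-node, per-site marginal amino-acid posteriors on a fixed tree.

    Gaps and unknown characters are treated as missing data.  The default
    model is equal-exchangeability with frequencies estimated from the
    alignment.
    """
    if model is None:
        model = PoissonAAModel.from_msa(msa)
    frame = _msa_to_frame(tree, msa)
    return marginal_reconstruct(tree, frame, model, root_prior)


@dataclass
class AncestralCalls:
    """Called ancestral residues: one character per (node, site), ``?`` when
    no residue clears the posterior threshold."""

    node_names: list[str]
    calls: np.ndarray  # (n_nodes, n_sites) unicode characters
    threshold: float

    def sequence(self, node: str) -> str:
        return "".join(self.calls[self.node_names.index(node)])

    def get(self, node: str, site: int) -> str:
        """Residue at a 1-based site, or the uncertain marker."""
        return str(self.calls[self.node_names.index(node), site - 1])

    @property
    def n_called(self) -> int:
        return int(np.sum(self.calls != UNCERTAIN))


def call_states(posteriors: MarginalPosteriors, threshold: float = 0.5) -> AncestralCalls:
    """Adopt the modal residue where its posterior strictly exceeds the
    threshold; otherwise mark the site uncertain."""
    probs = posteriors.probs  # (n_nodes, n_sites, 20)
    best = probs.argmax(axis=2)
    best_p = probs.max(axis=2)
    letters = np.array(list(AA_ALPHABET))
    calls = letters[best]
    calls[best_p <= threshold] = UNCERTAIN
    return AncestralCalls(list(posteriors.node_names), calls, threshold)


@dataclass(frozen=True)
class SubstitutionEvent:
    """One branch-site substitution between called/observed residues."""

    parent: str
    child: str
    site: int  # 1-based MSA column
    from_aa: str
    to_aa: str


def map_substitutions(
    tree: Phylogeny,
    calls: AncestralCalls,
    tip_sequences: Mapping[str, str],
) -> tuple[list[SubstitutionEvent], dict[str, int]]:
    """Substitution events per branch and site.

    Tips contribute their observed residues, internal nodes their called
    residues.  A branch-site with an uncertain (or gapped) endpoint emits no
    event and is tallied in the diagnostics (`skipped_uncertain`,
    `skipped_gap`).  Multiple hits on one branch-site count once.
    """
    name_to_row = {n: i for i, n in enumerate(calls.node_names)}
    n_sites = calls.calls.shape[1]

    def residues(name: str) -> np.ndarray:
        v = tree.index(name)
        if tree.is_tip(v):
            seq = tip_sequences[name]
            if len(seq) != n_sites:
                raise InvalidArgumentError(f"tip {name!r} length != alignment width")
            return np.array(list(seq))
        return calls.calls[name_to_row[name]]

    events: list[SubstitutionEvent] = []
    skipped_uncertain = 0
    skipped_gap = 0
    cache: dict[str, np.ndarray] = {}
    for v in tree.preorder():
        if v == tree.root:
            continue
        child = tree.names[v]
        parent = tree.names[int(tree.parent[v])]
        for name in (parent, child):
            if name not in cache:
                cache[name] = residues(name)
        rp, rc = cache[parent], cache[child]
        valid_p = np.isin(rp, list(AA_ALPHABET))
        valid_c = np.isin(rc, list(AA_ALPHABET))
        skipped_uncertain += int(np.sum((rp == UNCERTAIN) | (rc == UNCERTAIN)))
        skipped_gap += int(np.sum((~valid_p & (rp != UNCERTAIN)) | (~valid_c & (rc != UNCERTAIN))))
        diff = valid_p & valid_c & (rp != rc)
        for site in np.nonzero(diff)[0]:
            events.append(
                SubstitutionEvent(parent, child, int(site) + 1, str(rp[site]), str(rc[site]))
            )
    return events, {"skipped_uncertain": skipped_uncertain, "skipped_gap": skipped_gap}


def fragment_branch_set(tree: Phylogeny, fragment_tips: set[str]) -> set[tuple[str, str]]:
    """Branches whose descendant tips are all fragment tips (stems included)."""
    out = set()
    for v in tree.preorder():
        if v == tree.root:
            continue
        below = tree.subtree_tips(tree.names[v])
        if below and below <= fragment_tips:
            out.add((tree.names[int(tree.parent[v])], tree.names[v]))
    return out


@dataclass(frozen=True)
class SiteEnrichment:
    """Substitution counts at one site, split by fragment-branch membership."""

    site: int
    total: int
    fragment: int

    @property
    def ratio(self) -> float:
        return self.fragment / self.total


def site_fragment_ratio(
    events: Sequence[SubstitutionEvent],
    fragment_branches: set[tuple[str, str]],
    min_events: int = 5,
) -> list[SiteEnrichment]:
    """Per-site fragment-branch substitution ratio, for sites with at least
    `min_events` substitutions in total."""
    total: dict[int, int] = {}
    frag: dict[int, int] = {}
    for ev in events:
        total[ev.site] = total.get(ev.site, 0) + 1
        if (ev.parent, ev.child) in fragment_branches:
            frag[ev.site] = frag.get(ev.site, 0) + 1
    return [
        SiteEnrichment(site, n, frag.get(site, 0))
        for site, n in sorted(total.items())
        if n >= min_events
    ]


def top_sites(enrichments: Sequence[SiteEnrichment], k: int = 15) -> list[int]:
    """Sites ranked by fragment ratio (ties: higher fragment count, then
    lower site index); at most `k` returned."""
    if not enrichments:
        raise InvalidArgumentError("no enrichment records")
    ordered = sorted(enrichments, key=lambda e: (-e.ratio, -e.fragment, e.site))
    return [e.site for e in ordered[:k]]


def group_enrichment(
    enrichments: Sequence[SiteEnrichment],
    site_groups: Mapping[int, str],
) -> pd.DataFrame:
    """Pairwise Mann-Whitney comparisons of fragment ratios and fragment
    substitution counts between site groups (e.g. interface / NAD-binding /
    other).  Groups with fewer than 2 sites are skipped with a warning."""
    groups: dict[str, list[SiteEnrichment]] = {}
    for e in enrichments:
        g = site_groups.get(e.site, "other")
        groups.setdefault(g, []).append(e)
    usable = {}
    for g, members in groups.items():
        if len(members) < 2:
            warnings.warn(f"group {g!r} has < 2 sites; skipped")
        else:
            usable[g] = members
    rows = []
    names = sorted(usable)
    for i, g1 in enumerate(names):
        for g2 in names[i + 1:]:
            r1 = [e.ratio for e in usable[g1]]
            r2 = [e.ratio for e in usable[g2]]
            c1 = [e.fragment for e in usable[g1]]
            c2 = [e.fragment for e in usable[g2]]
            _, p_ratio = _stats.mann_whitney(r1, r2, alternative="two-sided")
            _, p_count = _stats.mann_whitney(c1, c2, alternative="two-sided")
            rows.append(
                {
                    "group1": g1,
                    "group2": g2,
                    "n1": len(r1),
                    "n2": len(r2),
                    "median_ratio1": float(np.median(r1)),
                    "median_ratio2": float(np.median(r2)),
                    "p_ratio": p_ratio,
                    "p_count": p_count,
                }
            )
    return pd.DataFrame(rows)
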
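"""Synthetic inputs with known ground truth for every pipeline stage.

Generates ultrametric species trees (random Yule and a deterministic
two-clade scaffold with designated convergent lineages), binary ortholog
presence/absence histories, planted ordered convergent losses, k-state
repertoire histories, two-domain protein alignments with fragment clades and
fast-evolving interface sites, and toy two-chain structures with planted
contacts.  Every generator is deterministic given its seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GenerationError, InvalidArgumentError
from .mk import BinaryRates, RateMatrixK
from .trees import Phylogeny

__all__ = [
    "SimConfig",
    "TrueHistory",
    "TwoCladeScaffold",
    "simulate_tree",
    "simulate_two_clade_tree",
    "simulate_binary_ogs",
    "plant_convergent_losses",
    "simulate_repertoire_states",
    "simulate_domain_msa",
    "DomainMSA",
    "write_toy_structure",
    "write_presence_tsv",
    "write_fasta",
]

AA = "ACDEFGHIKLMNPQRSTVWY"


# ------------------------------------------------------------------- configs
@dataclass
class SimConfig:
    """Bundle of generator settings for a convergence experiment."""

    n_tips: int = 64
    tree_depth: float = 1.0
    q_gain: float = 0.5
    q_loss: float = 0.5
    n_ogs: int = 500
    seed: int = 0
    clade_a_tips: frozenset = frozenset()
    clade_f_tips: frozenset = frozenset()
    planted_orders: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_tips < 2:
            raise InvalidArgumentError("n_tips must be >= 2")
        if self.q_gain < 0 or self.q_loss < 0:
            raise InvalidArgumentError("rates must be non-negative")
        if set(self.clade_a_tips) & set(self.clade_f_tips):
            raise InvalidArgumentError("clade tip sets must be disjoint")


@dataclass
class TrueHistory:
    """Full simulated node states plus planted loss branches per lineage."""

    node_states: pd.DataFrame  # index node names, columns OG ids, values 0/1
    loss_branches: dict[str, dict[str, int | None]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "node_states": {c: self.node_states[c].to_dict() for c in self.node_states},
                "loss_branches": self.loss_branches,
            },
            sort_keys=True,
        )


# ---------------------------------------------------------------- tree sims
def simulate_tree(n_tips: int, seed: int, depth: float = 1.0) -> Phylogeny:
    """Random ultrametric pure-birth (Yule) tree rescaled to the given depth.

    All nodes are uniquely named (tips ``T1..``, internals ``N1..`` in
    preorder) and both topology and branch lengths are deterministic given
    the seed.
    """
    if n_tips < 2:
        raise InvalidArgumentError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)
    # nodes: [parent, birth_time, death_time or None]
    parent = [-1, 0, 0]
    birth = [0.0, 0.0, 0.0]
    death: list[float | None] = [0.0, None, None]
    active = [1, 2]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        v = active.pop(idx)
        death[v] = t
        for _ in range(2):
            parent.append(v)
            birth.append(t)
            death.append(None)
            active.append(len(parent) - 1)
    present = t + rng.exponential(1.0 / n_tips)
    for v in active:
        death[v] = present
    scale = depth / present
    names = [""] * len(parent)
    children: dict[int, list[int]] = {}
    for v, p in enumerate(parent):
        children.setdefault(p, []).append(v)
    n_int = n_tip = 0
    stack = [0]
    while stack:
        v = stack.pop()
        kids = children.get(v, [])
        if kids:
            n_int += 1
            names[v] = f"N{n_int}"
        else:
            n_tip += 1
            names[v] = f"T{n_tip}"
        stack.extend(reversed(kids))
    blen = [(death[v] - birth[v]) * scale if v != 0 else 0.0 for v in range(len(parent))]
    return Phylogeny(names, parent, blen)


@dataclass
class TwoCladeScaffold:
    """An ultrametric tree with two designated convergent lineages.

    ``path_a`` / ``path_f`` are the ordered (parent, child) branches from the
    common ancestor of both focal clades down to each clade's own ancestor,
    mirroring the A0..A5 / F0..F7 path layout of a two-lineage convergence
    study.
    """

    tree: Phylogeny
    lca_fa: str
    lca_a: str
    lca_f: str
    path_a: list[tuple[str, str]]
    path_f: list[tuple[str, str]]
    clade_a_tips: set[str]
    clade_f_tips: set[str]


def simulate_two_clade_tree(
    n_clade_a: int = 4,
    n_clade_f: int = 4,
    path_a_len: int = 6,
    path_f_len: int = 8,
    n_outgroup: int = 2,
    seed: int = 0,
    depth: float = 1.0,
    clade_depth: float = 0.78,
) -> TwoCladeScaffold:
    """Deterministic ultrametric scaffold with controllable path lengths.

    Each path is a chain of internal nodes hanging side tips (so ancestral
    presence along the paths is identifiable from extant data), ending at the
    focal clade ancestor which subtends a ladder clade.  Node depths get a
    small seeded jitter while remaining ultrametric and order-preserving.
    """
    if min(n_clade_a, n_clade_f) < 2 or min(path_a_len, path_f_len) < 1 or n_outgroup < 1:
        raise InvalidArgumentError("need >=2 tips per clade, paths >=1, outgroup >=1")
    if not 0.2 < clade_depth / depth < 1.0:
        raise InvalidArgumentError("clade_depth must lie between the root and the tips")
    rng = np.random.default_rng(seed)
    names: list[str] = []
    parent: list[int] = []
    depths: list[float] = []

    def add(name: str, par: int, d: float) -> int:
        names.append(name)
        parent.append(par)
        depths.append(d)
        return len(names) - 1

    root = add("ROOT", -1, 0.0)
    # outgroup ladder
    d_og = 0.05
    anc = root
    for i in range(1, n_outgroup):
        node = add(f"ON{i}", anc, d_og * i / n_outgroup + 0.02)
        add(f"OUT{i}", node, depth)
        anc = node
    add(f"OUT{n_outgroup}", anc, depth)

    lca_fa = add("LCAFA", root, 0.08)

    def build_path(prefix: str, plen: int, n_clade: int, lca_label: str, start: int):
        d0, d1 = depths[start], clade_depth * depth
        node = start
        prev = d0
        for i in range(1, plen):
            d = d0 + (d1 - d0) * i / plen + float(rng.uniform(-0.01, 0.01))
            d = min(max(d, prev + 1e-3), d1 - 1e-3 * (plen - i))
            prev = d
            node = add(f"{prefix}{i}", node, d)
            add(f"S{prefix}{i}", node, depth)  # side tip
        lca = add(lca_label, node, d1)
        # ladder clade below the focal ancestor
        tips = []
        anc2 = lca
        for i in range(1, n_clade):
            t = add(f"C{prefix}{i}", anc2, depth)
            tips.append(names[t])
            if i < n_clade - 1:
                dd = d1 + (depth - d1) * i / (n_clade - 1)
                anc2 = add(f"{prefix}C{i}", anc2, dd)
        t = add(f"C{prefix}{n_clade}", anc2, depth)
        tips.append(names[t])
        return lca, set(tips)

    lca_a, tips_a = build_path("A", path_a_len, n_clade_a, "LCAA", lca_fa)
    lca_f, tips_f = build_path("F", path_f_len, n_clade_f, "LCAF", lca_fa)

    blen = [0.0] * len(names)
    for v in range(1, len(names)):
        blen[v] = depths[v] - depths[parent[v]]
    tree = Phylogeny(names, parent, blen)
    path_a = tree.path_branches("LCAFA", names[lca_a])
    path_f = tree.path_branches("LCAFA", names[lca_f])
    return TwoCladeScaffold(tree, "LCAFA", names[lca_a], names[lca_f],
                            path_a, path_f, tips_a, tips_f)


# ------------------------------------------------------------ binary traits
def simulate_binary_ogs(
    tree: Phylogeny,
    q_gain: float,
    q_loss: float,
    n_ogs: int,
    root_prob1: float | None = None,
    seed: int = 0,
    og_prefix: str = "OG",
) -> tuple[pd.DataFrame, TrueHistory]:
    """Independent two-state gain/loss histories for `n_ogs` ortholog groups.

    Returns the species x OG 0/1 tip table and the full node-state history.
    `root_prob1` defaults to the stationary presence probability.
    """
    if q_gain < 0 or q_loss < 0:
        raise InvalidArgumentError("rates must be non-negative")
    rates = BinaryRates(q_gain, q_loss)
    if root_prob1 is None:
        root_prob1 = float(rates.stationary()[1])
    if not 0.0 <= root_prob1 <= 1.0:
        raise InvalidArgumentError("root_prob1 must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    m = len(tree)
    states = np.zeros((m, n_ogs), dtype=np.int8)
    states[tree.root] = rng.random(n_ogs) < root_prob1
    Pstack = rates.transition_stack(tree.blen)
    for v in tree.preorder():
        if v == tree.root:
            continue
        p1 = np.where(states[int(tree.parent[v])] == 1, Pstack[v, 1, 1], Pstack[v, 0, 1])
        states[v] = rng.random(n_ogs) < p1
    og_ids = [f"{og_prefix}{i + 1:04d}" for i in range(n_ogs)]
    node_states = pd.DataFrame(states, index=tree.names, columns=og_ids)
    table = node_states.loc[tree.tip_names]
    return table.copy(), TrueHistory(node_states)


def _validate_path(tree: Phylogeny, path: Sequence[tuple[str, str]]) -> None:
    if not path:
        raise InvalidArgumentError("empty path")
    for i, (p, c) in enumerate(path):
        if tree.names[int(tree.parent[tree.index(c)])] != p:
            raise InvalidArgumentError(f"({p},{c}) is not a tree branch")
        if i and path[i - 1][1] != p:
            raise InvalidArgumentError("path branches are not contiguous")


def plant_convergent_losses(
    tree: Phylogeny,
    path_a: Sequence[tuple[str, str]],
    path_f: Sequence[tuple[str, str]],
    planted_orders: Mapping[str, tuple[int, int]],
    background_table: pd.DataFrame,
    background_history: TrueHistory | None = None,
) -> tuple[pd.DataFrame, TrueHistory]:
    """Overwrite a background table with OGs lost at known branches.

    ``planted_orders`` maps an OG name to 0-based branch indices on
    (path_a, path_f).  A planted OG is present (1) everywhere except at the
    loss branch's child and all of its descendants on each path, so its true
    loss order is exactly recoverable.
    """
    _validate_path(tree, path_a)
    _validate_path(tree, path_f)
    if path_a[0][0] != path_f[0][0]:
        raise InvalidArgumentError("paths must start at a common ancestor")
    cols = {}
    loss_branches = dict(background_history.loss_branches) if background_history else {}
    node_states = (
        background_history.node_states.copy()
        if background_history is not None
        else pd.DataFrame(index=tree.names)
    )
    for og, (ia, if_) in planted_orders.items():
        if not (0 <= ia < len(path_a)) or not (0 <= if_ < len(path_f)):
            raise InvalidArgumentError(f"planted branch for {og!r} not on declared path")
        col = pd.Series(1, index=tree.names, dtype=np.int8)
        for path, idx in ((path_a, ia), (path_f, if_)):
            child = path[idx][1]
            col[list(tree.subtree_nodes(child))] = 0
        cols[og] = col
        loss_branches[og] = {"A": ia, "F": if_}
    planted = pd.DataFrame(cols)
    node_states = pd.concat([node_states, planted], axis=1)
    tip_cols = planted.loc[background_table.index]
    table = pd.concat([background_table, tip_cols], axis=1)
    return table, TrueHistory(node_states, loss_branches)


# --------------------------------------------------------- k-state repertoire
def simulate_repertoire_states(
    tree: Phylogeny,
    rate_matrix: RateMatrixK | np.ndarray,
    seed: int = 0,
    root_state: int = 0,
) -> tuple[dict[str, int | str], dict[str, int]]:
    """Exact continuous-time Markov simulation of a k-state character.

    Jump-chain simulation along every branch from the given root state.
    Returns (tip states keyed by tip name, all node states); states are the
    matrix labels when provided, otherwise integer indices.
    """
    if not isinstance(rate_matrix, RateMatrixK):
        rate_matrix = RateMatrixK(np.asarray(rate_matrix, dtype=float))
    Q = rate_matrix.Q
    k = rate_matrix.k
    if not 0 <= root_state < k:
        raise InvalidArgumentError("root_state out of range")
    rng = np.random.default_rng(seed)
    node_state = {tree.root: root_state}
    for v in tree.preorder():
        if v == tree.root:
            continue
        s = node_state[int(tree.parent[v])]
        t_left = float(tree.blen[v])
        while True:
            out_rate = -Q[s, s]
            if out_rate <= 0:
                break
            wait = rng.exponential(1.0 / out_rate)
            if wait >= t_left:
                break
            t_left -= wait
            probs = Q[s].copy()
            probs[s] = 0.0
            probs = probs / probs.sum()
            s = int(rng.choice(k, p=probs))
        node_state[v] = s

    def lab(i: int):
        return rate_matrix.labels[i] if rate_matrix.labels else i

    tips = {tree.names[v]: lab(node_state[v]) for v in tree.tip_indices()}
    allnodes = {tree.names[v]: node_state[v] for v in range(len(tree))}
    return tips, allnodes


# --------------------------------------------------------------- domain MSA
@dataclass
class DomainMSA:
    """Simulated two-domain alignment with planted fragment clades."""

    alignment: dict[str, str]  # tip id -> aligned sequence (with gaps)
    true_classes: dict[str, str]  # tip id -> "complete" | "ALDH_only"
    interface_sites: tuple[int, ...]  # 1-based columns in the N-terminal region
    len_aldh: int
    len_adh: int
    node_sequences: dict[str, str] = field(default_factory=dict)


def simulate_domain_msa(
    tree: Phylogeny,
    len_aldh: int,
    len_adh: int,
    fragment_clades: Sequence[set[str]],
    interface_sites: Sequence[int],
    rate_multiplier: float,
    seed: int = 0,
    base_rate: float = 0.5,
) -> DomainMSA:
    """Amino-acid alignment where designated clades carry single-domain fragments.

    The first `len_aldh` columns are the retained domain; tips inside any
    fragment clade have all remaining (`len_adh`) columns gapped.
    `interface_sites` (1-based, within the retained domain) substitute at
    ``rate_multiplier`` x the base Poisson rate on branches whose descendant
    tips all lie inside one fragment clade (stem branches included).
    """
    if rate_multiplier < 1:
        raise InvalidArgumentError("rate_multiplier must be >= 1")
    sites = tuple(int(s) for s in interface_sites)
    if any(not 1 <= s <= len_aldh for s in sites):
        raise InvalidArgumentError("interface sites must lie in 1..len_aldh")
    clades = [set(c) for c in fragment_clades]
    for i in range(len(clades)):
        for j in range(i + 1, len(clades)):
            if clades[i] & clades[j]:
                raise InvalidArgumentError("fragment clades overlap")
    fragment_tips = set().union(*clades) if clades else set()
    rng = np.random.default_rng(seed)
    L = len_aldh + len_adh
    rates = np.full(L, base_rate)
    fast = np.array(sites, dtype=int) - 1 if sites else np.array([], dtype=int)

    def branch_in_fragment(v: int) -> bool:
        tips_below = tree.subtree_tips(tree.names[v])
        return any(tips_below <= c for c in clades) if tips_below else False

    seqs = np.zeros((len(tree), L), dtype=np.int8)
    seqs[tree.root] = rng.integers(0, 20, size=L)
    for v in tree.preorder():
        if v == tree.root:
            continue
        r = rates.copy()
        if fast.size and branch_in_fragment(v):
            r[fast] = base_rate * rate_multiplier
        lam = r * float(tree.blen[v])
        njump = rng.poisson(lam)
        seq = seqs[int(tree.parent[v])].copy()
        for site in np.nonzero(njump)[0]:
            s = seq[site]
            for _ in range(njump[site]):
                s = (s + 1 + rng.integers(0, 19)) % 20
            seq[site] = s
        seqs[v] = seq

    def to_str(row: np.ndarray) -> str:
        return "".join(AA[i] for i in row)

    alignment: dict[str, str] = {}
    true_classes: dict[str, str] = {}
    for v in tree.tip_indices():
        name = tree.names[v]
        s = to_str(seqs[v])
        if name in fragment_tips:
            s = s[:len_aldh] + "-" * len_adh
            true_classes[name] = "ALDH_only"
        else:
            true_classes[name] = "complete"
        alignment[name] = s
    node_sequences = {tree.names[v]: to_str(seqs[v]) for v in range(len(tree))
                      if not tree.is_tip(v)}
    return DomainMSA(alignment, true_classes, sites, len_aldh, len_adh, node_sequences)


# ------------------------------------------------------------ toy structures
def write_toy_structure(
    n_residues_per_chain: int,
    contact_pairs: Sequence[tuple[int, int]],
    seed: int = 0,
) -> str:
    """PDB text for two CA-only chains (B, C) with planted contacts.

    Every declared (chain-B residue, chain-C residue) pair sits at exactly
    4.0 Å; every non-declared inter-chain residue pair is farther than
    6.0 Å.  Placement is deterministic; `seed` is accepted for signature
    symmetry with the other generators and currently unused.
    """
    n = n_residues_per_chain
    pairs = [(int(b), int(c)) for b, c in contact_pairs]
    for b, c in pairs:
        if not (1 <= b <= n and 1 <= c <= n):
            raise InvalidArgumentError("contact pair references residue outside chain")
    partner_of_c: dict[int, int] = {}
    for b, c in pairs:
        if c in partner_of_c and partner_of_c[c] != b:
            raise GenerationError(
                "a chain-C residue cannot sit 4.0 Å from two separated chain-B residues"
            )
        partner_of_c[c] = b
    per_b_count: dict[int, int] = {}
    spacing = 20.0
    coords: list[tuple[str, int, float, float, float]] = []
    for i in range(1, n + 1):
        coords.append(("B", i, spacing * i, 0.0, 0.0))
    for j in range(1, n + 1):
        if j in partner_of_c:
            b = partner_of_c[j]
            idx = per_b_count.get(b, 0)
            per_b_count[b] = idx + 1
            theta = 0.4 * idx  # multiple partners fan out on the 4 Å sphere
            coords.append(("C", j, spacing * b, 4.0 * math.cos(theta), 4.0 * math.sin(theta)))
        else:
            coords.append(("C", j, spacing * j, 100.0, 0.0))
    lines = []
    for serial, (chain, resnum, x, y, z) in enumerate(coords, start=1):
        lines.append(
            f"ATOM  {serial:5d}  CA  ALA {chain}{resnum:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f" C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ------------------------------------------------------------------- writers
def write_presence_tsv(table: pd.DataFrame, path) -> None:
    """Species x OG 0/1 table as TSV (first column `species`)."""
    out = table.copy()
    out.index.name = "species"
    out.to_csv(path, sep="\t")


def write_fasta(sequences: Mapping[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    seqio_write(records, str(path), "fasta")
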
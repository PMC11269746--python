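"""Rule-based detection and classification of adhE-derived genes.

AdhE is a two-domain (N-terminal ALDH + C-terminal ADH) enzyme; decayed
genes retain one domain or part of both.  This module applies the filtering
cascade used to separate complete genes, fragments and paralogs from
sequence, alignment, homology-hit and gene-tree inputs: length windows,
identity/coverage hit filters, half-alignment gap filters, alignment-center
fragment classes, outgroup-based paralog exclusion, sequence-similarity
networks, and per-species repertoire states.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import networkx as nx
import pandas as pd

from .errors import DataError, InvalidArgumentError, TopologyError

__all__ = [
    "HitRecord",
    "FragmentRecord",
    "FragmentClass",
    "REPERTOIRE_STATES",
    "select_complete_candidates",
    "filter_hits",
    "split_halves_and_filter",
    "classify_fragment",
    "classify_fragments",
    "exclude_non_adhe",
    "build_ssn",
    "assign_repertoire",
]


class FragmentClass:
    """Catalog of fragment classes (plain strings for easy tabulation)."""

    COMPLETE = "complete"
    ALDH_ONLY = "ALDH_only"
    ADH_ONLY = "ADH_only"
    INCOMPLETE = "incomplete"
    ALL = (COMPLETE, ALDH_ONLY, ADH_ONLY, INCOMPLETE)


REPERTOIRE_STATES = (
    "none",
    "1_complete",
    "2_complete",
    "1_ALDH",
    "1_ADH",
    "1_incomplete",
    "complete_plus_ALDH",
)


@dataclass(frozen=True)
class HitRecord:
    """One homology hit: identity and target coverage as fractions."""

    query: str
    target: str
    identity: float
    coverage: float

    def __post_init__(self):
        if not (0.0 <= self.identity <= 1.0 and 0.0 <= self.coverage <= 1.0):
            raise InvalidArgumentError("identity and coverage must lie in [0, 1]")


@dataclass(frozen=True)
class FragmentRecord:
    """A sequence's placement in the alignment and its fragment class."""

    seq_id: str
    species: str
    length: int  # non-gap residues
    first: int  # first non-gap MSA column (1-based)
    last: int
    center: int
    fragment_class: str


def _ungapped_len(seq: str) -> int:
    return sum(1 for ch in seq if ch not in "-.")


def select_complete_candidates(
    sequences: Mapping[str, str], min_len: int = 800, max_len: int = 1000
) -> set[str]:
    """Ids of sequences whose ungapped length lies in [min_len, max_len]
    (bounds inclusive)."""
    return {sid for sid, s in sequences.items() if min_len <= _ungapped_len(s) <= max_len}


def filter_hits(hits, min_identity: float = 0.45, min_coverage: float = 0.45) -> set[str]:
    """Queries with at least one hit strictly exceeding both thresholds."""
    if isinstance(hits, pd.DataFrame):
        rows = (
            HitRecord(r.query, r.target, float(r.identity), float(r.coverage))
            for r in hits.itertuples(index=False)
        )
    else:
        rows = iter(hits)
    return {
        h.query for h in rows if h.identity > min_identity and h.coverage > min_coverage
    }


def split_halves_and_filter(
    msa: Mapping[str, str], half_cols: int = 500, max_gap_frac: float = 0.5
) -> tuple[set[str], set[str]]:
    """Ids retained in the first/last `half_cols` alignment columns.

    A sequence is excluded from a half when its gap fraction there strictly
    exceeds `max_gap_frac`.  Narrow alignments where the two halves overlap
    are allowed (with a warning); width < half_cols is an error.
    """
    if not msa:
        return set(), set()
    width = len(next(iter(msa.values())))
    if any(len(s) != width for s in msa.values()):
        raise DataError("alignment rows have unequal width")
    if width < half_cols:
        raise InvalidArgumentError(f"alignment width {width} < half width {half_cols}")
    if width < 2 * half_cols:
        warnings.warn("N- and C-terminal halves overlap on this narrow alignment")
    n_keep, c_keep = set(), set()
    for sid, s in msa.items():
        nh = s[:half_cols]
        ch = s[-half_cols:]
        if sum(c in "-." for c in nh) / half_cols <= max_gap_frac:
            n_keep.add(sid)
        if sum(c in "-." for c in ch) / half_cols <= max_gap_frac:
            c_keep.add(sid)
    return n_keep, c_keep


def _span(seq: str) -> tuple[int, int]:
    first = last = None
    for i, ch in enumerate(seq, start=1):
        if ch not in "-.":
            if first is None:
                first = i
            last = i
    if first is None:
        raise DataError("all-gap alignment row")
    return first, last


def classify_fragment(
    msa: Mapping[str, str],
    seq_id: str,
    len_threshold: int = 800,
    center_lo: int = 400,
    center_hi: int = 900,
    center_method: str = "midpoint",
) -> str:
    """Fragment class from ungapped length and alignment center position.

    complete: length > len_threshold and center in [center_lo, center_hi];
    ALDH_only: center < center_lo; ADH_only: center > center_hi; otherwise
    incomplete.  The center is the midpoint of the first and last non-gap
    columns (1-based, halves rounded down); ``center_method='mean'`` uses
    the rounded mean of all non-gap column indices instead.
    """
    seq = msa[seq_id]
    first, last = _span(seq)
    if center_method == "midpoint":
        center = (first + last) // 2
    elif center_method == "mean":
        cols = [i for i, ch in enumerate(seq, start=1) if ch not in "-."]
        center = int(sum(cols) / len(cols))
    else:
        raise InvalidArgumentError("center_method must be 'midpoint' or 'mean'")
    length = _ungapped_len(seq)
    if length > len_threshold and center_lo <= center <= center_hi:
        return FragmentClass.COMPLETE
    if center < center_lo:
        return FragmentClass.ALDH_ONLY
    if center > center_hi:
        return FragmentClass.ADH_ONLY
    return FragmentClass.INCOMPLETE


def classify_fragments(msa: Mapping[str, str], **kwargs) -> dict[str, str]:
    """Classify every row; total and deterministic."""
    return {sid: classify_fragment(msa, sid, **kwargs) for sid in msa}


def fragment_records(
    msa: Mapping[str, str], species_of: Mapping[str, str] | None = None, **kwargs
) -> list[FragmentRecord]:
    """FragmentRecord table for an alignment (species defaults to seq id)."""
    out = []
    for sid, seq in msa.items():
        first, last = _span(seq)
        out.append(
            FragmentRecord(
                seq_id=sid,
                species=(species_of or {}).get(sid, sid),
                length=_ungapped_len(seq),
                first=first,
                last=last,
                center=(first + last) // 2,
                fragment_class=classify_fragment(msa, sid, **kwargs),
            )
        )
    return out


def exclude_non_adhe(
    gene_tree, outgroup_id: str, complete_ids: Iterable[str]
) -> tuple[set[str], set[str]]:
    """Drop gene-tree leaves outside the clade anchored by complete genes.

    The tree is (re)rooted on `outgroup_id`; the ingroup is every leaf
    descending from the MRCA of `complete_ids`.  Returns (retained ids,
    excluded ids); the outgroup itself belongs to neither set.  Because the
    outgroup is a leaf, rerooting always separates it from the ingroup; the
    topology conflict that remains detectable is the outgroup being listed
    among the complete genes (checked both up front and after the MRCA
    computation).
    """
    if isinstance(gene_tree, str):
        tree = dendropy.Tree.get(
            data=gene_tree, schema="newick", preserve_underscores=True
        )
    else:
        tree = gene_tree
    complete_ids = set(complete_ids)
    if outgroup_id in complete_ids:
        raise TopologyError("outgroup cannot be one of the complete genes")
    taxa = {t.label for t in tree.taxon_namespace}
    if outgroup_id not in taxa:
        raise KeyError(f"outgroup {outgroup_id!r} not a leaf of the gene tree")
    missing = complete_ids - taxa
    if missing:
        raise KeyError(f"complete ids absent from the gene tree: {sorted(missing)[:5]}")
    og_node = tree.find_node_with_taxon_label(outgroup_id)
    tree.reroot_at_edge(og_node.edge, update_bipartitions=True)
    mrca = tree.mrca(taxon_labels=sorted(complete_ids))
    ingroup = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    if outgroup_id in ingroup:
        raise TopologyError("outgroup falls inside the MRCA of complete genes")
    all_leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    excluded = all_leaves - ingroup - {outgroup_id}
    return ingroup, excluded


def build_ssn(pairwise_identities, threshold: float) -> tuple[nx.Graph, list[set[str]]]:
    """Sequence similarity network: edge iff identity strictly > threshold.

    `pairwise_identities` is an iterable of (a, b, identity) or a DataFrame
    with those three columns.  All ids seen become nodes, so singletons are
    their own components.  Self-pairs are ignored with a warning; duplicate
    pairs keep their maximum identity.
    """
    if isinstance(pairwise_identities, pd.DataFrame):
        triples = pairwise_identities.iloc[:, :3].itertuples(index=False)
    else:
        triples = pairwise_identities
    g = nx.Graph()
    best: dict[frozenset, float] = {}
    for a, b, ident in triples:
        ident = float(ident)
        if not 0.0 <= ident <= 1.0:
            raise InvalidArgumentError("identity values must lie in [0, 1]")
        g.add_node(a)
        g.add_node(b)
        if a == b:
            warnings.warn(f"ignoring self-pair for {a!r}")
            continue
        key = frozenset((a, b))
        best[key] = max(best.get(key, 0.0), ident)
    for key, ident in best.items():
        if ident > threshold:
            a, b = sorted(key)
            g.add_edge(a, b, identity=ident)
    components = [set(c) for c in nx.connected_components(g)]
    return g, components


def assign_repertoire(
    species_fragments: Mapping[str, Mapping[str, int] | Sequence[str]],
    overrides: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Map each species' fragment multiset to a repertoire state label.

    Recognised combinations form the fixed 7-state catalog
    (:data:`REPERTOIRE_STATES`); anything else maps to ``"other"`` with a
    warning.  Explicit per-species overrides (e.g. tandem-artifact species
    forced to ``1_complete``) are applied last.
    """
    catalog = {
        (): "none",
        (("complete", 1),): "1_complete",
        (("complete", 2),): "2_complete",
        (("ALDH_only", 1),): "1_ALDH",
        (("ADH_only", 1),): "1_ADH",
        (("incomplete", 1),): "1_incomplete",
        (("ALDH_only", 1), ("complete", 1)): "complete_plus_ALDH",
    }
    out: dict[str, str] = {}
    for species, frags in species_fragments.items():
        counts = Counter(frags) if not isinstance(frags, Mapping) else Counter(
            {k: int(v) for k, v in frags.items() if v}
        )
        key = tuple(sorted(counts.items()))
        label = catalog.get(key)
        if label is None:
            warnings.warn(f"{species}: fragment combination {dict(counts)} outside catalog")
            label = "other"
        out[species] = label
    for species, label in (overrides or {}).items():
        out[species] = label
    return out
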
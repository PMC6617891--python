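"""Allo- vs autopolyploid origin calls from gene-tree clade placement.

The criterion: gene copies duplicated by genome doubling alone should be
each other's closest relatives (monophyletic) in the gene tree, whereas
homoeologs contributed by different parental lineages of an
allopolyploid fall in different major clades.  A call of
ALLOPOLYPLOID_PATTERN therefore requires an individual's copies to be
non-monophyletic *and* assigned to at least two distinct major clades
whose defining edges are well supported; a monophyletic copy set is
called AUTOPOLYPLOID_PATTERN; everything else — single copies, copies
separated only by poorly supported edges, copies in the same or in no
major clade — is UNINFORMATIVE.

Major clades are given by exemplar sequences (e.g. diploid carriers of
each gene variant); a sequence belongs to clade K when it descends from
the MRCA of K's exemplars and from no other clade's MRCA.

Diploid individuals carrying copies in two clades show the same signal
but are reported as a hybrid pattern rather than a polyploidy call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import dendropy

from .phylogeny import node_leaf_labels, node_support
from .variant_typing import GenotypeRecord, VariantLabel

__all__ = [
    "Verdict",
    "MonophylyStatus",
    "CladeExemplars",
    "OriginCall",
    "homoeolog_monophyly",
    "assign_major_clade",
    "classify_origin",
    "UNASSIGNED",
]

DEFAULT_SUPPORT_MIN = 70.0
UNASSIGNED = "unassigned"


class Verdict(str, Enum):
    ALLOPOLYPLOID_PATTERN = "allopolyploid_pattern"
    AUTOPOLYPLOID_PATTERN = "autopolyploid_pattern"
    UNINFORMATIVE = "uninformative"


class MonophylyStatus(str, Enum):
    MONOPHYLETIC = "monophyletic"
    NON_MONOPHYLETIC = "non_monophyletic"
    SINGLE_COPY = "single_copy"


@dataclass(frozen=True)
class CladeExemplars:
    """Major-clade id → exemplar sequence ids (disjoint sets)."""

    clades: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, members in self.clades.items():
            if not members:
                raise ValueError(f"clade {name!r} has no exemplars")
            overlap = seen & set(members)
            if overlap:
                raise ValueError(f"exemplar(s) in multiple clades: {sorted(overlap)}")
            seen |= set(members)


@dataclass(frozen=True)
class OriginCall:
    individual_id: str
    verdict: Verdict
    copies: tuple[tuple[str, VariantLabel, str], ...]  # (seq_id, label, clade)
    min_separating_support: float | None
    rationale: str
    ploidy: int = 0
    monophyly: MonophylyStatus = MonophylyStatus.SINGLE_COPY

    @property
    def display_verdict(self) -> str:
        """Diploids with copies in different clades show a hybrid, not a
        polyploidy, pattern."""
        if self.ploidy == 2 and self.verdict is Verdict.ALLOPOLYPLOID_PATTERN:
            return "hybrid_pattern"
        return self.verdict.value


def _leaf_set(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(l.taxon.label for l in tree.leaf_node_iter())


def _mrca(tree: dendropy.Tree, labels: frozenset[str]) -> dendropy.Node:
    node = tree.mrca(taxon_labels=list(labels))
    if node is None:
        raise KeyError(f"no MRCA for {sorted(labels)}")
    return node


def homoeolog_monophyly(
    tree: dendropy.Tree, individual_id: str, seq_map: Mapping[str, tuple[str, ...]]
) -> MonophylyStatus:
    """Is the individual's copy set exactly the leaf set under its MRCA?"""
    seq_ids = frozenset(seq_map[individual_id])
    missing = seq_ids - _leaf_set(tree)
    if missing:
        raise KeyError(
            f"{individual_id!r}: sequence(s) missing from tree: {sorted(missing)}"
        )
    if len(seq_ids) < 2:
        return MonophylyStatus.SINGLE_COPY
    mrca = _mrca(tree, seq_ids)
    if node_leaf_labels(mrca) == seq_ids:
        return MonophylyStatus.MONOPHYLETIC
    return MonophylyStatus.NON_MONOPHYLETIC


def assign_major_clade(
    tree: dendropy.Tree, seq_id: str, exemplars: CladeExemplars
) -> str:
    """Clade id whose exemplar MRCA (and no other) subtends the sequence."""
    leaves = _leaf_set(tree)
    if seq_id not in leaves:
        raise KeyError(f"sequence {seq_id!r} not in tree")
    hits: list[str] = []
    for name, members in exemplars.clades.items():
        missing = frozenset(members) - leaves
        if missing:
            raise KeyError(
                f"clade {name!r} exemplar(s) missing from tree: {sorted(missing)}"
            )
        mrca = _mrca(tree, frozenset(members))
        if seq_id in node_leaf_labels(mrca):
            hits.append(name)
    if len(hits) == 1:
        return hits[0]
    return UNASSIGNED  # outside all clades, or in nested/ambiguous MRCAs


def _separating_support(
    tree: dendropy.Tree,
    exemplars: frozenset[str],
    clade_copies: frozenset[str],
    other_copies: frozenset[str],
) -> float:
    """Best support of a clade separating one homoeolog from the others.

    Considers every edge whose clade contains the copy (or copies)
    assigned to a major clade together with that clade's exemplars
    while excluding the individual's copies assigned elsewhere, and
    returns the highest support among them.  This is the support of the
    claim "this copy is resolved inside this major clade, apart from
    the individual's other copies" — deliberately not the support of
    the exemplar MRCA edge alone, which can be a weak interior edge
    when other lineages attach basally within the major clade.
    """
    node = _mrca(tree, exemplars | clade_copies)
    best = math.nan
    while node is not None and node is not tree.seed_node:
        leaves = node_leaf_labels(node)
        if leaves & other_copies:
            break
        if not node.is_leaf():
            support = node_support(node)
            if support is not None and (math.isnan(best) or support > best):
                best = support
        node = node.parent_node
    return best


def classify_origin(
    tree: dendropy.Tree,
    genotype: GenotypeRecord,
    exemplars: CladeExemplars,
    support_min: float = DEFAULT_SUPPORT_MIN,
    ploidy: int = 0,
    require_support: bool = True,
) -> OriginCall:
    """Apply the clade-placement criterion to one individual.

    ``require_support=False`` disables the support gate (used when an
    externally supplied tree carries no bootstrap values).
    """
    seq_ids = genotype.seq_ids
    copies = tuple(
        (sid, label, assign_major_clade(tree, sid, exemplars))
        for sid, label, _ in genotype.per_sequence
    )
    if len(seq_ids) < 2:
        return OriginCall(
            genotype.individual_id, Verdict.UNINFORMATIVE, copies, None,
            "single gene copy recovered", ploidy, MonophylyStatus.SINGLE_COPY,
        )
    status = homoeolog_monophyly(
        tree, genotype.individual_id, {genotype.individual_id: seq_ids}
    )
    if status is MonophylyStatus.MONOPHYLETIC:
        return OriginCall(
            genotype.individual_id, Verdict.AUTOPOLYPLOID_PATTERN, copies, None,
            "gene copies are each other's closest relatives", ploidy, status,
        )
    assigned = {clade for _, _, clade in copies if clade != UNASSIGNED}
    if len(assigned) >= 2:
        clade_supports = {}
        for name in assigned:
            in_clade = frozenset(s for s, _, c in copies if c == name)
            elsewhere = frozenset(
                s for s, _, c in copies if c != name and c != UNASSIGNED
            )
            clade_supports[name] = _separating_support(
                tree, frozenset(exemplars.clades[name]), in_clade, elsewhere
            )
        finite = [s for s in clade_supports.values() if not math.isnan(s)]
        min_support = min(finite) if finite else math.nan
        if not require_support or (finite and min_support >= support_min):
            return OriginCall(
                genotype.individual_id, Verdict.ALLOPOLYPLOID_PATTERN, copies,
                None if math.isnan(min_support) else min_support,
                f"copies fall in distinct major clades {sorted(assigned)}",
                ploidy, status,
            )
        return OriginCall(
            genotype.individual_id, Verdict.UNINFORMATIVE, copies,
            None if math.isnan(min_support) else min_support,
            f"separating clades below support threshold {support_min:g}",
            ploidy, status,
        )
    return OriginCall(
        genotype.individual_id, Verdict.UNINFORMATIVE, copies, None,
        "copies not monophyletic but not in two distinct major clades",
        ploidy, status,
    )
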
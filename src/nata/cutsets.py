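"""Qualitative (logical) analysis of a non-adherence tree.

Reduces the Boolean structure of a tree to its minimal cut sets — the
smallest combinations of basic factors that are necessary and sufficient to
trigger discontinuation — and flags singleton cut sets as single points of
failure.

The expansion is exact and symbolic: OR gates take the union of their
children's cut-set lists, AND gates the pairwise unions across children,
followed by absorption-law minimization.  Priority-AND gates are treated as
plain AND for logical purposes (the sequencing constraint only tightens the
probability, never the combination of factors required); the required order
is recorded on the resulting cut sets so probabilistic engines can honour it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import NataError
from .model import GateKind, NonAdherenceTree

__all__ = ["CutSet", "CutSetReport", "minimal_cut_sets", "evaluate_truth"]

#: refuse symbolic expansion past this many intermediate products
MAX_PRODUCTS = 2**20


@dataclass(frozen=True)
class CutSet:
    """One minimal cut set.

    ``members`` lists the basic factor ids; when ``ordered`` is true the cut
    set was derived through a priority-AND gate and the member order is the
    required occurrence order.  For unordered cut sets the order is the
    canonical (sorted) one.
    """

    members: tuple[str, ...]
    ordered: bool = False

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a cut set cannot be empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"duplicate members in cut set {self.members}")

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class CutSetReport:
    """Minimal cut sets of a tree plus the derived single points of failure."""

    cut_sets: tuple[CutSet, ...]
    single_points: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        sets = [c.member_set for c in self.cut_sets]
        for i, a in enumerate(sets):
            for j, b in enumerate(sets):
                if i != j and a <= b:
                    raise ValueError(
                        f"cut sets are not minimal: {sorted(a)} absorbs {sorted(b)}"
                    )
        object.__setattr__(
            self,
            "single_points",
            tuple(c.members[0] for c in self.cut_sets if len(c) == 1),
        )


def _expand(tree: NonAdherenceTree, node_id: str) -> list[tuple[tuple[str, ...], bool]]:
    """(product, ordered) pairs for the subtree at ``node_id``.

    ``ordered`` marks products whose derivation passed through a PAND gate;
    their member order is the required occurrence order.
    """
    node = tree.node(node_id)
    if node.is_basic:
        return [((node.id,), False)]
    child_products = [_expand(tree, c) for c in node.children]
    if node.gate is GateKind.OR:
        out = [p for products in child_products for p in products]
    else:  # AND / PAND: cross-product of unions, preserving child order
        is_pand = node.gate is GateKind.PAND
        out = [((), is_pand)]
        for products in child_products:
            if len(out) * len(products) > MAX_PRODUCTS:
                raise NataError(
                    f"symbolic expansion exceeds {MAX_PRODUCTS} products at "
                    f"node {node_id!r}"
                )
            out = [
                (existing + tuple(m for m in p if m not in existing),
                 flag or pflag or is_pand)
                for existing, flag in out
                for p, pflag in products
            ]
    if len(out) > MAX_PRODUCTS:
        raise NataError(
            f"symbolic expansion exceeds {MAX_PRODUCTS} products at node {node_id!r}"
        )
    return out


def minimize(products: Sequence[tuple[str, ...]]) -> list[tuple[str, ...]]:
    """Absorption-law minimization of a product list.

    Drops any product whose member set is a strict superset of another's and
    dedupes equal sets (keeping the first, order-bearing, representative);
    idempotent on already-minimal lists.  Deterministic output order: by
    size, then lexicographically.
    """
    uniq: dict[frozenset[str], tuple[str, ...]] = {}
    for p in products:
        uniq.setdefault(frozenset(p), p)
    keys = list(uniq)
    keep = [k for k in keys if not any(other < k for other in keys)]
    kept = [uniq[k] for k in keep]
    return sorted(kept, key=lambda p: (len(p), tuple(sorted(p))))


def minimal_cut_sets(tree: NonAdherenceTree) -> CutSetReport:
    """Minimal cut sets of a tree, with single points of failure identified.

    Cut sets are returned sorted by size then lexicographically.  Cut sets
    whose derivation passed through a priority-AND gate carry
    ``ordered=True`` with members in required occurrence order; minimality
    itself ignores order (PAND minimizes as AND).
    """
    expanded = _expand(tree, tree.top_id)
    ordered_by_set = {frozenset(p): flag for p, flag in reversed(expanded)}
    products = minimize([p for p, _ in expanded])
    cut_sets = tuple(
        CutSet(
            members=p if ordered_by_set[frozenset(p)] else tuple(sorted(p)),
            ordered=ordered_by_set[frozenset(p)] and len(p) > 1,
        )
        for p in products
    )
    return CutSetReport(cut_sets=cut_sets)


def evaluate_truth(tree: NonAdherenceTree, assignment: Mapping[str, bool]) -> bool:
    """Bottom-up Boolean evaluation of the top event under a factor assignment.

    ``assignment`` must cover every basic id.  Priority-AND evaluates as
    plain AND (occurrence, not order, is modelled here); this is the oracle
    the cut-set expansion is verified against.
    """
    missing = set(tree.basic_ids()) - set(assignment)
    if missing:
        raise ValueError(f"assignment is missing basic ids: {sorted(missing)}")

    def walk(node_id: str) -> bool:
        node = tree.node(node_id)
        if node.is_basic:
            return bool(assignment[node.id])
        values = (walk(c) for c in node.children)
        if node.gate is GateKind.OR:
            return any(values)
        return all(values)  # AND and PAND

    return walk(tree.top_id)
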
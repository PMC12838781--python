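"""Rough-set lattices from binary relations.

A binary relation I ⊆ U1×U2 between two copies of the neuron set induces a
closure operator on subsets of U1,

    Cl(F) = R*(r*(F)),
    r*(F) = {g ∈ U2 : f I g for some f ∈ F},
    R*(G) = U1 − {f ∈ U1 : f I g for some g ∉ G},

whose fixed points, ordered by inclusion, form a complete lattice
L = {F ⊆ U1 : Cl(F) = F}.  When the relation is the identity, L is the full
Boolean algebra 2^U1.  When the relation is the *pasting* relation of a block
partition — identity within each block, complete between blocks — L is the
union of the Boolean algebras of the individual blocks, disjoint except for
the shared bottom ∅ and top U1.  The pasted lattice is non-distributive for
two or more blocks and is the order-theoretic skeleton of the "quantum logic"
connectivity conditions studied in this package.

Relations can also be thresholded directly out of a weight matrix
(w_ij ≥ θ), which is how the connectivity conditions induce lattices.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

__all__ = [
    "BinaryRelation",
    "RoughLattice",
    "DistributivityReport",
    "closure",
    "build_lattice",
    "pasted_relation",
    "block_relation",
    "identity_relation",
    "relation_from_weights",
    "check_distributivity",
    "hasse_edges",
    "lattice_to_json",
    "lattice_to_dot",
]

MAX_UNIVERSE = 20  # build_lattice enumerates 2^n subsets


def _default_labels(n: int, upper: bool) -> tuple[str, ...]:
    base = ord("A") if upper else ord("a")
    if n <= 26:
        return tuple(chr(base + i) for i in range(n))
    return tuple(("N" if upper else "n") + str(i) for i in range(n))


@dataclass(frozen=True)
class BinaryRelation:
    """A relation I ⊆ U1×U2 between two ordered label universes.

    ``pairs`` holds index pairs (i, j) with i indexing ``universe1`` and j
    indexing ``universe2``.
    """

    universe1: tuple[str, ...]
    universe2: tuple[str, ...]
    pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        n1, n2 = len(self.universe1), len(self.universe2)
        for i, j in self.pairs:
            if not (0 <= i < n1 and 0 <= j < n2):
                raise ValueError(f"pair ({i}, {j}) outside universes of size {n1}x{n2}")

    @property
    def n(self) -> int:
        return len(self.universe1)

    def image(self, i: int) -> frozenset[int]:
        """r({i}): the set of j ∈ U2 related to element i of U1."""
        return frozenset(j for (k, j) in self.pairs if k == i)

    def indices_of(self, labels: Iterable[str]) -> frozenset[int]:
        lookup = {lab: i for i, lab in enumerate(self.universe1)}
        out = set()
        for lab in labels:
            if lab not in lookup:
                raise KeyError(f"label {lab!r} is not in universe1")
            out.add(lookup[lab])
        return frozenset(out)

    def labels_of(self, indices: Iterable[int]) -> tuple[str, ...]:
        return tuple(sorted(self.universe1[i] for i in indices))


def identity_relation(n: int) -> BinaryRelation:
    """The diagonal relation {(i, i)}; its lattice is the full power set."""
    return BinaryRelation(
        _default_labels(n, True), _default_labels(n, False),
        frozenset((i, i) for i in range(n)),
    )


def _block_ids(block_sizes: Sequence[int]) -> list[int]:
    ids: list[int] = []
    for k, size in enumerate(block_sizes):
        if size < 1:
            raise ValueError("block sizes must be positive")
        ids.extend([k] * size)
    return ids


def block_relation(block_sizes: Sequence[int]) -> BinaryRelation:
    """The full block-diagonal relation: (i, j) ∈ I iff i, j share a block.

    This is what literal weight thresholding of a block-structured matrix
    produces.  Its closure fixed points are exactly the unions of blocks
    (2^b elements for b blocks), *not* the pasted lattice.
    """
    ids = _block_ids(block_sizes)
    n = len(ids)
    pairs = frozenset((i, j) for i in range(n) for j in range(n) if ids[i] == ids[j])
    return BinaryRelation(_default_labels(n, True), _default_labels(n, False), pairs)


def pasted_relation(block_sizes: Sequence[int]) -> BinaryRelation:
    """The relation realizing the pasting of per-block Boolean algebras.

    (i, j) ∈ I iff i = j, or i and j lie in *different* blocks: diagonal
    sub-relations bounded by a fully related background.  Its closure fixed
    points are ∅, U1, and every proper nonempty subset of each block —
    Σ(2^k_b − 2) + 2 elements — i.e. the per-block Boolean algebras glued at
    their shared top and bottom.
    """
    ids = _block_ids(block_sizes)
    n = len(ids)
    pairs = frozenset(
        (i, j) for i in range(n) for j in range(n) if i == j or ids[i] != ids[j]
    )
    return BinaryRelation(_default_labels(n, True), _default_labels(n, False), pairs)


def relation_from_weights(weights, theta: float | None = None) -> BinaryRelation:
    """Threshold a weight matrix into a relation: (i, j) ∈ I iff w_ij ≥ θ.

    ``weights`` is a :class:`~recres.connectivity.WeightMatrix` or a plain 2-D
    array.  When ``theta`` is omitted and the matrix carries class metadata,
    the threshold defaults to the midpoint between the strong-class lower
    bound and the largest upper bound among the remaining classes, so that
    exactly the strong entries are related.
    """
    import numpy as np

    values = getattr(weights, "values", weights)
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("weights must be a square matrix")
    n = values.shape[0]
    if theta is None:
        specs = getattr(weights, "class_specs", None)
        if specs and "strong" in specs:
            strong_low = specs["strong"].low
            others = [s.high for name, s in specs.items() if name != "strong" and s is not None]
            theta = (strong_low + max(others)) / 2 if others else strong_low
        else:
            raise ValueError("theta is required for matrices without class metadata")
    if theta > values.max():
        warnings.warn("threshold exceeds every weight: relation is empty", stacklevel=2)
    pairs = frozenset((i, j) for i in range(n) for j in range(n) if values[i, j] >= theta)
    return BinaryRelation(_default_labels(n, True), _default_labels(n, False), pairs)


def _closure_indices(F: frozenset[int], images: Sequence[frozenset[int]]) -> frozenset[int]:
    rstar: set[int] = set()
    for f in F:
        rstar |= images[f]
    return frozenset(i for i, img in enumerate(images) if img <= rstar)


def closure(F: Iterable[str] | Iterable[int], rel: BinaryRelation) -> frozenset:
    """Cl(F) = R*(r*(F)).  Accepts labels or integer indices; returns the same kind."""
    F = set(F)
    as_labels = any(isinstance(x, str) for x in F)
    idx = rel.indices_of(F) if as_labels else frozenset(int(i) for i in F)
    for i in idx:
        if not 0 <= i < rel.n:
            raise ValueError(f"index {i} outside universe of size {rel.n}")
    images = [rel.image(i) for i in range(rel.n)]
    out = _closure_indices(idx, images)
    return frozenset(rel.labels_of(out)) if as_labels else out


def _canonical_order(elements: Iterable[frozenset[int]], rel: BinaryRelation):
    return sorted(elements, key=lambda s: (len(s), tuple(sorted(rel.universe1[i] for i in s))))


@dataclass
class RoughLattice:
    """The fixed-point lattice of the closure operator of a relation.

    Elements are frozensets of U1 indices, canonically ordered by
    (cardinality, lexicographic labels).  Meet is the greatest fixed point
    below the intersection; join is the closure of the union.
    """

    relation: BinaryRelation
    elements: tuple[frozenset[int], ...]
    covers: tuple[tuple[int, int], ...] = field(default=())  # (lower, upper) element indices

    @property
    def _element_set(self) -> frozenset[frozenset[int]]:
        return frozenset(self.elements)

    @property
    def bottom(self) -> frozenset[int]:
        return self.elements[0]

    @property
    def top(self) -> frozenset[int]:
        return self.elements[-1]

    def index(self, x: frozenset[int]) -> int:
        return self.elements.index(x)

    def meet(self, x: frozenset[int], y: frozenset[int]) -> frozenset[int]:
        # Cl = R*∘r* arises from an adjunction (r*(F) ⊆ G  ⇔  F ⊆ R*(G)), so
        # fixed points are closed under intersection and meet is exactly x∩y.
        inter = x & y
        if inter in self._element_set:
            return inter
        # fall back to the greatest fixed point below x∩y (defensive; cannot
        # trigger for lattices built by build_lattice)
        return max((el for el in self.elements if el <= inter), key=len)

    def join(self, x: frozenset[int], y: frozenset[int]) -> frozenset[int]:
        return closure(x | y, self.relation)

    def labels(self, x: frozenset[int]) -> tuple[str, ...]:
        return self.relation.labels_of(x)


def build_lattice(rel: BinaryRelation) -> RoughLattice:
    """Enumerate all 2^n subsets of U1 and keep the closure fixed points."""
    n = rel.n
    if n > MAX_UNIVERSE:
        raise ValueError(f"universe of size {n} too large for 2^n enumeration")
    images = [rel.image(i) for i in range(n)]
    fixed: set[frozenset[int]] = set()
    for mask in range(1 << n):
        F = frozenset(i for i in range(n) if mask >> i & 1)
        if _closure_indices(F, images) == F:
            fixed.add(F)
    elements = tuple(_canonical_order(fixed, rel))
    lat = RoughLattice(rel, elements)
    lat.covers = tuple(hasse_edges(lat))
    return lat


def hasse_edges(lat: RoughLattice) -> list[tuple[int, int]]:
    """Cover pairs (i, j): element i ⊂ element j with nothing strictly between."""
    els = lat.elements
    edges = []
    for i, lo in enumerate(els):
        for j, hi in enumerate(els):
            if lo < hi and not any(lo < mid < hi for mid in els):
                edges.append((i, j))
    return edges


@dataclass(frozen=True)
class DistributivityReport:
    distributive: bool
    witness: tuple[frozenset[int], frozenset[int], frozenset[int]] | None = None

    def __bool__(self) -> bool:
        return self.distributive


def check_distributivity(lat: RoughLattice) -> DistributivityReport:
    """Test x∧(y∨z) = (x∧y)∨(x∧z) over all ordered triples of elements."""
    for x in lat.elements:
        for y in lat.elements:
            for z in lat.elements:
                lhs = lat.meet(x, lat.join(y, z))
                rhs = lat.join(lat.meet(x, y), lat.meet(x, z))
                if lhs != rhs:
                    return DistributivityReport(False, (x, y, z))
    return DistributivityReport(True)


def lattice_to_json(lat: RoughLattice) -> str:
    payload = {
        "universe": list(lat.relation.universe1),
        "elements": [list(lat.labels(el)) for el in lat.elements],
        "covers": [list(edge) for edge in lat.covers],
    }
    return json.dumps(payload, indent=2)


def lattice_to_dot(lat: RoughLattice, name: str = "hasse") -> str:
    """Graphviz DOT of the Hasse diagram (covers drawn bottom-up)."""
    def fmt(el: frozenset[int]) -> str:
        return "{" + ",".join(lat.labels(el)) + "}" if el else "∅"

    lines = [f"digraph {name} {{", "  rankdir=BT;", "  node [shape=box];"]
    for i, el in enumerate(lat.elements):
        lines.append(f'  n{i} [label="{fmt(el)}"];')
    for lo, hi in lat.covers:
        lines.append(f"  n{lo} -> n{hi};")
    lines.append("}")
    return "\n".join(lines)
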
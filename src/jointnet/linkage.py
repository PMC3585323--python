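"""Dyadic linkage-vector encoding of two directed binary networks.

Every ordered pair of distinct nodes (i, j) in a two-network system carries
a 4-bit linkage vector ``(x1, x2, x3, x4)`` where ``x1`` indicates an
A-edge i -> j, ``x2`` an A-edge j -> i, ``x3`` a B-edge i -> j and ``x4`` a
B-edge j -> i.  Reading the same dyad from the other side swaps the two
directions of each behavior, the *mirror* map ``(x1,x2,x3,x4) ->
(x2,x1,x4,x3)``; its orbits collapse the 16 states into 10 distinct linkage
classes (4 symmetric, 6 asymmetric).  The tally of linkage vectors over all
ordered pairs is the sufficient statistic for everything downstream.

Three tally conventions are supported:

``paper-n2``
    All n^2 ordered cells are tallied, the n diagonal cells counted as the
    all-zero state.  Class reports give asymmetric classes in one canonical
    orientation only and symmetric classes in full ordered count.  This is
    the convention under which the reference grooming/aggression table is
    reproduced bit-exactly.
``offdiag``
    The n(n-1) ordered off-diagonal cells.
``dyad``
    One canonical orientation per unordered dyad, n(n-1)/2 cells; mirror
    symmetry of the tally is deliberately waived.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

State = tuple[int, int, int, int]

#: All 16 linkage states in lexicographic order.
STATES: tuple[State, ...] = tuple(itertools.product((0, 1), repeat=4))

STATE_INDEX: dict[State, int] = {s: i for i, s in enumerate(STATES)}

#: The 10 class representatives in the row order of the reference table:
#: one-way A, mutual A, one-way B, mutual B, same-direction A+B,
#: opposite-direction A+B, mutual A + one-way B, one-way A + mutual B,
#: all four edges, empty dyad.
TABLE_CLASS_ORDER: tuple[State, ...] = (
    (1, 0, 0, 0),
    (1, 1, 0, 0),
    (0, 0, 1, 0),
    (0, 0, 1, 1),
    (1, 0, 1, 0),
    (1, 0, 0, 1),
    (1, 1, 1, 0),
    (1, 0, 1, 1),
    (1, 1, 1, 1),
    (0, 0, 0, 0),
)

CONVENTIONS = ("paper-n2", "offdiag", "dyad")


def mirror_vector(v: State) -> State:
    """Return the mirror state seen from the dyad's other side.

    Swaps the two directions within each behavior: ``(x1,x2,x3,x4) ->
    (x2,x1,x4,x3)``.  Involutive.
    """
    return (v[1], v[0], v[3], v[2])


def state_label(v: State) -> str:
    return "".join(str(b) for b in v)


def parse_state(label: str) -> State:
    bits = tuple(int(c) for c in label.strip())
    if len(bits) != 4 or any(b not in (0, 1) for b in bits):
        raise ValueError(f"not a 4-bit linkage state: {label!r}")
    return bits  # type: ignore[return-value]


@dataclass(frozen=True)
class LinkageClass:
    """One mirror-equivalence class of linkage vectors."""

    representative: State
    symmetric: bool

    @property
    def members(self) -> tuple[State, ...]:
        m = mirror_vector(self.representative)
        return (self.representative,) if self.symmetric else (self.representative, m)

    @property
    def label(self) -> str:
        return state_label(self.representative)


def canonical_classes() -> list[LinkageClass]:
    """The 10 linkage classes, in reference-table row order.

    The representative of an asymmetric class is the lexicographically
    larger of the two mirror images, which coincides with the orientation
    the reference table prints.
    """
    classes = []
    for rep in TABLE_CLASS_ORDER:
        m = mirror_vector(rep)
        assert rep >= m, "representatives are the lex-larger mirror image"
        classes.append(LinkageClass(representative=rep, symmetric=(m == rep)))
    return classes


@dataclass(frozen=True)
class DirectedBinaryNetwork:
    """A directed binary network: ordered node tuple plus a set of edges.

    Self-loops are rejected; every edge endpoint must be a declared node.
    Edge weights carry no meaning here — presence and direction only.
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node identifiers")
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop {u!r}->{v!r} not allowed")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge endpoint outside node set: {(u, v)!r}")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Sequence[str] | None = None,
        drop_self_loops: bool = False,
    ) -> "DirectedBinaryNetwork":
        """Build a network, optionally dropping self-loops with a warning."""
        kept = []
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                if drop_self_loops:
                    warnings.warn(f"dropping self-loop {u!r}->{u!r}")
                    continue
                raise ValueError(f"self-loop {u!r}->{u!r} not allowed")
            kept.append((u, v))
        if nodes is None:
            seen: dict[str, None] = {}
            for u, v in kept:
                seen.setdefault(u)
                seen.setdefault(v)
            nodes = tuple(seen)
        return cls(nodes=tuple(str(n) for n in nodes), edges=frozenset(kept))

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    def density(self) -> float:
        """Directed density m / n^2 (total edges over all ordered cells)."""
        return self.edge_count / self.n**2 if self.n else 0.0


@dataclass
class MarginalRates:
    """Per-ordered-pair edge probabilities for the two networks."""

    pA: float
    pB: float

    def __post_init__(self) -> None:
        for name, p in (("pA", self.pA), ("pB", self.pB)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")


@dataclass
class LinkageTally:
    """Counts of the 16 ordered linkage states.

    ``counts`` maps every state to a nonnegative integer of ordered cells;
    under ``paper-n2`` and ``offdiag`` the tally is mirror-symmetric.
    """

    n: int
    counts: dict[State, int]
    convention: str = "paper-n2"

    def __post_init__(self) -> None:
        if self.convention not in CONVENTIONS:
            raise ValueError(f"unknown convention {self.convention!r}")
        full = {s: int(self.counts.get(s, 0)) for s in STATES}
        if any(c < 0 for c in full.values()):
            raise ValueError("negative count")
        self.counts = full
        expected_total = self.total_cells
        got = sum(full.values())
        if got != expected_total:
            raise ValueError(
                f"tally totals {got}, but convention {self.convention!r} with "
                f"n={self.n} requires {expected_total}"
            )
        if self.convention != "dyad":
            for s in STATES:
                if full[s] != full[mirror_vector(s)]:
                    raise ValueError(
                        f"mirror symmetry violated at state {state_label(s)}"
                    )

    @property
    def total_cells(self) -> int:
        if self.convention == "paper-n2":
            return self.n**2
        if self.convention == "offdiag":
            return self.n * (self.n - 1)
        return self.n * (self.n - 1) // 2

    def as_vector(self) -> list[int]:
        return [self.counts[s] for s in STATES]

    @classmethod
    def from_class_counts(
        cls,
        class_counts: Mapping[State, int] | Sequence[int],
        n: int,
        convention: str = "paper-n2",
    ) -> "LinkageTally":
        """Expand 10-class representative counts into the 16-state tally.

        Asymmetric classes are duplicated into both orientations; symmetric
        classes are taken as full ordered counts.  Under ``paper-n2`` the n
        diagonal cells must already be included in the all-zero count.
        """
        if not isinstance(class_counts, Mapping):
            class_counts = dict(zip(TABLE_CLASS_ORDER, class_counts))
        counts: dict[State, int] = {s: 0 for s in STATES}
        for rep, c in class_counts.items():
            counts[rep] = int(c)
            m = mirror_vector(rep)
            if m != rep:
                counts[m] = int(c)
        return cls(n=n, counts=counts, convention=convention)


def _adjacency_bit(net: DirectedBinaryNetwork, i: str, j: str) -> int:
    return 1 if (i, j) in net.edges else 0


def _resolve_nodes(
    netA: DirectedBinaryNetwork,
    netB: DirectedBinaryNetwork,
    policy: str | Sequence[str],
) -> tuple[str, ...]:
    if not isinstance(policy, str):
        explicit = tuple(str(x) for x in policy)
        allowed = set(explicit)
        for name, net in (("A", netA), ("B", netB)):
            for u, v in net.edges:
                if u not in allowed or v not in allowed:
                    raise ValueError(
                        f"network {name} edge {(u, v)!r} has endpoint outside "
                        "the explicit node list"
                    )
        return explicit
    if policy == "union":
        seen = dict.fromkeys(netA.nodes)
        for x in netB.nodes:
            seen.setdefault(x)
        return tuple(seen)
    if policy == "intersection":
        bset = set(netB.nodes)
        return tuple(x for x in netA.nodes if x in bset)
    raise ValueError(f"unknown node policy {policy!r}")


def build_tally(
    netA: DirectedBinaryNetwork,
    netB: DirectedBinaryNetwork,
    nodes: str | Sequence[str] = "union",
    convention: str = "paper-n2",
) -> LinkageTally:
    """Tally the linkage vector of every ordered node pair.

    ``nodes`` is a policy (``"union"``, ``"intersection"``) or an explicit
    node sequence.  Under ``intersection`` or an explicit list, edges with
    endpoints outside the resolved node set raise (explicit list) or are
    silently out of frame (intersection — a deliberate restriction of the
    observation window, logged).

    Under the ``dyad`` convention each unordered pair contributes a single
    cell in the canonical orientation given by the resolved node order.
    """
    node_order = _resolve_nodes(netA, netB, nodes)
    if isinstance(nodes, str) and nodes == "intersection":
        dropped = (
            {u for e in netA.edges | netB.edges for u in e} - set(node_order)
        )
        if dropped:
            log.info("intersection policy drops %d node(s) from frame", len(dropped))
        in_frame = set(node_order)
        netA = DirectedBinaryNetwork(
            nodes=node_order,
            edges=frozenset(e for e in netA.edges if set(e) <= in_frame),
        )
        netB = DirectedBinaryNetwork(
            nodes=node_order,
            edges=frozenset(e for e in netB.edges if set(e) <= in_frame),
        )
    counts: dict[State, int] = {s: 0 for s in STATES}
    for a, i in enumerate(node_order):
        for b, j in enumerate(node_order):
            if a == b:
                continue
            if convention == "dyad" and a > b:
                continue
            state = (
                _adjacency_bit(netA, i, j),
                _adjacency_bit(netA, j, i),
                _adjacency_bit(netB, i, j),
                _adjacency_bit(netB, j, i),
            )
            counts[state] += 1
    if convention == "paper-n2":
        counts[(0, 0, 0, 0)] += len(node_order)
    return LinkageTally(n=len(node_order), counts=counts, convention=convention)


def class_observed_counts(tally: LinkageTally) -> dict[State, int]:
    """Collapse a tally to 10-class observed counts, representative keyed.

    Asymmetric classes report one orientation only (the number of unordered
    dyads in that configuration); symmetric classes report the full ordered
    count.  Row order follows :data:`TABLE_CLASS_ORDER`.
    """
    return {cl.representative: tally.counts[cl.representative] for cl in canonical_classes()}


def implied_edge_totals(tally: LinkageTally) -> tuple[int, int]:
    """Directed edge totals (mA, mB) implied by the full 16-state tally."""
    scale = 2 if tally.convention == "dyad" else 1
    mA = sum(c * s[0] for s, c in tally.counts.items())
    mB = sum(c * s[2] for s, c in tally.counts.items())
    if tally.convention == "dyad":
        # one orientation per dyad: both directions of each behavior count
        mA = sum(c * (s[0] + s[1]) for s, c in tally.counts.items())
        mB = sum(c * (s[2] + s[3]) for s, c in tally.counts.items())
        del scale
    return mA, mB


def estimate_marginals(tally: LinkageTally) -> MarginalRates:
    """Per-direction edge rates: implied edge totals over total cells.

    Under ``paper-n2`` this is m / n^2, the network density over all
    ordered cells; under ``offdiag`` m / n(n-1).
    """
    N = tally.total_cells
    if N == 0:
        raise ValueError("empty tally: no cells")
    mA, mB = implied_edge_totals(tally)
    if tally.convention == "dyad":
        return MarginalRates(pA=mA / (2 * N), pB=mB / (2 * N))
    return MarginalRates(pA=mA / N, pB=mB / N)
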
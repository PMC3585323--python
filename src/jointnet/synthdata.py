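"""Synthetic paired-network generation and parameter recovery.

The generator draws iid dyads from a mirror-symmetric 16-state joint
distribution in the tilted-exponential family: an independence null at the
configured marginal rates, optionally tilted by a sequence of (constraint,
multiplier) pairs.  Sampling is at the *dyad* level — each of the
n(n-1)/2 unordered pairs is assigned a linkage class, and asymmetric
classes get a fair-coin orientation — so the diagonal is never sampled and
recovery experiments tally under the ``offdiag`` convention.

Also houses the packaged reference fixture: the observed 10-class counts
of the 2009 grooming/aggression networks of a 77-member rhesus macaque
group, the worked example every reproduction test runs from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .linkage import (
    STATES,
    STATE_INDEX,
    DirectedBinaryNetwork,
    LinkageTally,
    MarginalRates,
    State,
    TABLE_CLASS_ORDER,
    build_tally,
    canonical_classes,
    mirror_vector,
)
from .maxent import (
    CellDistribution,
    ConstraintFunction,
    independence_distribution,
    sequential_fit,
    tilt,
)

# Observed 10-class counts for the 2009 grooming (A) / aggression (B)
# networks of group "14B" (n = 77), ordered-cell convention with the 77
# diagonal cells included in the all-zero class.
TABLE1_CLASS_COUNTS: tuple[int, ...] = (100, 28, 435, 154, 10, 28, 8, 5, 0, 4575)
TABLE1_N = 77


def table1_fixture() -> tuple[LinkageTally, dict[State, int]]:
    """The packaged grooming/aggression worked-example tally.

    Returns the full 16-state tally (``paper-n2`` convention, 5929 cells)
    and the 10-class observed counts keyed by class representative.
    """
    tally = LinkageTally.from_class_counts(
        dict(zip(TABLE_CLASS_ORDER, TABLE1_CLASS_COUNTS)),
        n=TABLE1_N,
        convention="paper-n2",
    )
    return tally, dict(zip(TABLE_CLASS_ORDER, TABLE1_CLASS_COUNTS))


@dataclass
class GeneratorConfig:
    """Configuration of the dyad-level paired-network generator."""

    n: int
    base_rates: MarginalRates
    tilts: list[tuple[ConstraintFunction, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 nodes")

    def distribution(self) -> CellDistribution:
        dist = independence_distribution(self.base_rates)
        for f, lam in self.tilts:
            dist, _ = tilt(dist, f, lam)
        return dist


def dyad_distribution(dist: CellDistribution) -> dict[State, float]:
    """Collapse a mirror-symmetric 16-state distribution to dyad level.

    A dyad's class probability folds both orientations: 2 p(rep) for
    asymmetric classes, p(rep) for symmetric ones.  Sums to 1.
    """
    if not dist.is_mirror_symmetric(atol=1e-9):
        raise ValueError("dyad collapse requires a mirror-symmetric distribution")
    out: dict[State, float] = {}
    for cl in canonical_classes():
        p = dist[cl.representative]
        out[cl.representative] = p if cl.symmetric else 2.0 * p
    return out


def _place_dyad(
    state: State, i: str, j: str, edgesA: list, edgesB: list
) -> None:
    x1, x2, x3, x4 = state
    if x1:
        edgesA.append((i, j))
    if x2:
        edgesA.append((j, i))
    if x3:
        edgesB.append((i, j))
    if x4:
        edgesB.append((j, i))


def sample_networks(
    config: GeneratorConfig,
) -> tuple[DirectedBinaryNetwork, DirectedBinaryNetwork]:
    """Sample a paired network from the configured dyad distribution.

    Each unordered dyad draws a linkage class independently; asymmetric
    classes are oriented by a fair coin from the same random stream.
    Fully reproducible given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    classes = canonical_classes()
    pd_ = dyad_distribution(config.distribution())
    probs = np.array([pd_[cl.representative] for cl in classes])
    probs = probs / probs.sum()
    nodes = tuple(f"v{k}" for k in range(config.n))
    edgesA: list[tuple[str, str]] = []
    edgesB: list[tuple[str, str]] = []
    pairs = [
        (nodes[a], nodes[b])
        for a in range(config.n)
        for b in range(a + 1, config.n)
    ]
    draws = rng.choice(len(classes), size=len(pairs), p=probs)
    flips = rng.random(len(pairs)) < 0.5
    for (i, j), k, flip in zip(pairs, draws, flips):
        cl = classes[k]
        state = cl.representative
        if not cl.symmetric and flip:
            state = mirror_vector(state)
        _place_dyad(state, i, j, edgesA, edgesB)
    netA = DirectedBinaryNetwork(nodes=nodes, edges=frozenset(edgesA))
    netB = DirectedBinaryNetwork(nodes=nodes, edges=frozenset(edgesB))
    return netA, netB


@dataclass
class RecoveryReport:
    """True vs. estimated multipliers from one synthetic refit."""

    names: list[str]
    true_lambdas: list[float]
    estimates: list[float]
    abs_errors: list[float]
    dyad_count: int
    seed: int


def recovery_experiment(
    config: GeneratorConfig,
    constraints: Sequence[Callable],
) -> RecoveryReport:
    """Sample networks, tally off-diagonal, refit, compare multipliers.

    ``constraints`` are builders mirroring the generating tilts'
    functional forms (same order).  The fit runs all constraints with the
    stopping rule disabled so every multiplier is estimated.
    """
    if len(constraints) != len(config.tilts):
        raise ValueError("one constraint builder per generating tilt required")
    netA, netB = sample_networks(config)
    tally = build_tally(netA, netB, nodes="union", convention="offdiag")
    traj = sequential_fit(tally, list(constraints), stop_early=False)
    fitted = [s.fitted for s in traj.steps[1:]]
    true = [lam for _, lam in config.tilts]
    est = [fc.lam for fc in fitted]
    return RecoveryReport(
        names=[fc.constraint.name for fc in fitted],
        true_lambdas=true,
        estimates=est,
        abs_errors=[abs(t - e) for t, e in zip(true, est)],
        dyad_count=config.n * (config.n - 1) // 2,
        seed=config.seed,
    )


def networks_from_class_counts(
    class_counts: Sequence[int] | dict[State, int],
    n: int,
) -> tuple[DirectedBinaryNetwork, DirectedBinaryNetwork]:
    """Deterministically realize networks with the given dyad census.

    Places the required number of dyads of each class, in class order,
    onto the lexicographic sequence of unordered pairs of ``n`` nodes.
    Symmetric-class counts are full ordered counts (so mutual classes
    occupy count/2 dyads; the all-zero count includes the n diagonal
    cells).  Re-tallying under ``paper-n2`` reproduces the input exactly.
    """
    if not isinstance(class_counts, dict):
        class_counts = dict(zip(TABLE_CLASS_ORDER, class_counts))
    dyad_counts: dict[State, int] = {}
    for cl in canonical_classes():
        c = int(class_counts.get(cl.representative, 0))
        if cl.symmetric:
            if cl.representative == (0, 0, 0, 0):
                c = c - n  # diagonal cells live in the all-zero class
            if c % 2:
                raise ValueError(
                    f"symmetric class {cl.label} needs an even ordered count"
                )
            c //= 2
        dyad_counts[cl.representative] = c
    total_dyads = sum(dyad_counts.values())
    if total_dyads != n * (n - 1) // 2:
        raise ValueError(
            f"class counts imply {total_dyads} dyads but n={n} has {n*(n-1)//2}"
        )
    nodes = tuple(f"v{k}" for k in range(n))
    pairs = iter(
        (nodes[a], nodes[b]) for a in range(n) for b in range(a + 1, n)
    )
    edgesA: list[tuple[str, str]] = []
    edgesB: list[tuple[str, str]] = []
    for rep, c in dyad_counts.items():
        for _ in range(c):
            i, j = next(pairs)
            _place_dyad(rep, i, j, edgesA, edgesB)
    netA = DirectedBinaryNetwork(nodes=nodes, edges=frozenset(edgesA))
    netB = DirectedBinaryNetwork(nodes=nodes, edges=frozenset(edgesB))
    return netA, netB
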
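"""Maximum-entropy model core: independence null, constraint functions,
exponential tilting with moment-matched Lagrange multipliers, and the
chi-squared stopping rule.

The model family lives on the 16 linkage states.  Step 0 is the
independence null p0(v) = pA^(x1+x2) (1-pA)^(2-x1-x2) pB^(x3+x4)
(1-pB)^(2-x3-x4) built from the two network densities.  Each constraint
function f is then accommodated by tilting the current model,

    p'(v) = p(v) exp(lambda f(v)) / Z(lambda),

with lambda solved so the tilted mean E'[f] equals the empirical mean of f
under the observed tally (the tilted distribution is the I-projection of
the current model onto the moment constraint: closest in KL divergence
among all distributions matching it).  Earlier multipliers stay frozen —
each accommodated model becomes the null of the next step.  Iteration stops
when the 10-class total chi-squared falls below a critical chi-squared
percentile (df 9 by default: 16 states collapse to 10 distinct classes).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .linkage import (
    STATES,
    STATE_INDEX,
    LinkageTally,
    MarginalRates,
    State,
    canonical_classes,
    class_observed_counts,
    estimate_marginals,
    mirror_vector,
    state_label,
)

log = logging.getLogger(__name__)

_X = np.array(STATES, dtype=float)  # (16, 4) design matrix of indicators
_MIRROR_PERM = np.array([STATE_INDEX[mirror_vector(s)] for s in STATES])


@dataclass
class CellDistribution:
    """A probability vector over the 16 linkage states."""

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (16,):
            raise ValueError("need exactly 16 cell probabilities")
        if np.any(p < 0):
            raise ValueError("negative probability")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {p.sum()}, not 1")
        self.probabilities = p

    def __getitem__(self, v: State) -> float:
        return float(self.probabilities[STATE_INDEX[v]])

    def is_mirror_symmetric(self, atol: float = 1e-12) -> bool:
        return bool(
            np.allclose(self.probabilities, self.probabilities[_MIRROR_PERM], atol=atol)
        )


@dataclass
class ConstraintFunction:
    """A real-valued function on the 16 linkage states.

    ``values`` holds f(v) per state in lexicographic state order;
    ``centering`` records the constants used in construction so that fitted
    models can be serialized and rebuilt exactly.
    """

    name: str
    values: np.ndarray
    centering: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (16,):
            raise ValueError("need exactly 16 values")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite constraint value")
        self.values = v

    def __call__(self, state: State) -> float:
        return float(self.values[STATE_INDEX[state]])

    def is_mirror_invariant(self, atol: float = 1e-12) -> bool:
        return bool(np.allclose(self.values, self.values[_MIRROR_PERM], atol=atol))

    @classmethod
    def from_callable(
        cls, name: str, fn: Callable[[State], float], centering: dict | None = None
    ) -> "ConstraintFunction":
        return cls(
            name=name,
            values=np.array([fn(s) for s in STATES], dtype=float),
            centering=centering or {},
        )


@dataclass
class FittedConstraint:
    """A constraint with its solved multiplier and tilt bookkeeping."""

    constraint: ConstraintFunction
    lam: float
    partition_value: float
    mean_zero_deviation: float
    empirical_target: float


@dataclass
class MaxEntModel:
    """Independence base plus an ordered stack of fitted tilts."""

    base: CellDistribution
    fitted: list[FittedConstraint]
    current: CellDistribution


@dataclass
class TrajectoryStep:
    label: str
    fitted: FittedConstraint | None
    expected: dict[State, float]
    chisq_cells: dict[State, float]
    total_chisq: float
    distribution: CellDistribution


@dataclass
class FitTrajectory:
    """Ordered record of the sequential accommodation, step 0 = null."""

    steps: list[TrajectoryStep]
    stopped_early: bool
    critical_value_used: float
    observed: dict[State, int]
    n_cells: int

    @property
    def totals(self) -> list[float]:
        return [s.total_chisq for s in self.steps]

    @property
    def model(self) -> MaxEntModel:
        return MaxEntModel(
            base=self.steps[0].distribution,
            fitted=[s.fitted for s in self.steps[1:] if s.fitted is not None],
            current=self.steps[-1].distribution,
        )


def independence_distribution(rates: MarginalRates) -> CellDistribution:
    """Product null: the four edge indicators independent at their rates."""
    pA, pB = rates.pA, rates.pB
    probs = (
        np.where(_X[:, 0] == 1, pA, 1 - pA)
        * np.where(_X[:, 1] == 1, pA, 1 - pA)
        * np.where(_X[:, 2] == 1, pB, 1 - pB)
        * np.where(_X[:, 3] == 1, pB, 1 - pB)
    )
    return CellDistribution(probabilities=probs)


def f_reciprocity(which_network: str, rate: float) -> ConstraintFunction:
    """Centered-product reciprocity constraint for one network.

    For network A: f(v) = (x1 - rate)(x2 - rate); for B the same on
    (x3, x4).  Exactly mean-zero whenever the two directions are
    independent with marginal ``rate``, so it is perpendicular to the
    matching independence null; a positive multiplier rewards mutual edges.
    """
    which = which_network.upper()
    if which not in ("A", "B"):
        raise ValueError("which_network must be 'A' or 'B'")
    i, j = (0, 1) if which == "A" else (2, 3)
    values = (_X[:, i] - rate) * (_X[:, j] - rate)
    return ConstraintFunction(
        name=f"reciprocity_{which}",
        values=values,
        centering={"rate": rate, "network": which},
    )


def f_opposition() -> ConstraintFunction:
    """Cross-network direction-opposition constraint.

    f(v) = (x1 - x2)(x4 - x3): +1 exactly on the two opposite-direction
    one-way states (1001, 0110), -1 on the same-direction ones (1010,
    0101), 0 elsewhere.  Mean-zero under any mirror-symmetric model with
    independent A and B blocks.
    """
    values = (_X[:, 0] - _X[:, 1]) * (_X[:, 3] - _X[:, 2])
    return ConstraintFunction(name="opposition", values=values, centering={})


def f_presence_covariance(a: float, b: float) -> ConstraintFunction:
    """Cross-network presence-covariance constraint.

    f(v) = (max(x1,x2) - a)(max(x3,x4) - b): positive when both behaviors
    or neither are present on the dyad, negative when exactly one is.  The
    centering constants a, b are the reference probabilities of "any
    A-edge" / "any B-edge" on a dyad cell.
    """
    if not (0.0 <= a <= 1.0 and 0.0 <= b <= 1.0):
        raise ValueError("centering constants must lie in [0, 1]")
    anyA = np.maximum(_X[:, 0], _X[:, 1])
    anyB = np.maximum(_X[:, 2], _X[:, 3])
    values = (anyA - a) * (anyB - b)
    return ConstraintFunction(
        name="presence_covariance", values=values, centering={"a": a, "b": b}
    )


def empirical_mean(f: ConstraintFunction, tally: LinkageTally) -> float:
    """Mean of f under the empirical cell distribution of the tally."""
    counts = np.array(tally.as_vector(), dtype=float)
    N = counts.sum()
    if N == 0:
        raise ValueError("empty tally")
    return float(counts @ f.values / N)


def model_mean(f: ConstraintFunction, dist: CellDistribution) -> float:
    return float(dist.probabilities @ f.values)


def tilt(
    dist: CellDistribution, f: ConstraintFunction, lam: float
) -> tuple[CellDistribution, float]:
    """Exponentially tilt ``dist`` by ``exp(lam * f)`` and renormalize.

    Returns the tilted distribution and the partition value
    Z = sum_v p(v) exp(lam f(v)).  Computed with max-subtraction so large
    multipliers cannot overflow.
    """
    logw = lam * f.values
    shift = logw.max()
    w = dist.probabilities * np.exp(logw - shift)
    total = w.sum()
    if total <= 0:
        raise ValueError("tilt annihilated all probability mass")
    Z = float(total * np.exp(shift))
    return CellDistribution(probabilities=w / total), Z


def solve_lambda(
    dist: CellDistribution,
    f: ConstraintFunction,
    target: float,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> float:
    """Solve for the multiplier matching the tilted mean to ``target``.

    The map lambda -> E_tilt[f] is d log Z / d lambda, strictly increasing
    with derivative Var_tilt[f] > 0 whenever f is non-degenerate on the
    support of ``dist``, so the root is unique.  Solved by bracketed Brent
    iteration with automatic bracket expansion from [-1, 1].
    """
    support = dist.probabilities > 0
    fvals = f.values[support]
    lo_attain, hi_attain = fvals.min(), fvals.max()
    if hi_attain - lo_attain < 1e-15:
        raise ValueError(
            f"constraint {f.name!r} is degenerate (constant on the model support)"
        )
    if not (lo_attain < target < hi_attain):
        raise ValueError(
            f"target {target} for {f.name!r} outside the attainable open "
            f"interval ({lo_attain}, {hi_attain})"
        )

    def residual(lam: float) -> float:
        return model_mean(f, tilt(dist, f, lam)[0]) - target

    lo, hi = -1.0, 1.0
    it = 0
    while residual(lo) > 0:
        lo *= 2.0
        it += 1
        if it > max_iter:
            raise RuntimeError("bracket expansion failed (low side)")
    it = 0
    while residual(hi) < 0:
        hi *= 2.0
        it += 1
        if it > max_iter:
            raise RuntimeError("bracket expansion failed (high side)")
    lam = optimize.brentq(residual, lo, hi, xtol=tol, maxiter=max_iter)
    return float(lam)


def expected_class_counts(dist: CellDistribution, N: float) -> dict[State, float]:
    """Expected 10-class counts at N total cells, representative keyed.

    Uses the same representative-orientation convention as the observed
    class counts: a class's expectation is N * p(representative), so
    asymmetric classes count one orientation only.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    return {
        cl.representative: N * dist[cl.representative] for cl in canonical_classes()
    }


def chisq_table(
    observed: Mapping[State, float], expected: Mapping[State, float]
) -> tuple[dict[State, float], float]:
    """Per-class (O - E)^2 / E cells and their total.

    Classes with O = E = 0 are excluded with a warning; E = 0 with O > 0 is
    an error (infinite discrepancy).
    """
    if set(observed) != set(expected):
        raise ValueError("observed and expected class sets differ")
    cells: dict[State, float] = {}
    total = 0.0
    for v, o in observed.items():
        e = expected[v]
        if e == 0:
            if o == 0:
                warnings.warn(
                    f"class {state_label(v)} has zero observed and expected "
                    "counts; excluded from chi-squared"
                )
                continue
            raise ValueError(
                f"expected count 0 with observed {o} in class {state_label(v)}"
            )
        cells[v] = (o - e) ** 2 / e
        total += cells[v]
    return cells, total


def critical_value(df: int, level: float) -> float:
    """Upper chi-squared quantile used by the stopping rule."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    return float(stats.chi2.ppf(level, df))


def mean_zero_deviation(f: ConstraintFunction, dist: CellDistribution) -> float:
    """E[f] under the pre-tilt model — recorded as a diagnostic.

    A constraint perpendicular to the current model has mean zero; a
    nonzero value means part of f's direction is already present.  Additive
    re-centering would not change the fitted tilt (constants are absorbed
    by the partition value and cancel in the moment constraint), so the
    deviation is logged rather than enforced.
    """
    return model_mean(f, dist)


# ---------------------------------------------------------------------------
# Constraint builders for the sequential fit.
#
# A builder receives the current model and the tally and returns the
# ConstraintFunction for the next accommodation, so centering constants can
# be drawn from current-model quantities.  The standard sequence f1-f4 is
# registered by name.

ConstraintBuilder = Callable[[CellDistribution, LinkageTally], ConstraintFunction]

_ANY_A = np.maximum(_X[:, 0], _X[:, 1])
_ANY_B = np.maximum(_X[:, 2], _X[:, 3])


def build_f1(current: CellDistribution, tally: LinkageTally) -> ConstraintFunction:
    """Reciprocity in network A, centered at the current A marginal."""
    rate = float(current.probabilities @ _X[:, 0])
    return f_reciprocity("A", rate)


def build_f2(current: CellDistribution, tally: LinkageTally) -> ConstraintFunction:
    """Reciprocity in network B, centered at the current B marginal."""
    rate = float(current.probabilities @ _X[:, 2])
    return f_reciprocity("B", rate)


def build_f3(current: CellDistribution, tally: LinkageTally) -> ConstraintFunction:
    return f_opposition()


def build_f4_model(current: CellDistribution, tally: LinkageTally) -> ConstraintFunction:
    """Presence covariance centered at the current model's any-edge rates."""
    a = float(current.probabilities @ _ANY_A)
    b = float(current.probabilities @ _ANY_B)
    return f_presence_covariance(a, b)


def build_f4_table_compat(
    current: CellDistribution, tally: LinkageTally
) -> ConstraintFunction:
    """Presence covariance with the reference-table-compatible centering.

    a is the current model's any-A rate; b is the empirical frequency of
    one-way-B-only cells.  Back-solving the published expected-count column
    identifies this centering; the model-based one in
    :func:`build_f4_model` is the principled default.
    """
    a = float(current.probabilities @ _ANY_A)
    counts = np.array(tally.as_vector(), dtype=float)
    b = float(
        (counts[STATE_INDEX[(0, 0, 1, 0)]] + counts[STATE_INDEX[(0, 0, 0, 1)]])
        / counts.sum()
    )
    return f_presence_covariance(a, b)


def standard_constraints(centering: str = "model") -> list[ConstraintBuilder]:
    """The published four-constraint sequence f1, f2, f3, f4."""
    f4 = {"model": build_f4_model, "paper-table-1-compat": build_f4_table_compat}
    try:
        return [build_f1, build_f2, build_f3, f4[centering]]
    except KeyError:
        raise ValueError(f"unknown centering policy {centering!r}") from None


CONSTRAINT_REGISTRY: dict[str, ConstraintBuilder] = {
    "f1": build_f1,
    "f2": build_f2,
    "f3": build_f3,
    "f4": build_f4_model,
    "f4-table-compat": build_f4_table_compat,
}


def sequential_fit(
    tally: LinkageTally,
    constraints: Sequence[ConstraintBuilder],
    df: int = 9,
    level: float = 0.99,
    stop_early: bool = True,
) -> FitTrajectory:
    """Greedy sequential accommodation with frozen earlier multipliers.

    Step 0 is the independence null at the tally's marginal rates.  Each
    subsequent step builds the next constraint against the current model,
    records its mean-zero deviation, solves the multiplier by moment
    matching against the constraint's empirical mean, and recomputes the
    10-class chi-squared table.  Stops early when the total drops below
    ``critical_value(df, level)`` (set ``stop_early=False`` to force all
    constraints, e.g. in recovery experiments).

    The df default of 9 follows from the 10 distinct classes and is not
    adjusted for the number of fitted constraints.
    """
    if not constraints:
        raise ValueError("need at least one constraint builder")
    if df != 9:
        log.warning("df=%d: the 10-class table conventionally uses df=9", df)
    observed = class_observed_counts(tally)
    N = float(tally.total_cells)
    crit = critical_value(df, level)

    current = independence_distribution(estimate_marginals(tally))
    expected = expected_class_counts(current, N)
    cells, total = chisq_table(observed, expected)
    steps = [
        TrajectoryStep(
            label="indep",
            fitted=None,
            expected=expected,
            chisq_cells=cells,
            total_chisq=total,
            distribution=current,
        )
    ]
    stopped_early = total < crit and stop_early
    if not stopped_early:
        for k, builder in enumerate(constraints, start=1):
            f = builder(current, tally)
            deviation = mean_zero_deviation(f, current)
            target = empirical_mean(f, tally)
            lam = solve_lambda(current, f, target)
            current, Z = tilt(current, f, lam)
            log.info(
                "step %d (%s): lambda=%.6g Z=%.6g mean-zero deviation=%.3g",
                k,
                f.name,
                lam,
                Z,
                deviation,
            )
            expected = expected_class_counts(current, N)
            cells, total = chisq_table(observed, expected)
            steps.append(
                TrajectoryStep(
                    label=f.name,
                    fitted=FittedConstraint(
                        constraint=f,
                        lam=lam,
                        partition_value=Z,
                        mean_zero_deviation=deviation,
                        empirical_target=target,
                    ),
                    expected=expected,
                    chisq_cells=cells,
                    total_chisq=total,
                    distribution=current,
                )
            )
            if stop_early and total < crit:
                stopped_early = k < len(constraints)
                break
    return FitTrajectory(
        steps=steps,
        stopped_early=stopped_early,
        critical_value_used=crit,
        observed=observed,
        n_cells=int(N),
    )


def joint_refit(
    tally: LinkageTally,
    constraints: Sequence[ConstraintBuilder],
    max_cycles: int = 200,
    tol: float = 1e-10,
) -> MaxEntModel:
    """Cyclic coordinate ascent to *simultaneous* moment matching.

    A non-standard alternative to :func:`sequential_fit`: constraint
    functions are built once against the independence null, then their
    multipliers are cycled until every moment matches its empirical target.
    """
    base = independence_distribution(estimate_marginals(tally))
    funcs = [b(base, tally) for b in constraints]
    targets = [empirical_mean(f, tally) for f in funcs]
    lams = [0.0] * len(funcs)

    def rebuild() -> CellDistribution:
        logw = sum(l * f.values for l, f in zip(lams, funcs))
        w = base.probabilities * np.exp(logw - np.max(logw))
        return CellDistribution(probabilities=w / w.sum())

    current = base
    for _ in range(max_cycles):
        for k, (f, t) in enumerate(zip(funcs, targets)):
            others = rebuild()
            # remove k's own contribution, then re-solve it
            logw = -lams[k] * f.values
            w = others.probabilities * np.exp(logw - logw.max())
            stripped = CellDistribution(probabilities=w / w.sum())
            lams[k] = solve_lambda(stripped, f, t)
        current = rebuild()
        # residuals measured only after the full cycle: each coordinate
        # update perturbs the moments solved before it
        worst = max(
            abs(model_mean(f, current) - t) for f, t in zip(funcs, targets)
        )
        if worst < tol:
            break
    fitted = [
        FittedConstraint(
            constraint=f,
            lam=l,
            partition_value=float("nan"),
            mean_zero_deviation=mean_zero_deviation(f, base),
            empirical_target=t,
        )
        for f, l, t in zip(funcs, lams, targets)
    ]
    return MaxEntModel(base=base, fitted=fitted, current=current)


# ---------------------------------------------------------------------------
# Serialization


def model_to_json(model: MaxEntModel) -> str:
    payload = {
        "base_probabilities": [repr(float(p)) for p in model.base.probabilities],
        "constraints": [
            {
                "name": fc.constraint.name,
                "values": [repr(float(v)) for v in fc.constraint.values],
                "centering": fc.constraint.centering,
                "lambda": repr(fc.lam),
                "partition_value": repr(fc.partition_value),
                "mean_zero_deviation": repr(fc.mean_zero_deviation),
                "empirical_target": repr(fc.empirical_target),
            }
            for fc in model.fitted
        ],
        "cell_probabilities": {
            state_label(s): repr(float(model.current.probabilities[i]))
            for i, s in enumerate(STATES)
        },
    }
    return json.dumps(payload, indent=2)


def model_from_json(text: str) -> MaxEntModel:
    payload = json.loads(text)
    base = CellDistribution(
        probabilities=np.array([float(x) for x in payload["base_probabilities"]])
    )
    fitted = []
    current = base
    for c in payload["constraints"]:
        f = ConstraintFunction(
            name=c["name"],
            values=np.array([float(v) for v in c["values"]]),
            centering=c["centering"],
        )
        lam = float(c["lambda"])
        current, _ = tilt(current, f, lam)
        fitted.append(
            FittedConstraint(
                constraint=f,
                lam=lam,
                partition_value=float(c["partition_value"]),
                mean_zero_deviation=float(c["mean_zero_deviation"]),
                empirical_target=float(c["empirical_target"]),
            )
        )
    stored = np.array(
        [float(payload["cell_probabilities"][state_label(s)]) for s in STATES]
    )
    if not np.allclose(stored, current.probabilities, atol=1e-12):
        raise ValueError("stored cell probabilities disagree with the tilt stack")
    return MaxEntModel(base=base, fitted=fitted, current=CellDistribution(stored))
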
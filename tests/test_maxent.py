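"""Maximum-entropy core: null model, constraints, tilts, sequential fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from jointnet.linkage import STATES, MarginalRates, state_label
from jointnet.maxent import (
    CellDistribution,
    ConstraintFunction,
    build_f4_model,
    build_f4_table_compat,
    chisq_table,
    critical_value,
    empirical_mean,
    expected_class_counts,
    f_opposition,
    f_presence_covariance,
    f_reciprocity,
    independence_distribution,
    joint_refit,
    mean_zero_deviation,
    model_from_json,
    model_mean,
    model_to_json,
    sequential_fit,
    solve_lambda,
    standard_constraints,
    tilt,
)
from jointnet.synthdata import table1_fixture

_X = np.array(STATES, dtype=float)


# --- independence null -----------------------------------------------------

def test_degenerate_rates_put_all_mass_on_empty_state():
    dist = independence_distribution(MarginalRates(pA=0.0, pB=0.0))
    assert dist[(0, 0, 0, 0)] == 1.0


def test_independence_expected_counts_match_published_null(fixture_tally):
    rates = MarginalRates(pA=187 / 5929, pB=645 / 5929)
    dist = independence_distribution(rates)
    expected = expected_class_counts(dist, 5929)
    assert expected[(0, 0, 0, 0)] == pytest.approx(4416.80, abs=0.02)
    assert expected[(1, 1, 0, 0)] == pytest.approx(4.68, abs=0.02)
    assert expected[(1, 0, 0, 0)] == pytest.approx(143.84, abs=0.02)


# --- constraint functions --------------------------------------------------

def test_reciprocity_values_by_substitution():
    p = 0.3
    f = f_reciprocity("A", p)
    assert f((1, 1, 0, 0)) == pytest.approx((1 - p) ** 2)
    assert f((0, 0, 1, 1)) == pytest.approx(p**2)
    dist = independence_distribution(MarginalRates(pA=p, pB=0.7))
    assert model_mean(f, dist) == pytest.approx(0.0, abs=1e-14)


def test_opposition_sign_pattern_and_block_independence_mean_zero():
    f = f_opposition()
    assert f((1, 0, 0, 1)) == 1
    assert f((0, 1, 1, 0)) == 1
    assert f((1, 0, 1, 0)) == -1
    assert f((0, 1, 0, 1)) == -1
    assert sum(abs(f(v)) for v in STATES) == 4
    # direct 16-state summation under a mirror-symmetric block-independent
    # model: any A-block distribution times any B-block distribution
    rng = np.random.default_rng(42)
    for _ in range(20):
        qa = rng.dirichlet(np.ones(3))  # P(00), P(11), P(one-way, split evenly)
        qb = rng.dirichlet(np.ones(3))
        pa = {(0, 0): qa[0], (1, 1): qa[1], (1, 0): qa[2] / 2, (0, 1): qa[2] / 2}
        pb = {(0, 0): qb[0], (1, 1): qb[1], (1, 0): qb[2] / 2, (0, 1): qb[2] / 2}
        total = sum(
            pa[v[:2]] * pb[v[2:]] * f(v) for v in STATES
        )
        assert total == pytest.approx(0.0, abs=1e-15)


def test_presence_covariance_values_and_sign_pattern():
    a, b = 0.3, 0.4
    f = f_presence_covariance(a, b)
    assert f((0, 0, 0, 0)) == pytest.approx(a * b)
    assert f((1, 0, 0, 1)) == pytest.approx((1 - a) * (1 - b))
    negative = [(1, 0, 0, 0), (1, 1, 0, 0), (0, 0, 1, 0), (0, 0, 1, 1)]
    positive = [
        (1, 0, 1, 0), (1, 0, 0, 1), (1, 1, 1, 0), (1, 0, 1, 1),
        (1, 1, 1, 1), (0, 0, 0, 0),
    ]
    for v in negative:
        assert f(v) < 0
    for v in positive:
        assert f(v) > 0


def test_shipped_constraints_are_mirror_invariant():
    for f in (
        f_reciprocity("A", 0.2),
        f_reciprocity("B", 0.7),
        f_opposition(),
        f_presence_covariance(0.1, 0.4),
    ):
        assert f.is_mirror_invariant()


# --- empirical and model means --------------------------------------------

def test_empirical_means_on_fixture(fixture_tally):
    f1 = f_reciprocity("A", 187 / 5929)
    assert empirical_mean(f1, fixture_tally) == pytest.approx(0.006427, abs=1e-6)
    f3 = f_opposition()
    assert empirical_mean(f3, fixture_tally) == pytest.approx(36 / 5929)


def test_constant_function_has_mean_equal_to_constant():
    f = ConstraintFunction(name="const", values=np.full(16, 2.5))
    dist = independence_distribution(MarginalRates(pA=0.2, pB=0.3))
    assert model_mean(f, dist) == pytest.approx(2.5)


# --- tilting ---------------------------------------------------------------

def test_zero_lambda_tilt_is_identity():
    dist = independence_distribution(MarginalRates(pA=0.2, pB=0.3))
    tilted, Z = tilt(dist, f_opposition(), 0.0)
    assert np.allclose(tilted.probabilities, dist.probabilities)
    assert Z == pytest.approx(1.0)


def test_tilting_by_constant_changes_nothing():
    dist = independence_distribution(MarginalRates(pA=0.2, pB=0.3))
    f = ConstraintFunction(name="const", values=np.full(16, 3.0))
    tilted, Z = tilt(dist, f, 1.7)
    assert np.allclose(tilted.probabilities, dist.probabilities)
    assert Z == pytest.approx(np.exp(1.7 * 3.0))


def test_opposition_tilt_moves_cell_ratio_by_exp_2lambda():
    dist = independence_distribution(MarginalRates(pA=0.25, pB=0.4))
    lam = 0.8
    tilted, _ = tilt(dist, f_opposition(), lam)
    before = dist[(1, 0, 0, 1)] / dist[(1, 0, 1, 0)]
    after = tilted[(1, 0, 0, 1)] / tilted[(1, 0, 1, 0)]
    assert after / before == pytest.approx(np.exp(2 * lam))


def test_extreme_lambda_does_not_overflow():
    dist = independence_distribution(MarginalRates(pA=0.2, pB=0.3))
    tilted, _ = tilt(dist, f_opposition(), 500.0)
    assert np.isfinite(tilted.probabilities).all()
    assert tilted.probabilities.sum() == pytest.approx(1.0)


# --- multiplier solving ----------------------------------------------------

def _brute_force_lambda(dist, f, target):
    """Grid + bisection oracle over lambda in [-10, 10]."""
    grid = np.linspace(-10, 10, 2001)

    def mean_at(lam):
        return model_mean(f, tilt(dist, f, lam)[0])

    vals = np.array([mean_at(l) for l in grid])
    k = int(np.argmin(np.abs(vals - target)))
    lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mean_at(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def test_solving_for_current_mean_gives_zero_lambda():
    dist = independence_distribution(MarginalRates(pA=0.2, pB=0.3))
    f = f_opposition()
    assert solve_lambda(dist, f, model_mean(f, dist)) == pytest.approx(0.0, abs=1e-9)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000), st.floats(0.1, 0.9))
def test_solver_matches_brute_force_oracle(seed, frac):
    rng = np.random.default_rng(seed)
    dist = CellDistribution(probabilities=rng.dirichlet(np.ones(16)))
    f = ConstraintFunction(name="rand", values=rng.normal(size=16))
    lo, hi = f.values.min(), f.values.max()
    target = lo + frac * (hi - lo)
    lam = solve_lambda(dist, f, target)
    assert abs(lam) < 10, "oracle grid covers [-10, 10] only"
    assert lam == pytest.approx(_brute_force_lambda(dist, f, target), abs=1e-6)
    tilted, _ = tilt(dist, f, lam)
    assert model_mean(f, tilted) == pytest.approx(target, abs=1e-8)


def test_solver_rejects_unattainable_targets_and_degenerate_constraints():
    dist = independence_distribution(MarginalRates(pA=0.2, pB=0.3))
    f = f_opposition()
    with pytest.raises(ValueError, match="attainable"):
        solve_lambda(dist, f, 1.5)
    const = ConstraintFunction(name="const", values=np.ones(16))
    with pytest.raises(ValueError, match="degenerate"):
        solve_lambda(dist, const, 0.5)


def test_single_tilt_is_the_kl_projection_onto_the_moment_constraint():
    """The fitted tilt minimizes KL to the base among distributions with
    the required moment (I-projection), checked against a generic
    constrained optimizer on the 16-simplex."""
    rng = np.random.default_rng(7)
    for _ in range(3):
        base = CellDistribution(probabilities=rng.dirichlet(np.ones(16) * 5))
        f = ConstraintFunction(name="rand", values=rng.normal(size=16))
        lo, hi = f.values.min(), f.values.max()
        target = lo + 0.6 * (hi - lo)
        lam = solve_lambda(base, f, target)
        tilted, _ = tilt(base, f, lam)
        kl_tilt = float(
            np.sum(tilted.probabilities * np.log(tilted.probabilities / base.probabilities))
        )

        def kl(q):
            q = np.clip(q, 1e-300, None)
            return float(np.sum(q * np.log(q / base.probabilities)))

        res = minimize(
            kl,
            x0=base.probabilities,
            constraints=[
                {"type": "eq", "fun": lambda q: q.sum() - 1.0},
                {"type": "eq", "fun": lambda q: q @ f.values - target},
            ],
            bounds=[(1e-12, 1.0)] * 16,
            method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-14},
        )
        assert res.success
        assert kl(res.x) == pytest.approx(kl_tilt, abs=1e-5)


# --- chi-squared machinery -------------------------------------------------

def test_chisq_cells_and_total_on_fixture(fixture_tally, fixture_class_counts):
    rates = MarginalRates(pA=187 / 5929, pB=645 / 5929)
    expected = expected_class_counts(independence_distribution(rates), 5929)
    cells, total = chisq_table(fixture_class_counts, expected)
    assert total == pytest.approx(383.2001, abs=5e-4)
    assert cells[(1, 1, 0, 0)] == pytest.approx(116.04, abs=0.01)


def test_chisq_perfect_fit_and_degenerate_cells():
    obs = {(0, 0, 0, 0): 5.0, (1, 0, 0, 0): 3.0}
    cells, total = chisq_table(obs, dict(obs))
    assert total == 0.0
    with pytest.warns(UserWarning, match="zero observed and expected"):
        cells, total = chisq_table(
            {(0, 0, 0, 0): 0.0, (1, 0, 0, 0): 3.0},
            {(0, 0, 0, 0): 0.0, (1, 0, 0, 0): 3.0},
        )
    assert (0, 0, 0, 0) not in cells
    with pytest.raises(ValueError, match="expected count 0"):
        chisq_table({(0, 0, 0, 0): 2.0}, {(0, 0, 0, 0): 0.0})


def test_critical_values_match_chi_squared_tables():
    assert critical_value(9, 0.95) == pytest.approx(16.919, abs=5e-4)
    assert critical_value(9, 0.99) == pytest.approx(21.666, abs=5e-4)
    assert critical_value(9, 0.99) > critical_value(9, 0.95)
    assert critical_value(10, 0.95) > critical_value(9, 0.95)
    with pytest.raises(ValueError):
        critical_value(9, 1.5)


# --- sequential fit --------------------------------------------------------

def test_sequential_fit_reproduces_published_trajectory(fitted_trajectory_compat):
    totals = fitted_trajectory_compat.totals
    published = (383.2001, 174.3299, 39.22938, 26.16519, 18.92789)
    for got, want in zip(totals, published):
        assert got == pytest.approx(want, rel=5e-4)
    assert totals == sorted(totals, reverse=True), "strictly decreasing"
    assert totals[-1] < 21.666


def test_sequential_fit_expected_columns_match_published_table(
    fitted_trajectory_compat,
):
    """Per-class expected counts after f1/f2/f3 agree with the published
    worked example to the printed rounding."""
    published = {
        "reciprocity_A": [133.89, 36.31, 537.71, 65.64, 16.34, 16.34, 4.43,
                          2.00, 0.54, 4405.07],
        "reciprocity_B": [134.64, 36.52, 477.63, 161.11, 14.52, 14.52, 3.94,
                          4.90, 1.33, 4429.76],
        "opposition": [134.41, 36.46, 476.81, 160.83, 8.06, 26.06, 3.93,
                       4.89, 1.33, 4422.09],
    }
    by_label = {s.label: s for s in fitted_trajectory_compat.steps}
    from jointnet.linkage import TABLE_CLASS_ORDER

    for label, column in published.items():
        step = by_label[label]
        for rep, want in zip(TABLE_CLASS_ORDER, column):
            assert step.expected[rep] == pytest.approx(want, abs=0.02), (
                label, state_label(rep))


def test_fitted_multipliers_match_published_values(fitted_trajectory_compat):
    lams = {s.label: s.fitted.lam for s in fitted_trajectory_compat.steps[1:]}
    assert lams["opposition"] == pytest.approx(0.586, abs=2e-3)
    assert lams["presence_covariance"] == pytest.approx(0.39, abs=5e-3)


def test_post_f1_mutual_grooming_expectation(fitted_trajectory_compat):
    step = fitted_trajectory_compat.steps[1]
    assert step.expected[(1, 1, 0, 0)] == pytest.approx(36.31, abs=0.02)


def test_model_centering_also_meets_the_stopping_bound(fitted_trajectory_model):
    assert fitted_trajectory_model.totals[-1] < 21.666


def test_moment_matching_and_normalization_per_step(
    fixture_tally, fitted_trajectory_compat
):
    for step in fitted_trajectory_compat.steps:
        p = step.distribution.probabilities
        assert abs(p.sum() - 1.0) < 1e-12
        assert step.distribution.is_mirror_symmetric()
        if step.fitted is not None:
            got = model_mean(step.fitted.constraint, step.distribution)
            assert got == pytest.approx(step.fitted.empirical_target, abs=1e-8)


def test_first_reciprocity_moment_survives_the_second_tilt(
    fitted_trajectory_compat,
):
    """The A-block and B-block tilts commute: accommodating the B
    reciprocity leaves the A reciprocity moment intact."""
    f1 = fitted_trajectory_compat.steps[1].fitted
    post_f2 = fitted_trajectory_compat.steps[2].distribution
    assert model_mean(f1.constraint, post_f2) == pytest.approx(
        f1.empirical_target, abs=1e-10
    )


def test_mean_zero_deviations_along_the_fit(fitted_trajectory_compat):
    """f2 is perpendicular to the post-f1 model and f3 to the post-f2
    model (block independence / mirror symmetry); the f4 deviation is a
    small nonzero covariance."""
    devs = {
        s.label: s.fitted.mean_zero_deviation
        for s in fitted_trajectory_compat.steps[1:]
    }
    assert devs["reciprocity_B"] == pytest.approx(0.0, abs=1e-12)
    assert devs["opposition"] == pytest.approx(0.0, abs=1e-12)
    assert devs["presence_covariance"] != 0.0
    assert abs(devs["presence_covariance"]) < 0.01


def test_fit_on_exact_independence_sample_stops_immediately():
    """A tally drawn exactly from an independence model fits at step 0."""
    from jointnet.linkage import LinkageTally

    # expand an exact product law over 40000 off-diagonal cells (n=201)
    n = 201
    N = n * (n - 1)
    pA, pB = 0.1, 0.2
    dist = independence_distribution(MarginalRates(pA=pA, pB=pB))
    # scale to integers: probabilities are rationals with denominator 10^8
    counts = {
        v: round(float(dist[v]) * N) for v in STATES
    }
    # fix rounding drift on the bulk cell
    drift = N - sum(counts.values())
    counts[(0, 0, 0, 0)] += drift
    tally = LinkageTally(n=n, counts=counts, convention="offdiag")
    traj = sequential_fit(tally, standard_constraints("model"))
    assert len(traj.steps) == 1
    assert traj.stopped_early


def test_joint_refit_matches_all_moments_simultaneously(fixture_tally):
    builders = standard_constraints("paper-table-1-compat")
    model = joint_refit(fixture_tally, builders)
    for fc in model.fitted:
        assert model_mean(fc.constraint, model.current) == pytest.approx(
            fc.empirical_target, abs=1e-8
        )


def test_model_json_round_trip(fitted_trajectory_compat):
    model = fitted_trajectory_compat.model
    text = model_to_json(model)
    back = model_from_json(text)
    assert np.array_equal(
        back.current.probabilities, model.current.probabilities
    )
    assert [fc.lam for fc in back.fitted] == [fc.lam for fc in model.fitted]
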
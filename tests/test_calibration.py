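"""Constrained least-squares complication calibration against independent oracles."""

import itertools

import numpy as np
import pytest
from scipy.optimize import Bounds, LinearConstraint, minimize

from actsim.calibration import (
    InfeasibleConstraints,
    _Block,
    _solve_block,
    build_calibration_problem,
    solve_calibration,
    verify_constraints,
)
from actsim.parameters import ComplicationTable, ConstraintSpec, all_profiles


def _make_block(ref, w, a_eq, b_eq, g_ub=None, h_ub=None):
    n = len(ref)
    return _Block(
        "pressure_ulcer", [None] * n, np.asarray(ref, float), np.asarray(w, float),
        a_eq=np.asarray(a_eq, float).reshape(-1, n), b_eq=np.asarray(b_eq, float),
        g_ub=np.asarray(g_ub, float).reshape(-1, n) if g_ub is not None else np.zeros((0, n)),
        h_ub=np.asarray(h_ub, float) if h_ub is not None else np.zeros(0),
        lower=np.zeros(n), upper=np.ones(n))


def _scipy_solve(block):
    """Independent oracle: scipy trust-constr on the same QP."""
    n = block.ref.size
    cons = []
    if block.a_eq.shape[0]:
        cons.append(LinearConstraint(block.a_eq, block.b_eq, block.b_eq))
    if block.g_ub.shape[0]:
        cons.append(LinearConstraint(block.g_ub, -np.inf, block.h_ub))
    res = minimize(
        lambda p: np.sum(block.weights * (p - block.ref) ** 2),
        x0=np.clip(block.ref, 0.01, 0.99),
        jac=lambda p: 2 * block.weights * (p - block.ref),
        hess=lambda p: np.diag(2 * block.weights),
        method="trust-constr", constraints=cons,
        bounds=Bounds(block.lower, block.upper),
        options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 3000})
    return res.x


def _grid_solve(block, steps=40):
    """Brute-force oracle for tiny single-equality instances: every grid
    candidate is projected exactly onto the equality row, so only truly
    feasible points compete."""
    n = block.ref.size
    row = block.a_eq[0]
    target = block.b_eq[0]
    grid = np.linspace(0.0, 1.0, steps + 1)
    best, best_val = None, np.inf
    for point in itertools.product(grid, repeat=n):
        p = np.array(point)
        p = p + (target - row @ p) * row / (row @ row)
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            continue
        val = float(np.sum(block.weights * (p - block.ref) ** 2))
        if val < best_val:
            best, best_val = p, val
    return best


class TestSolver:
    def test_two_cell_closed_form(self):
        """Mean incidence 0.2 with a male:female ratio of 2 pins the pair at
        (4/15, 2/15) no matter the reference table."""
        for ref in ([0.9, 0.1], [0.0, 1.0], [0.5, 0.5]):
            block = _make_block(ref, [0.5, 0.5],
                                a_eq=[[0.5, 0.5], [1.0, -2.0]], b_eq=[0.2, 0.0])
            p, diag = _solve_block(block)
            assert p == pytest.approx([4 / 15, 2 / 15], abs=1e-9)
            assert diag["kkt_residual"] < 1e-8

    def test_unconstrained_returns_reference(self):
        ref = [0.2, 0.7, 0.05]
        block = _make_block(ref, [0.3, 0.3, 0.4], a_eq=np.zeros((0, 3)), b_eq=[])
        p, _ = _solve_block(block)
        assert p == pytest.approx(ref, abs=1e-10)

    @pytest.mark.parametrize("trial", range(12))
    def test_random_small_instances_match_scipy(self, trial):
        """Instances up to 12 variables with equality, inequality and active
        box constraints agree with an independent convex solver."""
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(2, 13))
        ref = rng.uniform(-0.2, 1.2, n)  # push some solutions onto the box
        w = rng.uniform(0.2, 2.0, n)
        w = w / w.sum()
        # anchor the constraints on a known interior point so every
        # instance is feasible (while constraints may be active at the optimum)
        x0 = rng.uniform(0.1, 0.9, n)
        rows = []
        targets = []
        sel = rng.random(n) < 0.7
        if sel.any():
            row = np.where(sel, w, 0.0)
            row = row / row.sum()
            rows.append(row)
            targets.append(float(row @ x0))
        n_ub = int(rng.integers(0, 3))
        g = rng.uniform(0, 1, (n_ub, n))
        h = g @ x0 + rng.uniform(0.0, 0.3, n_ub)
        block = _make_block(ref, w, np.array(rows), np.array(targets), g, h)
        ours, _ = _solve_block(block)
        oracle = _scipy_solve(block)
        # trust-constr converges to ~1e-5 on these instances
        assert ours == pytest.approx(oracle, abs=5e-5)

    @pytest.mark.parametrize("trial", range(4))
    def test_tiny_instances_match_grid_search(self, trial):
        rng = np.random.default_rng(7 + trial)
        n = 3
        ref = rng.uniform(0, 1, n)
        w = np.full(n, 1.0 / n)
        row = np.full(n, 1.0 / n)
        block = _make_block(ref, w, [row], [round(float(rng.uniform(0.2, 0.8)), 2)])
        ours, _ = _solve_block(block)
        grid = _grid_solve(block, steps=60)
        assert float(np.sum(w * (ours - ref) ** 2)) <= \
            float(np.sum(w * (grid - ref) ** 2)) + 1e-3
        assert ours == pytest.approx(grid, abs=0.05)

    def test_conflicting_equalities_flagged_infeasible(self):
        row = np.array([0.5, 0.5])
        block = _make_block([0.2, 0.2], [0.5, 0.5],
                            a_eq=[row, row], b_eq=[0.1, 0.3])
        with pytest.raises(InfeasibleConstraints):
            _solve_block(block)


class TestFullProblem:
    def test_solution_satisfies_all_constraints(self, uncal_pack):
        co = uncal_pack.complications
        report = verify_constraints(co.table, co.constraints, co.profile_weights)
        assert report["satisfied"].all()
        assert report["residual"].abs().max() <= 1e-6

    def test_projection_identity_and_idempotence(self, uncal_pack):
        """A reference already satisfying the constraints is returned as is;
        re-solving from the solution reproduces the solution."""
        co = uncal_pack.complications
        problem = build_calibration_problem(co.table, co.constraints,
                                            co.profile_weights)
        again, _ = solve_calibration(problem)
        a = co.table.to_frame().sort_values(
            ["age_band", "gender", "mechanism", "neuro_band", "ais", "complication"])
        b = again.to_frame().sort_values(
            ["age_band", "gender", "mechanism", "neuro_band", "ais", "complication"])
        assert np.allclose(a["probability"].to_numpy(),
                           b["probability"].to_numpy(), atol=1e-7)

    def test_adding_constraint_never_decreases_objective(self, uncal_pack):
        co = uncal_pack.complications
        ref = co.reference_table
        base_cons = [c for c in co.constraints if c.complication == "pressure_ulcer"]
        extra = base_cons + [ConstraintSpec(
            "marginal_equality", "pressure_ulcer", 0.4,
            selector={"age_band": "60+"})]
        w = co.profile_weights

        def objective(table):
            profs = list(all_profiles())
            wv = np.array([w[p] for p in profs])
            wv = wv / wv.sum()
            diff = np.array([table.probability(p, "pressure_ulcer")
                             - ref.probability(p, "pressure_ulcer") for p in profs])
            return float(np.sum(wv * diff ** 2))

        t1, _ = solve_calibration(build_calibration_problem(ref, base_cons, w))
        t2, _ = solve_calibration(build_calibration_problem(ref, extra, w))
        assert objective(t2) >= objective(t1) - 1e-12

    def test_ratio_residual_arithmetic(self):
        """A table built with equal male/female risk checked against a
        ratio-2 constraint leaves residual p_female."""
        entries = {}
        for p in all_profiles():
            for comp in ("pressure_ulcer", "neuropathic_pain", "pneumonia",
                         "uti", "delirium"):
                entries[(p, comp)] = 0.2
        table = ComplicationTable(entries)
        cons = [ConstraintSpec("ratio", "pressure_ulcer", 2.0,
                               ratio_field="gender", ratio_num="male",
                               ratio_den="female")]
        report = verify_constraints(table, cons)
        assert report.loc[0, "residual"] == pytest.approx(0.2)
        assert not report.loc[0, "satisfied"]

    def test_empty_constraint_list_gives_empty_report(self, uncal_pack):
        report = verify_constraints(uncal_pack.complications.table, [])
        assert len(report) == 0

    def test_empty_stratum_rejected(self, uncal_pack):
        cons = [ConstraintSpec("marginal_equality", "uti", 0.2,
                               selector={"age_band": "200+"})]
        with pytest.raises(Exception, match="empty stratum"):
            build_calibration_problem(uncal_pack.complications.reference_table,
                                      cons, uncal_pack.complications.profile_weights)
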
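"""Constrained least-squares calibration of acute complication probabilities.

For each of the 640 patient profiles a probability of each of five acute
complications is needed (3,200 numbers), but no registry collects them
directly.  The calibration instead starts from a reference (literature-
prior) table and finds the closest table — in prevalence-weighted squared
deviation — that satisfies every constraint drawn from published evidence
(marginal incidences, stratum ratios such as "males have twice the chance
of females of getting a pressure ulcer", bounds, and the box [0, 1]).

This is a convex quadratic program with a diagonal Hessian.  Constraints
never couple complications, so the QP is solved block-separably per
complication with an equality-KKT solve plus a primal active set over the
inequality rows and box bounds.  As published evidence changes, edit the
constraint list and re-solve; the simulation probabilities update
automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import (
    COMPLICATIONS,
    ComplicationTable,
    ConstraintSpec,
    PackError,
    ProfileKey,
    all_profiles,
)

__all__ = [
    "CalibrationProblem", "InfeasibleConstraints", "build_calibration_problem",
    "solve_calibration", "verify_constraints",
]

KKT_TOL = 1e-8


class InfeasibleConstraints(PackError):
    """The constraint set admits no probability table."""


@dataclass
class _Block:
    """QP data for one complication: min sum w (p - r)^2 s.t. Aeq p = beq, G p <= h."""

    complication: str
    profiles: list[ProfileKey]
    ref: np.ndarray
    weights: np.ndarray
    a_eq: np.ndarray
    b_eq: np.ndarray
    g_ub: np.ndarray
    h_ub: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    labels_eq: list[str] = field(default_factory=list)
    labels_ub: list[str] = field(default_factory=list)


@dataclass
class CalibrationProblem:
    """A built QP, one block per complication (block-separable)."""

    blocks: dict[str, _Block]
    constraints: list[ConstraintSpec]


def _profile_index(profiles: list[ProfileKey]) -> dict[ProfileKey, int]:
    return {p: i for i, p in enumerate(profiles)}


def build_calibration_problem(
    reference: ComplicationTable,
    constraints: list[ConstraintSpec],
    weights: dict[ProfileKey, float] | None = None,
) -> CalibrationProblem:
    """Render constraints as linear rows over the 3,200 table entries.

    ``weights`` are profile prevalence weights (uniform when omitted); they
    weight both the objective and marginal-constraint aggregation.  Ratio
    constraints ``p_num = target * p_den`` are linearized per matched pair
    of profiles differing only in ``ratio_field``.
    """
    profiles = list(all_profiles())
    idx = _profile_index(profiles)
    n = len(profiles)
    if weights:
        w = np.array([max(weights.get(p, 0.0), 0.0) for p in profiles])
        if w.sum() <= 0:
            raise PackError("invalid parameter: profile weights sum to zero")
        w = np.maximum(w / w.sum(), 1e-9)  # keep the Hessian positive definite
    else:
        w = np.full(n, 1.0 / n)

    blocks: dict[str, _Block] = {}
    for comp in COMPLICATIONS:
        ref = np.array([reference.probability(p, comp) for p in profiles])
        rows_eq: list[np.ndarray] = []
        rhs_eq: list[float] = []
        lab_eq: list[str] = []
        rows_ub: list[np.ndarray] = []
        rhs_ub: list[float] = []
        lab_ub: list[str] = []
        lower = np.zeros(n)
        upper = np.ones(n)

        for k, c in enumerate(constraints):
            if c.complication != comp:
                continue
            label = f"{c.kind}[{k}]:{comp}"
            if c.kind in ("marginal_equality", "marginal_bound"):
                sel = np.array([c.selects(p) for p in profiles])
                if not sel.any():
                    raise PackError(f"empty stratum: {label}")
                row = np.where(sel, w, 0.0)
                row = row / row.sum()  # non-negative weights summing to 1
                if c.kind == "marginal_equality":
                    rows_eq.append(row)
                    rhs_eq.append(c.target)
                    lab_eq.append(label)
                elif c.direction == "le":
                    rows_ub.append(row)
                    rhs_ub.append(c.target)
                    lab_ub.append(label)
                else:  # ge
                    rows_ub.append(-row)
                    rhs_ub.append(-c.target)
                    lab_ub.append(label)
            elif c.kind == "ratio":
                matched = 0
                for p in profiles:
                    if getattr(p, c.ratio_field) != c.ratio_num or not c.selects(p):
                        continue
                    partner = p._replace(**{c.ratio_field: c.ratio_den})
                    row = np.zeros(n)
                    row[idx[p]] = 1.0
                    row[idx[partner]] = -c.target
                    rows_eq.append(row)
                    rhs_eq.append(0.0)
                    lab_eq.append(f"{label}:{'|'.join(p)}")
                    matched += 1
                if matched == 0:
                    raise PackError(f"empty stratum: {label}")
            elif c.kind == "box":
                sel = np.array([c.selects(p) for p in profiles])
                if not sel.any():
                    raise PackError(f"empty stratum: {label}")
                lower = np.where(sel, np.maximum(lower, c.lower), lower)
                upper = np.where(sel, np.minimum(upper, c.upper), upper)

        blocks[comp] = _Block(
            complication=comp, profiles=profiles, ref=ref, weights=w,
            a_eq=np.array(rows_eq) if rows_eq else np.zeros((0, n)),
            b_eq=np.array(rhs_eq), g_ub=np.array(rows_ub) if rows_ub else np.zeros((0, n)),
            h_ub=np.array(rhs_ub), lower=lower, upper=upper,
            labels_eq=lab_eq, labels_ub=lab_ub)
    return CalibrationProblem(blocks=blocks, constraints=list(constraints))


def _solve_block(b: _Block, max_iter: int = 1000) -> tuple[np.ndarray, dict]:
    """Primal active-set solve of one diagonal-Hessian QP block.

    Starting from a feasible point (a zero-objective linear program over
    the constraint set), each iteration solves the equality-constrained
    subproblem over the working set, takes the longest feasible step
    toward its minimizer, and adds the blocking inequality to the working
    set; at a subproblem minimizer, inequality rows with wrong-signed
    multipliers are dropped.  Terminates at a KKT point: for rows stored
    as ``a.p = rhs`` stationarity ``2W(p - r) + A'lam = 0`` requires
    ``lam >= 0`` for upper-type constraints (``a.p <= rhs``) and
    ``lam <= 0`` for lower bounds.
    """
    from scipy.optimize import linprog

    n = b.ref.size
    w = b.weights

    if b.a_eq.shape[0]:
        aug = np.hstack([b.a_eq, b.b_eq[:, None]])
        if np.linalg.matrix_rank(aug, tol=1e-10) > np.linalg.matrix_rank(b.a_eq, tol=1e-10):
            raise InfeasibleConstraints(
                f"infeasible constraint set: inconsistent equalities for {b.complication} "
                f"({', '.join(b.labels_eq[:4])} ...)")

    lp = linprog(np.zeros(n),
                 A_ub=b.g_ub if b.g_ub.shape[0] else None,
                 b_ub=b.h_ub if b.g_ub.shape[0] else None,
                 A_eq=b.a_eq if b.a_eq.shape[0] else None,
                 b_eq=b.b_eq if b.a_eq.shape[0] else None,
                 bounds=list(zip(b.lower, b.upper)), method="highs")
    if not lp.success:
        raise InfeasibleConstraints(
            f"infeasible constraint set for {b.complication}: no feasible table "
            f"(phase-1 status: {lp.message})")
    x = np.clip(lp.x, b.lower, b.upper)

    # working set of active inequalities: (row, rhs, kind, key)
    active: list[tuple[np.ndarray, float, str, int]] = []

    def subproblem() -> tuple[np.ndarray, np.ndarray]:
        rows = [b.a_eq] if b.a_eq.shape[0] else []
        rhs = [b.b_eq] if b.a_eq.shape[0] else []
        for row, r, _k, _key in active:
            rows.append(row[None, :])
            rhs.append(np.array([r]))
        A = np.vstack(rows) if rows else np.zeros((0, n))
        c = np.concatenate(rhs) if rows else np.zeros(0)
        m = A.shape[0]
        H = 2.0 * w
        kkt = np.zeros((n + m, n + m))
        kkt[:n, :n] = np.diag(H)
        kkt[:n, n:] = A.T
        kkt[n:, :n] = A
        sol, *_ = np.linalg.lstsq(kkt, np.concatenate([H * b.ref, c]), rcond=None)
        return sol[:n], sol[n:]

    n_eq = b.a_eq.shape[0]
    for it in range(max_iter):
        x_star, lam = subproblem()
        step = x_star - x
        if float(np.max(np.abs(step))) < 1e-11:
            # at the working-set minimizer: check dual feasibility
            mult = lam[n_eq:]
            worst_j, worst_v = -1, 1e-9
            for j, (_row, _rhs, kind, _key) in enumerate(active):
                bad = -mult[j] if kind in ("ub", "hi") else mult[j]
                if bad > worst_v:
                    worst_j, worst_v = j, bad
            if worst_j < 0:
                rows = [r for r, *_ in active]
                A_act = np.vstack([b.a_eq] + [r[None, :] for r in rows]) if (
                    n_eq or rows) else np.zeros((0, n))
                stat = 2.0 * w * (x - b.ref) + (A_act.T @ lam if A_act.shape[0] else 0.0)
                diag = {"kkt_residual": float(np.linalg.norm(stat, ord=np.inf)),
                        "objective": float(np.sum(w * (x - b.ref) ** 2)),
                        "active_bounds": sum(1 for *_a, k, _key in active
                                             if k in ("lo", "hi")),
                        "iterations": it + 1}
                if diag["kkt_residual"] > 1e-6:
                    raise InfeasibleConstraints(
                        f"solver tolerance not met for {b.complication}: "
                        f"KKT residual {diag['kkt_residual']:.2e}")
                return x, diag
            active.pop(worst_j)
            continue
        # longest feasible step toward the subproblem minimizer
        in_set = {(k, key) for _r, _c2, k, key in active}
        alpha, blocking = 1.0, None
        for i in range(b.g_ub.shape[0]):
            if ("ub", i) in in_set:
                continue
            denom = float(b.g_ub[i] @ step)
            if denom > 1e-12:
                a_i = (b.h_ub[i] - float(b.g_ub[i] @ x)) / denom
                if a_i < alpha:
                    alpha, blocking = a_i, (b.g_ub[i], b.h_ub[i], "ub", i)
        for j in range(n):
            if step[j] > 1e-12 and ("hi", j) not in in_set:
                a_j = (b.upper[j] - x[j]) / step[j]
                if a_j < alpha:
                    row = np.zeros(n)
                    row[j] = 1.0
                    alpha, blocking = a_j, (row, b.upper[j], "hi", j)
            elif step[j] < -1e-12 and ("lo", j) not in in_set:
                a_j = (b.lower[j] - x[j]) / step[j]
                if a_j < alpha:
                    row = np.zeros(n)
                    row[j] = 1.0
                    alpha, blocking = a_j, (row, b.lower[j], "lo", j)
        x = x + max(alpha, 0.0) * step
        if blocking is not None:
            active.append(blocking)
    raise InfeasibleConstraints(
        f"infeasible constraint set: active-set did not converge for {b.complication}")


def solve_calibration(problem: CalibrationProblem) -> tuple[ComplicationTable, pd.DataFrame]:
    """Solve the QP; returns the calibrated table and per-constraint diagnostics.

    Raises :class:`InfeasibleConstraints` when the constraint set is
    inconsistent.  The solve is deterministic.
    """
    entries: dict[tuple[ProfileKey, str], float] = {}
    diags: dict[str, dict] = {}
    for comp, block in problem.blocks.items():
        p, diag = _solve_block(block)
        diags[comp] = diag
        p = np.clip(p, 0.0, 1.0)  # numerical dust only; bounds are active-set enforced
        for prof, val in zip(block.profiles, p):
            entries[(prof, comp)] = float(val)
    table = ComplicationTable(entries)
    report = verify_constraints(table, problem.constraints,
                                weights={p: w for p, w in
                                         zip(next(iter(problem.blocks.values())).profiles,
                                             next(iter(problem.blocks.values())).weights)})
    bad = report[~report.satisfied]
    if len(bad):
        raise InfeasibleConstraints(
            "infeasible constraint set: residuals remain after solve:\n"
            + bad.to_string(index=False))
    report.attrs["solver"] = diags
    return table, report


def verify_constraints(
    table: ComplicationTable,
    constraints: list[ConstraintSpec],
    weights: dict[ProfileKey, float] | None = None,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Residual of every constraint against ``table`` with pass/fail at ``tol``."""
    profiles = list(all_profiles())
    if weights:
        w = np.array([max(weights.get(p, 0.0), 0.0) for p in profiles])
        w = w / w.sum()
    else:
        w = np.full(len(profiles), 1.0 / len(profiles))
    rows = []
    for k, c in enumerate(constraints):
        vals = np.array([table.probability(p, c.complication) for p in profiles])
        if c.kind in ("marginal_equality", "marginal_bound"):
            sel = np.array([c.selects(p) for p in profiles])
            ww = np.where(sel, w, 0.0)
            ww = ww / ww.sum()
            agg = float(ww @ vals)
            if c.kind == "marginal_equality":
                resid = agg - c.target
            elif c.direction == "le":
                resid = max(0.0, agg - c.target)
            else:
                resid = max(0.0, c.target - agg)
        elif c.kind == "ratio":
            worst = 0.0
            for p in profiles:
                if getattr(p, c.ratio_field) != c.ratio_num or not c.selects(p):
                    continue
                partner = p._replace(**{c.ratio_field: c.ratio_den})
                worst = max(worst, abs(table.probability(p, c.complication)
                                       - c.target * table.probability(partner, c.complication)))
            resid = worst
        else:  # box
            sel = np.array([c.selects(p) for p in profiles])
            below = np.clip(c.lower - vals[sel], 0, None)
            above = np.clip(vals[sel] - c.upper, 0, None)
            resid = float(max(below.max(initial=0.0), above.max(initial=0.0)))
        rows.append({"index": k, "kind": c.kind, "complication": c.complication,
                     "target": c.target, "residual": float(resid),
                     "satisfied": abs(resid) <= tol, "source": c.source})
    return pd.DataFrame(rows, columns=["index", "kind", "complication", "target",
                                       "residual", "satisfied", "source"])
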
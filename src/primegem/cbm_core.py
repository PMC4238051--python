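"""Linear and quadratic flux computations on metabolic models.

FBA (LP maximizing an objective flux under ``S v = 0`` and box bounds),
FVA (per-reaction flux ranges at a fixed objective fraction), MOMA (QP
minimizing the Euclidean distance to a wild-type flux distribution under
perturbed constraints), seeded wild-type flux sampling, and the primitive
bound manipulations (knock-out, fraction-of-max constraints) used by all
downstream stages.

LPs are solved with HiGHS through :func:`scipy.optimize.linprog`; the
MOMA QP is strictly convex in the flux variables and is solved with
``trust-constr`` using the exact Hessian ``2 I``.  Every perturbation
operation is copy-on-write: caller models are never mutated.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linprog, minimize

from .model_io import MetabolicModel, PrimegemError

#: feasibility tolerance for LP solutions (mass balance and bounds)
TAU_FEAS = 1e-7
#: convergence tolerance for the MOMA quadratic program
QP_TOL = 1e-8


class InfeasibleError(PrimegemError):
    """The constraint system of a model admits no feasible flux vector."""


class UnboundedError(PrimegemError):
    """The requested objective is unbounded."""


# ---------------------------------------------------------------------------
# FluxDistribution
# ---------------------------------------------------------------------------

@dataclass
class FluxDistribution:
    """A feasible flux vector with the attained objective (biomass) value."""

    fluxes: Dict[str, float]
    objective_id: str
    objective_value: float
    #: attained MOMA distance, when produced by :func:`moma`
    distance: Optional[float] = None

    def flux(self, rid: str) -> float:
        return self.fluxes[rid]

    def as_array(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.fluxes[r] for r in order], dtype=float)

    def write_tsv(self, path) -> None:
        """Serialize as TSV (reaction, flux) with a JSON header line."""
        header = {"objective_id": self.objective_id,
                  "objective_value": self.objective_value,
                  "distance": self.distance}
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(header) + "\n")
            fh.write("reaction\tflux\n")
            for rid, v in self.fluxes.items():
                fh.write(f"{rid}\t{v!r}\n")


# ---------------------------------------------------------------------------
# array form + solution checking
# ---------------------------------------------------------------------------

def _arrays(model: MetabolicModel):
    """(S csr, lb, ub, rxn ids, met index) in declaration order."""
    rids = model.reaction_ids
    mindex = {m: i for i, m in enumerate(model.metabolite_ids)}
    rows, cols, vals = [], [], []
    lb = np.empty(len(rids))
    ub = np.empty(len(rids))
    for j, r in enumerate(model.reactions):
        lb[j], ub[j] = r.lower_bound, r.upper_bound
        for mid, c in r.stoichiometry.items():
            rows.append(mindex[mid])
            cols.append(j)
            vals.append(c)
    S = sp.csr_matrix((vals, (rows, cols)), shape=(len(mindex), len(rids)))
    return S, lb, ub, rids


def _check_solution(S, lb, ub, v, tol: float = TAU_FEAS) -> None:
    scale = max(1.0, float(np.abs(v).max(initial=0.0)))
    resid = np.abs(S @ v).max(initial=0.0)
    if resid > tol * scale * 10:
        raise PrimegemError(f"solver returned mass-imbalanced solution "
                            f"(|Sv| = {resid:.2e})")
    if ((v - ub) > tol * scale * 10).any() or ((lb - v) > tol * scale * 10).any():
        raise PrimegemError("solver returned out-of-bounds solution")


def _solve_lp(S, lb, ub, c, sense: str):
    """min/max c.v subject to S v = 0, lb <= v <= ub; returns flux array."""
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(sign * c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=np.column_stack([lb, ub]), method="highs")
    if res.status == 2:
        raise InfeasibleError(
            "LP infeasible: mass-balance constraints cannot be met within "
            "the current flux bounds")
    if res.status == 3:
        raise UnboundedError("LP objective is unbounded")
    if not res.success:
        raise PrimegemError(f"LP solver failure: {res.message}")
    _check_solution(S, lb, ub, res.x)
    return res.x


# ---------------------------------------------------------------------------
# FBA / FVA
# ---------------------------------------------------------------------------

def fba(model: MetabolicModel, objective_id: Optional[str] = None,
        sense: str = "max") -> FluxDistribution:
    """Flux balance analysis: optimize one reaction flux.

    ``objective_id`` defaults to the model's biomass objective.  Returns an
    optimal vertex solution; raises :class:`InfeasibleError` /
    :class:`UnboundedError` with the offending constraint class or
    objective named.
    """
    if sense not in ("max", "min"):
        raise ValueError(f"unknown sense {sense!r}")
    obj = objective_id or model.objective
    S, lb, ub, rids = _arrays(model)
    c = np.zeros(len(rids))
    try:
        c[rids.index(obj)] = 1.0
    except ValueError:
        raise KeyError(f"objective reaction {obj!r} not in model")
    try:
        v = _solve_lp(S, lb, ub, c, sense)
    except UnboundedError:
        raise UnboundedError(f"objective {obj!r} is unbounded ({sense})")
    return FluxDistribution(dict(zip(rids, v.tolist())), obj, float(v @ c))


def fva(model: MetabolicModel, objective_id: Optional[str] = None,
        fraction: float = 1.0,
        reactions: Optional[Iterable[str]] = None) -> Dict[str, Tuple[float, float]]:
    """Flux variability analysis at ``objective >= fraction * optimum``.

    Returns reaction id -> (min flux, max flux).  The objective fraction is
    imposed as a lower bound on the objective reaction's flux.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    obj = objective_id or model.objective
    opt = fba(model, obj, "max").objective_value
    S, lb, ub, rids = _arrays(model)
    j_obj = rids.index(obj)
    # small slack keeps the pinned problem numerically feasible at fraction 1
    lb = lb.copy()
    lb[j_obj] = max(lb[j_obj], fraction * opt - TAU_FEAS * max(1.0, abs(opt)))
    targets = list(reactions) if reactions is not None else rids
    out: Dict[str, Tuple[float, float]] = {}
    for rid in targets:
        c = np.zeros(len(rids))
        c[rids.index(rid)] = 1.0
        vmin = float(_solve_lp(S, lb, ub, c, "min")[rids.index(rid)])
        vmax = float(_solve_lp(S, lb, ub, c, "max")[rids.index(rid)])
        if vmin > vmax:  # solver noise on pinned problems
            vmin = vmax = 0.5 * (vmin + vmax)
        out[rid] = (vmin, vmax)
    return out


# ---------------------------------------------------------------------------
# MOMA
# ---------------------------------------------------------------------------

def moma(model_perturbed: MetabolicModel, wt: FluxDistribution) -> FluxDistribution:
    """Minimization of metabolic adjustment.

    Solves ``argmin sum_i (v_wt,i - v_i)^2`` subject to the perturbed
    model's constraints.  The QP is strictly convex in the flux variables,
    so the minimizer is unique.  The attained squared distance is reported
    on ``distance``; the objective value is the perturbed biomass flux.
    """
    S, lb, ub, rids = _arrays(model_perturbed)
    missing = [r for r in rids if r not in wt.fluxes]
    if missing:
        raise PrimegemError(f"wild-type distribution lacks reactions {missing}")
    w = wt.as_array(rids)
    x0 = np.clip(w, lb, ub)
    res = minimize(
        lambda v: float(((v - w) ** 2).sum()),
        x0,
        jac=lambda v: 2.0 * (v - w),
        hess=lambda v: 2.0 * np.eye(len(rids)),
        method="trust-constr",
        constraints=[LinearConstraint(S.toarray(), 0.0, 0.0)],
        bounds=Bounds(lb, ub),
        options={"gtol": QP_TOL * 1e-2, "xtol": 1e-12, "maxiter": 3000},
    )
    v = np.asarray(res.x, dtype=float)
    resid = float(np.abs(S @ v).max(initial=0.0))
    if resid > 1e-6:
        raise InfeasibleError(
            f"MOMA could not satisfy mass balance (residual {resid:.2e}); "
            "the perturbed model is likely infeasible")
    v = _polish_qp(S.toarray(), lb, ub, w, np.clip(v, lb, ub))
    j_obj = rids.index(model_perturbed.objective)
    return FluxDistribution(dict(zip(rids, v.tolist())),
                            model_perturbed.objective, float(v[j_obj]),
                            distance=float(((v - w) ** 2).sum()))


def _polish_qp(S, lb, ub, w, v, eps: float = 1e-5):
    """Refine an approximate box/equality QP solution to machine precision.

    Fixes the variables the interior-point solve left (numerically) at
    their bounds and solves the remaining equality-constrained
    least-squares KKT system exactly.  Falls back to the unpolished
    solution whenever the polished one is infeasible or worse.
    """
    scale = np.maximum(1.0, np.abs(v))
    at_lb = (v - lb) <= eps * scale
    at_ub = (ub - v) <= eps * scale
    fixed = at_lb | at_ub
    x = np.where(at_ub, ub, np.where(at_lb, lb, v))
    free = ~fixed
    nf = int(free.sum())
    if nf:
        Sf = S[:, free]
        rhs_top = w[free]
        rhs_bot = -S[:, fixed] @ x[fixed]
        kkt = np.block([[np.eye(nf), Sf.T],
                        [Sf, np.zeros((S.shape[0], S.shape[0]))]])
        sol, *_ = np.linalg.lstsq(kkt, np.concatenate([rhs_top, rhs_bot]),
                                  rcond=None)
        x[free] = sol[:nf]
    ok = ((x >= lb - 1e-9) & (x <= ub + 1e-9)).all() \
        and np.abs(S @ x).max(initial=0.0) <= 1e-8 * max(1.0, np.abs(x).max()) \
        and ((x - w) ** 2).sum() <= ((v - w) ** 2).sum() + 1e-9
    return np.clip(x, lb, ub) if ok else v


# ---------------------------------------------------------------------------
# wild-type flux sampling
# ---------------------------------------------------------------------------

def sample_wt_distributions(model: MetabolicModel, n: int,
                            force: Optional[Tuple[str, float]] = None,
                            seed: int = 0) -> List[FluxDistribution]:
    """Sample ``n`` alternate optimal wild-type flux distributions.

    Each sample maximizes biomass; the optimal biomass value is then fixed
    and a random linear secondary objective (coefficients uniform on
    [-1, 1]) is optimized, which spans alternate optima reproducibly under
    ``seed``.  With ``force=(reaction, min_fraction)`` every sample
    additionally carries at least ``min_fraction`` times the reaction's
    maximal attainable flux.
    """
    work = model.copy()
    if force is not None:
        rid, frac = force
        tmax = fba(work, rid, "max").objective_value
        r = work.reaction(rid)
        r.lower_bound = max(r.lower_bound, frac * tmax)
        try:
            work.validate()
        except PrimegemError as exc:
            raise InfeasibleError(f"forcing constraint on {rid!r} infeasible: {exc}")
    try:
        opt = fba(work).objective_value
    except InfeasibleError:
        target = force[0] if force else None
        raise InfeasibleError(
            f"model infeasible at max growth"
            + (f" with forced activity of {target!r}" if target else ""))
    S, lb, ub, rids = _arrays(work)
    j_obj = rids.index(work.objective)
    lb = lb.copy()
    lb[j_obj] = max(lb[j_obj], opt - TAU_FEAS * max(1.0, abs(opt)))
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        c = rng.uniform(-1.0, 1.0, size=len(rids))
        v = _solve_lp(S, lb, ub, c, "min")
        out.append(FluxDistribution(dict(zip(rids, v.tolist())),
                                    work.objective, float(v[j_obj])))
    return out


# ---------------------------------------------------------------------------
# bound manipulations
# ---------------------------------------------------------------------------

def knock_out(model: MetabolicModel, reaction_ids: Iterable[str]) -> MetabolicModel:
    """Return a copy with the listed reactions' bounds fixed to [0, 0]."""
    if isinstance(reaction_ids, str):
        reaction_ids = [reaction_ids]
    out = model.copy()
    for rid in reaction_ids:
        r = out.reaction(rid)  # raises KeyError on unknown id
        r.lower_bound = 0.0
        r.upper_bound = 0.0
    return out


def constrain_fraction(model: MetabolicModel, reaction_id: str, fraction: float,
                       mode: str = "at-most-of-max") -> MetabolicModel:
    """Constrain a reaction relative to a maximal reference flux.

    ``at-most-of-max`` caps the reaction at ``fraction`` of its own maximal
    flux (fraction 0.25 implements "inhibit by at least 75%");
    ``at-least-of-max`` forces it to carry at least that much;
    ``exactly-of-max-objective`` pins the reaction's flux to ``fraction``
    times the *objective's* maximum (used with the objective reaction
    itself, e.g. growth at 50% of maximum).
    """
    out = model.copy()
    r = out.reaction(reaction_id)
    if mode in ("at-most-of-max", "at-least-of-max"):
        ref = fba(model, reaction_id, "max").objective_value
    elif mode == "exactly-of-max-objective":
        ref = fba(model, model.objective, "max").objective_value
    else:
        raise ValueError(f"unknown mode {mode!r}")
    val = fraction * ref
    if mode == "at-most-of-max":
        r.upper_bound = val
        r.lower_bound = min(r.lower_bound, val)
    elif mode == "at-least-of-max":
        if ref <= TAU_FEAS:
            warnings.warn(f"reaction {reaction_id!r} is blocked (max flux "
                          f"{ref:.2e}); at-least constraint left at 0",
                          stacklevel=2)
            val = 0.0
        r.lower_bound = max(r.lower_bound, val)
        r.upper_bound = max(r.upper_bound, r.lower_bound)
    else:
        r.lower_bound = val
        r.upper_bound = val
    return out.validate()
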
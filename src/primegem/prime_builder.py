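"""Phenotype-based cell-specific model construction (the PRIME algorithm).

From a generic metabolic model, a gene-expression matrix and a per-sample
phenotype (proliferation rate), build one bound-modified model per
sample:

1. split reversible reactions and tighten all upper bounds to the
   smallest common cap that preserves maximal biomass production (within
   ``epsilon``), narrowing the solution space and damping futile cycles;
2. correlate each reaction's expression (mean over its catalyzing
   enzymes) with the measured phenotype (Spearman, BH-FDR at ``alpha``)
   to select the growth-associated reaction set;
3. map the selected reactions' expression linearly onto upper bounds
   within an effective normalization range: the sign of the correlation
   orients the mapping (``E = sign(rho) * GE``) and a per-reaction
   min-max rescaling sends the lowest-expression sample to
   ``minNormVal`` and the highest to ``maxNormVal``.

The range itself is derived from the model: ``minNormVal`` is the largest
FVA flux minimum over the essential reactions (those whose knockout cuts
growth by more than 90%), i.e. the minimal flux the network must carry to
grow; ``maxNormVal`` is the end of the first linear segment of the
biomass-versus-bound curve, beyond which further bound relaxation yields
diminishing returns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import cbm_core
from .cbm_core import TAU_FEAS, fba, fva, knock_out
from .model_io import (MetabolicModel, PrimegemError, apply_media,
                       reaction_expression, split_reversible)
from .stats_validation import ConstantInputError, bh_adjust, spearman


class AssociationError(PrimegemError):
    """Growth association undefined (e.g. constant phenotype)."""


class NoAssociationsError(PrimegemError):
    """No reaction passed the FDR cut; supply an external association set."""


class RangeError(PrimegemError):
    """The normalization range could not be derived from the model."""


class DegenerateCurveError(RangeError):
    """Biomass did not respond to the bound sweep (flat curve)."""


class TransferError(PrimegemError):
    """An externally supplied association set cannot be applied."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthAssociation:
    """Per-reaction phenotype association (Spearman rho, p, BH q)."""

    reaction_id: str
    rho: float
    p_value: float
    q_value: float
    selected: bool
    tested: bool = True


@dataclass(frozen=True)
class NormalizationRange:
    """The flux window [minNormVal, maxNormVal] into which bounds are mapped."""

    min_norm_val: float
    max_norm_val: float

    def __post_init__(self):
        if not (0 < self.min_norm_val < self.max_norm_val):
            raise RangeError(
                f"invalid normalization range [{self.min_norm_val}, "
                f"{self.max_norm_val}]: need 0 < min < max")

    @property
    def width(self) -> float:
        return self.max_norm_val - self.min_norm_val

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.min_norm_val + self.max_norm_val)


@dataclass
class PrimeParams:
    """Tunable parameters of the pipeline (flux units follow the model)."""

    alpha: float = 0.05            # FDR level for the association cut
    step: float = 0.1              # bound-scan step, model flux units
    epsilon: float = 1e-4          # tolerated biomass loss while tightening
    fva_fraction: float = 0.9      # biomass fraction for essential-flux minima
    essential_threshold: float = 0.9   # growth drop defining essentiality
    slope_tol: float = 1e-3        # relative slope drop ending the first segment
    media_policy: str = "strict"


@dataclass
class PBCSModelSet:
    """One bound-modified model per sample, plus full provenance."""

    models: Dict[str, MetabolicModel]
    exp_matrix: pd.DataFrame       # E of the sign-adjusted expression (t x p)
    ub_matrix: pd.DataFrame        # normalized upper bounds (t x p)
    norm_range: NormalizationRange
    associations: List[GrowthAssociation]
    tightened_ub: float
    params: PrimeParams
    seed: Optional[int] = None
    base_model: Optional[MetabolicModel] = None

    @property
    def sample_ids(self) -> List[str]:
        return list(self.models.keys())

    @property
    def selected_reactions(self) -> List[str]:
        return list(self.ub_matrix.index)

    def provenance(self) -> dict:
        return {
            "samples": self.sample_ids,
            "selected_reactions": self.selected_reactions,
            "normalization_range": [self.norm_range.min_norm_val,
                                    self.norm_range.max_norm_val],
            "tightened_ub": self.tightened_ub,
            "params": asdict(self.params),
            "seed": self.seed,
            "associations": [asdict(a) for a in self.associations],
        }


# ---------------------------------------------------------------------------
# Step 1: global bound tightening
# ---------------------------------------------------------------------------

def tighten_global_bounds(model: MetabolicModel, step: float = 0.1,
                          epsilon: float = 1e-4,
                          ) -> Tuple[MetabolicModel, float]:
    """Cap all upper bounds at the smallest common value preserving growth.

    Scans a common cap ``U`` downward from the model's largest upper bound
    in steps of ``step`` and keeps the smallest grid value whose capped
    model (``ub_i = min(ub_i, U)``; caps never raise a bound) still attains
    at least ``B0 - epsilon`` biomass, where ``B0`` is the unmodified
    optimum.  Optimal biomass is non-decreasing in ``U``, so the grid is
    searched by bisection, which returns exactly the linear scan's answer.
    The scan floor is one step above zero.  Expects a split (irreversible)
    model; returns (capped model, U).
    """
    b0 = fba(model).objective_value
    if b0 <= TAU_FEAS:
        raise RangeError("nothing to tighten: maximal biomass is zero")
    start = max(r.upper_bound for r in model.reactions)
    if not np.isfinite(start):
        raise RangeError("cannot tighten a model with infinite upper bounds")

    def capped(u: float) -> MetabolicModel:
        out = model.copy()
        for r in out.reactions:
            r.upper_bound = min(r.upper_bound, u)
            r.lower_bound = min(r.lower_bound, r.upper_bound)
        return out

    def ok(u: float) -> bool:
        try:
            return fba(capped(u)).objective_value >= b0 - epsilon
        except cbm_core.InfeasibleError:
            return False

    n_steps = int(np.floor((start - TAU_FEAS) / step))  # grid: start - k*step > 0
    lo, hi = 0, n_steps                                 # k range; ok(0) is True
    if ok(start - n_steps * step):
        lo = hi = n_steps
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if ok(start - mid * step):
            lo = mid
        else:
            hi = mid - 1
    u = start - lo * step
    return capped(u), float(u)


# ---------------------------------------------------------------------------
# Step 2: growth association
# ---------------------------------------------------------------------------

def find_growth_associated(reaction_expr: pd.DataFrame, phenotype: pd.Series,
                           alpha: float = 0.05) -> List[GrowthAssociation]:
    """Spearman-correlate each reaction's expression with the phenotype.

    BH adjustment runs across all tested (mapped, non-constant) reactions;
    ``selected`` flags q <= alpha.  Constant expression rows are excluded
    with a warning; a constant phenotype raises :class:`AssociationError`.
    """
    samples = list(reaction_expr.columns)
    if len(samples) < 3:
        raise AssociationError("need at least 3 samples for correlation")
    if set(phenotype.index) < set(samples):
        raise AssociationError("phenotype does not cover all expression samples")
    y = phenotype.loc[samples].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise AssociationError("phenotype is constant; association undefined")

    tested_ids, rhos, ps, constant_ids = [], [], [], []
    for rid in reaction_expr.index:
        x = reaction_expr.loc[rid].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            constant_ids.append(rid)
            continue
        rho, p = spearman(x, y)
        tested_ids.append(rid)
        rhos.append(rho)
        ps.append(p)
    if constant_ids:
        warnings.warn(f"{len(constant_ids)} constant expression rows excluded "
                      f"from association testing", stacklevel=2)
    qs, sel = bh_adjust(ps, alpha=alpha) if tested_ids else (np.array([]),
                                                             np.array([], bool))
    out: List[GrowthAssociation] = []
    by_id = {rid: (r, p, q, s) for rid, r, p, q, s
             in zip(tested_ids, rhos, ps, qs, sel)}
    for rid in reaction_expr.index:
        if rid in by_id:
            r, p, q, s = by_id[rid]
            selected = bool(s) and r != 0.0
            out.append(GrowthAssociation(rid, float(r), float(p), float(q),
                                         selected, tested=True))
        else:
            out.append(GrowthAssociation(rid, float("nan"), float("nan"),
                                         float("nan"), False, tested=False))
    return out


# ---------------------------------------------------------------------------
# Normalization range
# ---------------------------------------------------------------------------

def compute_min_norm_val(model: MetabolicModel, essential_threshold: float = 0.9,
                         fva_fraction: float = 0.9) -> float:
    """Minimal flux necessary for biomass production.

    Essential reactions are those whose knockout drops growth below
    ``(1 - essential_threshold) * B0``; their FVA flux minima are taken at
    ``biomass >= fva_fraction * B0`` and the largest such minimum is
    returned (lowering any upper bound below it would be lethal).
    """
    b0 = fba(model).objective_value
    essentials = []
    for rid in model.reaction_ids:
        try:
            b_ko = fba(knock_out(model, rid)).objective_value
        except cbm_core.InfeasibleError:
            b_ko = 0.0
        if b_ko < (1.0 - essential_threshold) * b0 - TAU_FEAS:
            essentials.append(rid)
    if not essentials:
        raise RangeError("no essential reactions found; supply a "
                         "normalization range explicitly")
    ranges = fva(model, fraction=fva_fraction, reactions=essentials)
    return float(max(vmin for vmin, _ in ranges.values()))


def compute_max_norm_val(model: MetabolicModel, associated: Sequence[str],
                         min_norm_val: float, step: float = 0.1,
                         slope_tol: float = 1e-3) -> float:
    """End of the first linear segment of the biomass-versus-bound curve.

    A common upper bound ``u`` over the growth-associated reactions is
    swept from ``min_norm_val`` up to the model's largest upper bound in
    steps of ``step``, re-evaluating maximal biomass at each point.
    Returns the largest ``u`` whose marginal biomass gain still matches
    the initial per-step gain within ``slope_tol`` (relative); beyond it
    the return on relaxing the bounds diminishes.
    """
    associated = list(associated)
    if not associated:
        raise ValueError("associated reaction set is empty")
    for rid in associated:
        model.reaction(rid)  # KeyError on unknown ids
    u_max = max(r.upper_bound for r in model.reactions)
    grid = [min_norm_val]
    while grid[-1] + step <= u_max + 1e-9:
        grid.append(grid[-1] + step)
    if len(grid) < 2:
        raise DegenerateCurveError(
            "bound sweep has no room above min_norm_val")

    def biomass_at(u: float) -> float:
        work = model.copy()
        for rid in associated:
            r = work.reaction(rid)
            r.upper_bound = u
            r.lower_bound = min(r.lower_bound, u)
        try:
            return fba(work).objective_value
        except cbm_core.InfeasibleError:
            return 0.0

    b = [biomass_at(u) for u in grid]
    slope0 = (b[1] - b[0]) / step
    if slope0 <= TAU_FEAS:
        raise DegenerateCurveError(
            "biomass production is flat over the bound sweep; the "
            "associated reactions do not limit growth")
    floor = slope0 * step * (1.0 - slope_tol)
    for k in range(1, len(grid)):
        if (b[k] - b[k - 1]) < floor:
            return float(grid[k - 1])
    return float(grid[-1])


# ---------------------------------------------------------------------------
# Eq. of the expression-to-bound mapping
# ---------------------------------------------------------------------------

def build_exp_matrix(reaction_expr: pd.DataFrame,
                     associations: Sequence[GrowthAssociation]) -> pd.DataFrame:
    """Sign-adjusted expression matrix over the selected reactions.

    ``E[a, b] = sign(rho_a) * GE[a, b]``: positively correlated reactions
    keep their expression, negatively correlated ones are negated so that
    their highest-expressing samples end up with the *lowest* bounds.
    """
    rows = {}
    for a in associations:
        if not a.selected:
            continue
        if not np.isfinite(a.rho) or a.rho == 0.0:
            raise PrimegemError(
                f"selected reaction {a.reaction_id!r} has rho = {a.rho}; "
                "cannot orient the bound mapping")
        rows[a.reaction_id] = np.sign(a.rho) * reaction_expr.loc[a.reaction_id]
    if not rows:
        raise NoAssociationsError("no selected associations to map")
    return pd.DataFrame(rows).T


def normalize_bounds(exp_matrix: pd.DataFrame,
                     norm_range: NormalizationRange) -> pd.DataFrame:
    """Min-max rescale each reaction row of E into the normalization range.

    Row minima map to ``minNormVal`` and maxima to ``maxNormVal``.  A
    constant row carries no ordering information and is assigned the range
    midpoint with a warning.
    """
    lo, width = norm_range.min_norm_val, norm_range.width
    out = {}
    for rid in exp_matrix.index:
        row = exp_matrix.loc[rid].to_numpy(dtype=float)
        span = row.max() - row.min()
        if span == 0:
            warnings.warn(f"constant expression row {rid!r}: assigning the "
                          f"range midpoint", stacklevel=2)
            vals = np.full_like(row, norm_range.midpoint)
        else:
            vals = (row - row.min()) / span * width + lo
        out[rid] = np.clip(vals, lo, norm_range.max_norm_val)
    return pd.DataFrame(out, index=exp_matrix.columns).T


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class PreparedBase:
    """Split, media-constrained, tightened model plus its expression map."""

    base: MetabolicModel
    tightened_ub: float
    reaction_expr: pd.DataFrame
    unmapped: List[str]
    min_norm_val: float


def prepare_base(model: MetabolicModel, expr: pd.DataFrame,
                 media=None, params: Optional[PrimeParams] = None) -> PreparedBase:
    """Shared phenotype-independent preprocessing: media, split, tighten,
    gene-to-reaction expression mapping and the lower range endpoint."""
    p = params or PrimeParams()
    work = apply_media(model, media, policy=p.media_policy) if media else model
    work = split_reversible(work)
    work, u = tighten_global_bounds(work, step=p.step, epsilon=p.epsilon)
    rexpr, unmapped = reaction_expression(work, expr)
    min_nv = compute_min_norm_val(work, p.essential_threshold, p.fva_fraction)
    return PreparedBase(work, u, rexpr, unmapped, min_nv)


def normalization_range_for(prep: PreparedBase, selected_ids: Sequence[str],
                            params: Optional[PrimeParams] = None,
                            ) -> NormalizationRange:
    p = params or PrimeParams()
    max_nv = compute_max_norm_val(prep.base, selected_ids, prep.min_norm_val,
                                  step=p.step, slope_tol=p.slope_tol)
    return NormalizationRange(prep.min_norm_val, max_nv)


def _apply_bounds(base: MetabolicModel, ub_matrix: pd.DataFrame,
                  ) -> Dict[str, MetabolicModel]:
    models = {}
    for sample in ub_matrix.columns:
        m = base.copy()
        m.id = f"{base.id}::{sample}"
        for rid in ub_matrix.index:
            r = m.reaction(rid)
            r.upper_bound = float(ub_matrix.at[rid, sample])
            r.lower_bound = min(r.lower_bound, r.upper_bound)
        models[str(sample)] = m.validate()
    return models


def build_models(model: MetabolicModel, expr: pd.DataFrame,
                 phenotype: pd.Series, media=None,
                 params: Optional[PrimeParams] = None,
                 seed: Optional[int] = None) -> PBCSModelSet:
    """Run the full pipeline and return one model per expression sample.

    Both split directions of a selected reversible reaction share a gene
    set, hence an expression row, hence a correlation: the normalized
    bound is applied to both copies symmetrically.  An empty association
    set raises :class:`NoAssociationsError` (use
    :func:`build_models_transfer` with an external set as the remedy).
    """
    p = params or PrimeParams()
    prep = prepare_base(model, expr, media=media, params=p)
    phenotype = phenotype.loc[list(expr.columns)]
    assoc = find_growth_associated(prep.reaction_expr, phenotype, alpha=p.alpha)
    selected = [a for a in assoc if a.selected]
    if not selected:
        raise NoAssociationsError(
            "no reaction expression is significantly associated with the "
            "phenotype at the requested FDR level")
    nrange = normalization_range_for(prep, [a.reaction_id for a in selected],
                                     params=p)
    E = build_exp_matrix(prep.reaction_expr, selected)
    UB = normalize_bounds(E, nrange)
    models = _apply_bounds(prep.base, UB)
    return PBCSModelSet(models, E, UB, nrange, assoc, prep.tightened_ub, p,
                        seed=seed, base_model=prep.base)


def build_models_transfer(model: MetabolicModel, expr: pd.DataFrame,
                          associations: Sequence[GrowthAssociation],
                          norm_range: Optional[NormalizationRange] = None,
                          media=None, params: Optional[PrimeParams] = None,
                          _prepared: Optional[PreparedBase] = None,
                          ) -> PBCSModelSet:
    """Build models for a new cohort from an external association set.

    Identical to :func:`build_models` but skipping the correlation step
    (no phenotype needed): the supplied associations carry the selected
    reactions and correlation signs, and the expression-to-bound
    normalization is re-anchored across the *new* cohort's samples.
    """
    p = params or PrimeParams()
    selected = [a for a in associations if a.selected]
    if not selected:
        raise TransferError("external association set is empty")
    prep = _prepared or prepare_base(model, expr, media=media, params=p)
    known = set(prep.reaction_expr.index)
    missing = [a.reaction_id for a in selected if a.reaction_id not in known]
    if missing:
        raise TransferError(
            f"association reactions absent from the model or unmapped in the "
            f"expression matrix: {missing}")
    if norm_range is None:
        norm_range = normalization_range_for(
            prep, [a.reaction_id for a in selected], params=p)
    rexpr = prep.reaction_expr[list(expr.columns)]
    E = build_exp_matrix(rexpr, selected)
    UB = normalize_bounds(E, norm_range)
    models = _apply_bounds(prep.base, UB)
    return PBCSModelSet(models, E, UB, norm_range, list(associations),
                        prep.tightened_ub, p, base_model=prep.base)
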
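"""Downstream phenotype simulation on cell-specific model sets.

Growth prediction (per-model FBA biomass optimum), reaction/gene
knockdown screens (FBA re-optimization or MOMA against sampled wild-type
flux distributions), differential-target ranking, cancer-versus-normal
selectivity classification and scoring, ATP- and IC50/AC50-style drug
response estimation, exchange-flux (uptake/secretion) prediction, and
pre/post-knockdown flux-shift analysis via one-sided rank-sum tests.

Growth survival ``Gs`` is the fraction of the sample's wild-type growth
retained after the perturbation, clipped to [0, 1] after solver
tolerance; growth inhibition is ``Gi = 1 - Gs``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import cbm_core
from .cbm_core import (TAU_FEAS, FluxDistribution, fba, knock_out, moma,
                       sample_wt_distributions)
from .model_io import MetabolicModel, PrimegemError
from .prime_builder import PBCSModelSet
from .stats_validation import bh_adjust

ModelSet = Union[PBCSModelSet, Mapping[str, MetabolicModel]]


def _models_of(models: ModelSet) -> Dict[str, MetabolicModel]:
    if isinstance(models, PBCSModelSet):
        return models.models
    return dict(models)


# ---------------------------------------------------------------------------
# growth prediction
# ---------------------------------------------------------------------------

def predict_growth(models: ModelSet) -> pd.Series:
    """FBA biomass optimum per sample model.

    Infeasible sample models are recorded as NaN (and warned about),
    never silently reported as zero growth.
    """
    out = {}
    failed = []
    for sample, m in _models_of(models).items():
        try:
            out[sample] = fba(m).objective_value
        except cbm_core.InfeasibleError:
            out[sample] = float("nan")
            failed.append(sample)
    if failed:
        warnings.warn(f"growth prediction failed (infeasible) for {failed}",
                      stacklevel=2)
    return pd.Series(out, name="predicted_growth")


# ---------------------------------------------------------------------------
# knockdown screen
# ---------------------------------------------------------------------------

@dataclass
class KnockdownResult:
    """Effect of one target perturbation in one sample model."""

    sample: str
    target: str            # as requested (gene or reaction id)
    reactions: Tuple[str, ...]  # reactions actually perturbed
    mode: str
    gs: Optional[float]    # growth survival in [0, 1]; None if undefined
    growth: Optional[float]      # post-perturbation growth
    wt_growth: Optional[float]   # forced wild-type reference growth
    note: str = ""

    @property
    def gi(self) -> Optional[float]:
        return None if self.gs is None else 1.0 - self.gs


def _expand_target(model: MetabolicModel, target: str) -> List[str]:
    """A reaction id maps to itself; a gene id expands to every reaction
    catalyzed solely by that gene (isoenzyme-backed reactions remain)."""
    if target in set(model.reaction_ids):
        return [target]
    rxns = [r.id for r in model.reactions if r.genes == frozenset([target])]
    return rxns


def knockdown_screen(models: ModelSet, targets: Sequence[str],
                     mode: str = "fba-max", inhibition: float = 0.75,
                     force_wt: float = 0.5, wt_samples: int = 10,
                     seed: int = 0) -> List[KnockdownResult]:
    """Simulate partial knockdown of each target in each sample model.

    Per sample and target: the target's maximal attainable flux ``tmax``
    is found; the wild-type reference fixes the target active at
    ``force_wt * tmax`` and maximizes growth; the perturbed model caps the
    target at ``(1 - inhibition) * tmax`` (the forcing is dropped).  Under
    ``fba-max`` the perturbed growth is re-optimized; under ``moma`` it is
    averaged over ``wt_samples`` sampled wild-type distributions adjusted
    by MOMA.  Unmappable targets are skipped with a note; infeasible
    forcing leaves ``gs`` undefined and flagged.
    """
    if mode not in ("fba-max", "moma"):
        raise ValueError(f"unknown screen mode {mode!r}")
    out: List[KnockdownResult] = []
    for si, (sample, m) in enumerate(_models_of(models).items()):
        for target in targets:
            rxns = _expand_target(m, target)
            if not rxns:
                out.append(KnockdownResult(sample, target, (), mode, None,
                                           None, None, "target unmappable"))
                continue
            res = _knockdown_one(m, sample, target, rxns, mode, inhibition,
                                 force_wt, wt_samples,
                                 seed=seed + 7919 * si)
            out.append(res)
    return out


def _knockdown_one(m: MetabolicModel, sample: str, target: str,
                   rxns: List[str], mode: str, inhibition: float,
                   force_wt: float, wt_samples: int, seed: int,
                   ) -> KnockdownResult:
    tmax = {rid: fba(m, rid, "max").objective_value for rid in rxns}
    forced = m.copy()
    for rid in rxns:
        r = forced.reaction(rid)
        r.lower_bound = max(r.lower_bound, force_wt * tmax[rid])
    try:
        wt_growth = fba(forced).objective_value
    except cbm_core.InfeasibleError:
        return KnockdownResult(sample, target, tuple(rxns), mode, None, None,
                               None, "forcing infeasible")
    perturbed = m.copy()
    for rid in rxns:
        r = perturbed.reaction(rid)
        r.upper_bound = min(r.upper_bound, (1.0 - inhibition) * tmax[rid])
        r.lower_bound = min(r.lower_bound, r.upper_bound)
    if mode == "fba-max":
        try:
            growth = fba(perturbed).objective_value
        except cbm_core.InfeasibleError:
            return KnockdownResult(sample, target, tuple(rxns), mode, None,
                                   None, wt_growth, "perturbed infeasible")
    else:
        force = (rxns[0], force_wt) if len(rxns) == 1 else None
        wt_model = forced if force is None else m
        dists = sample_wt_distributions(wt_model, wt_samples, force=force,
                                        seed=seed)
        growth = float(np.mean([moma(perturbed, d).objective_value
                                for d in dists]))
    if wt_growth <= TAU_FEAS:
        return KnockdownResult(sample, target, tuple(rxns), mode, None, growth,
                               wt_growth, "wild-type growth is zero")
    gs = float(np.clip(growth / wt_growth, 0.0, 1.0))
    return KnockdownResult(sample, target, tuple(rxns), mode, gs, growth,
                           wt_growth)


def screen_to_frame(screen: Sequence[KnockdownResult]) -> pd.DataFrame:
    """Tidy (sample, target, mode, Gs, Gi, growth) table of a screen."""
    return pd.DataFrame([{
        "sample": r.sample, "target": r.target, "mode": r.mode,
        "Gs": r.gs, "Gi": r.gi, "growth": r.growth,
        "wt_growth": r.wt_growth, "note": r.note,
    } for r in screen])


# ---------------------------------------------------------------------------
# differential-target ranking
# ---------------------------------------------------------------------------

def rank_differential_targets(screen: Sequence[KnockdownResult],
                              model: MetabolicModel,
                              max_reactions_per_gene: int = 3,
                              ) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Rank single-gene targets by cross-sample variance of post-KD growth.

    Filters to reactions catalyzed by exactly one gene whose gene maps to
    at most ``max_reactions_per_gene`` reactions, excluding exchange and
    cross-compartment transport reactions; the survivors are ranked by the
    variance of their knockdown growth across samples, descending.
    Returns (ranked table, filter attrition counts).
    """
    by_gene = model.reactions_by_gene()
    attrition = {"not_single_gene": 0, "gene_too_promiscuous": 0,
                 "transport_or_exchange": 0, "too_few_samples": 0}
    rows = []
    frame = screen_to_frame(list(screen)).dropna(subset=["growth"])
    for target, grp in frame.groupby("target"):
        if target not in set(model.reaction_ids):
            continue
        rid = target
        genes = model.reaction(rid).genes
        if len(genes) != 1:
            attrition["not_single_gene"] += 1
            continue
        gene = next(iter(genes))
        if len(by_gene.get(gene, [])) > max_reactions_per_gene:
            attrition["gene_too_promiscuous"] += 1
            continue
        if model.is_exchange(rid) or model.is_transport(rid):
            attrition["transport_or_exchange"] += 1
            continue
        if len(grp) < 2:
            attrition["too_few_samples"] += 1
            continue
        rows.append({"target": target, "gene": gene,
                     "variance": float(grp["growth"].var(ddof=1)),
                     "n_samples": len(grp)})
    table = pd.DataFrame(rows, columns=["target", "gene", "variance",
                                        "n_samples"])
    if len(table):
        table = table.sort_values("variance", ascending=False,
                                  kind="mergesort").reset_index(drop=True)
    return table, attrition


# ---------------------------------------------------------------------------
# selectivity
# ---------------------------------------------------------------------------

@dataclass
class SelectivityRecord:
    """Cancer-versus-normal effect of one target across two model cohorts."""

    target: str
    gi_cancer: Dict[str, float]
    gi_normal: Dict[str, float]
    score: float
    klass: str  # selective | non-selective | neither

    @property
    def worst_gi_cancer(self) -> float:
        return min(self.gi_cancer.values())

    @property
    def worst_gi_normal(self) -> float:
        return max(self.gi_normal.values())


def selectivity_classify(cancer_screen: Sequence[KnockdownResult],
                         normal_screen: Sequence[KnockdownResult],
                         sel_normal_max: float = 0.20,
                         sel_cancer_min: float = 0.30,
                         gap_min: float = 0.20,
                         nonsel_min: float = 0.50,
                         summary: str = "mean") -> List[SelectivityRecord]:
    """Classify targets as selective / non-selective / neither.

    Selective: Gi < ``sel_normal_max`` in *every* normal sample, Gi >
    ``sel_cancer_min`` in *every* cancer sample, and the smallest
    cancer-normal inhibition gap exceeds ``gap_min``.  Non-selective:
    Gi > ``nonsel_min`` in every sample of both cohorts.  The score is
    ``(Gi_cancer - Gi_normal) * Gs_normal`` on cohort-level summaries
    (``summary``: 'mean' or 'worst').
    """
    if summary not in ("mean", "worst"):
        raise ValueError(f"unknown summary {summary!r}")
    c_by: Dict[str, Dict[str, float]] = {}
    n_by: Dict[str, Dict[str, float]] = {}
    for r in cancer_screen:
        if r.gi is not None:
            c_by.setdefault(r.target, {})[r.sample] = r.gi
    for r in normal_screen:
        if r.gi is not None:
            n_by.setdefault(r.target, {})[r.sample] = r.gi
    if set(c_by) != set(n_by):
        raise PrimegemError(
            f"target universes differ between screens: "
            f"{sorted(set(c_by) ^ set(n_by))}")
    out = []
    for target in sorted(c_by):
        gic, gin = c_by[target], n_by[target]
        if summary == "mean":
            gi_c, gi_n = float(np.mean(list(gic.values()))), \
                float(np.mean(list(gin.values())))
        else:
            gi_c, gi_n = min(gic.values()), max(gin.values())
        score = (gi_c - gi_n) * (1.0 - gi_n)
        gap = min(gic.values()) - max(gin.values())
        if (max(gin.values()) < sel_normal_max
                and min(gic.values()) > sel_cancer_min and gap > gap_min):
            klass = "selective"
        elif (min(gic.values()) > nonsel_min and min(gin.values()) > nonsel_min):
            klass = "non-selective"
        else:
            klass = "neither"
        out.append(SelectivityRecord(target, gic, gin, float(score), klass))
    return out


# ---------------------------------------------------------------------------
# drug response
# ---------------------------------------------------------------------------

@dataclass
class AtpResponse:
    sample: str
    atp_pre: float    # mean ATP flux over the forced wild-type samples
    atp_post: float   # mean ATP flux after target knockout, via MOMA
    note: str = ""


def drug_response_atp(models: ModelSet, target: str, atp_reaction: str,
                      force_wt: float = 0.5, wt_samples: int = 10,
                      seed: int = 0) -> List[AtpResponse]:
    """Estimate post-knockout ATP production per sample.

    Wild-type distributions are sampled with the drug-target reaction
    forced to carry at least ``force_wt`` of its maximal flux (so the
    knockout has something to perturb); the knockout distribution is the
    MOMA adjustment to the target-deleted model; the mean flux through
    ``atp_reaction`` before and after is reported.
    """
    out = []
    for si, (sample, m) in enumerate(_models_of(models).items()):
        m.reaction(atp_reaction)
        try:
            dists = sample_wt_distributions(m, wt_samples,
                                            force=(target, force_wt),
                                            seed=seed + 7919 * si)
        except cbm_core.InfeasibleError as exc:
            out.append(AtpResponse(sample, float("nan"), float("nan"),
                                   f"forcing infeasible: {exc}"))
            continue
        ko = knock_out(m, [target])
        pre = float(np.mean([d.flux(atp_reaction) for d in dists]))
        post = float(np.mean([moma(ko, d).flux(atp_reaction) for d in dists]))
        out.append(AtpResponse(sample, pre, post))
    return out


def drug_response_ic50(models: ModelSet, target: str,
                       response_level: Optional[Mapping[str, float]] = None,
                       fraction: float = 0.5) -> pd.Series:
    """In-silico IC50/AC50 proxy: maximal target flux at half-growth.

    Growth is pinned to ``fraction`` of its maximum (IC50) or of a
    supplied per-sample maximal response level (AC50), and the maximal
    flux the target reaction can still carry is returned per sample.
    Blocked targets yield 0 with a warning.
    """
    out = {}
    for sample, m in _models_of(models).items():
        m.reaction(target)
        if response_level is not None:
            level = fraction * float(response_level[sample])
        else:
            level = fraction * fba(m).objective_value
        pinned = m.copy()
        r = pinned.reaction(pinned.objective)
        # pin growth with a tolerance collar to stay numerically feasible
        r.lower_bound = level - TAU_FEAS * max(1.0, abs(level))
        r.upper_bound = level + TAU_FEAS * max(1.0, abs(level))
        val = fba(pinned, target, "max").objective_value
        if abs(val) <= TAU_FEAS:
            warnings.warn(f"target {target!r} is blocked in sample {sample!r}",
                          stacklevel=2)
            val = 0.0
        out[sample] = float(val)
    return pd.Series(out, name=f"max_{target}_flux")


# ---------------------------------------------------------------------------
# exchange rates
# ---------------------------------------------------------------------------

def predict_exchange_rates(models: ModelSet, exchange_ids: Sequence[str],
                           growth_fraction: float = 0.9) -> pd.DataFrame:
    """Maximal exchange flux magnitude at near-maximal growth.

    Biomass is constrained to at least ``growth_fraction`` of its optimum
    and the exchange flux is pushed to its extreme in whichever direction
    admits the larger magnitude; the signed net flux is reported (uptake
    negative).  Split exchange pairs are recombined through the model's
    split map when the original exchange id is queried.
    """
    rows = {}
    for sample, m in _models_of(models).items():
        opt = fba(m).objective_value
        work = m.copy()
        r_obj = work.reaction(work.objective)
        r_obj.lower_bound = max(r_obj.lower_bound,
                                growth_fraction * opt - TAU_FEAS)
        vals = {}
        for ex in exchange_ids:
            vals[ex] = _net_exchange_extreme(work, ex)
        rows[sample] = vals
    return pd.DataFrame(rows).T[list(exchange_ids)]


def _net_exchange_extreme(model: MetabolicModel, ex: str) -> float:
    S, lb, ub, rids = cbm_core._arrays(model)
    c = np.zeros(len(rids))
    if ex in set(rids):
        c[rids.index(ex)] = 1.0
    elif ex in model.split_map:
        fid, bid = model.split_map[ex]
        c[rids.index(fid)] = 1.0
        if bid is not None:
            c[rids.index(bid)] = -1.0
    else:
        raise KeyError(f"exchange reaction {ex!r} not found in model")
    vmax = float(c @ cbm_core._solve_lp(S, lb, ub, c, "max"))
    vmin = float(c @ cbm_core._solve_lp(S, lb, ub, c, "min"))
    return vmin if abs(vmin) > abs(vmax) else vmax


# ---------------------------------------------------------------------------
# flux-shift analysis
# ---------------------------------------------------------------------------

@dataclass
class FluxShiftReport:
    reaction_id: str
    direction: str      # up | down | unchanged
    p_value: float      # one-sided rank-sum p of the reported direction
    q_value: float      # BH-adjusted across reactions


def flux_shift_analysis(model: MetabolicModel, target: str, n: int = 1000,
                        force_wt: float = 0.5, inhibition: float = 1.0,
                        seed: int = 0, alpha: float = 0.05,
                        ) -> List[FluxShiftReport]:
    """Reactions whose flux shifts significantly after a target knockdown.

    ``n`` wild-type distributions are sampled with the target forced
    active; each is MOMA-adjusted to the knockdown model (target capped at
    ``(1 - inhibition)`` of its maximal flux).  Per reaction, one-sided
    rank-sum tests are run in both directions, BH-adjusted across
    reactions; the direction with the smaller adjusted p is reported, or
    ``unchanged`` if neither passes ``alpha``.
    """
    tmax = fba(model, target, "max").objective_value
    dists = sample_wt_distributions(model, n, force=(target, force_wt),
                                    seed=seed)
    perturbed = model.copy()
    r = perturbed.reaction(target)
    r.upper_bound = min(r.upper_bound, (1.0 - inhibition) * tmax)
    r.lower_bound = min(r.lower_bound, r.upper_bound)
    post = [moma(perturbed, d) for d in dists]
    rids = model.reaction_ids
    pre_mat = np.array([[d.flux(rid) for rid in rids] for d in dists])
    post_mat = np.array([[d.flux(rid) for rid in rids] for d in post])
    p_up = np.empty(len(rids))
    p_down = np.empty(len(rids))
    for j in range(len(rids)):
        a, b = post_mat[:, j], pre_mat[:, j]
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            p_up[j] = p_down[j] = 1.0
            continue
        p_up[j] = sps.ranksums(a, b, alternative="greater").pvalue
        p_down[j] = sps.ranksums(a, b, alternative="less").pvalue
    q_up, _ = bh_adjust(p_up, alpha)
    q_down, _ = bh_adjust(p_down, alpha)
    out = []
    for j, rid in enumerate(rids):
        if q_up[j] <= alpha and q_up[j] <= q_down[j]:
            out.append(FluxShiftReport(rid, "up", float(p_up[j]), float(q_up[j])))
        elif q_down[j] <= alpha:
            out.append(FluxShiftReport(rid, "down", float(p_down[j]),
                                       float(q_down[j])))
        else:
            q = min(q_up[j], q_down[j])
            p = p_up[j] if q_up[j] <= q_down[j] else p_down[j]
            out.append(FluxShiftReport(rid, "unchanged", float(p), float(q)))
    return out
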
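"""Synthetic fixtures with known ground truth.

Hand-solved toy metabolic models, seeded expression/phenotype cohorts
whose growth-associated genes and effect directions are known by
construction, an expression-proportional baseline bound-setter (the
simple comparator the phenotype-aware pipeline improves on), and an
engineered two-cohort design with a built-in cancer-selective target.

The cohort generator emulates the statistical regime that motivates
phenotype-based modeling: near-identical transcriptomes across samples
(high inter-sample correlation) with a subtle growth-linked signal in a
small gene subset.  It does not attempt realistic transcriptome
covariance or genome scale.

Toy models (uptake negative on unsplit exchanges):

``chain``
    EX_A [-10, 0] -> R1: A -> B -> BIOMASS.  Optimum 10; every interior
    reaction is essential; at 90% growth the chain must carry 9.
``parallel``
    Two routes A -> B (R1, R2).  Optimum 10; knocking out either route
    alone leaves the optimum at 10.
``branched-atp``
    Adds an ATP branch (RATP: A -> ATP, ATPD demand) competing with
    biomass for the shared input: forcing ATP demand d yields biomass
    10 - d.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import prime_builder
from .model_io import (MetabolicModel, Metabolite, PrimegemError, Reaction,
                       reaction_expression, split_reversible)
from .cbm_core import fba

_WIDE = 1000.0


# ---------------------------------------------------------------------------
# toy models
# ---------------------------------------------------------------------------

def _rxn(rid, stoich, lb, ub, genes=()):
    return Reaction(rid, dict(stoich), float(lb), float(ub), frozenset(genes))


def make_toy_model(name: str) -> MetabolicModel:
    """Return a named toy fixture with documented hand-solved FBA optima."""
    if name == "chain":
        model = MetabolicModel(
            id="chain",
            metabolites=[Metabolite("A"), Metabolite("B")],
            reactions=[
                _rxn("EX_A", {"A": -1}, -10, 0),
                _rxn("R1", {"A": -1, "B": 1}, 0, _WIDE, {"gR1"}),
                _rxn("BIOMASS", {"B": -1}, 0, _WIDE),
            ],
            objective="BIOMASS", exchanges=frozenset({"EX_A"}))
    elif name == "parallel":
        model = MetabolicModel(
            id="parallel",
            metabolites=[Metabolite("A"), Metabolite("B")],
            reactions=[
                _rxn("EX_A", {"A": -1}, -10, 0),
                _rxn("R1", {"A": -1, "B": 1}, 0, _WIDE, {"gR1"}),
                _rxn("R2", {"A": -1, "B": 1}, 0, _WIDE, {"gR2"}),
                _rxn("BIOMASS", {"B": -1}, 0, _WIDE),
            ],
            objective="BIOMASS", exchanges=frozenset({"EX_A"}))
    elif name == "branched-atp":
        model = MetabolicModel(
            id="branched-atp",
            metabolites=[Metabolite("A"), Metabolite("B"), Metabolite("ATP")],
            reactions=[
                _rxn("EX_A", {"A": -1}, -10, 0),
                _rxn("R1", {"A": -1, "B": 1}, 0, _WIDE, {"gR1"}),
                _rxn("RATP", {"A": -1, "ATP": 1}, 0, _WIDE, {"gATP"}),
                _rxn("ATPD", {"ATP": -1}, 0, _WIDE),
                _rxn("BIOMASS", {"B": -1}, 0, _WIDE),
            ],
            objective="BIOMASS", exchanges=frozenset({"EX_A"}))
    else:
        raise ValueError(f"unknown toy model {name!r}; expected chain, "
                         f"parallel or branched-atp")
    return model.validate()


def make_cohort_model(n_decoy_reactions: int = 19) -> MetabolicModel:
    """The chain fixture extended with gene-bearing decoy side branches.

    Each decoy ``Dk: A -> Wk`` (gene ``gDk``) plus a secretion ``EX_Wk``
    drains the shared input without contributing to biomass, so decoys
    never limit growth; they exist to populate the association test with
    null reactions.  The chain's hand-solved values (optimum 10, essential
    set, normalization range [9, 10]) are unchanged.
    """
    model = make_toy_model("chain")
    mets = list(model.metabolites)
    rxns = [r.copy() for r in model.reactions]
    exchanges = set(model.exchanges)
    for k in range(n_decoy_reactions):
        w = f"W{k}"
        mets.append(Metabolite(w))
        rxns.append(_rxn(f"D{k}", {"A": -1, w: 1}, 0, _WIDE, {f"gD{k}"}))
        rxns.append(_rxn(f"EX_{w}", {w: -1}, 0, _WIDE))
        exchanges.add(f"EX_{w}")
    out = MetabolicModel(id="cohort-chain", metabolites=mets, reactions=rxns,
                         objective="BIOMASS", exchanges=frozenset(exchanges))
    return out.validate()


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Generative recipe for a synthetic expression/phenotype cohort.

    ``association`` maps each growth-associated gene to its effect
    direction (+1: expression rises with growth, -1: falls).  True genes
    get expression affine in the designed growth rate plus Gaussian noise
    ``sigma``; decoy genes get i.i.d. jitter (sd ``decoy_sd``) around
    per-gene baselines shared across samples, so inter-sample expression
    correlation stays high.  Designed growth rates must be attainable by
    the target model.
    """

    n_samples: int = 40
    growth_rates: Optional[Sequence[float]] = None   # default: linspace(9, 10)
    association: Mapping[str, int] = field(
        default_factory=lambda: {"gR1": +1})
    n_decoys: int = 19
    sigma: float = 0.0          # noise sd on the growth-linked expression
    pheno_sigma: float = 0.0    # measurement noise sd on the phenotype
    decoy_sd: float = 1.0
    baseline: float = 100.0     # expression scale of the cohort
    effect_scale: float = 10.0  # expression units per unit growth rate
    seed: int = 0


def make_cohort(model: MetabolicModel, spec: CohortSpec,
                ) -> Tuple[pd.DataFrame, pd.Series, dict]:
    """Generate (expression, phenotype, ground truth) for ``model``.

    Decoy genes are drawn from the model's gene complement not named in
    ``spec.association`` (exercising the association null); if the model
    runs out, extra unmapped decoy gene ids are appended (exercising the
    unmapped-gene flag path).
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.n_samples
    growth = (np.asarray(spec.growth_rates, dtype=float)
              if spec.growth_rates is not None else np.linspace(9.0, 10.0, p))
    if len(growth) != p:
        raise PrimegemError("growth_rates length must equal n_samples")
    bmax = fba(model).objective_value
    if (growth < 0).any() or (growth > bmax + 1e-9).any():
        raise PrimegemError(
            f"designed growth rates outside the attainable range [0, {bmax}]")
    for g, d in spec.association.items():
        if g not in model.genes:
            raise PrimegemError(f"associated gene {g!r} not in model")
        if d not in (+1, -1):
            raise PrimegemError(f"direction for {g!r} must be +1 or -1")

    samples = [f"S{i:03d}" for i in range(p)]
    centered = growth - growth.mean()
    rows, index = [], []
    for g, d in spec.association.items():
        expr = (spec.baseline + d * spec.effect_scale * centered
                + rng.normal(0.0, spec.sigma, size=p))
        rows.append(expr)
        index.append(g)
    pool = sorted(model.genes - set(spec.association))
    decoys = pool[: spec.n_decoys]
    decoys += [f"gNOISE{k}" for k in range(spec.n_decoys - len(decoys))]
    for g in decoys:
        base_g = spec.baseline * rng.uniform(0.5, 1.5)
        rows.append(base_g + rng.normal(0.0, spec.decoy_sd, size=p))
        index.append(g)
    expr = pd.DataFrame(rows, index=index, columns=samples)
    phenotype = pd.Series(
        growth + rng.normal(0.0, spec.pheno_sigma, size=p),
        index=samples, name="growth_rate")

    by_gene = model.reactions_by_gene()
    truth = {
        "association": dict(spec.association),
        "reactions": {rid: d for g, d in spec.association.items()
                      for rid in by_gene.get(g, [])},
        "decoys": decoys,
        "growth_rates": growth.tolist(),
        "seed": spec.seed,
    }
    return expr, phenotype, truth


# ---------------------------------------------------------------------------
# expression-proportional baseline
# ---------------------------------------------------------------------------

def eflux_baseline(model: MetabolicModel, expr: pd.DataFrame,
                   params: Optional[prime_builder.PrimeParams] = None,
                   ) -> Dict[str, MetabolicModel]:
    """Expression-proportional bound setting (comparison baseline only).

    Every mapped reaction's upper bound is scaled by its expression
    relative to the reaction's cohort maximum, applied to the split,
    globally tightened model — no phenotype input, no reaction selection
    and no sign handling.  Deliberately simple: on cohorts whose binding
    reaction is negatively growth-correlated this baseline inverts the
    growth ranking, which is exactly what the sign-aware pipeline fixes.
    """
    p = params or prime_builder.PrimeParams()
    base = split_reversible(model)
    base, u = prime_builder.tighten_global_bounds(base, p.step, p.epsilon)
    rexpr, _ = reaction_expression(base, expr)
    out: Dict[str, MetabolicModel] = {}
    for sample in expr.columns:
        m = base.copy()
        m.id = f"{base.id}::eflux::{sample}"
        for rid in rexpr.index:
            row = rexpr.loc[rid]
            top = float(row.max())
            if top <= 0:
                continue
            r = m.reaction(rid)
            r.upper_bound = r.upper_bound * max(0.0, float(row[sample])) / top
            r.lower_bound = min(r.lower_bound, r.upper_bound)
        out[str(sample)] = m.validate()
    return out


# ---------------------------------------------------------------------------
# engineered selectivity cohorts
# ---------------------------------------------------------------------------

def make_selectivity_cohorts(n_cancer: int = 4, n_normal: int = 4,
                             ) -> Tuple[Dict[str, MetabolicModel],
                                        Dict[str, MetabolicModel], dict]:
    """Two model cohorts with one engineered cancer-selective target.

    The shared network feeds biomass through RT (gene gT) or a bypass
    RALT (gene gALT), then an obligatory step RC (gene gC); a detached
    side pathway RS (gene gS) runs off its own input.  Cancer models have
    the bypass closed, so inhibiting RT collapses their growth; normal
    models keep the bypass open and shrug the inhibition off.  RC is
    essential everywhere (the engineered non-selective target) and RS
    touches nothing (neither class).  Ground truth names the classes.
    """
    def build(cancer: bool, tag: str) -> MetabolicModel:
        alt_ub = 0.0 if cancer else 10.0
        model = MetabolicModel(
            id=tag,
            metabolites=[Metabolite("A"), Metabolite("B"), Metabolite("C"),
                         Metabolite("D"), Metabolite("W")],
            reactions=[
                _rxn("EX_A", {"A": 1}, 0, 10),
                _rxn("RT", {"A": -1, "B": 1}, 0, 10, {"gT"}),
                _rxn("RALT", {"A": -1, "B": 1}, 0, alt_ub, {"gALT"}),
                _rxn("RC", {"B": -1, "C": 1}, 0, 10, {"gC"}),
                _rxn("BIOMASS", {"C": -1}, 0, 10),
                _rxn("EX_D", {"D": 1}, 0, 10),
                _rxn("RS", {"D": -1, "W": 1}, 0, 10, {"gS"}),
                _rxn("EX_W", {"W": -1}, 0, 10),
            ],
            objective="BIOMASS",
            exchanges=frozenset({"EX_A", "EX_D", "EX_W"}))
        return model.validate()

    cancer = {f"C{i}": build(True, f"cancer-{i}") for i in range(n_cancer)}
    normal = {f"N{i}": build(False, f"normal-{i}") for i in range(n_normal)}
    truth = {"selective": ["RT"], "non_selective": ["RC"], "neither": ["RS"]}
    return cancer, normal, truth
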
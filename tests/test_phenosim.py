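"""Downstream simulations: growth, knockdowns, selectivity, drugs, exchanges."""

import numpy as np
import pandas as pd
import pytest

import primegem as pg
from primegem.phenosim import screen_to_frame


@pytest.fixture(scope="module")
def sel_cohorts():
    return pg.make_selectivity_cohorts(n_cancer=3, n_normal=3)


@pytest.fixture(scope="module")
def sel_screens(sel_cohorts):
    cancer, normal, _ = sel_cohorts
    targets = ["RT", "RC", "RS"]
    sc = pg.knockdown_screen(cancer, targets, mode="fba-max", seed=1)
    sn = pg.knockdown_screen(normal, targets, mode="fba-max", seed=1)
    return sc, sn


# ---------------------------------------------------------------------------
# growth prediction
# ---------------------------------------------------------------------------

def test_predict_growth_matches_designed_ranks(cohort_mset, cohort):
    _, pheno, _ = cohort
    pred = pg.predict_growth(cohort_mset)
    rho, _ = pg.spearman(pred.loc[pheno.index].to_numpy(), pheno.to_numpy())
    assert rho == pytest.approx(1.0)
    # the sample pinned at the bottom of the range grows least
    low = cohort_mset.ub_matrix.loc["R1"].idxmin()
    assert pred.idxmin() == low


def test_predict_growth_uniform_expression_gives_equal_models(cohort_model):
    expr, pheno, _ = pg.make_cohort(cohort_model, pg.CohortSpec(seed=0))
    flat = expr.copy()
    flat.loc["gR1"] = 100.0  # no growth signal left in the mapped gene
    with pytest.raises(pg.prime_builder.NoAssociationsError):
        pg.build_models(cohort_model, flat, pheno)
    # identical expression columns (transfer mode) -> identical growth
    assoc = [pg.GrowthAssociation("R1", 1.0, 1e-9, 1e-8, True)]
    two = expr[[expr.columns[0]]].copy()
    two["twin"] = two.iloc[:, 0]
    with pytest.warns(UserWarning, match="constant"):
        mset = pg.build_models_transfer(cohort_model, two, assoc,
                                        pg.NormalizationRange(9.0, 10.0))
    pred = pg.predict_growth(mset)
    assert pred.iloc[0] == pytest.approx(pred.iloc[1], rel=1e-9)


def test_predict_growth_flags_infeasible_models(split_chain):
    broken = split_chain.copy()
    broken.reaction("BIOMASS").lower_bound = 50.0
    with pytest.warns(UserWarning, match="infeasible"):
        pred = pg.predict_growth({"ok": split_chain, "bad": broken})
    assert pred["ok"] == pytest.approx(10.0, rel=1e-6)
    assert np.isnan(pred["bad"])


# ---------------------------------------------------------------------------
# knockdown screen
# ---------------------------------------------------------------------------

def test_full_knockout_of_essential_chain_reaction(split_chain):
    res = pg.knockdown_screen({"s": split_chain}, ["R1"], mode="fba-max",
                              inhibition=1.0)
    assert res[0].gs == pytest.approx(0.0, abs=1e-7)
    assert res[0].gi == pytest.approx(1.0, abs=1e-7)


def test_parallel_path_rescues_fba_knockout(split_parallel):
    res = pg.knockdown_screen({"s": split_parallel}, ["R1"], mode="fba-max",
                              inhibition=1.0)
    assert res[0].gs == pytest.approx(1.0, abs=1e-7)


def test_partial_inhibition_caps_growth(split_chain):
    res = pg.knockdown_screen({"s": split_chain}, ["R1"], mode="fba-max",
                              inhibition=0.75)
    # R1 max is 10 -> capped at 2.5 -> growth 2.5 of wt 10
    assert res[0].growth == pytest.approx(2.5, rel=1e-6)
    assert res[0].gs == pytest.approx(0.25, rel=1e-6)


def test_gene_target_expansion_and_unmappable(split_parallel):
    res = pg.knockdown_screen({"s": split_parallel}, ["gR1", "gGHOST"],
                              mode="fba-max", inhibition=1.0)
    by_target = {r.target: r for r in res}
    assert by_target["gR1"].reactions == ("R1",)
    assert by_target["gGHOST"].gs is None
    assert by_target["gGHOST"].note == "target unmappable"


def test_moma_mode_bounded_by_fba_mode(split_parallel, split_chain):
    for model in (split_parallel, split_chain):
        f = pg.knockdown_screen({"s": model}, ["R1"], mode="fba-max",
                                inhibition=0.75)
        m = pg.knockdown_screen({"s": model}, ["R1"], mode="moma",
                                inhibition=0.75, wt_samples=5, seed=2)
        assert m[0].gs <= f[0].gs + 1e-6


def test_knockout_gi_dominates_partial_knockdown(sel_cohorts):
    cancer, normal, _ = sel_cohorts
    models = {**cancer, **normal}
    targets = ["RT", "RC", "RS"]
    partial = pg.knockdown_screen(models, targets, inhibition=0.75)
    full = pg.knockdown_screen(models, targets, inhibition=1.0)
    key = lambda r: (r.sample, r.target)
    gi_p = {key(r): r.gi for r in partial}
    for r in full:
        assert r.gi >= gi_p[key(r)] - 1e-7


# ---------------------------------------------------------------------------
# differential ranking
# ---------------------------------------------------------------------------

def test_rank_differential_targets_filters_and_ordering(sel_cohorts):
    cancer, normal, _ = sel_cohorts
    # mixed cohort: RT binds in cancer models only -> highest growth variance
    models = {**cancer, **normal}
    model = next(iter(models.values()))
    screen = pg.knockdown_screen(models, ["RT", "RC", "RS"], inhibition=0.75)
    table, attrition = pg.rank_differential_targets(screen, model)
    assert table.iloc[0]["target"] == "RT"
    rs_var = float(table.set_index("target").at["RS", "variance"])
    assert rs_var == pytest.approx(0.0, abs=1e-12)   # identical everywhere
    assert table.iloc[-1]["target"] == "RS"


def test_rank_differential_excludes_multi_gene_and_promiscuous():
    cancer, _, _ = pg.make_selectivity_cohorts(2, 2)
    model = next(iter(cancer.values())).copy()
    model.reactions[1].genes = frozenset({"gT", "gT2"})   # RT now two-gene
    model.reactions[3].genes = frozenset({"gC"})
    # make gC promiscuous: pretend it also catalyzes 3 extra reactions
    for k in range(3):
        model.metabolites.append(pg.Metabolite(f"P{k}"))
        model.reactions.append(pg.Reaction(f"RP{k}", {f"P{k}": 1}, 0, 1,
                                           frozenset({"gC"})))
    screen = pg.knockdown_screen({"c": model, "c2": model},
                                 ["RT", "RC", "RS"], inhibition=0.75)
    table, attrition = pg.rank_differential_targets(screen, model)
    assert attrition["not_single_gene"] >= 1
    assert attrition["gene_too_promiscuous"] >= 1
    assert "RT" not in set(table["target"])
    assert "RC" not in set(table["target"])


# ---------------------------------------------------------------------------
# selectivity
# ---------------------------------------------------------------------------

def test_selectivity_classify_engineered_design(sel_screens, sel_cohorts):
    _, _, truth = sel_cohorts
    sc, sn = sel_screens
    recs = {r.target: r for r in pg.selectivity_classify(sc, sn)}
    assert recs["RT"].klass == "selective"
    assert recs["RC"].klass == "non-selective"
    assert recs["RS"].klass == "neither"
    # score = (Gi_c - Gi_n) * Gs_n on cohort means
    assert recs["RT"].score == pytest.approx((0.75 - 0.0) * 1.0, rel=1e-6)
    assert recs["RC"].score == pytest.approx(0.0, abs=1e-9)
    only_selective = [t for t, r in recs.items() if r.klass == "selective"]
    assert only_selective == truth["selective"]


def test_selectivity_formula_on_synthetic_records():
    def rec(target, gi_c, gi_n):
        mk = lambda sample, gi: pg.KnockdownResult(sample, target, (target,),
                                                   "fba-max", 1 - gi, None, 1.0)
        return [mk("c1", gi_c)], [mk("n1", gi_n)]
    sc, sn = rec("T", 0.9, 0.1)
    r = pg.selectivity_classify(sc, sn)[0]
    assert r.score == pytest.approx((0.9 - 0.1) * 0.9)
    assert r.klass == "selective"
    r = pg.selectivity_classify(*rec("T", 0.6, 0.6))[0]
    assert r.score == pytest.approx(0.0)
    assert r.klass == "non-selective"
    r = pg.selectivity_classify(*rec("T", 0.25, 0.1))[0]
    assert r.klass == "neither"
    with pytest.raises(pg.PrimegemError, match="universes"):
        pg.selectivity_classify(sc, rec("OTHER", 0.5, 0.5)[1])


# ---------------------------------------------------------------------------
# drug response
# ---------------------------------------------------------------------------

def test_atp_response_decoupled_vs_coupled(branched_atp):
    split = pg.split_reversible(branched_atp)
    # a detached side pathway is not coupled to ATP production: pre ~ post
    m = split.copy()
    m.metabolites.append(pg.Metabolite("D"))
    m.metabolites.append(pg.Metabolite("W"))
    m.reactions.append(pg.Reaction("EX_D", {"D": 1}, 0, 3))
    m.reactions.append(pg.Reaction("RSIDE", {"D": -1, "W": 1}, 0, 3))
    m.reactions.append(pg.Reaction("EX_W", {"W": -1}, 0, 3))
    res = pg.drug_response_atp({"s": m}, "RSIDE", "ATPD", wt_samples=5,
                               seed=4)[0]
    assert res.atp_post == pytest.approx(res.atp_pre, abs=1e-4)
    # whereas knocking out the biomass branch diverts the shared input
    # into the ATP branch: the MOMA compromise settles at 10/3
    res_r1 = pg.drug_response_atp({"s": split}, "R1", "ATPD", wt_samples=5,
                                  seed=4)[0]
    assert res_r1.atp_post == pytest.approx(10.0 / 3.0, rel=1e-5)
    # RATP is the sole ATP route: post-KO ATP flux is stoichiometrically 0
    res2 = pg.drug_response_atp({"s": split}, "RATP", "ATPD", wt_samples=5,
                                seed=4)[0]
    assert res2.atp_post == pytest.approx(0.0, abs=1e-6)
    assert res2.atp_pre >= 5.0 - 1e-6   # forced at 50% of its max
    # seeded repeatability
    res3 = pg.drug_response_atp({"s": split}, "RATP", "ATPD", wt_samples=5,
                                seed=4)[0]
    assert res3.atp_post == res2.atp_post and res3.atp_pre == res2.atp_pre


def test_ic50_target_flux_at_half_growth(split_parallel, split_chain):
    # pinning biomass at 5 lets R1 carry at most the whole conversion flux 5
    ser = pg.drug_response_ic50({"s": split_parallel}, "R1")
    assert ser["s"] == pytest.approx(5.0, rel=1e-5)
    # the biomass reaction itself reports half its own maximum
    ser2 = pg.drug_response_ic50({"s": split_chain}, "BIOMASS")
    assert ser2["s"] == pytest.approx(5.0, rel=1e-5)
    # AC50 with response level equal to max growth coincides with IC50
    ser3 = pg.drug_response_ic50({"s": split_parallel}, "R1",
                                 response_level={"s": 10.0})
    assert ser3["s"] == pytest.approx(ser["s"], rel=1e-6)


# ---------------------------------------------------------------------------
# exchange rates
# ---------------------------------------------------------------------------

def test_exchange_rates_signed_uptake(split_chain, tight_chain):
    tab = pg.predict_exchange_rates({"s": split_chain}, ["EX_A"],
                                    growth_fraction=0.9)
    assert tab.at["s", "EX_A"] == pytest.approx(-10.0, rel=1e-6)
    tab1 = pg.predict_exchange_rates({"s": split_chain}, ["EX_A"],
                                     growth_fraction=1.0)
    assert tab1.at["s", "EX_A"] == pytest.approx(-10.0, rel=1e-5)


def test_exchange_secretion_without_producer_is_zero(split_chain):
    m = split_chain.copy()
    m.metabolites.append(pg.Metabolite("Q"))
    m.reactions.append(pg.Reaction("EX_Q", {"Q": -1}, 0, 50))
    tab = pg.predict_exchange_rates({"s": m}, ["EX_Q"], growth_fraction=0.9)
    assert tab.at["s", "EX_Q"] == pytest.approx(0.0, abs=1e-7)


# ---------------------------------------------------------------------------
# flux shift
# ---------------------------------------------------------------------------

def test_flux_shift_detects_forced_drop_and_leaves_branch_alone(branched_atp):
    split = pg.split_reversible(branched_atp)
    reports = {r.reaction_id: r
               for r in pg.flux_shift_analysis(split, "RATP", n=30,
                                               inhibition=1.0, seed=6)}
    assert reports["RATP"].direction == "down"
    assert reports["RATP"].q_value < 0.05
    assert reports["ATPD"].direction == "down"
    again = {r.reaction_id: (r.direction, r.p_value, r.q_value)
             for r in pg.flux_shift_analysis(split, "RATP", n=30,
                                             inhibition=1.0, seed=6)}
    assert again == {k: (v.direction, v.p_value, v.q_value)
                     for k, v in reports.items()}


def test_flux_shift_disconnected_reaction_unchanged(split_chain):
    m = split_chain.copy()
    m.metabolites.append(pg.Metabolite("D"))
    m.metabolites.append(pg.Metabolite("W"))
    m.reactions.append(pg.Reaction("EX_D", {"D": 1}, 0, 3))
    m.reactions.append(pg.Reaction("RSIDE", {"D": -1, "W": 1}, 0, 3))
    m.reactions.append(pg.Reaction("EX_W", {"W": -1}, 0, 3))
    reports = {r.reaction_id: r
               for r in pg.flux_shift_analysis(m, "R1", n=30, inhibition=0.75,
                                               seed=7)}
    assert reports["R1"].direction == "down"
    assert reports["RSIDE"].direction == "unchanged"
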
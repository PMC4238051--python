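# primegem

Phenotype-based cell-specific genome-scale metabolic modeling.

## The problem

Constraint-based metabolic models predict flux phenotypes from a
stoichiometric network `S` under steady state and bounds,

    S·v = 0,   v_min ≤ v ≤ v_max,

with growth predicted by maximizing a biomass reaction (FBA).  Building a
model *per cell line or patient sample* from expression data is hard when
transcriptomes are nearly identical across samples: presence/absence
discretization collapses all samples onto the same model, and naive
expression-proportional bounds ignore that expression and flux are only
partially, and sometimes inversely, related.

`primegem` implements a phenotype-based approach: given a generic model,
a genes × samples expression matrix and one phenotype value per sample
(e.g. proliferation rate), it

1. splits reversible reactions and tightens all upper bounds to the
   smallest common cap `U` that preserves maximal biomass within `ε`;
2. scores each reaction with the mean expression of its catalyzing
   enzymes, Spearman-correlates that against the phenotype, and keeps the
   reactions passing BH-FDR at `α = 0.05`;
3. maps the selected reactions' expression onto upper bounds, orienting
   by the correlation sign and rescaling per reaction across samples,

        E_{a,b}  = sign(ρ_a) · GE_{a,b}
        UB_{a,b} = (E_{a,b} − min E_a) / (max E_a − min E_a)
                   · (maxNormVal − minNormVal) + minNormVal,

   so the lowest-expression sample gets `minNormVal` and the highest gets
   `maxNormVal`.  The range is derived from the network itself:
   `minNormVal` is the largest FVA flux minimum over the essential
   reactions (knockout cuts growth by >90%) at 90% of maximal growth, and
   `maxNormVal` ends the first linear segment of the biomass-versus-bound
   curve.

The per-sample models then drive downstream simulations: growth
prediction, reaction/gene knockdown screens (FBA or MOMA — the quadratic
program `min Σ_i (V_wt,i − V_KO,i)²` against sampled wild-type optima),
in-silico IC50/AC50 and ATP drug-response estimates, uptake/secretion
predictions at ≥90% growth, cancer-versus-normal selectivity scoring
`(Gi_cancer − Gi_normal)·Gs_normal`, pre/post-knockdown flux-shift tests,
and k-fold cross-validation with empiric permutation p-values
`(n+1)/(N+1)`.

## Worked example

Build models for a synthetic 40-sample cohort with one growth-linked
gene and 19 decoys, then validate the recovery:

```python
import primegem as pg

model = pg.make_cohort_model(19)
expr, pheno, truth = pg.make_cohort(model, pg.CohortSpec(seed=0))
mset = pg.build_models(model, expr, pheno)
print("selected reactions:", mset.selected_reactions)
print("normalization range: [%.3f, %.3f]" % (mset.norm_range.min_norm_val,
                                             mset.norm_range.max_norm_val))
pred = pg.predict_growth(mset)
rho, p = pg.spearman(pred.loc[pheno.index], pheno)
print("predicted vs designed growth: Spearman rho = %.3f (p = %.2e)" % (rho, p))
cv = pg.kfold_cv(model, expr, pheno, k=5, repeats=20, seed=1)
print("5-fold CV mean test rho = %.3f" % cv.mean)
screen = pg.knockdown_screen(mset.models, ["R1"], inhibition=0.75)
print("R1 knockdown Gs range: %.3f-%.3f" % (min(r.gs for r in screen),
                                            max(r.gs for r in screen)))
```

prints

```
selected reactions: ['R1']
normalization range: [9.000, 10.000]
predicted vs designed growth: Spearman rho = 1.000 (p = 0.00e+00)
5-fold CV mean test rho = 1.000
R1 knockdown Gs range: 0.250-0.250
```

The pipeline found exactly the designed growth-associated reaction `R1`,
derived the bound window `[9, 10]` from the network (the chain must carry
9 units of flux at 90% of its maximal growth of 10, and relaxing the
bound past 10 buys no more growth), recovered the designed growth ranking
perfectly both in-sample and out-of-sample under cross-validation, and —
since `R1`'s maximal flux is 10 — a 75% inhibition caps growth at 2.5,
i.e. 25% survival in every sample.

The same steps are available from the shell: `primegem make-fixtures`,
`primegem build`, `primegem screen`, `primegem drug-response`,
`primegem exchange`, `primegem cv`, `primegem flux-shift`.  Every command
writes a provenance JSON (parameters, seed, input checksums) beside its
outputs.

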
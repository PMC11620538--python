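# medomics

Multi-omic mediation analysis for environmental health studies.

`medomics` implements a precision environmental-health analysis framework
that asks how a continuous exposure (e.g. prenatal blood mercury) affects a
health outcome (e.g. serum CK-18, a liver-injury biomarker) *through*
molecular intermediates measured on several omics layers (methylome,
transcriptome, miRNA, proteome, metabolome). It crosses three mediation
approaches with three multi-omic integration stages:

|                                | early (concatenate) | intermediate (layer-aware joint model) | late (per layer) |
|--------------------------------|---------------------|----------------------------------------|------------------|
| **high-dimensional mediation** | one penalized outcome model over all features | layer-specific penalty multipliers, bootstrap SEs | penalized model per layer |
| **latent-factor mediation**    | PCA of the concatenation (>80% variance) | joint/individual variance decomposition, permutation rank selection | PCA per layer |
| **latent-cluster quasi-mediation** | one cluster variable over all features | one cluster variable per layer, K^m subgroup configurations | serial chain via posterior inclusion probabilities |

## The statistics

With exposure X, outcome Y, and mediator M_j, each mediation analysis rests
on the product-of-coefficients decomposition

- **α_j** — coefficient of X in `M_j ~ X + covariates`,
- **β_j** — coefficient of M_j in the outcome model, adjusted for X,
- **indirect effect** α_j·β_j with a **distribution-of-the-product** CI
  (quantiles of A·B for independent normals A~N(α̂, se_α²), B~N(β̂, se_β²),
  by numerical CDF inversion),
- **%TE** = 100·α_j·β_j/γ, where **γ** is the total effect of X on Y.

Around this core the package provides:

- harmonization (cord-blood mercury ÷ 1.7), within-cohort scaling of X and
  Y, and internally studentized residualization of every omics feature on
  the covariates (`preprocess`);
- total-effect sensitivity analyses: change-in-estimate forward covariate
  selection, fixed-effects meta-analysis with Cochran's Q, and the
  **robustness value** RV = ½(√(f⁴+4f²) − f²) with f = |t|/√df
  (`exposure_outcome`);
- **meet-in-the-middle screening**: features ranked by |α·β| per layer with
  a sure-independence-screening budget of 2n/ln(n) features, rounded up to
  a multiple of five and split across layers (`preselect`);
- penalized high-dimensional mediation with lasso selection, OLS refit,
  joint-significance p-values and BH correction (`hdmed`);
- latent-factor mediation, including a joint-and-individual variance
  decomposition X_i = J_i + A_i + E_i with permutation rank selection
  (`latentmed`);
- a latent-unknown-cluster EM model (exposure → cluster → omics & outcome)
  with early/parallel/serial integration (`lucid`);
- seeded synthetic-study generators with truth tables (`simdata`) and a
  thin `medomics` CLI over all stages (`cli`).

## Worked example

`examples/02_screening_and_mediation.py` plants ten mediators
(α = β = 0.4) in a 120-feature methylome layer next to an 80-feature null
transcriptome layer at n = 500 and runs the full first column of the grid:

```
screening budget at n=500: 166 features, 83 per layer (2n/ln n, rounded up to a multiple of 5)
meet-in-the-middle retained 163 features by |alpha*beta| rank

early integration: 10 mediators (true mediators planted: 10)
    layer      feature_id  alpha  beta  indirect  pct_te
methylome methylome_f0001  0.451 0.438     0.197  13.444
methylome methylome_f0000  0.386 0.450     0.174  11.826
...
  -> indirect = alpha*beta; pct_te = 100*alpha*beta/gamma, the share
     of the total effect (gamma = 1.468) mediated

intermediate integration: 10 mediators; tuned per-layer penalty multipliers = {'methylome': 0.25, 'transcriptome': 1.0}
```

All ten planted mediators are reported with no false positives; each row's
`pct_te` is that feature's share of the total effect, and the tuned penalty
multipliers show the signal-free layer being penalized harder. The other
examples cover the total-effect sensitivity analyses (`01`), latent-factor
mediation (`03`), and latent-cluster quasi-mediation with its subgroup
table (`04`).

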
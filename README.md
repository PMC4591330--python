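# glaucodrive

Glaucoma gradually erodes the peripheral visual field, and drivers with
glaucoma are at elevated risk of motor-vehicle collisions (MVC) — yet static
perimetry alone predicts that risk poorly. `glaucodrive` implements a
longitudinal analysis chain for predicting MVC risk from repeated
divided-attention measurements: driving-simulator metrics and the Useful
Field of View (UFOV) test, collected every six months, feed a parametric
survival model whose hazard updates as each new visit arrives. It is aimed
at vision scientists and biostatisticians studying driving fitness in
ophthalmic disease.

The package covers:

* **Driving-simulator metrics** — per-visit scalars from raw telemetry and
  stimulus/response logs:
  * *curve coherence*, the central-task measure: the maximum over delay
    shifts of the normalized cross-correlation between road curvature
    `k_road` and driven path curvature `k_own`,

    ```
    coherence = max over d of  (1/n) Σ_t (k_own(t) − mean k_own)(k_road(t−d) − mean k_road)
                               ───────────────────────────────────────────────────────────
                                              SD(k_own) · SD(k_road)
    ```

    with window statistics recomputed at each shift, so an exact match
    scores 1;
  * mean reaction times to low- and high-contrast peripheral stimuli
    (Michelson contrasts 0.04 and 0.27 under the alpha-blending display
    model), their difference (the *corrected* reaction time, isolating
    visual processing from the motor response), and a false-positive rate.
* **Perimetry covariates** — Nelson-Quigg binocular summation
  (`S_bino = sqrt(S_L² + S_R²)` on linear sensitivities `S = 10^(dB/10)`),
  reliability filtering, and abnormality / glaucoma classification of SAP
  series.
* **Survival modelling** — a Weibull proportional-hazards model with
  time-dependent covariates, `h(t|x) = λ p t^(p−1) exp(x(t)'β)`, fitted by
  maximum likelihood on counting-process episodes with covariates z-scored
  at baseline and carried forward between visits, so `exp(β)` is a hazard
  ratio per 1 SD worse. Kaplan-Meier curves and per-subject predicted
  survival trajectories that update with each visit come with it.
* **Model comparison** — Royston's D-based explained variation
  `R²_D = (D²/κ²) / (π²/6 + D²/κ²)`, `κ = √(8/π)`, for ranking predictive
  models whose hazard ratios are not directly comparable, plus rank-sum /
  Fisher's-exact group-comparison tables.
* **A synthetic-cohort generator** — the study's raw records are not
  deposited, so a latent-ability mechanism generates cohorts (default: 117
  glaucoma drivers + 50 controls, ~9.4% MVC incidence) by inverting the same
  Weibull time-dependent-covariate model, making parameter recovery a
  well-posed test of the whole chain.

## Worked example

```python
import glaucodrive as gd
from glaucodrive.evaluation import royston_r2
from glaucodrive.survival import WeibullTDModel

config = gd.CohortConfig(seed=1)          # study-scale defaults
cohort = gd.generate_cohort(config)

episodes = gd.episodes_from_cohort(cohort, ["rt_low"])
fit = WeibullTDModel(episodes).fit()
print(fit.summary())
print(f"Royston D = {royston_r2(fit, episodes).D:.2f}, "
      f"R2_D = {royston_r2(fit, episodes).r2:.2f}")
```

prints

```
Weibull PH model with time-dependent covariates
================================================================
subjects:   117    events:   14    time at risk:    201.0 y
shape p:   0.767  (95% CI 0.462-1.273)    scale lambda: 0.06765 / y^p
log-likelihood: -48.159    converged: True
----------------------------------------------------------------
covariate                HR/SD            95% CI         p
rt_low                    1.72    1.10-2.70         0.0172
================================================================
Royston D = 1.03, R2_D = 0.20
```

Read: in this simulated cohort of 117 glaucoma drivers (14 MVCs over 201
person-years), each 1 SD slower low-contrast reaction time carries a 1.72-fold
higher instantaneous MVC risk (Wald 95% CI 1.10–2.70); the fitted Weibull
shape near 1 indicates a roughly constant baseline hazard; and the model's
prognostic separation explains about 20% of outcome variation on Royston's
scale. `fit.predict_survival(history, horizon)` then yields the individual
risk trajectory implied by any subject's visit-by-visit covariate history.

The same chain runs from the shell:

```
glaucodrive all --outdir out/ --seed 1
```

writing the cohort tables, raw telemetry for a subject subset, recomputed
metrics, univariable and multivariable hazard-ratio tables, baseline and
glaucoma-vs-control comparisons, Royston R² for the driving-simulator and
UFOV models, Kaplan-Meier and predicted-survival figures, and a
reproducibility manifest.

## Layout

| module                   | contents                                              |
| ------------------------ | ----------------------------------------------------- |
| `glaucodrive.metrics`    | telemetry/event-log containers, coherence, RT, contrast |
| `glaucodrive.perimetry`  | binocular summation, reliability, classification      |
| `glaucodrive.simulate`   | cohort config + generators, hazard inversion, calibration |
| `glaucodrive.survival`   | episode tables, `WeibullTDModel`/`WeibullTDResults`, KM |
| `glaucodrive.evaluation` | Royston R²_D, group comparisons                       |
| `glaucodrive.pipeline`   | stage orchestration, manifest                         |
| `glaucodrive.cli`        | `glaucodrive` command                                 |

See `docs/methods.md` for the model assumptions, generator design and
numerical choices.
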
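# stargardt-endpoint

A composite clinical-trial endpoint pipeline for retinal degeneration in
early-onset Stargardt disease (STGD1). Individual outcome measures in this
rare ABCA4 maculopathy — visual acuity above all — progress too noisily for
small phase I/II trials to detect a treatment effect. This package builds a
more responsive endpoint by (1) standardizing five biomarkers to a common
retinal-eccentricity scale, (2) combining their changes from baseline into a
weighted composite, (3) choosing the weights that maximize responsiveness
under a random-slope mixed model, (4) validating the chosen composite by
hold-out prediction, and (5) quantifying trial power by paired-eye
Monte-Carlo simulation. It is written for biostatisticians and ophthalmic
researchers designing progression endpoints for inherited retinal disease.

## The model

Measurements are expressed as retinal eccentricity ε (degrees from the
foveal center, 1° ≈ 0.3 mm): acuity via ε = log₁ᐟ₁.₂(BCVA), atrophy areas
(QDAF/DDAF on autofluorescence imaging) via ε = √(area/π)/0.3, transverse
OCT band loss (EZ/ELM) via ε = loss/0.6. The composite change of an eye at
follow-up Δt is the weighted mean

ΔC(Δt) = Σ w·Δε / Σ w,  (missing biomarkers renormalized away)

and is modelled with a zero-intercept nested random-slope model

ΔC_ij(Δt_ik) = (s + s_i + s_ij)·Δt_ik + E_ijk,

with population slope s, patient and eye-within-patient slope deviations,
and iid residuals (REML estimation). Responsiveness is the
mean-to-standard-deviation ratio MSDR = s/RMSE; all 10,626 weight
combinations on a 5% grid are searched exhaustively for the maximal MSDR.
See `docs/methods.md` for the full account.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on synthetic
cohorts drawn with the published cohort structure (the real per-visit
measurements are not redistributed here):

```
python analysis/01_generate_cohorts.py --seed 0
python analysis/02_standardize_eccentricity.py
python analysis/03_grader_agreement.py
python analysis/04_univariable_progression.py
python analysis/05_optimize_weights.py        # full 10,626-combination search
python analysis/06_validate_holdout.py
python analysis/07_trial_power.py
```

Output of steps 04, 06 and 07 on the seed-0 development cohort:

```
biomarker  slope_deg_per_year  ci_low  ci_high  residual_sd_deg  msdr  n_obs
     bcva               0.175  -0.032    0.383            3.667 0.048     66
     qdaf               0.379   0.291    0.467            0.154 2.465     66
     ddaf               0.619   0.556    0.683            0.268 2.309     66
       ez               0.254   0.164    0.345            0.179 1.420     63
      elm               0.346   0.230    0.461            0.185 1.874     66

development: R2 0.905, calibration slope 0.982 [0.841, 1.122], intercept 0.046 [-0.2, 0.293]
validation:  R2 0.937, calibration slope 0.976 [0.878, 1.074], intercept -0.041 [-0.271, 0.189]

power at a 25% treatment effect:
                   scenario  power
optimal_weighted_2yr_paired 0.9371
         one_year_follow_up 0.5534
                 non_paired 0.3152
                  bcva_only 0.0501
```

Reading: acuity is essentially uninformative (MSDR 0.05 — its residual SD of
3.7°/yr swamps its 0.18°/yr slope) while the imaging biomarkers carry strong
signal; the held-out last visits are predicted with R² ≈ 0.9 and a
calibration slope near 1 in both cohorts; and a two-year paired-eye trial in
14 patients detects a 25% slowing of progression with ~94% power using the
weighted composite, versus 5% (chance level) using acuity alone. Exact
numbers vary with the generator seed.

## Library surface

```python
import stargardt_endpoint as se

cohort = se.read_cohort("visits.csv")                  # or .xlsx + column_map
ecc    = se.standardize_cohort(cohort.to_frame())      # adds eps_* columns
deltas = se.deltas_from_baseline(ecc)
result = se.optimize_weights(deltas)                   # exhaustive MSDR search
cal, fit, adj = se.holdout_validation(ecc, result.best)
curve  = se.simulate_trial(fit, adj, se.TrialDesign(seed=1))
```

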
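# lesionatoms

Hemisphere-aware decomposition of stroke lesion topographies and Bayesian
hierarchical prediction of post-stroke cognitive outcomes.

After an ischaemic stroke, the pattern of damaged brain tissue carries
information about which cognitive functions are lost — and much of that
information is lateralized: language-related deficits tend to follow
left-hemispheric damage, visuospatial deficits right-hemispheric damage.
This package implements an analysis pipeline that quantifies such
lateralization at three levels — whole hemispheres, distributed lesion
patterns ("lesion atoms"), and individual atlas regions — for researchers
working with registered lesion masks and neuropsychological outcome scores.
Because clinical lesion datasets are rarely public, the package ships a
fully specified synthetic-cohort generator with known ground truth, and its
entire test-bed runs on simulated cohorts.

## Pipeline and model

1. **Parcellation** — each binary lesion mask (NIfTI, already registered to
   the atlas grid) is reduced to voxel counts per atlas region (54 homologous
   regions per hemisphere, 108 total); counts are log-transformed
   (`log1p`) and concatenated into a patients × 108 lesion matrix. Patients
   with bilateral lesions are excluded.
2. **Atom decomposition** — non-negative matrix factorization, V ≈ W·H,
   learns k = 10 *lesion atoms*: non-negative spatial patterns of
   co-occurring regional damage (columns of W, unit-L2). Each patient's atom
   loadings are slotted into left- or right-hemisphere predictor columns
   according to the lesioned side (2k = 20 columns).
3. **Hierarchical outcome model** — per cognitive outcome y (z-scored):

   ```
   τ       ~ HalfNormal(s_τ)                joint hyperprior
   σ_h     ~ HalfNormal(τ),   h ∈ {L, R}    hemisphere dispersions
   β_{h,a} ~ Normal(0, σ_h²)                atom coefficients
   γ_j     ~ Normal(0, 1);  α ~ Normal(0,1);  σ_ε ~ HalfNormal(1)
   y_i     ~ Normal(α + Σ_{h,a} β_{h,a} H_{i,h,a} + x_iᵀγ, σ_ε²)
   ```

   Covariates x are age, age², sex, age×sex, time since stroke, education
   years, pre-stroke cognition (IQCODE) and total lesion volume (the volume
   term can be dropped per outcome). The posterior of σ_L vs σ_R *is* the
   hemisphere-level relevance comparison; draws come from the package's own
   No-U-Turn sampler (numba-compiled, with a pure-python reference engine).
4. **Relevance summaries** — 94% highest-posterior-density intervals (HPDI)
   for everything; atom-level lateralization = the per-draw difference
   Δ_a = β_{L,a} − β_{R,a} has a 94% HPDI excluding zero; region-level
   relevance back-projects coefficients through the basis (W·β_h per draw);
   posterior-predictive R² summarizes explained variance.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
cohort (600 unilateral patients, left-dominant truth σ_L = 0.30,
σ_R = 0.03, generative R² = 0.5):

```
python analysis/01_simulate_cohort.py
python analysis/02_parcellate_masks.py
python analysis/03_learn_lesion_atoms.py
python analysis/04_fit_outcome_model.py
python analysis/05_relevance_report.py
```

which prints, among other things:

```
parcellated 600 unilateral patients (288 left, 312 right)
left vs right total lesion volume: t = -0.80, P = 0.42
reconstruction of the 108-dim region representation: r = 0.999
sigma_L: posterior mean 0.1743, 94% HPDI [0.1031, 0.2606]
sigma_R: posterior mean 0.0415, 94% HPDI [0.0000, 0.0880]
posterior-predictive R^2: 0.513 (94% HPDI [0.467, 0.561])
diagnostics: max R-hat 1.004, min ESS 851, 3 divergences -> converged=True
```

Read: lesion volume is balanced across hemispheres (as constructed), the
10-atom encoding loses almost nothing of the region-wise lesion
representation, and the fitted hemisphere dispersions recover the
left-dominant truth — the σ_L posterior sits well above σ_R, so the left
hemisphere's atoms carry most of the predictive relevance for this outcome,
and the model's explained variance matches the generative 0.5. The final
driver then lists which individual atoms are lateralized and which regions
carry the relevance.

The same pipeline runs from the command line (`lesionatoms run --config
config.yaml --seed 1`) with subcommands `simulate`, `parcellate`,
`decompose`, `fit`, `report`, `run`, and a `--subset "age>=65"` filter for
sensitivity reruns.

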
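# vmdoc — VMD-based EEG features for disorders-of-consciousness classification

`vmdoc` is a tested re-implementation of a resting-state EEG analysis
pipeline for classifying disorders of consciousness (DOC): coma,
unresponsive wakefulness syndrome (UWS) and minimally conscious state
(MCS).  It is written for signal-processing and clinical-neurophysiology
researchers who want the full chain — adaptive decomposition, statistical
features, rank-based feature screening, cross-validated evaluation — as
importable, seeded, unit-tested code rather than a one-off script.

Clinical DOC recordings are rarely shareable, so the package also ships a
synthetic cohort generator that emulates the statistical structure such
cohorts are assumed to have (graded spectral profiles, a complexity
gradient, oscillatory slowing, class-consistent CRS-R/GCS scores).  The
entire analysis downstream of the generator is the same code a real EDF/CSV
cohort would run through.

## The method

**Variational mode decomposition (VMD).**  A signal x(t) is split into K
narrow-band modes u_k(t) with center frequencies ω_k by minimizing the
summed bandwidth of the analytic, baseband-shifted modes subject to
reconstruction:

    min_{u_k, ω_k}  Σ_k ‖ ∂_t[ (δ(t) + j/πt) * u_k(t) ] e^{−jω_k t} ‖²₂
    s.t.            Σ_k u_k = x

solved via the augmented Lagrangian (penalty α, dual λ) by alternating
frequency-domain ADMM updates — a Wiener-filter mode update
û_k = (x̂ − Σ_{i≠k}û_i + λ̂/2)/(1 + 2α(ω − ω_k)²), a spectral-centroid
update of ω_k, and dual ascent with step τ.  Defaults: K = 5, α = 2000,
τ = 0, uniform ω initialization.

**Features.**  Four statistics per component — normalized spectral entropy,
sample entropy SampEn(m=2, r=0.2σ), skewness and Pearson kurtosis —
computed under three signal representations per subject: raw channels
(17×4 = 68 features), five canonical frequency bands (17×5×4 = 340), and
five VMD modes (17×5×4 = 340).

**Screening and evaluation.**  Per-feature Kruskal-Wallis test across the
class groups (select at raw p < 0.05; Dunn's post-hoc localizes pairs;
Spearman ρ against CRS-R/GCS quantifies clinical relevance), then
stratified 10-fold cross-validation of KNN, linear SVM, decision tree and
an ensemble of bagged trees (EBT), with within-fold z-scoring and
pooled-fold confusion metrics (accuracy, macro precision/recall, F1, in %).

See `docs/methods.md` for the full model description, parameter defaults,
and what the synthetic cohort does and does not emulate.

## Worked example

```bash
python analysis/01_simulate.py          # 45 subjects, 17 ch, 60 s @ 256 Hz
python analysis/03_extract_features.py  # 68 / 340 / 340 feature tables
python analysis/04_select_features.py   # Kruskal-Wallis screen per task
python analysis/05_classify.py          # CV grid: 48 evaluations
python analysis/06_compare.py           # improvement tables
```

With the default seed (0) the screen keeps 76/340 VMD features for the
3-class task, 45 of which correlate with CRS-R at |ρ| in [0.2, 0.5], and
the classification step prints, for EBT on the selected features:

```
3-class EBT with selected features:
approach  accuracy
     raw      66.7
   bands      75.6
     vmd      80.0
```

i.e. on this cohort the adaptively decomposed representation beats fixed
frequency bands, which beat raw-channel features — the qualitative ordering
the pipeline is designed to probe.  The mean raw-channel sample entropy
rises with the level of consciousness (coma 0.77 < UWS 0.81 < MCS 0.87 at
this seed), the complexity gradient the features are meant to capture.
`06_compare.py` additionally recomputes all 40 improvement figures of the
published reference accuracy tables shipped with the package and reports
`all exact: True`.

The same pipeline is scriptable through a single CLI
(`vmdoc simulate | decompose | extract | select | classify | report | all`)
or the `ExperimentConfig`/`run_experiment` API, and accepts real cohorts as
CSV-per-subject (or EDF) plus a label manifest.

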
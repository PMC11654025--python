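# Methods

## Problem setting

Morphological response criteria grade colorectal-cancer liver metastases on
portal-venous-phase CT into three groups: Group 1 (homogeneous attenuation,
sharp tumour–liver interface, no peripheral rim enhancement), Group 3
(heterogeneous, ill-defined interface, rim enhancement) and Group 2
(intermediate).  Under bevacizumab-based chemotherapy, a patient whose
lesions convert from Group 2/3 at baseline to Group 1 at the ~3-month
follow-up is a *responder*; this morphological response predicts overall
survival better than size-based criteria.  The weak point of the scheme is
Group 2, which absorbs reader uncertainty.  `morphmr` implements a
semi-supervised refinement: a small residual network is trained only on the
unambiguous groups (1 vs 3) and then *triages* each Group-2 image into
Group 1, 2 or 3 from its output probability.  Patient-level response is
re-derived from the combined labels, and the two criteria — radiologist
(RD-MR) and network-refined (ResNet-MR) — are compared by their ability to
discriminate survival.

Because no real imaging cohort is distributed with the package, every
component is exercised on a synthetic lesion-phantom cohort with known
ground truth.  The real-data interface (PNG patches, Labelme-style polygon
annotations, CSV manifests) exists and is tested, but all quantitative
results shipped with the package are synthetic.

## Lesion phantom

One ROI is a 64×64 patch at a fixed pitch of 1 mm/pixel, so a 4.5 cm lesion
(the cohort's mean diameter) fills ~70 % of the field.  A latent
severity *s* ∈ [0, 1] drives the three morphological axes affinely:

* heterogeneity-blob amplitude `0.15·s` inside the lesion (correlated
  Gaussian field, 2.5 px scale) — within-lesion variance grows as *s*²;
* boundary blur σ from 0.3 px (sharp) to 3 px as *s* → 1;
* an additive rim of amplitude `0.25·s` in a ~2.5 px band inside the
  boundary.

The background is liver-level (0.50) with a low-amplitude correlated
texture so the classifier cannot separate groups on background statistics;
the lesion core is hypoattenuating (0.32); pixel noise is N(0, 0.02²).
Group labels follow inclusive severity cuts: *s* ≤ 0.33 → Group 1,
*s* ≥ 0.67 → Group 3, else Group 2.  Because all stochastic fields are
drawn before severity-dependent scaling, rim contrast and core variance are
monotone in severity at a fixed seed — the property the monotonicity suite
checks.  Lesions larger than the 6.4 cm field are rendered centre-cropped
(with a warning) up to a 12.8 cm hard limit; the true diameter always
travels with the image as a separate feature, mirroring how resized ROIs
lose absolute scale.

What the phantom deliberately omits: organs and vascular anatomy, partial
volume and beam-hardening effects, inter-reader segmentation variability.
Passing tests therefore demonstrate that the pipeline's logic and training
machinery work under controlled contrast, not that the classifier would
reach the same accuracy on clinical CT.

## Synthetic cohort

Defaults mirror the reference clinical cohort: 84 patients, 85.7 % with
multiple lesions (up to 5), truncated-normal diameters 4.52 ± 3.12 cm
(≥ 1 cm), baseline scan plus one follow-up at 99 ± 9 days (clipped to
90–120), 1–4 axial slices per lesion per scan.  Small fractions of lesions
are flagged vessel-encasing (5 %) or subcapsular (8 %); these are never
rendered and only exercise the eligibility filter.

Latent responder status (default probability 0.5) controls both imaging and
survival.  Baseline severities are Group-3-like; follow-up severities drop
below the Group-1 cut for responders and stay Group-3-like for
non-responders (each non-responder lesion independently "improves" with
probability 0.3, with at least one persisting lesion enforced).  Mid-band
(Group 2) severities arise only through an explicit ambiguity redraw, with
per-lesion probability `ambiguity_fraction` (default 0.15, calibrated so
that roughly a third of latent responders carry at least one ambiguous
lesion — the shift the reference cohort shows between its two criteria);
ambiguous severities *lean* with the latent status, responders in
(0.34, 0.48) and non-responders in (0.52, 0.66), leaving a small margin
around 0.5 so the lean is well defined.  Slice-level severities jitter
±0.015 within the lesion's group band.

Survival is exponential with medians 36.51 months (responders) and 21.20
months (non-responders), administratively censored at 60 months; draws of
≤ 3 months are resampled, emulating the study's exclusion of early deaths.
By memorylessness the resulting median is exactly the configured median
plus 3 months — the closed form the calibration tests use.  Downstaging
(conversion to curative hepatectomy/ablation) is Bernoulli with
probability 0.375 for latent responders and 0.175 otherwise.

The whole cohort is a pure function of `(CohortConfig, seed)`;
`render_images=False` keeps the latent severities but skips rendering for
survival-only studies.

## Classifier

The network is a 10-weight-layer residual CNN: a stride-2 stem convolution,
four residual blocks of two 3×3 convolutions (projection shortcuts; the
first three blocks downsample, spatial sizes 32→16→8→4), global average
pooling, then one dense sigmoid unit that also receives the lesion diameter
(z-scored over the training split).  All layers, backpropagation and Adam
are implemented in numpy (NHWC im2col convolutions); gradients are verified
against finite differences in the test suite, with ReLU-kink outliers
tolerated explicitly.

Training uses class-weighted binary cross-entropy (Group 3 → 1), a
stratified seeded 3:1 train/validation split, and per-epoch validation AUC
and accuracy.  The default `TrainConfig` (learning rate 1e-5, 120 epochs,
batch 32, widths 16/32/64/128) reproduces the reference recipe; for
training this architecture *from random initialisation* on phantoms those
steps are far too small (≈10³ Adam steps of 1e-5 barely move He-scale
weights), so the experiment layer supplies a phantom profile — learning
rate 1e-3, 25 epochs, widths 8/16/32/64, and a 3-member seed ensemble —
sized for a single CPU.

Two choices matter for triage quality and were made on variance-reduction
grounds:

* **Ensembling on logits.**  Member outputs are combined as the mean
  *logit* (geometric mean of odds).  Extreme-group training leaves the
  decision boundary inside the unlabelled mid-severity gap essentially
  unconstrained; averaging several independently initialised members
  stabilises its position, and combining on the logit scale preserves the
  saturation that probability-averaging destroys (a mean of probabilities
  is pulled toward 0.5, which starves the outer triage bands).
* **Orientation averaging at prediction time.**  The phantom statistics are
  invariant under the 8 dihedral symmetries of the square, so predictions
  average the logit over all 8 orientations.

Triage maps the (ensemble) probability *p* to Group 1 if *p* ≤ 0.25, Group
3 if *p* ≥ 0.75, else Group 2 (inclusive, configurable).  The mechanism by
which a binary network yields three classes is this package's design; the
thresholds are symmetric and exposed for sensitivity analysis.  Lesion
assessments take the worst (maximum) group over slices; patient response
requires *all* eligible lesions to respond, with the index lesion the worst
one, ties broken by diameter; only the first follow-up scan is used.

Lesions that end up Group 1 at *baseline* after triage have no defined
response; they are skipped with a warning (patients with no assessable
lesion are excluded and itemised).  This keeps the refinement monotone: a
patient called responder by the radiologist criterion cannot flip to
non-responder through a baseline relabel alone.

## Survival statistics

Kaplan–Meier, the 1-df log-rank (Mantel–Cox) statistic, fixed-horizon
mortality AUC and the paired DeLong comparison are implemented from first
principles in `morphmr.survstats`; `lifelines`, `scikit-learn` and
exhaustive enumeration serve as independent oracles in the tests.  The KM
median is the first time with S(t) ≤ 0.5.  For horizon AUC the marker is
**non-responder status** (non-response predicts death); deaths at or before
the horizon are cases, patients alive at the horizon are controls, and
patients censored before the horizon are excluded and counted — the
simplest defensible rule; no inverse-probability-of-censoring weighting.
For a binary marker the AUC equals (sensitivity + specificity)/2, which the
tests check against rank-based AUC.  Confidence intervals and the test
against 0.5 use the DeLong variance; the between-criteria comparison uses
the paired DeLong covariance.  Proportions are compared two-sided with
Fisher's exact test when any expected cell is below 5, Pearson chi-square
otherwise; α = 0.05 throughout.

## Experiment presets and problem sizes

`ExperimentConfig` defaults run the 84-patient cohort end to end.  The
qualitative direction checks (network-refined criterion discriminates
2-year mortality at least as well as the oracle-radiologist criterion;
rescued "new-responders" outlive the remaining non-responders) run on
`enriched_experiment_config`: 200 patients with the ambiguity redraw
enriched among latent responders (0.35 vs 0.05 per lesion).  The size was
chosen from a patient-level Monte Carlo of the rescue process so that a few
dozen new-responders are expected; at that size the expected 2-year AUC
gain is ≈ +0.03 and the direction holds in most — not all — seeds (the
survival overlap of exponential arms with medians 36.5 and 21.2 makes both
AUCs sit near 0.5–0.55, so seed-level noise is material).  The shipped
checks run at a fixed seed and are exactly reproducible; single-seed runs
with other seeds can show a reversed AUC direction, which is reported, not
suppressed.

Parameter-recovery checks use 50 replicated survival-only cohorts of 200
patients with the censoring horizon beyond the support (all deaths
observed), where the Schoenfeld approximation puts log-rank power above
0.95.

## Known limitations

* The phantom's three axes are perfectly correlated through one latent
  severity; real morphology moves on partially independent axes.
* The ambiguity lean ties Group-2 appearance deterministically to latent
  status, which is the most favourable world for triage; interobserver
  noise is available (`label_noise`) but defaults to 0.
* Binary-marker horizon AUC discards censored-before-horizon patients
  rather than reweighting.
* The network has no normalisation layers; very deep or very wide variants
  of the architecture would need them, but at the shipped widths training
  is stable.
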
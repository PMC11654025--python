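# morphmr

Semi-supervised refinement of CT morphological response criteria for
colorectal-cancer liver metastases, exercised end to end on a synthetic
lesion-phantom cohort with simulated survival.

## The problem

On portal-venous-phase CT, liver metastases treated with bevacizumab-based
chemotherapy are graded by *morphological criteria* into Group 1
(homogeneous attenuation, sharp tumour–liver interface, no peripheral rim
enhancement), Group 3 (heterogeneous, ill-defined interface, rim
enhancement) or Group 2 (intermediate).  A patient whose lesions all convert
from Group 2/3 at baseline to Group 1 at the ~3-month follow-up is a
morphological **responder**, a status that predicts overall survival (OS)
better than size-based criteria under anti-VEGF therapy.  Group 2 is the
scheme's weak point: it absorbs reader uncertainty and dilutes the
responder/non-responder split.

`morphmr` implements a refinement of the radiologist-determined response
(RD-MR): a small residual network is trained only on the unambiguous
Group 1 vs Group 3 images (label *y* = 1 for Group 3, binary cross-entropy,
sigmoid output *p*), and every Group-2 image is **triaged** by

```
group(p) = 1 if p ≤ 0.25,   3 if p ≥ 0.75,   2 otherwise
```

Lesion assessments take the worst (maximum) group over slices, patients are
re-called with the same all-lesions-respond rule (ResNet-MR), and the two
criteria are compared by Kaplan–Meier/log-rank survival separation and by
fixed-horizon mortality AUC (for the binary non-responder marker,
AUC = (sensitivity + specificity)/2, DeLong variance, paired DeLong
comparison).  Patients called non-responders by RD-MR but responders by
ResNet-MR are the **new-responders** the refinement is after.

Since no imaging cohort ships with the package, a phantom generator stands
in for the data: 64×64 lesion patches whose appearance is driven by a latent
severity through the three morphological axes, longitudinal multi-lesion
patients, exponential survival tied to a latent responder status, and
ground-truth labels throughout.  Who this is for: anyone who wants a tested,
reproducible reference implementation of the triage-and-compare pipeline, or
a sandbox for studying ambiguous-class triage against survival endpoints.

## Worked example

```python
from morphmr.pipeline import ExperimentConfig, run_experiment

report = run_experiment(ExperimentConfig(seed=1))  # 84 synthetic patients
print(report.image_counts_by_group)
print(report.survival_tables["rd_mr"])
print(report.survival_tables["resnet_mr"])
print(len(report.new_responders))
```

prints (about 3–4 minutes on one CPU)

```
{1: 296, 2: 185, 3: 739}
{'n_responders': 22, 'n_nonresponders': 62, 'median_responder': 31.65, 'median_nonresponder': 29.27, 'logrank_chi2': 0.304, 'logrank_p': 0.581}
{'n_responders': 30, 'n_nonresponders': 54, 'median_responder': 43.47, 'median_nonresponder': 27.09, 'logrank_chi2': 3.593, 'logrank_p': 0.058}
8
```

Reading: of 1220 labelled slice images, 185 are ambiguous (Group 2).  The
oracle-radiologist criterion calls 22 of 84 patients responders, but the
ambiguous lesions hide enough true responders among the non-responders that
the survival split is weak (31.6 vs 29.3 months, log-rank p = 0.58).
Triage of the ambiguous images rescues 8 patients (the new-responders), and
the refined criterion separates survival visibly better (43.5 vs 27.1
months, p = 0.058); the 2-year mortality AUC of the non-responder marker
rises from 0.522 to 0.553.  `enriched_experiment_config()` runs the larger
(n = 200) direction experiment in which a few dozen new-responders appear.

The same stages are scriptable from the shell:

```bash
morphmr simulate --out data/ --seed 1
morphmr train --manifest data/manifest.csv --out model.zip --seed 1
morphmr classify --model model.zip --manifest data/manifest.csv --out assessments.csv
morphmr respond --assessments assessments.csv --criterion resnet_mr --out calls.csv
morphmr evaluate --calls calls.csv --cohort data/cohort.csv --out report/
```

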
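"""Reference clinical cohort summary counts and arithmetic reconciliation.

The generator defaults in :mod:`morphmr.cohort` are calibrated to a
published clinical cohort of 84 bevacizumab-treated patients with liver-only
metastatic colorectal cancer.  Only summary counts are available (the
underlying images and per-patient data were never released), so this module
records those counts and provides the arithmetic-consistency checks that can
be computed from them: training-set size from the per-group image counts,
responder counts and percentages, and reconciliation of the downstaging rows
(hepatectomy / ablation / both overlap).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ReferenceCohort:
    """Published summary counts of the reference clinical cohort."""

    n_patients: int = 84
    # image counts per radiologist-assigned morphological group
    images_group1: int = 187
    images_group2: int = 589
    images_group3: int = 220
    images_total: int = 996
    reported_training_images: int = 407
    # patient-level calls
    rd_responders: int = 28
    resnet_responders: int = 44
    new_responders: int = 16
    # downstaging rows (hepatectomy and RFA overlap)
    downstaging_total: int = 24
    hepatectomy: int = 21
    rfa: int = 7
    both_hepatectomy_rfa: int = 4
    # downstaging proportions in the new-responder comparison
    new_responder_downstaging_pct: float = 37.5
    resnet_nonresponder_downstaging_pct: float = 17.5
    resnet_nonresponders: int = 40


REFERENCE = ReferenceCohort()


def training_set_size(cohort: ReferenceCohort = REFERENCE) -> int:
    """Extreme-group (Group 1 + Group 3) image count fed to the network."""
    return cohort.images_group1 + cohort.images_group3


def resnet_responders_from_parts(cohort: ReferenceCohort = REFERENCE) -> int:
    """Original responders plus rescued new-responders."""
    return cohort.rd_responders + cohort.new_responders


def responder_pct(count: int, cohort: ReferenceCohort = REFERENCE) -> float:
    """Responder percentage of the cohort, to one decimal."""
    return round(100.0 * count / cohort.n_patients, 1)


def downstaging_reconciled(cohort: ReferenceCohort = REFERENCE) -> int:
    """Downstaged patients by inclusion-exclusion over the treatment rows."""
    return cohort.hepatectomy + cohort.rfa - cohort.both_hepatectomy_rfa


def downstaging_counts_from_pcts(cohort: ReferenceCohort = REFERENCE) -> tuple[int, int]:
    """Absolute downstaging counts implied by the reported percentages."""
    new = cohort.new_responder_downstaging_pct / 100.0 * cohort.new_responders
    non = cohort.resnet_nonresponder_downstaging_pct / 100.0 * cohort.resnet_nonresponders
    return int(round(new)), int(round(non))
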
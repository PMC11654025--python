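"""Patient-level morphological response calling.

A lesion *responds* when its morphological group changes from 2 or 3 at
baseline to 1 at the first follow-up.  A patient is a responder only if every
eligible lesion responds (the worst-lesion rule); the index lesion is the
worst-status lesion, ties broken by the largest diameter.  The same rule is
applied under two criteria that differ only in where the lesion groups come
from: the radiologist oracle (RD-MR) or the network triage (ResNet-MR).
"new-responders" are patients RD-MR calls non-responders but ResNet-MR calls
responders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .classifier import LesionAssessment
from .cohort import ExclusionReason, LesionRecord, PatientRecord

logger = logging.getLogger(__name__)

MIN_ELIGIBLE_DIAMETER_CM = 1.0


@dataclass
class ResponseCall:
    """Responder status for one patient under one named criterion."""

    patient_id: str
    criterion: str  # "rd_mr" | "resnet_mr"
    responder: bool
    index_lesion_id: Optional[str]
    baseline_group: Optional[int]
    followup_group: Optional[int]
    n_skipped_baseline_g1: int = 0


def lesion_eligible(lesion: LesionRecord) -> bool:
    """Labelling eligibility: no vessel/subcapsular exclusion, >= 1 cm."""
    return (
        lesion.exclusion_reason == ExclusionReason.NONE
        and lesion.diameter_cm >= MIN_ELIGIBLE_DIAMETER_CM
    )


def call_lesion_response(baseline_group: int, followup_group: int) -> bool:
    """Lesion responds iff it moves from Group 2/3 to Group 1."""
    for g in (baseline_group, followup_group):
        if g not in (1, 2, 3):
            raise ValueError(f"group must be 1, 2 or 3, got {g}")
    if baseline_group == 1:
        raise ValueError(
            "response is undefined for a lesion already Group 1 at baseline"
        )
    return followup_group == 1


class PatientExcluded(ValueError):
    """Raised when no eligible, assessable lesion supports a response call."""


def call_patient_response(
    patient: PatientRecord,
    assessments: Mapping[Tuple[str, int], LesionAssessment],
    criterion: str,
) -> ResponseCall:
    """Patient-level call from per-(lesion, timepoint) group assessments.

    Uses only the baseline and the *first* follow-up scan.  Lesions whose
    baseline assessment is Group 1 (possible after ambiguous-image triage)
    have no defined response and are skipped with a warning; if no lesion
    remains, the patient is excluded via :class:`PatientExcluded`.
    """
    followup = patient.first_followup
    lesion_calls: List[Tuple[LesionRecord, int, int, bool]] = []
    n_skipped = 0
    for lesion in patient.lesions:
        if not lesion_eligible(lesion):
            continue
        base = assessments.get((lesion.lesion_id, 0))
        post = assessments.get((lesion.lesion_id, followup))
        if base is None or post is None:
            continue
        if base.group == 1:
            n_skipped += 1
            logger.warning(
                "%s: lesion %s is Group 1 at baseline under %s; response undefined, skipped",
                patient.patient_id, lesion.lesion_id, criterion,
            )
            continue
        lesion_calls.append(
            (lesion, base.group, post.group, call_lesion_response(base.group, post.group))
        )

    if not lesion_calls:
        raise PatientExcluded(
            f"{patient.patient_id}: no eligible lesion with defined baseline/follow-up "
            f"assessments under {criterion}"
        )

    responder = all(c[3] for c in lesion_calls)
    # index lesion: worst response first (non-responding lesions outrank
    # responding ones), ties broken by largest diameter
    worst = sorted(lesion_calls, key=lambda c: (c[3], -c[0].diameter_cm))[0]
    return ResponseCall(
        patient_id=patient.patient_id,
        criterion=criterion,
        responder=responder,
        index_lesion_id=worst[0].lesion_id,
        baseline_group=worst[1],
        followup_group=worst[2],
        n_skipped_baseline_g1=n_skipped,
    )


def identify_new_responders(
    rd_calls: Mapping[str, ResponseCall],
    resnet_calls: Mapping[str, ResponseCall],
) -> Tuple[Set[str], Set[str]]:
    """Patients rescued by the network criterion, plus containment violations.

    Returns ``(new_responders, violations)``: new-responders are RD-MR
    non-responders that ResNet-MR calls responders; violations are patients
    moving the other way (responder -> non-responder), which the refinement
    should never produce — they are reported, not hidden.
    """
    if set(rd_calls) != set(resnet_calls):
        raise ValueError(
            "RD-MR and ResNet-MR call sets must cover the same patients; "
            f"difference: {set(rd_calls) ^ set(resnet_calls)}"
        )
    new = {
        pid
        for pid in rd_calls
        if not rd_calls[pid].responder and resnet_calls[pid].responder
    }
    violations = {
        pid
        for pid in rd_calls
        if rd_calls[pid].responder and not resnet_calls[pid].responder
    }
    if violations:
        logger.warning(
            "containment violated: %d patient(s) moved responder -> non-responder: %s",
            len(violations), sorted(violations),
        )
    return new, violations
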
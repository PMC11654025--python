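"""Synthetic longitudinal cohort generation.

Emulates the shape of an unresectable, liver-only metastatic colorectal
cancer cohort treated with bevacizumab-based chemotherapy: each patient has
a baseline CT and a first follow-up about three months later, one to several
liver lesions with a handful of axial slices each, an overall-survival time
whose hazard depends on a latent responder status, and a downstaging flag
(conversion to curative-intent hepatectomy and/or ablation).

Latent responders have all eligible lesions drop below the Group-1 severity
cut at follow-up; non-responders keep at least one lesion above it.  A
configurable fraction of follow-up lesions is redrawn into the mid-severity
("Group 2") band, where the oracle label is ambiguous but the lean — which
side of 0.5 the severity falls on — still tracks the latent status.  These
ambiguous-leaning-responder patients are the ones a downstream classifier
can rescue from a non-responder call.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .phantom import (
    DEFAULT_G1_CUT,
    DEFAULT_G3_CUT,
    AxisSlopes,
    LesionPhantomParams,
    RoiImage,
    params_from_severity,
    render_lesion,
)

logger = logging.getLogger(__name__)

MONTHS_PER_DAY = 12.0 / 365.25

#: follow-up severity bands for ambiguous ("Group-2") lesions; the lean
#: (side of 0.5) encodes the latent responder status with a small margin.
AMBIG_RESPONDER_BAND = (0.34, 0.48)
AMBIG_NONRESPONDER_BAND = (0.52, 0.66)


class ExclusionReason(str, Enum):
    NONE = "none"
    VESSEL_ENCASING = "vessel_encasing"
    SUBCAPSULAR = "subcapsular"
    SUB_CM = "sub_cm"


@dataclass
class LesionRecord:
    """One metastatic lesion with its per-timepoint slice images.

    Lesions encasing hepatic vessels or sitting in the subcapsular region are
    flagged ineligible for labelling and carry no rendered slices; sub-cm
    lesions are ineligible by the size criterion.
    """

    lesion_id: str
    diameter_cm: float
    exclusion_reason: ExclusionReason = ExclusionReason.NONE
    slices_by_timepoint: Dict[int, List[RoiImage]] = field(default_factory=dict)
    #: latent follow-up/baseline severities, kept even when rendering is off
    severity_by_timepoint: Dict[int, float] = field(default_factory=dict)

    @property
    def eligible(self) -> bool:
        return self.exclusion_reason == ExclusionReason.NONE


@dataclass
class PatientRecord:
    """A patient: lesions, scan schedule, survival outcome, ground truth."""

    patient_id: str
    lesions: List[LesionRecord]
    timepoints: List[int]            # days from treatment start; baseline = 0
    os_months: float
    event: bool
    downstaging: bool
    latent_responder: bool

    def __post_init__(self) -> None:
        if not self.lesions:
            raise ValueError(f"{self.patient_id}: at least one lesion required")
        if 0 not in self.timepoints or len(self.timepoints) < 2:
            raise ValueError(
                f"{self.patient_id}: baseline (day 0) and at least one follow-up required"
            )
        if self.os_months <= 3.0:
            raise ValueError(
                f"{self.patient_id}: OS must exceed 3 months for inclusion"
            )

    @property
    def first_followup(self) -> int:
        return sorted(t for t in self.timepoints if t > 0)[0]


@dataclass
class CohortConfig:
    """Generator settings; defaults mirror the reference clinical cohort."""

    n_patients: int = 84
    p_multiple_lesions: float = 0.857
    max_lesions: int = 5
    diameter_mean_cm: float = 4.52
    diameter_sd_cm: float = 3.12
    p_latent_responder: float = 0.5
    median_os_responder_months: float = 36.51
    median_os_nonresponder_months: float = 21.20
    censor_horizon_months: float = 60.0
    followup_interval_days_median: float = 99.0
    followup_interval_days_jitter: float = 9.0
    #: per-lesion probability of a mid-band ("Group 2") follow-up severity;
    #: calibrated so that roughly a third of latent responders carry at least
    #: one ambiguous lesion, matching the reference cohort's responder-count
    #: shift (28 -> 44 of 84) under ~2.5 eligible lesions per patient
    ambiguity_fraction: float = 0.15
    #: optional separate mid-band probability for non-responders' lesions;
    #: None means use ambiguity_fraction for both arms.  Setting it lower
    #: enriches ambiguity among latent responders.
    ambiguity_fraction_nonresponder: Optional[float] = None
    slices_min: int = 1
    slices_max: int = 4
    p_vessel_encasing: float = 0.05
    p_subcapsular: float = 0.08
    p_downstaging_responder: float = 0.375
    p_downstaging_nonresponder: float = 0.175
    p_lesion_improves_nonresponder: float = 0.3
    g1_cut: float = DEFAULT_G1_CUT
    g3_cut: float = DEFAULT_G3_CUT
    noise_sd: float = 0.02
    slopes: AxisSlopes = field(default_factory=AxisSlopes)
    render_images: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_multiple_lesions",
            "p_latent_responder",
            "ambiguity_fraction",
            "p_vessel_encasing",
            "p_subcapsular",
            "p_downstaging_responder",
            "p_downstaging_nonresponder",
            "p_lesion_improves_nonresponder",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.ambiguity_fraction_nonresponder is not None and not (
            0.0 <= self.ambiguity_fraction_nonresponder <= 1.0
        ):
            raise ValueError("ambiguity_fraction_nonresponder must be in [0,1]")
        if self.median_os_responder_months <= 0 or self.median_os_nonresponder_months <= 0:
            raise ValueError("median OS values must be positive")
        if self.censor_horizon_months <= 0:
            raise ValueError("censor_horizon_months must be positive")
        if not 1 <= self.slices_min <= self.slices_max <= 8:
            raise ValueError("slice counts must satisfy 1 <= min <= max <= 8")
        if self.max_lesions < 1:
            raise ValueError("max_lesions must be >= 1")


def simulate_survival(
    latent_responder: bool, config: CohortConfig, rng_seed: int
) -> Tuple[float, bool]:
    """Draw (os_months, event) for one patient.

    Survival is exponential with the configured group median (rate
    ``ln 2 / median``); administrative censoring truncates at
    ``censor_horizon_months``.  Death times of 3 months or less are redrawn,
    matching the cohort inclusion rule that early deaths are excluded.
    """
    median = (
        config.median_os_responder_months
        if latent_responder
        else config.median_os_nonresponder_months
    )
    rate = np.log(2.0) / median
    rng = np.random.default_rng(rng_seed)
    t = 0.0
    for _ in range(1000):
        t = rng.exponential(1.0 / rate)
        if t > 3.0:
            break
    else:  # pragma: no cover - practically unreachable
        raise RuntimeError("failed to draw an inclusion-compatible survival time")
    event = t <= config.censor_horizon_months
    os_months = min(t, config.censor_horizon_months)
    return float(os_months), bool(event)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, low: float, high: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return float(x)
    return float(np.clip(mean, low, high))  # pragma: no cover


def _draw_followup_severity(
    rng: np.random.Generator, responder: bool, improves: bool, config: CohortConfig
) -> float:
    """Latent follow-up severity before any ambiguity redraw.

    Responding lesions drop into the Group-1 band; persisting lesions stay
    Group-3-like.  Mid-band (Group-2) severities arise only through the
    ambiguity redraw, so their lean always encodes the latent status.
    """
    if responder or improves:
        return float(rng.uniform(0.0, config.g1_cut))
    return float(rng.uniform(config.g3_cut, 1.0))


def generate_cohort(config: CohortConfig) -> List[PatientRecord]:
    """Generate the full synthetic cohort; a pure function of the config.

    Per patient: lesion count (solitary vs multiple per
    ``p_multiple_lesions``), truncated-normal diameters (>= 1 cm, so every
    rendered lesion passes the size criterion), a baseline scan at day 0 and
    a follow-up near the configured median interval, per-lesion severities at
    both timepoints, survival via :func:`simulate_survival`, and a
    downstaging flag with responder-dependent probability.
    """
    if config.n_patients < 2:
        raise ValueError("n_patients must be >= 2 for any survival comparison")

    root = np.random.SeedSequence(config.seed)
    patients: List[PatientRecord] = []
    for pidx, pseq in enumerate(root.spawn(config.n_patients)):
        child = pseq.spawn(3)
        rng = np.random.default_rng(child[0])
        surv_seed = int(child[1].generate_state(1)[0] % (2**31))
        render_seq = child[2]

        patient_id = f"P{pidx:04d}"
        latent_responder = bool(rng.random() < config.p_latent_responder)

        multiple = rng.random() < config.p_multiple_lesions
        n_lesions = int(rng.integers(2, config.max_lesions + 1)) if multiple and config.max_lesions >= 2 else 1

        followup_day = int(
            round(
                np.clip(
                    rng.normal(config.followup_interval_days_median, config.followup_interval_days_jitter),
                    90,
                    120,
                )
            )
        )
        timepoints = [0, followup_day]

        lesions: List[LesionRecord] = []
        for lidx in range(n_lesions):
            diameter = _truncated_normal(
                rng, config.diameter_mean_cm, config.diameter_sd_cm, 1.0, 12.0
            )
            reason = ExclusionReason.NONE
            u = rng.random()
            if u < config.p_vessel_encasing:
                reason = ExclusionReason.VESSEL_ENCASING
            elif u < config.p_vessel_encasing + config.p_subcapsular:
                reason = ExclusionReason.SUBCAPSULAR
            lesions.append(
                LesionRecord(
                    lesion_id=f"{patient_id}-L{lidx}",
                    diameter_cm=diameter,
                    exclusion_reason=reason,
                )
            )
        if all(not l.eligible for l in lesions):
            lesions[0].exclusion_reason = ExclusionReason.NONE

        eligible = [l for l in lesions if l.eligible]
        # baseline: untreated disease is Group-3-like; a configurable fraction
        # sits in the ambiguous mid band (no lean — baseline predates treatment)
        baseline_sev = {
            l.lesion_id: (
                float(rng.uniform(config.g1_cut + 0.01, config.g3_cut - 0.01))
                if rng.random() < config.ambiguity_fraction
                else float(rng.uniform(config.g3_cut, 1.0))
            )
            for l in eligible
        }

        followup_sev: Dict[str, float] = {}
        for _ in range(1000):
            followup_sev = {}
            for l in eligible:
                improves = rng.random() < config.p_lesion_improves_nonresponder
                followup_sev[l.lesion_id] = _draw_followup_severity(
                    rng, latent_responder, improves, config
                )
            if latent_responder or any(
                s > config.g1_cut for s in followup_sev.values()
            ):
                break
        else:  # pragma: no cover
            raise RuntimeError("failed to draw non-responder follow-up severities")

        # ambiguity redraw: lesion lands in the mid band, lean follows latent status
        band = AMBIG_RESPONDER_BAND if latent_responder else AMBIG_NONRESPONDER_BAND
        q_amb = config.ambiguity_fraction
        if not latent_responder and config.ambiguity_fraction_nonresponder is not None:
            q_amb = config.ambiguity_fraction_nonresponder
        for l in eligible:
            if rng.random() < q_amb:
                followup_sev[l.lesion_id] = float(rng.uniform(*band))

        for l in eligible:
            l.severity_by_timepoint = {0: baseline_sev[l.lesion_id], followup_day: followup_sev[l.lesion_id]}
            for t in timepoints:
                sev = l.severity_by_timepoint[t]
                n_slices = int(rng.integers(config.slices_min, config.slices_max + 1))
                group = _group(sev, config)
                slice_sevs = _jitter_within_group(rng, sev, group, n_slices, config)
                if config.render_images:
                    images = []
                    for k, ssev in enumerate(slice_sevs):
                        params = params_from_severity(
                            ssev, l.diameter_cm, slopes=config.slopes, noise_sd=config.noise_sd
                        )
                        seed_k = int(render_seq.spawn(1)[0].generate_state(1)[0] % (2**31))
                        images.append(
                            render_lesion(
                                params,
                                seed_k,
                                slice_index=k,
                                g1_cut=config.g1_cut,
                                g3_cut=config.g3_cut,
                            )
                        )
                    l.slices_by_timepoint[t] = images

        os_months, event = simulate_survival(latent_responder, config, surv_seed)
        p_ds = (
            config.p_downstaging_responder
            if latent_responder
            else config.p_downstaging_nonresponder
        )
        downstaging = bool(rng.random() < p_ds)

        patients.append(
            PatientRecord(
                patient_id=patient_id,
                lesions=lesions,
                timepoints=timepoints,
                os_months=os_months,
                event=event,
                downstaging=downstaging,
                latent_responder=latent_responder,
            )
        )
    return patients


def _group(severity: float, config: CohortConfig) -> int:
    from .phantom import severity_to_group

    return severity_to_group(severity, config.g1_cut, config.g3_cut)


def _jitter_within_group(
    rng: np.random.Generator, sev: float, group: int, n: int, config: CohortConfig
) -> List[float]:
    """Per-slice severity jitter, clipped so every slice keeps the lesion's group."""
    if group == 1:
        lo, hi = 0.0, config.g1_cut
    elif group == 3:
        lo, hi = config.g3_cut, 1.0
    else:
        lo, hi = config.g1_cut + 0.005, config.g3_cut - 0.005
        # preserve the lean of ambiguous lesions
        if sev < 0.5:
            hi = min(hi, 0.495)
        else:
            lo = max(lo, 0.505)
    return [float(np.clip(sev + rng.normal(0.0, 0.015), lo, hi)) for _ in range(n)]


# ---------------------------------------------------------------------------
# persistence


def cohort_table(patients: List[PatientRecord]) -> pd.DataFrame:
    """One row per patient: outcome fields plus generator ground truth."""
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "os_months": [p.os_months for p in patients],
            "event": [p.event for p in patients],
            "downstaging": [p.downstaging for p in patients],
            "latent_responder": [p.latent_responder for p in patients],
        }
    )


def image_manifest(patients: List[PatientRecord]) -> pd.DataFrame:
    """One row per rendered slice image."""
    rows = []
    for p in patients:
        for l in p.lesions:
            for t, images in sorted(l.slices_by_timepoint.items()):
                for img in images:
                    rows.append(
                        {
                            "patient_id": p.patient_id,
                            "lesion_id": l.lesion_id,
                            "timepoint_days": t,
                            "slice_index": img.slice_index,
                            "true_group": img.true_group,
                            "latent_severity": img.latent_severity,
                            "diameter_cm": img.diameter_cm,
                        }
                    )
    return pd.DataFrame(rows)


def _lesion_polygon(img: RoiImage, n_vertices: int = 24) -> List[List[float]]:
    """Approximate lesion boundary polygon (circle at the nominal radius)."""
    from .phantom import PIXEL_PITCH_CM, ROI_SIZE

    r = min(img.diameter_cm / PIXEL_PITCH_CM / 2.0, ROI_SIZE / 2 - 1)
    c = (ROI_SIZE - 1) / 2.0
    ang = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    return [[float(c + r * np.cos(a)), float(c + r * np.sin(a))] for a in ang]


def save_cohort(patients: List[PatientRecord], out_dir: str | Path) -> None:
    """Write cohort CSV, image manifest CSV, PNGs and polygon annotations.

    PNGs are 8-bit grayscale; each image gets a Labelme-style JSON sidecar
    with a single ``lesion`` polygon, for parity with the real-data
    annotation format.
    """
    from PIL import Image

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    cohort_table(patients).to_csv(out / "cohort.csv", index=False)

    rows = []
    for p in patients:
        for l in p.lesions:
            for t, images in sorted(l.slices_by_timepoint.items()):
                for img in images:
                    name = f"{l.lesion_id}_d{t}_s{img.slice_index}"
                    rel = f"images/{name}.png"
                    Image.fromarray(
                        (img.pixels * 255).round().astype(np.uint8), mode="L"
                    ).save(out / rel)
                    ann = {
                        "version": "5.0.0",
                        "flags": {},
                        "shapes": [
                            {
                                "label": "lesion",
                                "points": _lesion_polygon(img),
                                "shape_type": "polygon",
                            }
                        ],
                        "imagePath": f"{name}.png",
                        "imageHeight": img.pixels.shape[0],
                        "imageWidth": img.pixels.shape[1],
                    }
                    (out / "images" / f"{name}.json").write_text(json.dumps(ann))
                    rows.append(
                        {
                            "patient_id": p.patient_id,
                            "lesion_id": l.lesion_id,
                            "timepoint_days": t,
                            "slice_index": img.slice_index,
                            "path": rel,
                            "true_group": img.true_group,
                            "diameter_cm": img.diameter_cm,
                        }
                    )
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)


def config_from_json(path: str | Path) -> CohortConfig:
    """Load a CohortConfig from a JSON file (unknown keys rejected)."""
    data = json.loads(Path(path).read_text())
    slopes = data.pop("slopes", None)
    cfg = CohortConfig(**data)
    if slopes is not None:
        cfg.slopes = AxisSlopes(**slopes)
    return cfg
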
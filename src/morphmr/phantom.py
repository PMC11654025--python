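"""Synthetic lesion-phantom rendering.

Liver metastases assessed on portal-venous-phase CT are graded into three
morphological groups from three visual criteria: overall attenuation
homogeneity, sharpness of the tumour--liver interface, and presence of a
peripheral enhancing rim.  Group 1 lesions are homogeneous, sharply
marginated and rim-free; Group 3 lesions are heterogeneous, ill-defined and
rim-enhancing; Group 2 is intermediate.

This module renders 64x64 grayscale region-of-interest (ROI) patches that
vary continuously along those three axes, driven by a single latent
``severity`` in [0, 1] (0 = fully Group-1-like, 1 = fully Group-3-like).
The renderer is a phantom, not a CT simulator: an elliptical lesion on a
weakly textured liver background, with

* a heterogeneity blob field inside the lesion, amplitude growing with
  ``1 - homogeneity``;
* Gaussian blurring of the lesion boundary, width growing with
  ``1 - interface_sharpness``;
* an additive peripheral ring of amplitude ``rim_amplitude``;
* i.i.d. Gaussian pixel noise.

All randomness is driven by an explicit seed: the same (params, seed) pair
renders bit-identical images, and because the underlying noise fields depend
only on the seed, rim contrast and within-lesion variance are monotone in
severity at fixed seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Field of view is 64 px at 1 mm/px, so a 4.5 cm lesion spans ~45 px (~70%).
ROI_SIZE = 64
PIXEL_PITCH_CM = 0.1
#: Lesions beyond twice the field of view cannot be meaningfully cropped.
MAX_DIAMETER_CM = 2.0 * ROI_SIZE * PIXEL_PITCH_CM

#: Default group cuts on the latent severity axis.
DEFAULT_G1_CUT = 0.33
DEFAULT_G3_CUT = 0.67


@dataclass(frozen=True)
class RenderStyle:
    """Fixed intensity conventions of the phantom (normalised [0, 1] units)."""

    liver_level: float = 0.50       # background parenchyma intensity
    core_level: float = 0.32        # hypoattenuating lesion core
    background_texture_sd: float = 0.02
    background_corr_px: float = 4.0
    hetero_max: float = 0.15        # blob amplitude at homogeneity 0
    hetero_corr_px: float = 2.5
    edge_sigma_max_px: float = 3.0  # boundary blur at interface_sharpness 0
    edge_sigma_min_px: float = 0.3
    rim_amplitude_max: float = 0.25
    rim_width_px: float = 2.5
    ellipticity: float = 0.15       # max relative axis anisotropy


DEFAULT_STYLE = RenderStyle()


@dataclass(frozen=True)
class AxisSlopes:
    """Affine severity -> morphological-axis mapping.

    Slopes of 1 give full contrast between the severity extremes; smaller
    slopes compress the axes toward their Group-1 values, letting tests set
    up harder classification regimes.
    """

    homogeneity: float = 1.0
    interface: float = 1.0
    rim: float = 1.0


DEFAULT_SLOPES = AxisSlopes()


@dataclass(frozen=True)
class LesionPhantomParams:
    """Latent severity plus the three morphological axes for one rendered ROI.

    ``severity`` is the single ground-truth axis; under the default mapping it
    monotonically decreases homogeneity and interface sharpness and increases
    rim amplitude.
    """

    severity: float
    homogeneity: float
    interface_sharpness: float
    rim_amplitude: float
    diameter_cm: float
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError(f"severity must be in [0,1], got {self.severity}")
        if not 0.0 <= self.homogeneity <= 1.0:
            raise ValueError(f"homogeneity must be in [0,1], got {self.homogeneity}")
        if not 0.0 <= self.interface_sharpness <= 1.0:
            raise ValueError(
                f"interface_sharpness must be in [0,1], got {self.interface_sharpness}"
            )
        if self.rim_amplitude < 0:
            raise ValueError(f"rim_amplitude must be >= 0, got {self.rim_amplitude}")
        if self.diameter_cm <= 0:
            raise ValueError(f"diameter_cm must be > 0, got {self.diameter_cm}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


def params_from_severity(
    severity: float,
    diameter_cm: float,
    *,
    slopes: AxisSlopes = DEFAULT_SLOPES,
    style: RenderStyle = DEFAULT_STYLE,
    noise_sd: float = 0.02,
) -> LesionPhantomParams:
    """Map a latent severity onto the three morphological axes (affine)."""
    return LesionPhantomParams(
        severity=severity,
        homogeneity=1.0 - slopes.homogeneity * severity,
        interface_sharpness=1.0 - slopes.interface * severity,
        rim_amplitude=style.rim_amplitude_max * slopes.rim * severity,
        diameter_cm=diameter_cm,
        noise_sd=noise_sd,
    )


@dataclass
class RoiImage:
    """A 64x64 normalised intensity patch plus the auxiliary size feature.

    ``diameter_cm`` travels alongside the pixels because absolute scale is
    lost when ROIs are resized to a fixed grid; the classifier receives it as
    a separate scalar input.  ``true_group``/``latent_severity`` are present
    for synthetic data and absent for real images.
    """

    pixels: np.ndarray
    diameter_cm: float
    slice_index: int = 0
    true_group: Optional[int] = None
    latent_severity: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.shape != (ROI_SIZE, ROI_SIZE):
            raise ValueError(
                f"ROI must be {ROI_SIZE}x{ROI_SIZE}, got {self.pixels.shape}"
            )
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("pixel values must lie in [0,1] after normalisation")
        if self.diameter_cm <= 0:
            raise ValueError("diameter_cm must be > 0")
        if self.slice_index < 0:
            raise ValueError("slice_index must be >= 0")
        if self.true_group is not None and self.true_group not in (1, 2, 3):
            raise ValueError(f"true_group must be 1, 2 or 3, got {self.true_group}")


def severity_to_group(
    severity: float,
    g1_cut: float = DEFAULT_G1_CUT,
    g3_cut: float = DEFAULT_G3_CUT,
) -> int:
    """Discretise latent severity into morphological Group 1, 2 or 3.

    Cuts are inclusive: severity <= g1_cut -> 1, severity >= g3_cut -> 3,
    otherwise 2.
    """
    if not 0.0 <= g1_cut < g3_cut <= 1.0:
        raise ValueError(f"require 0 <= g1_cut < g3_cut <= 1, got {g1_cut}, {g3_cut}")
    if not 0.0 <= severity <= 1.0:
        raise ValueError(f"severity must be in [0,1], got {severity}")
    if severity <= g1_cut:
        return 1
    if severity >= g3_cut:
        return 3
    return 2


def _lesion_geometry(params: LesionPhantomParams, rng: np.random.Generator):
    """Elliptical signed distance (px) to the lesion boundary; negative inside."""
    radius_px = params.diameter_cm / PIXEL_PITCH_CM / 2.0
    ecc = DEFAULT_STYLE.ellipticity
    ax_a = radius_px * (1.0 + ecc * (rng.random() - 0.5))
    ax_b = radius_px**2 / ax_a  # preserve area
    theta = rng.random() * np.pi
    yy, xx = np.mgrid[0:ROI_SIZE, 0:ROI_SIZE].astype(np.float64)
    yy -= (ROI_SIZE - 1) / 2.0
    xx -= (ROI_SIZE - 1) / 2.0
    c, s = np.cos(theta), np.sin(theta)
    u = c * xx + s * yy
    v = -s * xx + c * yy
    r_norm = np.sqrt((u / ax_a) ** 2 + (v / ax_b) ** 2)
    mean_radius = np.sqrt(ax_a * ax_b)
    # signed distance approximation in pixels
    return (r_norm - 1.0) * mean_radius, mean_radius


def render_lesion(
    params: LesionPhantomParams,
    rng_seed: int,
    *,
    style: RenderStyle = DEFAULT_STYLE,
    slice_index: int = 0,
    g1_cut: float = DEFAULT_G1_CUT,
    g3_cut: float = DEFAULT_G3_CUT,
) -> RoiImage:
    """Render one 64x64 lesion ROI; deterministic given (params, rng_seed).

    Lesions larger than the field of view are rendered anyway (the boundary
    falls outside the patch, i.e. a centre crop) with a warning; beyond
    ``MAX_DIAMETER_CM`` an error names the limit.
    """
    if params.diameter_cm > MAX_DIAMETER_CM:
        raise ValueError(
            f"diameter {params.diameter_cm:.2f} cm exceeds the renderable limit of "
            f"{MAX_DIAMETER_CM:.1f} cm ({ROI_SIZE} px field at {PIXEL_PITCH_CM * 10:.0f} mm/px)"
        )
    if params.diameter_cm > ROI_SIZE * PIXEL_PITCH_CM:
        warnings.warn(
            f"lesion of {params.diameter_cm:.2f} cm exceeds the "
            f"{ROI_SIZE * PIXEL_PITCH_CM:.1f} cm field of view; boundary is cropped",
            stacklevel=2,
        )

    rng = np.random.default_rng(rng_seed)
    # Draw every stochastic field up-front, before severity-dependent scaling,
    # so that a fixed seed yields severity-monotone rim contrast and variance.
    bg_white = rng.standard_normal((ROI_SIZE, ROI_SIZE))
    blob_white = rng.standard_normal((ROI_SIZE, ROI_SIZE))
    pixel_noise = rng.standard_normal((ROI_SIZE, ROI_SIZE))
    signed_dist, _ = _lesion_geometry(params, rng)

    bg_field = ndimage.gaussian_filter(bg_white, style.background_corr_px)
    bg_field /= max(bg_field.std(), 1e-12)
    background = style.liver_level + style.background_texture_sd * bg_field

    blobs = ndimage.gaussian_filter(blob_white, style.hetero_corr_px)
    blobs /= max(blobs.std(), 1e-12)
    hetero_amp = style.hetero_max * (1.0 - params.homogeneity)
    lesion_field = style.core_level + hetero_amp * blobs

    # Interface: soft alpha mask, blur width set by (1 - interface_sharpness).
    edge_sigma = style.edge_sigma_min_px + (style.edge_sigma_max_px - style.edge_sigma_min_px) * (
        1.0 - params.interface_sharpness
    )
    hard_mask = (signed_dist <= 0.0).astype(np.float64)
    alpha = ndimage.gaussian_filter(hard_mask, edge_sigma)

    img = background * (1.0 - alpha) + lesion_field * alpha

    # Peripheral rim: band straddling the boundary, mild fixed smoothing so
    # its contrast scales linearly with rim_amplitude.
    ring = np.exp(-0.5 * (signed_dist / style.rim_width_px) ** 2)
    ring = ndimage.gaussian_filter(ring, 0.5)
    img = img + params.rim_amplitude * ring

    img = img + params.noise_sd * pixel_noise
    img = np.clip(img, 0.0, 1.0)

    return RoiImage(
        pixels=img,
        diameter_cm=params.diameter_cm,
        slice_index=slice_index,
        true_group=severity_to_group(params.severity, g1_cut, g3_cut),
        latent_severity=params.severity,
    )


def lesion_masks(diameter_cm: float, rng_seed: int, params: Optional[LesionPhantomParams] = None):
    """Core / rim-annulus boolean masks for a lesion rendered with ``rng_seed``.

    Used by tests and calibration: the geometry RNG stream is replayed so the
    masks align with ``render_lesion`` output for the same seed.
    """
    if params is None:
        params = params_from_severity(0.0, diameter_cm)
    rng = np.random.default_rng(rng_seed)
    rng.standard_normal((ROI_SIZE, ROI_SIZE))
    rng.standard_normal((ROI_SIZE, ROI_SIZE))
    rng.standard_normal((ROI_SIZE, ROI_SIZE))
    signed_dist, mean_radius = _lesion_geometry(params, rng)
    core = signed_dist < -0.35 * mean_radius
    # inner annulus: just inside the boundary, where the enhancing rim sits
    rim = (signed_dist <= 0.0) & (signed_dist >= -DEFAULT_STYLE.rim_width_px)
    return core, rim


def rim_contrast(img: RoiImage, rng_seed: int) -> float:
    """Mean rim-annulus minus mean core intensity for a rendered image."""
    params = params_from_severity(
        img.latent_severity if img.latent_severity is not None else 0.0,
        img.diameter_cm,
    )
    core, rim = lesion_masks(img.diameter_cm, rng_seed, params)
    return float(img.pixels[rim].mean() - img.pixels[core].mean())


def core_variance(img: RoiImage, rng_seed: int) -> float:
    """Within-lesion (core) intensity variance for a rendered image."""
    params = params_from_severity(
        img.latent_severity if img.latent_severity is not None else 0.0,
        img.diameter_cm,
    )
    core, _ = lesion_masks(img.diameter_cm, rng_seed, params)
    return float(img.pixels[core].var())
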
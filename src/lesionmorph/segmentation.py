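"""Semi-automated ischemic lesion segmentation from ADC maps.

Acutely ischemic tissue shows restricted diffusion, i.e. low apparent
diffusion coefficient (ADC). Segmentation is a brain-masked upper threshold on
the ADC map — the default of 620e-6 mm²/s is the established cutoff for acute
ischemia — followed by removal of implausibly small components (< 10 mm³,
likely noise or artifact). The threshold is inclusive ("maximum" read as an
attained upper bound) and ADC values <= 0 are treated as invalid background so
that air or masked-out voxels can never enter the lesion. Manual rater
corrections are accepted as an externally edited mask via
:func:`apply_manual_edits`; interactive editing itself is out of scope, as is
any registration.
"""

from __future__ import annotations

import logging

import numpy as np

from .shape import connectivity_structure
from .volumes import ImageVolume, LesionMask, require_same_grid

__all__ = ["segment_adc", "remove_small_components", "apply_manual_edits"]

logger = logging.getLogger(__name__)

DEFAULT_ADC_THRESHOLD = 620e-6  # mm²/s
DEFAULT_MIN_COMPONENT_MM3 = 10.0


def segment_adc(
    adc: ImageVolume,
    brain_mask: LesionMask,
    threshold: float = DEFAULT_ADC_THRESHOLD,
) -> LesionMask:
    """Threshold an ADC map inside the brain mask.

    A voxel is lesion iff it lies in the brain mask, its ADC is strictly
    positive (zero marks invalid/background voxels) and its ADC does not exceed
    ``threshold`` (inclusive).
    """
    require_same_grid(adc, brain_mask, "ADC map and brain mask")
    if threshold <= 0:
        raise ValueError(f"ADC threshold must be positive, got {threshold}")
    data = adc.data
    out = brain_mask.data & (data > 0) & (data <= threshold)
    return LesionMask(out, adc.spacing_mm)


def remove_small_components(
    mask: LesionMask,
    min_volume_mm3: float = DEFAULT_MIN_COMPONENT_MM3,
    connectivity: int = 26,
) -> LesionMask:
    """Drop connected components whose physical volume is *strictly* below
    ``min_volume_mm3``; a component of exactly the threshold volume survives.
    """
    if min_volume_mm3 < 0:
        raise ValueError(f"min_volume_mm3 must be non-negative, got {min_volume_mm3}")
    if mask.is_empty() or min_volume_mm3 == 0:
        return mask
    from scipy import ndimage

    labels, n = ndimage.label(mask.data, structure=connectivity_structure(connectivity))
    if n == 0:
        return mask
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    volumes = counts * mask.voxel_volume_mm3
    keep = volumes >= min_volume_mm3
    keep[0] = False
    return LesionMask(keep[labels], mask.spacing_mm)


def apply_manual_edits(mask: LesionMask, edits: LesionMask) -> LesionMask:
    """Adopt a manually corrected mask after validating it.

    The edited mask replaces the automatic one verbatim; validation only
    checks that it is binary and lives on the same grid. The voxel delta is
    logged for provenance.
    """
    require_same_grid(mask, edits, "mask and manual edits")
    added = int((edits.data & ~mask.data).sum())
    removed = int((mask.data & ~edits.data).sum())
    logger.info("manual edits applied: +%d voxels, -%d voxels", added, removed)
    return LesionMask(edits.data.copy(), edits.spacing_mm)
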
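"""Differentiation co-emergence scoring.

After directed differentiation, the blue channel reports a lineage
transcription factor (PAX6 for neuro-ectoderm, EOMES for mesendoderm)
instead of a nuclear stain.  Each population's marker-positive area
fraction is the area of (population ∧ marker) over the population area,
and the enrichment ratio divides the CRISPRi fraction by the WT
fraction: >1 means the knockdown population differentiates
preferentially.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .imaging import BinaryMask, ColonyImage, make_mask, split_channels

logger = logging.getLogger(__name__)


@dataclass
class LineageScore:
    frac_wt: float
    frac_crispri: float
    enrichment: float
    marker_name: str
    areas: dict


def marker_positive_fraction(pop_mask: BinaryMask, marker_mask: BinaryMask) -> float:
    """Fraction of the population area that is marker-positive, in [0, 1]."""
    if pop_mask.shape != marker_mask.shape:
        raise ValueError("masks must share one shape")
    if pop_mask.area == 0:
        raise ValueError("population mask is empty")
    overlap = int((pop_mask.grid & marker_mask.grid).sum())
    return overlap / pop_mask.area


def lineage_enrichment_ratio(frac_crispri: float, frac_wt: float) -> float:
    """CRISPRi-over-WT marker fraction ratio.

    ``frac_wt == 0`` with a positive CRISPRi fraction gives the infinity
    sentinel; 0/0 is missing (nan).
    """
    if frac_wt == 0.0:
        if frac_crispri > 0.0:
            return math.inf
        logger.warning("0/0 enrichment ratio; reported as missing")
        return math.nan
    return frac_crispri / frac_wt


def score_lineage(
    image: ColonyImage,
    marker_name: str = "PAX6",
    threshold_method: str = "otsu",
    fixed_value: float | None = None,
    min_object_px: int = 64,
    min_hole_px: int = 64,
) -> LineageScore:
    """Score marker co-emergence on one image.

    Channel roles: red = CRISPRi, green = WT, blue = marker.  All three
    channels are masked with the same recipe.
    """
    planes = split_channels(image)
    masks = {
        role: make_mask(planes[role], method=threshold_method,
                        fixed_value=fixed_value, min_object_px=min_object_px,
                        min_hole_px=min_hole_px, source_channel=role)
        for role in ("red", "green", "blue")
    }
    frac_crispri = marker_positive_fraction(masks["red"], masks["blue"])
    frac_wt = marker_positive_fraction(masks["green"], masks["blue"])
    areas = {
        "crispri_total": masks["red"].area,
        "wt_total": masks["green"].area,
        "marker_total": masks["blue"].area,
        "crispri_marker": int((masks["red"].grid & masks["blue"].grid).sum()),
        "wt_marker": int((masks["green"].grid & masks["blue"].grid).sum()),
    }
    return LineageScore(
        frac_wt=frac_wt,
        frac_crispri=frac_crispri,
        enrichment=lineage_enrichment_ratio(frac_crispri, frac_wt),
        marker_name=marker_name,
        areas=areas,
    )
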
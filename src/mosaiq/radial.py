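"""Radial segregation scoring of two-population mosaic colonies.

The score asks whether the CRISPRi (red) population is enriched at the
colony edge or center relative to the WT (green) population.  From the
nuclear (blue) mask the colony's equivalent-area radius r is derived;
the inner band is the nuclear mask within ¼·r of the centroid and the
outer band the nuclear mask beyond ¾·r (the middle band is deliberately
unused).  Each population contributes an inner/outer area ratio, and the
combined score averages the red ratio with the *inverse* of the green
ratio, so that edge-sorted red colonies score below 1 and center-sorted
ones above 1.

Two ratio variants are provided:

* ``density_normalized`` (default): the population's share of the
  nuclear area in each band — a uniformly mixed population scores 1
  regardless of band geometry;
* ``literal_area``: the raw inner/outer population area quotient (the
  per-population total-area normalization cancels in the quotient); a
  uniform population scores the band-area ratio, 1/7 in the continuum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .imaging import BinaryMask, ColonyImage, make_mask, split_channels

logger = logging.getLogger(__name__)

VARIANTS = ("density_normalized", "literal_area")


@dataclass
class ColonyGeometry:
    """Centroid and equivalent-area radius derived from the nuclear mask."""

    centroid: tuple[float, float]
    radius: float
    dapi_area: int

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("colony radius must be > 0")


@dataclass(frozen=True)
class RadialConfig:
    """Band geometry and ratio variant for segregation scoring."""

    inner_frac: float = 0.25
    outer_frac: float = 0.75
    variant: str = "density_normalized"

    def __post_init__(self) -> None:
        if not 0.0 < self.inner_frac < self.outer_frac < 1.0:
            raise ValueError(
                "radial bands require 0 < inner_frac < outer_frac < 1"
            )
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")


@dataclass
class RadialScore:
    """Per-colony segregation score and its area bookkeeping."""

    variant: str
    ratio_red: float
    ratio_green: float
    combined: float
    areas: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


def colony_geometry(dapi_mask: BinaryMask) -> ColonyGeometry:
    """Centroid and equivalent-area radius of the nuclear mask.

    The radius is ``sqrt(area / pi)``: the radius of the disk with the
    mask's area.  This is robust to ragged colony borders.
    """
    area = dapi_mask.area
    if area == 0:
        raise ValueError("no colony detected: nuclear mask is empty")
    if area < 16:
        logger.warning("degenerate nuclear mask: only %d pixels", area)
    rows, cols = np.nonzero(dapi_mask.grid)
    return ColonyGeometry(
        centroid=(float(rows.mean()), float(cols.mean())),
        radius=math.sqrt(area / math.pi),
        dapi_area=area,
    )


def radial_band_masks(
    geometry: ColonyGeometry,
    dapi_mask: BinaryMask,
    config: RadialConfig = RadialConfig(),
) -> tuple[BinaryMask, BinaryMask]:
    """Inner and outer band masks (disjoint by construction).

    inner = nuclear mask within ``inner_frac * r`` of the centroid,
    outer = nuclear mask at or beyond ``outer_frac * r``.
    """
    h, w = dapi_mask.shape
    rr, cc = np.ogrid[:h, :w]
    dist = np.hypot(rr - geometry.centroid[0], cc - geometry.centroid[1])
    inner = dapi_mask.grid & (dist <= config.inner_frac * geometry.radius)
    outer = dapi_mask.grid & (dist >= config.outer_frac * geometry.radius)
    prov = {"radius": geometry.radius, "centroid": geometry.centroid}
    return (
        BinaryMask(inner, source_channel="inner_band",
                   provenance={**prov, "frac": config.inner_frac}),
        BinaryMask(outer, source_channel="outer_band",
                   provenance={**prov, "frac": config.outer_frac}),
    )


def population_radial_ratio(
    pop_mask: BinaryMask,
    inner_mask: BinaryMask,
    outer_mask: BinaryMask,
    dapi_mask: BinaryMask,
    variant: str = "density_normalized",
) -> float:
    """Inner/outer area ratio of one population.

    density_normalized: (pop∧inner / inner) / (pop∧outer / outer);
    literal_area: pop∧inner / pop∧outer.  A zero denominator with a
    positive numerator yields ``inf``; 0/0 yields ``nan`` (missing) with
    a warning — batch scoring never raises on degenerate colonies.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    if pop_mask.area == 0:
        raise ValueError("population mask is empty")
    for m in (inner_mask, outer_mask, dapi_mask):
        if m.shape != pop_mask.shape:
            raise ValueError("all masks must share one shape")

    a_in = int((pop_mask.grid & inner_mask.grid).sum())
    a_out = int((pop_mask.grid & outer_mask.grid).sum())
    if variant == "density_normalized":
        band_in, band_out = inner_mask.area, outer_mask.area
        if band_in == 0 or band_out == 0:
            logger.warning("empty radial band; ratio undefined")
            return math.nan
        num = a_in / band_in
        den = a_out / band_out
    else:
        num, den = float(a_in), float(a_out)

    if den == 0.0:
        if num > 0.0:
            return math.inf
        logger.warning("0/0 population ratio; reported as missing")
        return math.nan
    return num / den


def combined_segregation_score(ratio_red: float, ratio_green: float) -> float:
    """Mean of the red ratio and the inverse green ratio.

    Any non-finite input (infinity sentinel or missing) or a zero green
    ratio gives ``nan`` — a missing score, never an exception mid-batch.
    """
    if not (math.isfinite(ratio_red) and math.isfinite(ratio_green)):
        return math.nan
    if ratio_green == 0.0:
        logger.warning("green ratio is 0; combined score missing")
        return math.nan
    return 0.5 * (ratio_red + 1.0 / ratio_green)


@dataclass(frozen=True)
class ScoreConfig:
    """Full per-colony scoring recipe: masking + band geometry."""

    threshold_method: str = "otsu"
    fixed_value: float | None = None
    min_object_px: int = 64
    min_hole_px: int = 64
    radial: RadialConfig = RadialConfig()


def score_colony(image: ColonyImage, config: ScoreConfig = ScoreConfig()) -> RadialScore:
    """Score one colony image end to end.

    Pipeline: split channels → mask each channel → colony geometry from
    the nuclear mask → band masks → per-population ratios → combined
    score.  Stage failures carry the stage name.
    """
    planes = split_channels(image)
    masks: dict[str, BinaryMask] = {}
    for role in ("red", "green", "blue"):
        try:
            masks[role] = make_mask(
                planes[role],
                method=config.threshold_method,
                fixed_value=config.fixed_value,
                min_object_px=config.min_object_px,
                min_hole_px=config.min_hole_px,
                source_channel=role,
            )
        except ValueError as exc:
            raise ValueError(f"masking stage failed for {role!r} channel: {exc}") from exc

    geometry = colony_geometry(masks["blue"])
    inner, outer = radial_band_masks(geometry, masks["blue"], config.radial)
    flags: list[str] = []
    ratios = {}
    for role in ("red", "green"):
        try:
            ratios[role] = population_radial_ratio(
                masks[role], inner, outer, masks["blue"], config.radial.variant
            )
        except ValueError as exc:
            raise ValueError(f"ratio stage failed for {role!r} channel: {exc}") from exc
        if not math.isfinite(ratios[role]):
            flags.append(f"ratio_{role}_nonfinite")

    combined = combined_segregation_score(ratios["red"], ratios["green"])
    if math.isnan(combined):
        flags.append("combined_missing")

    areas = {
        "dapi": masks["blue"].area,
        "inner_band": inner.area,
        "outer_band": outer.area,
    }
    for role in ("red", "green"):
        areas[f"{role}_total"] = masks[role].area
        areas[f"{role}_inner"] = int((masks[role].grid & inner.grid).sum())
        areas[f"{role}_outer"] = int((masks[role].grid & outer.grid).sum())

    return RadialScore(
        variant=config.radial.variant,
        ratio_red=ratios["red"],
        ratio_green=ratios["green"],
        combined=combined,
        areas=areas,
        flags=flags,
    )


class RadialSegregation:
    """Model-style wrapper: ``RadialSegregation(image).fit()``.

    ``fit`` computes the score under both ratio variants and returns a
    results object with the areas and a text summary.
    """

    def __init__(self, image: ColonyImage, config: ScoreConfig = ScoreConfig()):
        self.image = image
        self.config = config

    def fit(self) -> "RadialSegregationResults":
        scores = {}
        for variant in VARIANTS:
            cfg = ScoreConfig(
                threshold_method=self.config.threshold_method,
                fixed_value=self.config.fixed_value,
                min_object_px=self.config.min_object_px,
                min_hole_px=self.config.min_hole_px,
                radial=RadialConfig(
                    inner_frac=self.config.radial.inner_frac,
                    outer_frac=self.config.radial.outer_frac,
                    variant=variant,
                ),
            )
            scores[variant] = score_colony(self.image, cfg)
        return RadialSegregationResults(
            scores=scores, primary_variant=self.config.radial.variant, model=self
        )


@dataclass
class RadialSegregationResults:
    scores: dict[str, RadialScore]
    primary_variant: str
    model: RadialSegregation = field(repr=False, default=None)

    @property
    def combined(self) -> float:
        return self.scores[self.primary_variant].combined

    def summary(self) -> str:
        lines = ["Radial segregation score", "-" * 26]
        for variant, s in self.scores.items():
            mark = " (primary)" if variant == self.primary_variant else ""
            lines.append(f"{variant}{mark}:")
            lines.append(f"  ratio_red   : {s.ratio_red:.4g}")
            lines.append(f"  ratio_green : {s.ratio_green:.4g}")
            lines.append(f"  combined    : {s.combined:.4g}")
        a = self.scores[self.primary_variant].areas
        lines.append(
            f"areas (px): dapi={a['dapi']} inner_band={a['inner_band']} "
            f"outer_band={a['outer_band']}"
        )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# batch summaries


@dataclass
class GroupSummary:
    group_stats: pd.DataFrame
    test: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None
    n_excluded: dict


def summarize_scores(scores_by_group: dict[str, list[float]]) -> GroupSummary:
    """Group means/SDs plus the appropriate two-or-more-group test.

    Non-finite scores are excluded (counted per group); groups left with
    fewer than two finite scores are dropped with a warning.  Two groups
    → two-tailed unpaired t-test; three or more → one-way ANOVA followed
    by Tukey HSD pairwise comparisons.
    """
    from .expression import one_way_anova, tukey_hsd  # local import: no cycle

    finite: dict[str, np.ndarray] = {}
    n_excluded: dict[str, int] = {}
    for group, values in scores_by_group.items():
        arr = np.asarray(list(values), dtype=float)
        keep = np.isfinite(arr)
        n_excluded[group] = int((~keep).sum())
        arr = arr[keep]
        if arr.size < 2:
            logger.warning("group %r has <2 finite scores; excluded", group)
            continue
        finite[group] = arr
    if len(finite) < 2:
        raise ValueError("need at least two groups with >=2 finite scores")

    stats_rows = [
        {"group": g, "n": int(v.size), "mean": float(v.mean()),
         "sd": float(v.std(ddof=1))}
        for g, v in finite.items()
    ]
    group_stats = pd.DataFrame(stats_rows)

    names = list(finite)
    if len(finite) == 2:
        t, p = stats.ttest_ind(finite[names[0]], finite[names[1]], equal_var=True)
        return GroupSummary(group_stats, "t-test", float(t), float(p),
                            None, n_excluded)
    res = one_way_anova(list(finite.values()))
    pairwise = tukey_hsd(list(finite.values()), labels=names)
    return GroupSummary(group_stats, "anova", res.F, res.p_value,
                        pairwise, n_excluded)
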
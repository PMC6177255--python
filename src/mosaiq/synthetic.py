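"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the study's raw observations:

* mosaic colony images — ~100-cell two-population colonies at a 1:3
  CRISPRi:WT ratio, painted as end-state label patterns (well mixed,
  radially biased toward edge or center, or sorted into discrete
  islands);
* AFM force-indentation curves following the Hertz spherical-indenter
  law with a pre-contact baseline and additive force noise;
* qPCR Ct tables with additive per-(gene, group, day) effects around a
  housekeeping-normalised baseline.

Every generator draws all randomness from a single seeded
``numpy.random.Generator`` per call: identical spec + seed gives
bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.draw import disk as _draw_disk

from .hertz import ForceCurve, hertz_force
from .imaging import ColonyImage

MODES = ("mixed", "radial_edge", "radial_center", "islands")


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid {fieldname}: {msg}")


# ---------------------------------------------------------------------------
# colony images


@dataclass(frozen=True)
class ColonySpec:
    """Parameters of one synthetic mosaic colony.

    ``mode`` controls label placement; ``strength`` (s in [0, 1])
    interpolates between uniform mixing (0) and the full radial bias (1)
    for the two radial modes.  Defaults reflect the study conditions:
    ~100-cell aggregates with a quarter of cells in the CRISPRi (red)
    population.
    """

    image_size: int = 512
    colony_radius: float = 200.0
    n_cells: int = 100
    fraction_red: float = 0.25
    mode: str = "mixed"
    strength: float = 0.0
    n_islands: int = 3
    cell_radius: float = 20.0
    intensity: float = 1000.0
    noise_sd: float = 0.0
    background: float = 0.0
    seed: int = 0
    um_per_pixel: float | None = None

    def validate(self) -> None:
        _require(self.n_cells >= 1, "n_cells", "must be >= 1")
        _require(0.0 <= self.fraction_red <= 1.0, "fraction_red", "must be in [0, 1]")
        _require(0.0 <= self.strength <= 1.0, "strength", "must be in [0, 1]")
        _require(self.colony_radius < self.image_size / 2,
                 "colony_radius", "must be < image_size/2")
        _require(self.colony_radius > 0, "colony_radius", "must be > 0")
        _require(self.mode in MODES, "mode", f"must be one of {MODES}")
        _require(self.n_islands >= 1, "n_islands", "must be >= 1")
        _require(self.cell_radius > 0, "cell_radius", "must be > 0")
        _require(self.intensity > 0, "intensity", "must be > 0")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(self.background >= 0, "background", "must be >= 0")


@dataclass
class ColonyGroundTruth:
    """Planted cell centers and labels for one synthetic colony."""

    cell_centers: np.ndarray  # (n, 2) float, (row, col)
    labels: np.ndarray        # (n,) str, 'red' | 'green'
    mode: str
    strength: float

    def __post_init__(self) -> None:
        self.cell_centers = np.asarray(self.cell_centers, dtype=float)
        self.labels = np.asarray(self.labels)
        if len(self.labels) != len(self.cell_centers):
            raise ValueError("labels and cell_centers must align")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "row": self.cell_centers[:, 0],
            "col": self.cell_centers[:, 1],
            "label": self.labels,
        })


def _sample_in_disk(rng: np.random.Generator, n: int, center: float,
                    radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Uniform points in a disk; returns (centers (n,2), radial distances)."""
    rho = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    rows = center + rho * np.sin(theta)
    cols = center + rho * np.cos(theta)
    return np.column_stack([rows, cols]), rho


def render_disks(centers: np.ndarray, cell_radius: float,
                 shape: tuple[int, int]) -> np.ndarray:
    """Boolean union of hard disks of ``cell_radius`` at ``centers``."""
    mask = np.zeros(shape, dtype=bool)
    for row, col in np.asarray(centers, dtype=float):
        rr, cc = _draw_disk((row, col), cell_radius, shape=shape)
        mask[rr, cc] = True
    return mask


def generate_colony_image(spec: ColonySpec) -> tuple[ColonyImage, ColonyGroundTruth]:
    """Render one synthetic mosaic colony plus its ground truth.

    Cell centers are sampled uniformly in the colony disk; labels follow
    ``spec.mode``; each cell is painted as a hard disk of
    ``spec.cell_radius`` into its population channel (red or green) and
    into the blue (nuclear) channel, at ``spec.intensity`` over
    ``spec.background``, then i.i.d. Gaussian noise of ``spec.noise_sd``
    is added and the image clipped at zero.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    center = (spec.image_size - 1) / 2.0
    centers, rho = _sample_in_disk(rng, spec.n_cells, center, spec.colony_radius)

    n = spec.n_cells
    n_red = int(round(spec.fraction_red * n))
    labels = np.full(n, "green", dtype=object)
    if n_red > 0:
        s = spec.strength
        rel = rho / spec.colony_radius
        if spec.mode == "mixed":
            red_idx = rng.permutation(n)[:n_red]
        elif spec.mode == "radial_edge":
            w = (1.0 - s) + s * rel
            red_idx = rng.choice(n, size=n_red, replace=False, p=w / w.sum())
        elif spec.mode == "radial_center":
            w = (1.0 - s) + s * (1.0 - rel)
            red_idx = rng.choice(n, size=n_red, replace=False, p=w / w.sum())
        else:  # islands
            seeds, _ = _sample_in_disk(rng, spec.n_islands, center,
                                       spec.colony_radius)
            d2 = ((centers[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
            nearest = d2.min(axis=1)
            red_idx = np.argsort(nearest, kind="stable")[:n_red]
        labels[red_idx] = "red"
    labels = labels.astype(str)

    shape = (spec.image_size, spec.image_size)
    channels = np.full((3, *shape), float(spec.background))
    is_red = labels == "red"
    red_mask = render_disks(centers[is_red], spec.cell_radius, shape)
    green_mask = render_disks(centers[~is_red], spec.cell_radius, shape)
    level = spec.background + spec.intensity
    channels[0][red_mask] = level
    channels[1][green_mask] = level
    channels[2][red_mask | green_mask] = level
    if spec.noise_sd > 0:
        channels = channels + rng.normal(0.0, spec.noise_sd, size=channels.shape)
        channels = np.clip(channels, 0.0, None)

    image = ColonyImage(channels=channels, um_per_pixel=spec.um_per_pixel)
    truth = ColonyGroundTruth(cell_centers=centers, labels=labels,
                              mode=spec.mode, strength=spec.strength)
    return image, truth


def write_colony_ground_truth(path: str | Path, spec: ColonySpec,
                              truth: ColonyGroundTruth) -> None:
    """Ground truth as CSV (row, col, label) plus a JSON sidecar of the spec."""
    path = Path(path)
    truth.to_dataframe().to_csv(path, index=False)
    path.with_suffix(".json").write_text(
        json.dumps(dataclasses.asdict(spec), indent=2)
    )


# ---------------------------------------------------------------------------
# AFM force curves


@dataclass(frozen=True)
class ForceCurveSpec:
    """Parameters of one synthetic Hertz-behaved force curve.

    Defaults mirror the instrument settings of the study: 5 µm-diameter
    spherical tip (R = 2.5 µm), incompressible sample (ν = 0.5), spring
    constant 0.05 N/m, 4 nN maximum force.
    """

    E_true: float = 1000.0          # Pa
    tip_radius: float = 2.5         # um
    poisson: float = 0.5
    contact_point: float = 1.0      # um along the sample axis
    spring_constant: float = 0.05   # N/m
    max_force: float = 4.0          # nN
    n_points: int = 200
    noise_sd: float = 0.0           # nN
    seed: int = 0

    def validate(self) -> None:
        _require(self.E_true > 0, "E_true", "must be > 0")
        _require(self.tip_radius > 0, "tip_radius", "must be > 0")
        _require(0 <= self.poisson < 1, "poisson", "must be in [0, 1)")
        _require(self.contact_point >= 0, "contact_point", "must be >= 0")
        _require(self.spring_constant > 0, "spring_constant", "must be > 0")
        _require(self.max_force > 0, "max_force", "must be > 0")
        _require(self.n_points >= 10, "n_points", "must be >= 10")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")


def generate_force_curve(spec: ForceCurveSpec) -> ForceCurve:
    """Simulate an approach curve: baseline, contact point, Hertz rise.

    The sample axis runs from 0 through ``spec.contact_point`` (baseline,
    F = 0 + noise) and on to the depth where the noise-free force reaches
    ``spec.max_force`` (truncation).  The contact point falls exactly on
    the sample grid.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    # indentation depth at which F(noise-free) hits max_force
    f_unit = hertz_force(1.0, spec.E_true, spec.tip_radius, spec.poisson)
    delta_max = (spec.max_force / f_unit) ** (2.0 / 3.0)
    n_pre = max(spec.n_points // 3, 2) if spec.contact_point > 0 else 0
    n_post = spec.n_points - n_pre
    pre = np.linspace(0.0, spec.contact_point, n_pre, endpoint=False)
    post = spec.contact_point + np.linspace(0.0, delta_max, n_post)
    x = np.concatenate([pre, post])
    indent = np.clip(x - spec.contact_point, 0.0, None)
    force = hertz_force(indent, spec.E_true, spec.tip_radius, spec.poisson)
    if spec.noise_sd > 0:
        force = force + rng.normal(0.0, spec.noise_sd, size=force.shape)
    return ForceCurve(delta=x, force=force, tip_radius=spec.tip_radius,
                      poisson=spec.poisson)


def force_curve_to_raw(curve: ForceCurve, k: float) -> pd.DataFrame:
    """Export a curve in the raw (z, deflection) dialect: δ = z − d, F = k·d."""
    if k <= 0:
        raise ValueError("invalid spring_constant: must be > 0")
    d = curve.force / (k * 1000.0)  # nN / (N/m) -> um
    z = curve.delta + d
    return pd.DataFrame({"z_um": z, "deflection_um": d})


# ---------------------------------------------------------------------------
# qPCR Ct tables


@dataclass(frozen=True)
class CtDesign:
    """Design of a synthetic qPCR experiment.

    ``effect`` maps (gene, group) or (gene, group, day) to an additive
    ΔCt shift (negative = up-regulation).  The housekeeping gene carries
    no group effects by default — simply leave it out of ``effect``.
    Defaults follow the study's four-arm design with three biological
    replicates per condition.
    """

    genes: tuple[str, ...] = ("18S", "geneX", "geneY")
    groups: tuple[str, ...] = ("pure_uninduced", "mixed_uninduced",
                               "pure_kd", "mixed_kd")
    days: tuple[int, ...] = (1,)
    baseline_ct: Mapping[str, float] | float = 25.0
    effect: Mapping[tuple, float] = field(default_factory=dict)
    replicate_sd: float = 0.3
    n_replicates: int = 3
    housekeeping_gene: str = "18S"
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_replicates >= 1, "n_replicates", "must be >= 1")
        _require(self.replicate_sd >= 0, "replicate_sd", "must be >= 0")
        _require(len(self.genes) >= 1, "genes", "must be non-empty")
        _require(len(self.groups) >= 1, "groups", "must be non-empty")
        _require(len(self.days) >= 1, "days", "must be non-empty")
        _require(self.housekeeping_gene in self.genes, "housekeeping_gene",
                 f"{self.housekeeping_gene!r} not in genes")

    def all_genes(self) -> tuple[str, ...]:
        return tuple(self.genes)

    def baseline_for(self, gene: str) -> float:
        if isinstance(self.baseline_ct, Mapping):
            if gene not in self.baseline_ct:
                raise ValueError(f"invalid baseline_ct: no entry for {gene!r}")
            return float(self.baseline_ct[gene])
        if gene == self.housekeeping_gene:
            return 10.0  # abundant housekeeping transcript
        return float(self.baseline_ct)

    def effect_for(self, gene: str, group: str, day) -> float:
        eff = self.effect
        return float(eff.get((gene, group, day), eff.get((gene, group), 0.0)))


def generate_ct_table(design: CtDesign) -> pd.DataFrame:
    """Simulate a replicate-level Ct table.

    One row per (group, day, biological replicate, gene):
    ``Ct = baseline + effect + Normal(0, replicate_sd)``.  Columns:
    sample_id, group, day, gene, replicate, ct.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    rows = []
    for day in design.days:
        for group in design.groups:
            for rep in range(1, design.n_replicates + 1):
                sample_id = f"{group}_d{day}_b{rep}"
                for gene in design.all_genes():
                    ct = design.baseline_for(gene)
                    ct += design.effect_for(gene, group, day)
                    if design.replicate_sd > 0:
                        ct += rng.normal(0.0, design.replicate_sd)
                    rows.append({"sample_id": sample_id, "group": group,
                                 "day": day, "gene": gene,
                                 "replicate": rep, "ct": ct})
    return pd.DataFrame(rows)
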
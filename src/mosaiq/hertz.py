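"""Hertz contact-mechanics fitting of AFM force-indentation curves.

A spherical tip of radius :math:`R` indenting an incompressible elastic
half-space by a depth :math:`\\delta` experiences the Hertz force

.. math::

    F = \\tfrac{4}{3} \\frac{E}{1 - \\nu^2} \\sqrt{R}\\, \\delta^{3/2},

where :math:`E` is the Young's modulus and :math:`\\nu` the Poisson
ratio (0.5 for an incompressible sample).  The measured curve carries an
unknown contact point :math:`\\delta_0` along the sample axis: before
contact the force is baseline (zero), after contact it follows the Hertz
law in :math:`\\delta - \\delta_0`.  ``HertzModel.fit`` estimates
:math:`(E, \\delta_0)` jointly by grid search over the sampled positions
with a least-squares amplitude fit at each candidate.

Units at the interface: positions/indentations in µm, forces in nN,
moduli in Pa, spring constants in N/m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

# F[nN] = _FORCE_SCALE * (4/3) * E[Pa]/(1-nu^2) * sqrt(R[um]) * delta[um]^1.5
# sqrt(1e-6 m/um) * (1e-6 m/um)^1.5 * 1e9 nN/N = 1e-3
_FORCE_SCALE = 1e-3

DEFAULT_TIP_RADIUS_UM = 2.5   # 5 µm diameter borosilicate sphere
DEFAULT_POISSON = 0.5         # incompressible sample


def hertz_force(
    delta: np.ndarray | float,
    E: float,
    tip_radius: float = DEFAULT_TIP_RADIUS_UM,
    poisson: float = DEFAULT_POISSON,
) -> np.ndarray | float:
    """Forward Hertz model: force (nN) at indentation depth ``delta`` (µm).

    Parameters
    ----------
    delta : array_like
        Indentation depth in µm, all values >= 0.
    E : float
        Young's modulus in Pa.
    tip_radius : float
        Spherical tip radius in µm.
    poisson : float
        Poisson ratio in [0, 1).
    """
    delta_arr = np.asarray(delta, dtype=float)
    if np.any(delta_arr < 0):
        raise ValueError("indentation depth must be >= 0")
    if tip_radius <= 0:
        raise ValueError("tip_radius must be > 0")
    if not 0 <= poisson < 1:
        raise ValueError("poisson must lie in [0, 1)")
    out = (
        _FORCE_SCALE
        * (4.0 / 3.0)
        * (E / (1.0 - poisson**2))
        * np.sqrt(tip_radius)
        * delta_arr**1.5
    )
    return out if isinstance(delta, np.ndarray) else float(out)


def deflection_to_force_indentation(
    z: Sequence[float], d: Sequence[float], k: float
) -> tuple[np.ndarray, np.ndarray]:
    """Convert raw (piezo position, cantilever deflection) to (δ, F).

    ``F = k·d`` (N/m × µm → nN requires a factor 1000) and
    ``δ = z − d``.  The pre-contact baseline is left in place; the fitter
    estimates the contact point itself.

    Parameters
    ----------
    z, d : array_like, µm
        Piezo position and cantilever deflection, equal length.
    k : float
        Cantilever spring constant in N/m.
    """
    z = np.asarray(z, dtype=float)
    d = np.asarray(d, dtype=float)
    if z.shape != d.shape:
        raise ValueError("z and d must have equal length")
    if k <= 0:
        raise ValueError("spring constant k must be > 0")
    force_nN = k * d * 1000.0  # N/m * um = 1e-6 N/m*m = ... -> nN
    delta = z - d
    return delta, force_nN


@dataclass
class ForceCurve:
    """One AFM approach segment.

    ``delta`` is the sample-axis position in µm *including* the
    pre-contact baseline region — the true zero of indentation (the
    contact point) is unknown and estimated by the fitter.  ``force`` is
    in nN.
    """

    delta: np.ndarray
    force: np.ndarray
    tip_radius: float = DEFAULT_TIP_RADIUS_UM
    poisson: float = DEFAULT_POISSON

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.delta.shape != self.force.shape or self.delta.ndim != 1:
            raise ValueError("delta and force must be equal-length 1-D arrays")
        if self.delta.size < 10:
            raise ValueError("force curve needs at least 10 samples")
        if self.tip_radius <= 0:
            raise ValueError("tip_radius must be > 0")
        if not 0 <= self.poisson < 1:
            raise ValueError("poisson must lie in [0, 1)")
        order = np.argsort(self.delta, kind="stable")
        self.delta = self.delta[order]
        self.force = self.force[order]

    @classmethod
    def from_raw(
        cls,
        z: Sequence[float],
        d: Sequence[float],
        k: float,
        tip_radius: float = DEFAULT_TIP_RADIUS_UM,
        poisson: float = DEFAULT_POISSON,
    ) -> "ForceCurve":
        """Build a curve from raw (z, deflection) arrays and spring constant."""
        delta, force = deflection_to_force_indentation(z, d, k)
        return cls(delta=delta, force=force, tip_radius=tip_radius, poisson=poisson)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"delta_um": self.delta, "force_nN": self.force})


@dataclass
class HertzResults:
    """Estimates from a single-curve Hertz fit.

    Attributes
    ----------
    E : float
        Young's modulus in Pa (NaN when not converged).
    contact_point : float
        Estimated contact position on the sample axis, µm.
    rss : float
        Residual sum of squares of the selected fit, nN².
    n_points_used : int
        Post-contact samples entering the amplitude fit.
    converged : bool
    """

    E: float
    contact_point: float
    rss: float
    n_points_used: int
    converged: bool
    model: "HertzModel" = field(repr=False, default=None)

    def predict(self, delta: np.ndarray) -> np.ndarray:
        """Fitted force (nN) at sample-axis positions ``delta`` (µm)."""
        if not self.converged:
            raise ValueError("fit did not converge; nothing to predict")
        ind = np.clip(np.asarray(delta, dtype=float) - self.contact_point, 0, None)
        return hertz_force(ind, self.E, self.model.tip_radius, self.model.poisson)

    def summary(self) -> str:
        lines = [
            "Hertz spherical-indentation fit",
            "-" * 33,
            f"converged        : {self.converged}",
            f"Young's modulus E: {self.E:.6g} Pa",
            f"contact point    : {self.contact_point:.6g} um",
            f"RSS              : {self.rss:.6g} nN^2",
            f"post-contact n   : {self.n_points_used}",
            f"tip radius       : {self.model.tip_radius:g} um",
            f"Poisson ratio    : {self.model.poisson:g}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Overlay data and fitted curve; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.curve.delta, self.model.curve.force, ".", label="data")
        if self.converged:
            ax.plot(self.model.curve.delta, self.predict(self.model.curve.delta),
                    "-", label=f"Hertz fit, E={self.E:.3g} Pa")
        ax.set_xlabel("sample axis (um)")
        ax.set_ylabel("force (nN)")
        ax.legend()
        return ax


class HertzModel:
    """Joint contact-point + modulus estimator for one force curve.

    The contact point is searched over the curve's own sample grid.  At a
    candidate :math:`\\delta_0` the model is
    ``F = c * max(delta - delta0, 0)^{3/2}`` with the pre-contact baseline
    forced to zero; the amplitude ``c >= 0`` has a closed-form least-squares
    solution and the candidate minimising the total RSS wins (ties: the
    earliest contact point).  ``E`` follows from ``c`` by inverting the
    Hertz prefactor.
    """

    def __init__(
        self,
        curve: ForceCurve | None = None,
        *,
        delta: Sequence[float] | None = None,
        force: Sequence[float] | None = None,
        tip_radius: float = DEFAULT_TIP_RADIUS_UM,
        poisson: float = DEFAULT_POISSON,
    ) -> None:
        if curve is None:
            curve = ForceCurve(delta=np.asarray(delta, float),
                               force=np.asarray(force, float),
                               tip_radius=tip_radius, poisson=poisson)
        self.curve = curve
        self.tip_radius = curve.tip_radius
        self.poisson = curve.poisson

    def fit(
        self,
        min_post_contact: int = 5,
        max_indentation: float | None = None,
    ) -> HertzResults:
        """Fit the curve.

        Parameters
        ----------
        min_post_contact : int
            Minimum samples beyond the candidate contact point for a fit
            to be considered.
        max_indentation : float, optional
            If given, samples indented deeper than this (µm beyond the
            candidate contact point) are excluded from the fit; off by
            default.
        """
        x = self.curve.delta
        F = self.curve.force
        prefactor = (
            _FORCE_SCALE * (4.0 / 3.0) / (1.0 - self.poisson**2)
            * np.sqrt(self.tip_radius)
        )

        best = None  # (rss, idx, c, n_used)
        for i, d0 in enumerate(x):
            ind = np.clip(x - d0, 0.0, None)
            use = np.ones_like(x, dtype=bool)
            if max_indentation is not None:
                use = ind <= max_indentation
            g = ind[use] ** 1.5
            post = g > 0
            if int(post.sum()) < min_post_contact:
                continue
            denom = float(g @ g)
            if denom == 0.0:
                continue
            c = max(float(F[use] @ g) / denom, 0.0)
            resid = F[use] - c * g
            rss = float(resid @ resid)
            if best is None or rss < best[0] - 1e-15 * max(best[0], 1.0):
                best = (rss, i, c, int(post.sum()))

        if best is None or best[2] <= 0.0:
            return HertzResults(E=float("nan"), contact_point=float("nan"),
                                rss=float("nan") if best is None else best[0],
                                n_points_used=0 if best is None else best[3],
                                converged=False, model=self)
        rss, i, c, n_used = best
        E = c / prefactor
        return HertzResults(E=float(E), contact_point=float(x[i]), rss=rss,
                            n_points_used=n_used, converged=True, model=self)


def fit_hertz_curve(curve: ForceCurve, **kwargs) -> HertzResults:
    """Convenience wrapper: ``HertzModel(curve).fit(**kwargs)``."""
    return HertzModel(curve).fit(**kwargs)


# ---------------------------------------------------------------------------
# force maps


@dataclass
class ForceMap:
    """A raster of force curves (nominally 6×6, one point every 5 µm)."""

    curves: list[ForceCurve]
    positions: list[tuple[int, int]]
    spacing_um: float = 5.0

    def __post_init__(self) -> None:
        if not self.curves:
            raise ValueError("force map needs at least one curve")
        if len(self.curves) != len(self.positions):
            raise ValueError("curves and positions must align")
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("grid positions must be distinct")


@dataclass
class ForceMapSummary:
    """Per-area statistics over the converged fits of a force map."""

    mean_E: float
    median_E: float
    sd_E: float
    n_converged: int
    n_total: int
    table: pd.DataFrame

    def summary(self) -> str:
        return (
            f"Force map: {self.n_converged}/{self.n_total} curves converged\n"
            f"  mean E   : {self.mean_E:.6g} Pa\n"
            f"  median E : {self.median_E:.6g} Pa\n"
            f"  SD E     : {self.sd_E:.6g} Pa"
        )


def summarize_force_map(fmap: ForceMap, **fit_kwargs) -> ForceMapSummary:
    """Fit every curve in the map and summarise the converged moduli.

    Non-converged points are excluded from the statistics but retained
    (flagged) in the per-point table.
    """
    rows = []
    for (r, c), curve in zip(fmap.positions, fmap.curves):
        res = HertzModel(curve).fit(**fit_kwargs)
        rows.append({"row": r, "col": c, "E_Pa": res.E,
                     "contact_point_um": res.contact_point,
                     "rss": res.rss, "converged": res.converged})
    table = pd.DataFrame(rows)
    ok = table.loc[table["converged"], "E_Pa"].to_numpy()
    if ok.size == 0:
        raise ValueError("no curve in the force map converged")
    return ForceMapSummary(
        mean_E=float(np.mean(ok)),
        median_E=float(np.median(ok)),
        sd_E=float(np.std(ok, ddof=1)) if ok.size > 1 else 0.0,
        n_converged=int(ok.size),
        n_total=len(fmap.curves),
        table=table,
    )


# ---------------------------------------------------------------------------
# CSV dialects


def read_force_curve_csv(
    path,
    k: float | None = None,
    tip_radius: float = DEFAULT_TIP_RADIUS_UM,
    poisson: float = DEFAULT_POISSON,
) -> ForceCurve:
    """Read a force curve from CSV.

    Accepts either columns ``delta_um, force_nN`` or raw columns
    ``z_um, deflection_um`` (the latter requires the spring constant
    ``k`` in N/m).
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"delta_um", "force_nN"} <= cols:
        return ForceCurve(df["delta_um"].to_numpy(), df["force_nN"].to_numpy(),
                          tip_radius=tip_radius, poisson=poisson)
    if {"z_um", "deflection_um"} <= cols:
        if k is None:
            raise ValueError("raw (z, deflection) input requires spring constant k")
        return ForceCurve.from_raw(df["z_um"].to_numpy(),
                                   df["deflection_um"].to_numpy(), k,
                                   tip_radius=tip_radius, poisson=poisson)
    raise ValueError(
        f"{path}: expected columns (delta_um, force_nN) or (z_um, deflection_um)"
    )


def write_force_curve_csv(path, curve: ForceCurve) -> None:
    curve.to_frame().to_csv(path, index=False)
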
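"""Comparative-CT fold changes and the four-arm significance analysis.

Relative quantification follows the comparative threshold-cycle method
with PCR efficiency 2: after averaging technical replicates,

    ΔCt  = Ct_gene − Ct_housekeeping        (per sample)
    ΔΔCt = ΔCt_sample − ΔCt_reference
    fold change = 2^(−ΔΔCt).

The mixed-colony experiment adds a double normalization: each sample's
fold change is divided by its time-matched *pure un-induced* control and
the result by the time-matched *mixed un-induced* control, so that
effects of merely mixing two cell lines cancel before knockdown effects
are assessed.

Significance per gene and day uses a one-way ANOVA across the four arms
(pure/mixed × un-induced/induced) followed by Tukey HSD pairwise
comparisons, from which three named contrasts are read off:

* ``mixing_effect``      — mixed un-induced vs pure un-induced
* ``kd_effect``          — pure knockdown vs pure un-induced
* ``kd_in_mixed_effect`` — mixed knockdown vs mixed un-induced

Entries with adjusted p ≥ α are masked (the "grey" cells of a rendered
heat map).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: the three contrasts of the four-arm design, as (group, reference group)
CONTRASTS: dict[str, tuple[str, str]] = {
    "mixing_effect": ("mixed_uninduced", "pure_uninduced"),
    "kd_effect": ("pure_kd", "pure_uninduced"),
    "kd_in_mixed_effect": ("mixed_kd", "mixed_uninduced"),
}

REQUIRED_CT_COLUMNS = ("sample_id", "group", "day", "gene", "ct")


def _check_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if not np.isfinite(table["ct"]).all():
        raise ValueError("Ct values must be finite")
    return table


def delta_ct(table: pd.DataFrame, housekeeping: str = "18S") -> pd.DataFrame:
    """Per-(sample, gene) ΔCt relative to the housekeeping gene.

    Technical replicates (rows sharing sample_id and gene) are averaged
    first.  Samples without a housekeeping measurement are excluded with
    a warning.  Returns columns sample_id, group, day, gene, delta_ct.
    """
    table = _check_ct_table(table)
    if housekeeping not in set(table["gene"]):
        raise ValueError(f"housekeeping gene {housekeeping!r} absent from table")
    means = (
        table.groupby(["sample_id", "group", "day", "gene"], sort=False)["ct"]
        .mean()
        .reset_index()
    )
    hk = means[means["gene"] == housekeeping].set_index("sample_id")["ct"]
    out = means[means["gene"] != housekeeping].copy()
    missing_hk = ~out["sample_id"].isin(hk.index)
    if missing_hk.any():
        dropped = sorted(out.loc[missing_hk, "sample_id"].unique())
        logger.warning("excluding %d sample(s) without housekeeping Ct: %s",
                       len(dropped), dropped)
        out = out[~missing_hk]
    out["delta_ct"] = out["ct"].to_numpy() - hk.loc[out["sample_id"]].to_numpy()
    return out.drop(columns="ct").reset_index(drop=True)


def fold_change(delta_ct_sample: float, delta_ct_reference: float) -> float:
    """2^(−ΔΔCt) relative quantity (PCR efficiency 2)."""
    if not (np.isfinite(delta_ct_sample) and np.isfinite(delta_ct_reference)):
        raise ValueError("both delta-Ct values must be finite")
    return float(2.0 ** (-(delta_ct_sample - delta_ct_reference)))


def fold_change_table(
    dct: pd.DataFrame, reference_group: str = "pure_uninduced"
) -> pd.DataFrame:
    """Per-sample fold changes versus a reference group's mean ΔCt.

    The reference ΔCt is the mean over the reference group's samples,
    matched on gene and day.  Rows whose (gene, day) lacks the reference
    group are emitted as missing with a warning.
    """
    if reference_group not in set(dct["group"]):
        raise ValueError(f"reference group {reference_group!r} absent")
    ref = (
        dct[dct["group"] == reference_group]
        .groupby(["gene", "day"])["delta_ct"]
        .mean()
    )
    out = dct.copy()
    keys = pd.MultiIndex.from_frame(out[["gene", "day"]])
    has_ref = keys.isin(ref.index)
    if (~has_ref).any():
        logger.warning("no reference for %d row(s); fold change missing",
                       int((~has_ref).sum()))
    ref_vals = np.full(len(out), np.nan)
    ref_vals[has_ref] = ref.loc[keys[has_ref]].to_numpy()
    out["fold_change"] = 2.0 ** (-(out["delta_ct"] - ref_vals))
    out["normalization_stage"] = "vs_reference"
    return out


def double_normalize(
    fc: pd.DataFrame,
    pure_control: str = "pure_uninduced",
    mixed_control: str = "mixed_uninduced",
) -> pd.DataFrame:
    """Two-stage control normalization of a per-sample fold-change table.

    Stage 1 divides every sample's fold change by the day-matched mean of
    the pure un-induced control; stage 2 divides the stage-1 values by
    the day-matched mean of the (stage-1-normalized) mixed un-induced
    control.  Returns a long table with ``normalization_stage`` in
    {vs_reference, vs_pure_uninduced, vs_mixed_uninduced}; gene/days
    missing a control are emitted with missing values and a warning.
    """
    if (fc["fold_change"].dropna() <= 0).any():
        raise ValueError("fold changes must be > 0")
    stages = [fc.assign(normalization_stage="vs_reference")]
    current = fc.copy()
    for stage_name, control in (
        ("vs_pure_uninduced", pure_control),
        ("vs_mixed_uninduced", mixed_control),
    ):
        ctrl = (
            current[current["group"] == control]
            .groupby(["gene", "day"])["fold_change"]
            .mean()
        )
        keys = pd.MultiIndex.from_frame(current[["gene", "day"]])
        has = keys.isin(ctrl.index)
        if (~has).any():
            logger.warning("stage %s: control %r missing for %d row(s)",
                           stage_name, control, int((~has).sum()))
        vals = np.full(len(current), np.nan)
        vals[has] = ctrl.loc[keys[has]].to_numpy()
        current = current.assign(
            fold_change=current["fold_change"].to_numpy() / vals,
            normalization_stage=stage_name,
        )
        stages.append(current)
    return pd.concat(stages, ignore_index=True)


# ---------------------------------------------------------------------------
# group tests


@dataclass
class AnovaResult:
    F: float
    p_value: float
    df_between: int
    df_within: int


def one_way_anova(groups: Sequence[np.ndarray]) -> AnovaResult:
    """Standard one-way fixed-effects ANOVA.

    F = (SSB/df_b) / (SSW/df_w) with p from the F distribution.  At
    least two groups with two finite values each are required; for a
    single pair of observations use a t-test instead.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 groups; for 2 groups a t-test is equivalent")
    for g in groups:
        if g.size < 2 or not np.isfinite(g).all():
            raise ValueError("each group needs >= 2 finite values")
    F, p = stats.f_oneway(*groups)
    k = len(groups)
    n = sum(g.size for g in groups)
    if not np.isfinite(F):  # zero within-group variance, distinct means
        logger.warning("degenerate ANOVA: zero within-group variance")
        return AnovaResult(float("inf"), 0.0, k - 1, n - k)
    return AnovaResult(float(F), float(p), k - 1, n - k)


def tukey_hsd(
    groups: Sequence[np.ndarray],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise contrasts with studentized-range adjusted p-values.

    Returns a frame with group_a, group_b, mean_diff (a − b), p_adj and
    a significance flag at ``alpha``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("Tukey HSD needs >= 2 groups")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.tukey_hsd(*groups)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            p = float(res.pvalue[i, j])
            rows.append({
                "group_a": labels[i],
                "group_b": labels[j],
                "mean_diff": float(groups[i].mean() - groups[j].mean()),
                "p_adj": p,
                "significant": bool(p < alpha),
            })
    return pd.DataFrame(rows)


def significance_table(
    dct: pd.DataFrame,
    contrasts: Mapping[str, tuple[str, str]] = CONTRASTS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene/day contrast table with non-significant entries masked.

    For each (gene, day) with all four design arms present, a one-way
    ANOVA across the arms is followed by Tukey HSD; the named contrasts
    are extracted with their adjusted p-values.  The response is
    −ΔCt per sample (log2 expression relative to housekeeping), so the
    effect estimate is a log2 fold difference.  Gene/days with an
    incomplete design are skipped with a logged reason.
    """
    needed = {g for pair in contrasts.values() for g in pair}
    rows = []
    for (gene, day), sub in dct.groupby(["gene", "day"]):
        by_group = {g: -v["delta_ct"].to_numpy()
                    for g, v in sub.groupby("group")}
        missing = sorted(needed - set(by_group))
        if missing or any(v.size < 2 for v in by_group.values()):
            logger.warning("skipping gene=%s day=%s: incomplete design (%s)",
                           gene, day, missing or "replicates < 2")
            continue
        labels = sorted(by_group)
        one_way_anova([by_group[g] for g in labels])  # validity gate
        pair_p = tukey_hsd([by_group[g] for g in labels], labels=labels,
                           alpha=alpha)
        lookup = {
            frozenset((r.group_a, r.group_b)): r
            for r in pair_p.itertuples()
        }
        for name, (a, b) in contrasts.items():
            r = lookup[frozenset((a, b))]
            p = r.p_adj
            effect = float(by_group[a].mean() - by_group[b].mean())
            rows.append({
                "gene": gene, "day": day, "contrast": name,
                "effect_log2": effect, "p_value": p,
                "significant": bool(p < alpha),
                "masked": bool(p >= alpha),
            })
    return pd.DataFrame(
        rows, columns=["gene", "day", "contrast", "effect_log2",
                       "p_value", "significant", "masked"]
    )


# ---------------------------------------------------------------------------
# model-style wrapper


class ComparativeCt:
    """Comparative-CT analysis of a replicate-level Ct table.

    Parameters
    ----------
    table : DataFrame
        Columns sample_id, group, day, gene, (replicate,) ct.
    housekeeping : str
        Housekeeping gene for ΔCt (18S rRNA in the study design).
    reference_group, pure_control, mixed_control : str
        Group names used for the reference fold change and the two
        normalization stages.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        housekeeping: str = "18S",
        reference_group: str = "pure_uninduced",
        pure_control: str = "pure_uninduced",
        mixed_control: str = "mixed_uninduced",
        contrasts: Mapping[str, tuple[str, str]] = CONTRASTS,
        alpha: float = 0.05,
    ) -> None:
        self.table = _check_ct_table(table)
        self.housekeeping = housekeeping
        self.reference_group = reference_group
        self.pure_control = pure_control
        self.mixed_control = mixed_control
        self.contrasts = dict(contrasts)
        self.alpha = alpha

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kwargs) -> "ComparativeCt":
        return cls(table, **kwargs)

    def fit(self) -> "ComparativeCtResults":
        dct = delta_ct(self.table, self.housekeeping)
        fc = fold_change_table(dct, self.reference_group)
        normalized = double_normalize(fc, self.pure_control, self.mixed_control)
        sig = significance_table(dct, self.contrasts, self.alpha)
        return ComparativeCtResults(
            delta_ct=dct, fold_changes=fc, normalized=normalized,
            significance=sig, model=self,
        )


@dataclass
class ComparativeCtResults:
    """Tables produced by :meth:`ComparativeCt.fit`."""

    delta_ct: pd.DataFrame
    fold_changes: pd.DataFrame
    normalized: pd.DataFrame
    significance: pd.DataFrame
    model: ComparativeCt = field(repr=False, default=None)

    def final_fold_changes(self) -> pd.DataFrame:
        """Per-sample fold changes after both normalization stages."""
        out = self.normalized
        return out[out["normalization_stage"] == "vs_mixed_uninduced"].copy()

    def summary(self) -> str:
        n_sig = int(self.significance["significant"].sum())
        n_all = len(self.significance)
        lines = [
            "Comparative-CT analysis",
            "-" * 24,
            f"samples        : {self.delta_ct['sample_id'].nunique()}",
            f"genes          : {self.delta_ct['gene'].nunique()}",
            f"housekeeping   : {self.model.housekeeping}",
            f"reference group: {self.model.reference_group}",
            f"contrasts      : {n_sig}/{n_all} significant at "
            f"alpha={self.model.alpha}",
        ]
        if n_all:
            flagged = self.significance[self.significance["significant"]]
            for r in flagged.itertuples():
                lines.append(
                    f"  {r.gene} d{r.day} {r.contrast}: "
                    f"log2FC={r.effect_log2:+.2f} p={r.p_value:.3g}"
                )
        return "\n".join(lines)

    def plot_heatmap(self, contrast: str, ax=None):
        """Genes × days heat map of log2 effects, masked cells hatched grey."""
        import matplotlib.pyplot as plt

        sig = self.significance[self.significance["contrast"] == contrast]
        pivot = sig.pivot(index="gene", columns="day", values="effect_log2")
        masked = sig.pivot(index="gene", columns="day", values="masked")
        data = pivot.to_numpy(dtype=float)
        data = np.where(masked.to_numpy(dtype=bool), np.nan, data)
        if ax is None:
            _, ax = plt.subplots()
        cmap = plt.get_cmap("RdBu_r").copy()
        cmap.set_bad("lightgrey")
        im = ax.imshow(data, cmap=cmap, aspect="auto")
        ax.set_xticks(range(len(pivot.columns)), [f"d{d}" for d in pivot.columns])
        ax.set_yticks(range(len(pivot.index)), pivot.index)
        ax.set_title(contrast)
        plt.colorbar(im, ax=ax, label="log2 fold change")
        return ax
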
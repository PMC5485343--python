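"""Longitudinal statistics for two-arm wound-healing studies.

The headline analysis is a mixed-design (split-plot) repeated-measures ANOVA
on wound areas: treatment arm is the between-subject factor, measurement time
the within-subject factor, and the time x treatment interaction tests whether
the healing time course differs between arms.  For a balanced design with
``a`` arms, ``s`` subjects per arm and ``t`` timepoints the classical
decomposition is

    SS_total        = sum (Y_ijk - grand)^2
    SS_treatment    = s t sum_i (mean_i.. - grand)^2          df a-1
    SS_subjects     = t sum_ij (mean_ij. - mean_i..)^2        df a(s-1)
    SS_time         = a s sum_k (mean_..k - grand)^2          df t-1
    SS_interaction  = s sum_ik (mean_i.k - mean_i.. - mean_..k + grand)^2
                                                              df (a-1)(t-1)
    SS_residual     = SS_total - all of the above             df a(s-1)(t-1)

with F_treatment = MS_treatment / MS_subjects and the within-subject effects
tested against MS_residual.  Method agreement between OCT and fluorescein
planimetry is summarized by Pearson correlation, mean bias and the
least-squares line on paired animal-timepoint measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import ValidationError

__all__ = [
    "RepeatedMeasuresAnova",
    "RMAnovaResults",
    "MethodAgreement",
    "rm_anova",
    "pearson",
    "compare_methods",
    "summarize_groups",
    "estimate_closure_speeds",
    "mixed_anova_arrays",
]

EFFECTS = ("treatment", "time", "time:treatment", "subjects", "residual")


def mixed_anova_arrays(Y: np.ndarray) -> dict[str, np.ndarray]:
    """Split-plot ANOVA on an array of cell values, batched over leading axes.

    ``Y`` has shape (..., a, s, t): arms x subjects-within-arm x timepoints.
    Returns a dict of arrays (``ss_*``, ``df_*``, ``f_*``, ``p_*``) with the
    leading batch shape, so Monte-Carlo replicates cost one vectorized call.
    """
    Y = np.asarray(Y, dtype=float)
    a, s, t = Y.shape[-3:]
    if a < 2 or s < 2 or t < 2:
        raise ValidationError("need >= 2 arms, >= 2 subjects per arm, >= 2 timepoints")
    grand = Y.mean(axis=(-3, -2, -1), keepdims=True)
    m_arm = Y.mean(axis=(-2, -1), keepdims=True)       # (..., a, 1, 1)
    m_subj = Y.mean(axis=-1, keepdims=True)            # (..., a, s, 1)
    m_time = Y.mean(axis=(-3, -2), keepdims=True)      # (..., 1, 1, t)
    m_cell = Y.mean(axis=-2, keepdims=True)            # (..., a, 1, t)

    ss_total = ((Y - grand) ** 2).sum(axis=(-3, -2, -1))
    ss_treat = (s * t) * ((m_arm - grand) ** 2).sum(axis=(-3, -2, -1))
    ss_subj = t * ((m_subj - m_arm) ** 2).sum(axis=(-3, -2, -1))
    ss_time = (a * s) * ((m_time - grand) ** 2).sum(axis=(-3, -2, -1))
    ss_inter = s * ((m_cell - m_arm - m_time + grand) ** 2).sum(axis=(-3, -2, -1))
    ss_resid = ss_total - ss_treat - ss_subj - ss_time - ss_inter

    df = {
        "treatment": a - 1,
        "subjects": a * (s - 1),
        "time": t - 1,
        "time:treatment": (a - 1) * (t - 1),
        "residual": a * (s - 1) * (t - 1),
    }
    ms_subj = ss_subj / df["subjects"]
    ms_resid = np.maximum(ss_resid, 0) / df["residual"]
    with np.errstate(divide="ignore", invalid="ignore"):
        f_treat = (ss_treat / df["treatment"]) / ms_subj
        f_time = (ss_time / df["time"]) / ms_resid
        f_inter = (ss_inter / df["time:treatment"]) / ms_resid
    # zero effect SS means F = 0 even when the error term is also 0
    f_treat = np.where(ss_treat == 0, 0.0, f_treat)
    f_time = np.where(ss_time == 0, 0.0, f_time)
    f_inter = np.where(ss_inter == 0, 0.0, f_inter)
    return {
        "ss_treatment": ss_treat,
        "ss_subjects": ss_subj,
        "ss_time": ss_time,
        "ss_interaction": ss_inter,
        "ss_residual": ss_resid,
        "ss_total": ss_total,
        "df": df,
        "f_treatment": f_treat,
        "f_time": f_time,
        "f_interaction": f_inter,
        "p_treatment": sps.f.sf(f_treat, df["treatment"], df["subjects"]),
        "p_time": sps.f.sf(f_time, df["time"], df["residual"]),
        "p_interaction": sps.f.sf(f_inter, df["time:treatment"], df["residual"]),
    }


def _gg_epsilon(Y: np.ndarray) -> float:
    """Greenhouse–Geisser sphericity epsilon from the pooled within-group covariance."""
    a, s, t = Y.shape
    dev = Y - Y.mean(axis=1, keepdims=True)  # remove group means
    flat = dev.reshape(a * s, t)
    S = flat.T @ flat / (a * (s - 1))
    C = np.eye(t) - np.full((t, t), 1.0 / t)
    Sc = C @ S @ C
    tr = np.trace(Sc)
    denom = (t - 1) * np.sum(Sc * Sc)
    if denom <= 0:
        return 1.0
    return float(min(1.0, max(tr * tr / denom, 1.0 / (t - 1))))


class RepeatedMeasuresAnova:
    """Mixed-design repeated-measures ANOVA model for a long-format table.

    Parameters
    ----------
    data : DataFrame
        Long format with one row per subject x timepoint.
    dv, subject, within, between : str
        Column names of the dependent variable, subject identifier,
        within-subject factor (time) and between-subject factor (arm).

    The design must be balanced: every subject measured at every timepoint,
    each subject in exactly one arm.  Missing cells raise (naming them) rather
    than being imputed.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        dv: str = "area_mm2",
        subject: str = "animal_id",
        within: str = "timepoint_h",
        between: str = "arm",
    ):
        for col in (dv, subject, within, between):
            if col not in data.columns:
                raise ValidationError(f"column {col!r} missing from table")
        self.data = data
        self.dv, self.subject, self.within, self.between = dv, subject, within, between

        arms = sorted(data[between].unique())
        times = np.sort(data[within].unique())
        if len(times) < 2:
            raise ValidationError("need >= 2 timepoints")
        subj_arm = data.groupby(subject)[between].nunique()
        if (subj_arm > 1).any():
            bad = list(subj_arm[subj_arm > 1].index)
            raise ValidationError(f"subjects in more than one arm: {bad}")

        pivot = data.pivot_table(index=[between, subject], columns=within, values=dv, aggfunc="count")
        if (pivot.fillna(0) > 1).any().any():
            raise ValidationError("duplicate rows: more than one value per (subject, timepoint)")
        missing = pivot.isna()
        if missing.any().any():
            cells = [
                f"{idx[1]}@{col}" for idx in pivot.index for col in pivot.columns if missing.loc[idx, col]
            ]
            raise ValidationError(f"unbalanced design, missing cells: {cells[:10]}")

        counts = data.groupby(between)[subject].nunique()
        if counts.nunique() != 1 or counts.min() < 2:
            raise ValidationError(
                f"arms must have equal n >= 2 subjects (got {dict(counts)})"
            )

        self.arms, self.times = arms, times
        wide = data.pivot_table(index=[between, subject], columns=within, values=dv)
        s = int(counts.iloc[0])
        self._Y = np.stack(
            [wide.loc[arm].sort_index().to_numpy() for arm in arms]
        )  # (a, s, t)
        self._n_per_arm = s

    def fit(self, correction: str | None = None) -> "RMAnovaResults":
        """Fit the split-plot decomposition.

        ``correction=None`` reports the uncorrected univariate F tests;
        ``correction="gg"`` additionally applies the Greenhouse–Geisser
        sphericity adjustment to the within-subject p-values (noted in the
        result).
        """
        if correction not in (None, "gg"):
            raise ValidationError("correction must be None or 'gg'")
        r = mixed_anova_arrays(self._Y)
        df = r["df"]
        eps = 1.0
        notes = ["sphericity not adjusted (uncorrected univariate F)"]
        p_time, p_inter = r["p_time"], r["p_interaction"]
        if correction == "gg":
            eps = _gg_epsilon(self._Y)
            p_time = sps.f.sf(r["f_time"], eps * df["time"], eps * df["residual"])
            p_inter = sps.f.sf(r["f_interaction"], eps * df["time:treatment"], eps * df["residual"])
            notes = [f"Greenhouse–Geisser adjustment applied (epsilon = {eps:.3f})"]

        rows = []
        for eff, ss, dfe, f, p in (
            ("treatment", r["ss_treatment"], df["treatment"], r["f_treatment"], r["p_treatment"]),
            ("subjects", r["ss_subjects"], df["subjects"], np.nan, np.nan),
            ("time", r["ss_time"], df["time"], r["f_time"], p_time),
            ("time:treatment", r["ss_interaction"], df["time:treatment"], r["f_interaction"], p_inter),
            ("residual", r["ss_residual"], df["residual"], np.nan, np.nan),
        ):
            rows.append(
                {"effect": eff, "SS": float(ss), "df": int(dfe), "MS": float(ss) / dfe,
                 "F": float(f), "p": float(p)}
            )
        table = pd.DataFrame(rows).set_index("effect")
        return RMAnovaResults(
            model=self, anova_table=table, ss_total=float(r["ss_total"]), epsilon=eps, notes=notes
        )


@dataclass
class RMAnovaResults:
    """Results of :class:`RepeatedMeasuresAnova.fit`."""

    model: RepeatedMeasuresAnova
    anova_table: pd.DataFrame
    ss_total: float
    epsilon: float
    notes: list[str] = field(default_factory=list)

    @property
    def interaction_p(self) -> float:
        """P-value of the time x treatment interaction (the headline effect)."""
        return float(self.anova_table.loc["time:treatment", "p"])

    @property
    def interaction_F(self) -> float:
        return float(self.anova_table.loc["time:treatment", "F"])

    def summary(self) -> str:
        a, s, t = self.model._Y.shape
        lines = [
            "Repeated-measures ANOVA (mixed design)",
            f"  arms: {a} ({', '.join(map(str, self.model.arms))}), "
            f"subjects/arm: {s}, timepoints: {t}",
            "",
            self.anova_table.to_string(float_format=lambda v: f"{v:.6g}"),
            "",
        ]
        lines += [f"  note: {n}" for n in self.notes]
        return "\n".join(lines)


def rm_anova(
    table: pd.DataFrame, method: str | None = None, correction: str | None = None, dv: str = "area_mm2"
) -> RMAnovaResults:
    """Fit the mixed-design ANOVA, optionally restricted to one method's rows."""
    if method is not None:
        if "method" not in table.columns:
            raise ValidationError("table has no 'method' column")
        table = table[table["method"] == method]
        if table.empty:
            raise ValidationError(f"no rows with method {method!r}")
    return RepeatedMeasuresAnova(table, dv=dv).fit(correction=correction)


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p-value (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValidationError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance in one of the inputs")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class MethodAgreement:
    """Agreement between the two planimetry methods on paired measurements."""

    pearson_r: float
    p_value: float
    n_pairs: int
    mean_bias_mm2: float  # mean(FLUO - OCT)
    slope: float          # FLUO ~ slope * OCT + intercept
    intercept: float
    n_excluded_zero_pairs: int = 0

    def __post_init__(self) -> None:
        if not -1 <= self.pearson_r <= 1 or self.n_pairs < 3:
            raise ValidationError("invalid agreement result")

    def summary(self) -> str:
        return (
            f"Method agreement (fluorescein vs OCT), n = {self.n_pairs} pairs"
            f" ({self.n_excluded_zero_pairs} closed-wound pairs excluded)\n"
            f"  Pearson r = {self.pearson_r:.3f} (p = {self.p_value:.3g})\n"
            f"  mean bias (FLUO - OCT) = {self.mean_bias_mm2:.3f} mm^2\n"
            f"  FLUO = {self.slope:.3f} * OCT + {self.intercept:.3f}"
        )


def compare_methods(table: pd.DataFrame, exclude_double_zero: bool = True) -> MethodAgreement:
    """Pair OCT and fluorescein areas per (animal, timepoint) and summarize agreement.

    Accepts either a wide table with ``oct_area_mm2``/``fluoro_area_mm2``
    columns or a long table with ``method`` in {OCT, FLUO} and ``area_mm2``.
    Pairs where both methods read 0 (closed wound) are uninformative constants
    and are excluded from the correlation by default.
    """
    if {"oct_area_mm2", "fluoro_area_mm2"}.issubset(table.columns):
        oct_a = table["oct_area_mm2"].to_numpy(dtype=float)
        flu_a = table["fluoro_area_mm2"].to_numpy(dtype=float)
    else:
        need = {"animal_id", "timepoint_h", "method", "area_mm2"}
        if not need.issubset(table.columns):
            raise ValidationError(f"table must have columns {sorted(need)} or wide area columns")
        wide = table.pivot_table(
            index=["animal_id", "timepoint_h"], columns="method", values="area_mm2"
        )
        if not {"OCT", "FLUO"}.issubset(wide.columns):
            raise ValidationError("need both OCT and FLUO rows to pair")
        wide = wide.dropna(subset=["OCT", "FLUO"])
        oct_a = wide["OCT"].to_numpy(dtype=float)
        flu_a = wide["FLUO"].to_numpy(dtype=float)

    n_zero = 0
    if exclude_double_zero:
        both_zero = (oct_a == 0) & (flu_a == 0)
        n_zero = int(both_zero.sum())
        oct_a, flu_a = oct_a[~both_zero], flu_a[~both_zero]
    if len(oct_a) < 3:
        raise ValidationError(f"only {len(oct_a)} informative pairs (need >= 3)")

    r, p = pearson(oct_a, flu_a)
    fit = sps.linregress(oct_a, flu_a)
    return MethodAgreement(
        pearson_r=r,
        p_value=p,
        n_pairs=len(oct_a),
        mean_bias_mm2=float(np.mean(flu_a - oct_a)),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_excluded_zero_pairs=n_zero,
    )


def summarize_groups(table: pd.DataFrame, dv: str = "area_mm2") -> pd.DataFrame:
    """Mean +/- sample SD (n-1) per (arm, timepoint, method) cell.

    SD is reported as missing (NaN) for single-observation cells.
    """
    if table.empty:
        raise ValidationError("empty table")
    keys = [k for k in ("arm", "timepoint_h", "method") if k in table.columns]
    if not keys:
        raise ValidationError("table has none of the grouping columns arm/timepoint_h/method")
    out = (
        table.groupby(keys)[dv]
        .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan)
        .reset_index()
    )
    return out


def estimate_closure_speeds(
    series: pd.DataFrame, area_col: str = "oct_area_mm2"
) -> pd.DataFrame:
    """Estimate per-arm radial closure speeds from measured areas.

    Converts each area to an equivalent radius ``sqrt(area/pi)`` and fits a
    per-animal least-squares line of radius against time over the open-wound
    points (radius > 0, needing >= 2 of them); the speed is the negated slope
    in um/h.  Returns per-arm mean/SD/n of the per-animal speeds.
    """
    need = {"animal_id", "arm", "timepoint_h", area_col}
    if not need.issubset(series.columns):
        raise ValidationError(f"series must have columns {sorted(need)}")
    rows = []
    for (animal, arm), g in series.groupby(["animal_id", "arm"]):
        r = np.sqrt(g[area_col].to_numpy(dtype=float) / math.pi)
        t = g["timepoint_h"].to_numpy(dtype=float)
        open_pts = r > 0
        if open_pts.sum() < 2:
            continue
        slope = np.polyfit(t[open_pts], r[open_pts], 1)[0]  # mm/h
        rows.append({"animal_id": animal, "arm": arm, "speed_um_per_h": -slope * 1000.0})
    per_animal = pd.DataFrame(rows)
    if per_animal.empty:
        raise ValidationError("no animal had >= 2 open-wound measurements")
    return (
        per_animal.groupby("arm")["speed_um_per_h"]
        .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan)
        .reset_index()
    )
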
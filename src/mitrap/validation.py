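"""Arithmetic and group tests for the wet-lab validation layers.

Covers dual-luciferase reporter normalization, Western-blot densitometry,
CD107a degranulation, TAP1 immunohistochemistry scoring and the patient-level
comparison of miR expression between TAP1-high and TAP1-low melanoma lesions.
Every normalization maps its own reference to exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


# -- dual luciferase -----------------------------------------------------------


def rlu_normalize(records: pd.DataFrame, control_label: str) -> pd.DataFrame:
    """Firefly/Renilla normalization of reporter wells.

    ``records`` needs columns condition, ffl, rl.  Per-well RLU = FFL / RL;
    per-condition mean RLU is divided by the control condition's mean, so the
    control maps to 1.  Returns condition, mean_rlu, normalized.
    """
    required = {"condition", "ffl", "rl"}
    if not required.issubset(records.columns):
        raise ValueError(f"reporter records need columns {sorted(required)}")
    if (records["rl"] <= 0).any():
        raise ValueError("Renilla signal must be positive")
    df = records.assign(rlu=records["ffl"] / records["rl"])
    means = df.groupby("condition", sort=False)["rlu"].mean()
    if control_label not in means.index:
        raise ValueError(f"control condition {control_label!r} missing")
    out = means.reset_index().rename(columns={"rlu": "mean_rlu"})
    out["normalized"] = out["mean_rlu"] / means[control_label]
    return out


# -- densitometry --------------------------------------------------------------


def relative_density(
    band: float, loading: float, parental_band: float, parental_loading: float
) -> float:
    """Band density in arbitrary units: loading-control-normalized density of
    a transfectant lane relative to the parental lane."""
    for name, v in (
        ("band", band),
        ("loading", loading),
        ("parental_band", parental_band),
        ("parental_loading", parental_loading),
    ):
        if v <= 0:
            raise ValueError(f"{name} density must be positive, got {v}")
    return (band / loading) / (parental_band / parental_loading)


# -- degranulation -------------------------------------------------------------


def specific_degranulation(
    with_targets_pct: float, spontaneous_pct: float, nc_specific_pct: float | None = None
) -> tuple[float, float | None]:
    """Specific CD107a signal and x-fold change versus the negative control.

    Spontaneous degranulation (effectors alone) is subtracted from the
    with-target percentage and floored at 0 (a negative specific signal is not
    meaningful).  The fold is specific / NC-specific; an NC of 0 yields None
    (undefined fold).
    """
    for name, v in (("with_targets", with_targets_pct), ("spontaneous", spontaneous_pct)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} percentage {v} outside [0, 100]")
    specific = max(0.0, with_targets_pct - spontaneous_pct)
    if nc_specific_pct is None:
        return specific, None
    if nc_specific_pct == 0:
        return specific, None
    return specific, specific / nc_specific_pct


# -- immunohistochemistry ------------------------------------------------------

IHC_CATEGORIES = ("0%", "1-10%", "11-30%", ">30%")


@dataclass(frozen=True)
class IhcScore:
    frequency_pct: float
    category: str  # one of IHC_CATEGORIES
    group: str  # low / intermediate / high


def ihc_category(frequency_pct: float) -> IhcScore:
    """Grade tumor-cell TAP1 positivity into the four frequency categories.

    Boundary values land in the lower-bound bracket (10 -> "1-10%",
    30 -> "11-30%").  Groups: low = 0-10%, intermediate = 11-30%, high > 30%.
    """
    f = frequency_pct
    if not 0.0 <= f <= 100.0:
        raise ValueError(f"frequency {f} outside [0, 100]")
    if f == 0:
        return IhcScore(f, "0%", "low")
    if f <= 10:
        return IhcScore(f, "1-10%", "low")
    if f <= 30:
        return IhcScore(f, "11-30%", "intermediate")
    return IhcScore(f, ">30%", "high")


# -- group comparisons ---------------------------------------------------------


def group_compare(
    values_a,
    values_b,
    paired: bool = False,
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sided t-test between two groups of measurements.

    Unpaired comparisons default to Welch's unequal-variance variant;
    ``equal_var=True`` selects the pooled-variance test.  Paired comparisons
    require equal lengths.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test needs equal-length groups")
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def group_compare_mannwhitney(values_a, values_b) -> tuple[float, float]:
    """Nonparametric alternative (two-sided Mann-Whitney U)."""
    res = stats.mannwhitneyu(list(values_a), list(values_b), alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def mir_vs_tap1_groups(
    patients: pd.DataFrame, mir_id: str | None = None, method: str = "t"
) -> tuple[tuple[float, float], pd.DataFrame]:
    """Compare miR expression between TAP1-high and TAP1-low lesions.

    ``patients`` needs columns patient_id, tap1_group ("high"/"low"),
    cd8_per_hpf, mir_rel_expr and, when several miRs share the table, mir_id.
    Returns the (statistic, p-value) of the unpaired comparison plus a
    per-patient overview (TAP1 group and frequency, CD8 count, miR value).
    """
    df = patients
    if mir_id is not None:
        df = df.loc[df["mir_id"] == mir_id]
    high = df.loc[df["tap1_group"] == "high", "mir_rel_expr"]
    low = df.loc[df["tap1_group"] == "low", "mir_rel_expr"]
    if high.empty or low.empty:
        raise ValueError("both TAP1 groups must be non-empty")
    if method == "t":
        test = group_compare(high, low, paired=False)
    elif method == "mannwhitney":
        test = group_compare_mannwhitney(high, low)
    else:
        raise ValueError(f"unknown method {method!r}")
    cols = [
        c
        for c in ("patient_id", "tap1_group", "tap1_frequency_pct", "cd8_per_hpf",
                  "mir_id", "mir_rel_expr")
        if c in df.columns
    ]
    overview = df[cols].sort_values(
        ["tap1_group", "patient_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return test, overview
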
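"""ΔCt / ΔΔCt arithmetic for qPCR validation of miTRAP enrichment.

Relative abundance follows the ΔCt method with a fixed amplification
efficiency of 2: one cycle difference doubles the template.  miR assays are
normalized to RNU6A, mRNA assays to GAPDH or ACTB.  The *miTRAP ratio* is the
fold enrichment of a miR in a pull-down eluate versus the input lysate
(input set to 1), reported per bait so target and control baits compare.

Ct values live in [0, 40]; a Ct of 40 marks a censored (undetermined) reaction
and is flagged rather than dropped.  Technical replicates average on the Ct
scale before any exponentiation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

CT_MAX = 40.0


def _check_ct(ct: float, name: str = "Ct") -> None:
    if not 0.0 <= ct <= CT_MAX:
        raise ValueError(f"{name} {ct} outside [0, {CT_MAX}]")


def is_censored(ct: float) -> bool:
    return ct >= CT_MAX


def mean_ct(cts) -> float:
    """Average technical replicates on the Ct scale."""
    vals = list(cts)
    if not vals:
        raise ValueError("no Ct values")
    for v in vals:
        _check_ct(v)
    return sum(vals) / len(vals)


@dataclass(frozen=True)
class Fold:
    value: float
    censored: bool = False  # below-detection flag


def relative_expression(ct_target: float, ct_reference: float) -> Fold:
    """2^-(ct_target - ct_reference); censored when both assays hit Ct 40."""
    _check_ct(ct_target, "target Ct")
    _check_ct(ct_reference, "reference Ct")
    if is_censored(ct_target) and is_censored(ct_reference):
        raise ValueError("target and reference both censored: expression undefined")
    value = 2.0 ** -(ct_target - ct_reference)
    return Fold(value=value, censored=is_censored(ct_target))


def mitrap_ratio(ct_eluate: float, ct_input: float) -> Fold:
    """Eluate-vs-input fold enrichment: 2^-(ct_eluate - ct_input).

    The input baseline maps to exactly 1.  A censored eluate Ct is reported as
    a below-detection fold with the flag set.
    """
    _check_ct(ct_eluate, "eluate Ct")
    _check_ct(ct_input, "input Ct")
    value = 2.0 ** -(ct_eluate - ct_input)
    return Fold(value=value, censored=is_censored(ct_eluate))


def fold_change_ddct(
    measurements: pd.DataFrame,
    condition: str,
    control_condition: str,
    reference_assay: str,
) -> dict[str, Fold]:
    """Per-assay 2^-ΔΔCt between two conditions.

    ``measurements`` needs columns sample_id (condition label), assay_id, ct.
    Technical replicates (repeated rows) average on the Ct scale.  ΔΔCt =
    (Ct_assay - Ct_ref) in ``condition`` minus the same in
    ``control_condition``.
    """
    required = {"sample_id", "assay_id", "ct"}
    if not required.issubset(measurements.columns):
        raise ValueError(f"measurements need columns {sorted(required)}")
    means = (
        measurements.groupby(["sample_id", "assay_id"])["ct"].mean().unstack("assay_id")
    )
    for cond in (condition, control_condition):
        if cond not in means.index:
            raise ValueError(f"condition {cond!r} missing from measurements")
        if reference_assay not in means.columns or math.isnan(
            means.loc[cond, reference_assay]
        ):
            raise ValueError(f"reference assay missing in condition {cond!r}")
    out: dict[str, Fold] = {}
    for assay in means.columns:
        if assay == reference_assay:
            continue
        ct_c = means.loc[condition, assay]
        ct_b = means.loc[control_condition, assay]
        if math.isnan(ct_c) or math.isnan(ct_b):
            continue
        ddct = (ct_c - means.loc[condition, reference_assay]) - (
            ct_b - means.loc[control_condition, reference_assay]
        )
        out[assay] = Fold(value=2.0**-ddct, censored=is_censored(ct_c))
    return out


def mitrap_ratio_table(ct_table: pd.DataFrame, input_sample: str = "input") -> pd.DataFrame:
    """miTRAP ratios for every (assay, eluate sample) against the input.

    ``ct_table`` needs columns sample_id, assay_id, ct and optionally
    is_reference (reference assays are skipped).  Technical replicates
    average on the Ct scale.  Output: assay_id, sample_id, fold, censored.
    """
    df = ct_table
    if "is_reference" in df.columns:
        df = df.loc[~df["is_reference"].astype(bool)]
    means = df.groupby(["sample_id", "assay_id"])["ct"].mean()
    if input_sample not in means.index.get_level_values("sample_id"):
        raise ValueError(f"input sample {input_sample!r} missing")
    rows = []
    for (sample, assay), ct in means.items():
        if sample == input_sample:
            continue
        try:
            ct_in = means.loc[(input_sample, assay)]
        except KeyError:
            continue
        fold = mitrap_ratio(ct, ct_in)
        rows.append(
            {"assay_id": assay, "sample_id": sample, "fold": fold.value,
             "censored": fold.censored}
        )
    return pd.DataFrame(rows, columns=["assay_id", "sample_id", "fold", "censored"])
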
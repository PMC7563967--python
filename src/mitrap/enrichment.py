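"""Per-miR enrichment of the target-bait eluate over the control-bait eluate.

The pull-down uses two baits: the 3'UTR of interest fused to MS2 stem loops
(``target``) and the MS2 loops alone (``control``).  A miR is *enriched* when
its tpm ratio target/control exceeds 1; the candidate filter later demands a
much larger ratio.  Replicates are combined by geometric mean (ratios are
multiplicative) and a small tpm pseudocount stabilizes zero-control miRs.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_PSEUDOCOUNT = 0.01  # tpm


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (reporting convention for percentages)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def aggregate_replicates(values, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """Combine replicate tpm values into one: geometric mean of (tpm + pseudocount)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no replicate values to combine")
    if (arr < 0).any():
        raise ValueError("tpm values must be non-negative")
    return float(np.exp(np.mean(np.log(arr + pseudocount))))


def enrichment_ratio(
    tpm_target: float, tpm_control: float, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """(tpm_target + pc) / (tpm_control + pc)."""
    if tpm_target < 0 or tpm_control < 0:
        raise ValueError("tpm values must be non-negative")
    if pseudocount <= 0 and (tpm_target == 0 and tpm_control == 0):
        raise ValueError("ratio undefined: both tpm zero with no pseudocount")
    if pseudocount <= 0 and tpm_control == 0:
        raise ValueError("ratio undefined: control tpm zero with no pseudocount")
    return (tpm_target + pseudocount) / (tpm_control + pseudocount)


def build_enrichment_table(
    tpm: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """Turn a replicate-level tpm table into one enrichment record per miR.

    Input needs columns mir_id, sample_id, bait, tpm (bait in {target, control,
    input}).  miRs absent from a sample count as tpm 0 there.  Output columns:
    mir_id, tpm_target, tpm_control, tpm_input (replicate-combined), ratio,
    enriched, pseudocount_dominated (control tpm below the pseudocount, i.e.
    the ratio is floored by the stabilizer rather than measured).
    """
    required = {"mir_id", "sample_id", "bait", "tpm"}
    if not required.issubset(tpm.columns):
        raise ValueError(f"tpm table needs columns {sorted(required)}")
    wide = tpm.pivot_table(
        index="mir_id", columns="sample_id", values="tpm", fill_value=0.0
    )
    bait_of = tpm.drop_duplicates("sample_id").set_index("sample_id")["bait"]

    def combined(bait: str) -> pd.Series:
        cols = [s for s in wide.columns if bait_of.get(s) == bait]
        if not cols:
            return pd.Series(np.nan, index=wide.index)
        logs = np.log(wide[cols] + pseudocount)
        return np.exp(logs.mean(axis=1))

    out = pd.DataFrame(
        {
            "mir_id": wide.index,
            "tpm_target": combined("target").to_numpy(),
            "tpm_control": combined("control").to_numpy(),
            "tpm_input": combined("input").to_numpy(),
        }
    )
    if out["tpm_target"].isna().any() or out["tpm_control"].isna().any():
        raise ValueError("tpm table must contain target and control bait samples")
    # combined values already carry the pseudocount; plain quotient here
    out["ratio"] = out["tpm_target"] / out["tpm_control"]
    out["enriched"] = out["ratio"] > 1.0
    out["pseudocount_dominated"] = out["tpm_control"] <= 2 * pseudocount
    return out.reset_index(drop=True)


def flag_enriched(records: pd.DataFrame) -> pd.DataFrame:
    """Strictly-enriched subset: ratio > 1."""
    return records.loc[records["ratio"] > 1.0].reset_index(drop=True)


@dataclass(frozen=True)
class EnrichmentSummary:
    n_total: int
    n_enriched: int
    pct_enriched: float
    #: rows of (vote count, n miRs, percentage of the enriched set)
    breakdown: list[tuple[int, int, float]] = field(default_factory=list)


def summarize_enrichment(records: pd.DataFrame, votes: dict[str, int]) -> EnrichmentSummary:
    """Summarize the enriched fraction and its prediction-vote breakdown.

    ``votes`` maps mir_id -> number of prediction tools calling a site.  Every
    enriched miR must have a vote count.  Percentages are rounded half-up to
    two decimals.
    """
    n_total = len(records)
    enriched = records.loc[records["enriched"], "mir_id"]
    n_enriched = len(enriched)
    if n_enriched == 0:
        return EnrichmentSummary(n_total, 0, 0.0, [])
    missing = [m for m in enriched if m not in votes]
    if missing:
        raise ValueError(f"no vote count for enriched miR {missing[0]!r}")
    counts: dict[int, int] = {}
    for m in enriched:
        counts[votes[m]] = counts.get(votes[m], 0) + 1
    breakdown = [
        (k, n_k, round_half_up(100.0 * n_k / n_enriched))
        for k, n_k in sorted(counts.items())
    ]
    pct = round_half_up(100.0 * n_enriched / n_total)
    return EnrichmentSummary(n_total, n_enriched, pct, breakdown)
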
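"""Six-criterion candidate filter and ranking for miTRAP-enriched miRs.

A miR passes when, for every criterion with data available:

  (i)   predicted by at least ``min_tools`` of the six prediction tools;
  (ii)  tpm in the target-bait eluate higher than ``min_tpm_target``;
  (iii) tpm in the control-bait eluate less than ``max_tpm_control``;
  (iv)  enrichment ratio higher than ``min_ratio``;
  (v)   duplex free energy below ``max_energy`` (strong predicted binding);
  (vi)  miTRAP ratio on the target bait exceeding the control bait's by a
        factor of at least ``mitrap_factor``.

All inequalities are strict.  Criteria whose inputs are missing for a miR are
*not applicable* (NA) rather than failing, so a report can be produced from a
ratio/vote/energy table alone.  Thresholds for (v) and (vi) are conventions
(only "high" is prescribed by the assay's logic); they default to values
consistent with the published retained/excluded candidates and are fully
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

CRITERIA = ("votes", "tpm_target", "tpm_control", "ratio", "energy", "mitrap")


@dataclass(frozen=True)
class SelectionThresholds:
    min_tools: int = 4
    min_tpm_target: float = 1000.0
    max_tpm_control: float = 100.0
    min_ratio: float = 50.0
    max_energy: float = -20.0  # kcal/mol
    mitrap_factor: float = 2.0

    def __post_init__(self):
        if self.min_ratio <= 1:
            raise ValueError("min_ratio must exceed 1")
        if self.max_energy >= 0:
            raise ValueError("max_energy must be negative")
        if self.min_tools < 0:
            raise ValueError("min_tools must be non-negative")
        if self.mitrap_factor <= 0:
            raise ValueError("mitrap_factor must be positive")


def apply_criteria(
    records: pd.DataFrame,
    votes: dict[str, int],
    energies: dict[str, float] | None = None,
    mitrap_folds: dict[str, tuple[float, float]] | None = None,
    thresholds: SelectionThresholds = SelectionThresholds(),
    criteria: tuple[str, ...] = CRITERIA,
) -> pd.DataFrame:
    """Evaluate the selection criteria per miR and rank the passers.

    ``records`` needs a mir_id column plus whichever of tpm_target,
    tpm_control, ratio are available.  ``energies`` maps mir_id to duplex free
    energy; ``mitrap_folds`` maps mir_id to (target-bait fold, control-bait
    fold).  ``criteria`` restricts which of the six are evaluated at all.

    Returns one row per input miR (lossless) with a nullable-boolean column
    ``crit_<name>`` per criterion (pd.NA = not applicable), ``pass_all`` and
    ``rank`` (NA for non-passers).  Passers rank by enrichment ratio
    descending, ties by more negative energy, then mir_id.
    """
    unknown = set(criteria) - set(CRITERIA)
    if unknown:
        raise ValueError(f"unknown criteria: {sorted(unknown)}")
    if "mir_id" not in records.columns:
        raise ValueError("records need a mir_id column")
    energies = energies or {}
    mitrap_folds = mitrap_folds or {}

    out = records.copy().reset_index(drop=True)
    missing_votes = [m for m in out["mir_id"] if m not in votes]
    if missing_votes:
        raise ValueError(f"no vote count for miR {missing_votes[0]!r}")
    out["votes"] = out["mir_id"].map(votes)
    out["energy"] = out["mir_id"].map(energies)
    out["mitrap_target"] = out["mir_id"].map(
        {m: f[0] for m, f in mitrap_folds.items()}
    )
    out["mitrap_control"] = out["mir_id"].map(
        {m: f[1] for m, f in mitrap_folds.items()}
    )

    def crit(name: str, series: pd.Series, test) -> pd.Series:
        if name not in criteria:
            return pd.Series(pd.NA, index=out.index, dtype="boolean")
        res = pd.Series(pd.NA, index=out.index, dtype="boolean")
        avail = series.notna()
        res[avail] = test(series[avail])
        return res

    t = thresholds
    out["crit_votes"] = crit(
        "votes", out["votes"], lambda s: s >= t.min_tools
    )
    out["crit_tpm_target"] = crit(
        "tpm_target",
        out["tpm_target"] if "tpm_target" in out.columns else pd.Series(pd.NA, index=out.index),
        lambda s: s > t.min_tpm_target,
    )
    out["crit_tpm_control"] = crit(
        "tpm_control",
        out["tpm_control"] if "tpm_control" in out.columns else pd.Series(pd.NA, index=out.index),
        lambda s: s < t.max_tpm_control,
    )
    out["crit_ratio"] = crit(
        "ratio",
        out["ratio"] if "ratio" in out.columns else pd.Series(pd.NA, index=out.index),
        lambda s: s > t.min_ratio,
    )
    out["crit_energy"] = crit("energy", out["energy"], lambda s: s < t.max_energy)
    mit = pd.Series(pd.NA, index=out.index, dtype="object")
    avail = out["mitrap_target"].notna() & out["mitrap_control"].notna()
    mit[avail] = (
        out.loc[avail, "mitrap_target"]
        > t.mitrap_factor * out.loc[avail, "mitrap_control"]
    )
    out["crit_mitrap"] = (
        mit.astype("boolean")
        if "mitrap" in criteria
        else pd.Series(pd.NA, index=out.index, dtype="boolean")
    )

    crit_cols = [f"crit_{c}" for c in CRITERIA]
    # all applicable criteria must hold; NA criteria are ignored
    out["pass_all"] = out[crit_cols].fillna(True).all(axis=1)

    passers = out.loc[out["pass_all"]].copy()
    ratio_key = passers["ratio"] if "ratio" in passers.columns else 0.0
    energy_key = passers["energy"].fillna(0.0)
    order = passers.assign(_r=-pd.to_numeric(ratio_key), _e=energy_key).sort_values(
        ["_r", "_e", "mir_id"]
    )
    out["rank"] = pd.NA
    out.loc[order.index, "rank"] = range(1, len(order) + 1)
    out["rank"] = out["rank"].astype("Int64")
    return out


def rank_candidates(report: pd.DataFrame) -> list[str]:
    """Ordered mir_ids of the passers (rank 1 first)."""
    passers = report.loc[report["rank"].notna()].sort_values("rank")
    return list(passers["mir_id"])


_THRESH_TEXT = {
    "votes": ("votes", ">=", "min_tools"),
    "tpm_target": ("tpm_target", ">", "min_tpm_target"),
    "tpm_control": ("tpm_control", "<", "max_tpm_control"),
    "ratio": ("ratio", ">", "min_ratio"),
    "energy": ("energy", "<", "max_energy"),
}


def selection_audit(
    report: pd.DataFrame, thresholds: SelectionThresholds = SelectionThresholds()
) -> dict[str, list[str]]:
    """Per-miR list of failed criteria with observed vs threshold values."""
    audit: dict[str, list[str]] = {}
    for _, row in report.iterrows():
        failures = []
        for name in CRITERIA:
            verdict = row[f"crit_{name}"]
            if verdict is pd.NA or pd.isna(verdict) or bool(verdict):
                continue
            if name == "mitrap":
                failures.append(
                    f"miTRAP fold {row['mitrap_target']:g} <= "
                    f"{thresholds.mitrap_factor:g} x control fold "
                    f"{row['mitrap_control']:g}"
                )
            else:
                col, op, tname = _THRESH_TEXT[name]
                bad_op = {">": "<=", "<": ">=", ">=": "<"}[op]
                failures.append(
                    f"{col} {row[col]:g} {bad_op} {getattr(thresholds, tname):g}"
                )
        audit[row["mir_id"]] = failures
    return audit
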
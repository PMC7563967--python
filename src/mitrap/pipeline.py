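"""End-to-end screen: counts -> tpm -> enrichment -> votes -> candidate report."""

from __future__ import annotations

import pandas as pd

from .enrichment import build_enrichment_table, summarize_enrichment, EnrichmentSummary
from .predictions import PredictionVoteMatrix, load_tool_predictions
from .quantify import aggregate_loci, counts_to_tpm
from .selection import SelectionThresholds, apply_criteria


def run_screen(
    counts: pd.DataFrame,
    prediction_tables: dict[str, pd.DataFrame] | None = None,
    vote_matrix: PredictionVoteMatrix | None = None,
    thresholds: SelectionThresholds = SelectionThresholds(),
    energies: dict[str, float] | None = None,
    mitrap_folds: dict[str, tuple[float, float]] | None = None,
    pseudocount: float = 0.01,
    criteria: tuple[str, ...] = ("votes", "tpm_target", "tpm_control", "ratio"),
) -> tuple[pd.DataFrame, EnrichmentSummary]:
    """Run the full quantification + selection pipeline on a count table.

    By default the four sequencing-side criteria are applied (votes, eluate
    tpm floor, control tpm ceiling, ratio); pass energies/miTRAP folds and
    extend ``criteria`` to add the hybridization and qPCR filters.  Returns
    the candidate report and the enrichment summary.
    """
    if (prediction_tables is None) == (vote_matrix is None):
        raise ValueError("provide exactly one of prediction_tables or vote_matrix")
    if vote_matrix is None:
        vote_matrix = load_tool_predictions(prediction_tables)
    per_mir = aggregate_loci(counts)
    tpm = counts_to_tpm(per_mir)
    records = build_enrichment_table(tpm, pseudocount=pseudocount)
    votes = vote_matrix.vote_counts()
    summary = summarize_enrichment(records, votes)
    report = apply_criteria(
        records,
        votes,
        energies=energies,
        mitrap_folds=mitrap_folds,
        thresholds=thresholds,
        criteria=criteria,
    )
    return report, summary
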
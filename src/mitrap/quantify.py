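"""Small-RNA count quantification: locus aggregation, tpm scaling, read-length QC.

Counts arrive as one row per (miR, genomic locus, sample).  A mature miR can be
encoded by multiple loci, so per-miR counts are the sum over its loci.  tpm here
is pure counts-per-million over the miR fraction: mature miRs are ~22 nt, so no
length normalization is applied (unlike mRNA TPM).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: columns every raw count table must carry
COUNT_COLUMNS = ("mir_id", "locus_id", "sample_id", "count")
#: sample metadata carried through quantification when present
META_COLUMNS = ("bait", "replicate")

TPM_SCALE = 1_000_000


def _check_count_table(counts: pd.DataFrame) -> None:
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    if (counts["count"] < 0).any():
        raise ValueError("negative counts are not allowed")


def aggregate_loci(counts: pd.DataFrame) -> pd.DataFrame:
    """Collapse locus-level rows to one row per (mir_id, sample_id).

    Per-miR count is the sum over its loci; per-sample totals are conserved.
    Duplicate (mir_id, locus_id, sample_id) rows indicate a malformed input
    and raise ``ValueError``.
    """
    _check_count_table(counts)
    dup = counts.duplicated(subset=["mir_id", "locus_id", "sample_id"])
    if dup.any():
        bad = counts.loc[dup, ["mir_id", "locus_id", "sample_id"]].iloc[0]
        raise ValueError(
            "duplicate count rows for "
            f"({bad['mir_id']}, {bad['locus_id']}, {bad['sample_id']})"
        )
    keys = ["mir_id", "sample_id"] + [c for c in META_COLUMNS if c in counts.columns]
    out = counts.groupby(keys, as_index=False, sort=True)["count"].sum()
    return out


def counts_to_tpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale per-miR counts to transcripts-per-million within each sample.

    ``tpm = count / sample_total * 1e6``.  Every sample must have a positive
    total; an all-zero (or absent) sample raises an error naming it.
    """
    if "mir_id" not in counts.columns or "sample_id" not in counts.columns:
        raise ValueError("tpm input needs mir_id and sample_id columns")
    if (counts["count"] < 0).any():
        raise ValueError("negative counts are not allowed")
    totals = counts.groupby("sample_id")["count"].sum()
    empty = totals[totals <= 0]
    if not empty.empty:
        raise ValueError(f"sample {empty.index[0]!r} has zero total count")
    out = counts.copy()
    out["tpm"] = (
        out["count"] / out["sample_id"].map(totals).astype(float) * TPM_SCALE
    )
    keep = ["mir_id", "sample_id"] + [c for c in META_COLUMNS if c in out.columns]
    return out[keep + ["tpm"]]


@dataclass(frozen=True)
class LengthQC:
    modal_length: int
    passed: bool


def length_qc(
    histogram: dict[int, int], lo: int = 21, hi: int = 23
) -> LengthQC:
    """Advisory read-length check: pass iff the modal length is in [lo, hi].

    miTRAP eluate libraries are size-selected for the miR fraction, so a clean
    library peaks at 21-23 nt.  Ties between equally frequent lengths resolve
    toward the smaller length.
    """
    if not histogram:
        raise ValueError("empty read-length histogram")
    if any(v < 0 for v in histogram.values()):
        raise ValueError("negative read counts in histogram")
    if all(v == 0 for v in histogram.values()):
        raise ValueError("all-zero read-length histogram")
    # tie-break: max count, then smaller length
    mode = min(histogram, key=lambda k: (-histogram[k], k))
    return LengthQC(modal_length=mode, passed=lo <= mode <= hi)


def read_counts_tsv(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t")
    _check_count_table(counts)
    return counts


def write_tpm_tsv(tpm: pd.DataFrame, path) -> None:
    tpm.to_csv(path, sep="\t", index=False)
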
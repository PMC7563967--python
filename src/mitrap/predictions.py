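"""Consensus voting over miR target-prediction tools.

Six prediction tools (miRWalk, microrna.org, miRDB, TargetScan, RNA22,
RNAhybrid) are queried for sites of each miR in the bait 3'UTR; their yes/no
calls are merged into a miR x tool boolean matrix and a per-miR vote count.
The tools themselves are external — only their output tables are consumed.

A verbatim transcription of the published TAP1-screen candidate table (21
enriched miRs with >=4 votes, their RNA-seq enrichment ratios and RNAhybrid
binding energies) ships with the package and is loaded with
:func:`load_candidate_fixture`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import pandas as pd

DEFAULT_TOOLS = (
    "miRWalk",
    "microrna.org",
    "miRDB",
    "TargetScan",
    "RNA22",
    "RNAhybrid",
)

_TRUE_TOKENS = {"yes", "true", "1", "y"}
_FALSE_TOKENS = {"no", "false", "0", "n"}


def parse_bool_token(token, row: int | None = None) -> bool:
    t = str(token).strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    where = f" at row {row}" if row is not None else ""
    raise ValueError(f"cannot parse prediction token {token!r}{where}")


@dataclass
class PredictionVoteMatrix:
    """Boolean miR x tool matrix; absent (miR, tool) pairs are False."""

    matrix: pd.DataFrame  # index mir_id, columns tools, dtype bool

    @property
    def tools(self) -> tuple[str, ...]:
        return tuple(self.matrix.columns)

    @property
    def mirs(self) -> tuple[str, ...]:
        return tuple(self.matrix.index)

    def count_votes(self, mir_id: str) -> int:
        if mir_id not in self.matrix.index:
            raise KeyError(f"unknown miR {mir_id!r}")
        return int(self.matrix.loc[mir_id].sum())

    def vote_counts(self) -> dict[str, int]:
        return {m: int(v) for m, v in self.matrix.sum(axis=1).items()}

    def filter_by_votes(self, min_tools: int) -> set[str]:
        if not 0 <= min_tools <= len(self.tools):
            raise ValueError("min_tools out of range")
        counts = self.matrix.sum(axis=1)
        return set(counts.index[counts >= min_tools])

    def to_frame(self) -> pd.DataFrame:
        out = self.matrix.reset_index().rename(columns={"index": "mir_id"})
        out["votes"] = self.matrix.sum(axis=1).to_numpy()
        return out


def load_tool_predictions(
    tables: dict[str, pd.DataFrame], tools: tuple[str, ...] = DEFAULT_TOOLS
) -> PredictionVoteMatrix:
    """Merge per-tool (mir_id, predicted) tables into a vote matrix.

    Token parsing is case-insensitive ("yes"/"Yes" both true); miRs missing
    from a tool's table default to not-predicted.
    """
    unknown = [t for t in tables if t not in tools]
    if unknown:
        raise ValueError(f"tables for unknown tools: {unknown}")
    mirs: list[str] = []
    seen = set()
    for tab in tables.values():
        for m in tab["mir_id"]:
            if m not in seen:
                seen.add(m)
                mirs.append(m)
    matrix = pd.DataFrame(False, index=pd.Index(sorted(mirs), name="mir_id"),
                          columns=list(tools))
    for tool, tab in tables.items():
        if not {"mir_id", "predicted"}.issubset(tab.columns):
            raise ValueError(f"table for {tool} needs mir_id and predicted columns")
        for i, row in enumerate(tab.itertuples(index=False)):
            matrix.loc[row.mir_id, tool] = parse_bool_token(row.predicted, row=i)
    return PredictionVoteMatrix(matrix)


def matrix_from_frame(frame: pd.DataFrame, tools: tuple[str, ...] = DEFAULT_TOOLS) -> PredictionVoteMatrix:
    """Rebuild a vote matrix from a wide frame (mir_id + one column per tool)."""
    mat = frame.set_index("mir_id")[list(tools)]
    return PredictionVoteMatrix(mat.astype(bool))


# -- shipped candidate fixture ------------------------------------------------

FIXTURE_NAME = "tap1_candidate_mirs.tsv"


@dataclass(frozen=True)
class CandidateRecord:
    accession: str
    mir_id: str
    enrichment_ratio: float
    predictions: dict[str, bool]
    votes: int
    binding_energy: float


def _fixture_path(name: str):
    return importlib.resources.files("mitrap.data").joinpath(name)


def load_candidate_fixture(path=None) -> list[CandidateRecord]:
    """Load the shipped TAP1-screen candidate table (21 miRs).

    On load, each row's printed vote count is audited against the recomputed
    count of its six per-tool booleans; an inconsistent row raises with its
    accession.
    """
    if path is None:
        path = _fixture_path(FIXTURE_NAME)
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        preds = {t: parse_bool_token(row[t]) for t in DEFAULT_TOOLS}
        votes = int(row["votes"])
        if votes != sum(preds.values()):
            raise ValueError(
                f"fixture row {row['accession']}: printed vote count {votes} "
                f"!= recomputed {sum(preds.values())}"
            )
        if row["binding_energy"] > 0:
            raise ValueError(f"fixture row {row['accession']}: positive energy")
        records.append(
            CandidateRecord(
                accession=row["accession"],
                mir_id=row["mir_id"],
                enrichment_ratio=float(row["enrichment_ratio"]),
                predictions=preds,
                votes=votes,
                binding_energy=float(row["binding_energy"]),
            )
        )
    return records


def fixture_vote_matrix(records: list[CandidateRecord]) -> PredictionVoteMatrix:
    mat = pd.DataFrame(
        {t: [r.predictions[t] for r in records] for t in DEFAULT_TOOLS},
        index=pd.Index([r.mir_id for r in records], name="mir_id"),
    )
    return PredictionVoteMatrix(mat.astype(bool))


def load_published_vote_breakdown(path=None) -> pd.DataFrame:
    """Vote-count breakdown (votes, n_mirs) of the published enriched set."""
    if path is None:
        path = _fixture_path("enriched_vote_breakdown.tsv")
    return pd.read_csv(path, sep="\t")
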
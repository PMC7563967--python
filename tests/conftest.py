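"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import pytest

from mitrap.hybridization import (
    NearestNeighborParams,
    can_pair,
    normalize_rna,
)
from mitrap.predictions import load_candidate_fixture, fixture_vote_matrix


def brute_force_mfe(mir_seq: str, target_seq: str, params: NearestNeighborParams) -> float:
    """Exhaustive enumeration of all legal intermolecular pairings.

    Independent of the dynamic program: walks every monotone set of base pairs
    respecting the loop-size cap, scoring each structure as initiation plus
    per-step stack or linear loop terms, and returns the minimum energy (0.0
    when no negative-energy structure exists — the same sentinel convention).
    """
    mir = normalize_rna(mir_seq)
    rev = normalize_rna(target_seq)[::-1]
    n, m = len(mir), len(rev)
    best: list[float] = []

    def extend(i0: int, k0: int, energy: float) -> None:
        best.append(energy)
        for i in range(i0 + 1, n):
            gap_a = i - i0 - 1
            if gap_a > params.max_loop:
                break
            for k in range(k0 + 1, m):
                gap_b = k - k0 - 1
                if gap_a + gap_b > params.max_loop:
                    break
                if not can_pair(mir[i], rev[k]):
                    continue
                if gap_a == 0 and gap_b == 0:
                    step = params.stacks[f"{mir[i0]}{mir[i]}/{rev[k0]}{rev[k]}"]
                elif gap_a == 0 or gap_b == 0:
                    step = params.bulge_per_nt * (gap_a + gap_b)
                else:
                    step = params.internal_per_nt * (gap_a + gap_b)
                extend(i, k, energy + step)

    for i in range(n):
        for k in range(m):
            if can_pair(mir[i], rev[k]):
                extend(i, k, params.initiation)
    if not best or min(best) >= 0:
        return 0.0
    return min(best)


@pytest.fixture(scope="session")
def candidate_records():
    return load_candidate_fixture()


@pytest.fixture(scope="session")
def candidate_votes(candidate_records):
    return fixture_vote_matrix(candidate_records)
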
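"""miR:3'UTR hybridization: seed scanning and nearest-neighbor duplex MFE.

The duplex model is intermolecular-only (RNAhybrid's model class): the miR and
a UTR window form an antiparallel duplex of Watson-Crick and G:U wobble pairs
with bulges and internal loops, and no intramolecular structure.  The free
energy of a structure is a duplex-initiation penalty plus, for each pair of
consecutive base pairs, either a nearest-neighbor stack term (no unpaired
nucleotides between them) or a linear loop penalty.  The minimum over all
non-crossing pairings is found by dynamic programming.

The embedded stack table carries the standard Watson-Crick RNA/RNA
nearest-neighbor free energies (37 degC) plus a G:U wobble set; loop costs are
linear per unpaired nucleotide with a size cap rather than full Turner loop
tables, so energies are an independent score, not a reproduction of RNAhybrid's
output.  Dangling ends are free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
_PAIRABLE = {
    ("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"),
    ("G", "U"), ("U", "G"),  # wobble
}

# Watson-Crick RNA/RNA nearest-neighbor stack free energies, kcal/mol, 37 degC,
# keyed "XY/WZ" for the stack 5'-X Y-3' over 3'-W Z-5' (X:W and Y:Z paired).
_WC_STACKS = {
    "AA/UU": -0.93,
    "AU/UA": -1.10,
    "UA/AU": -1.33,
    "CU/GA": -2.08,
    "CA/GU": -2.11,
    "GU/CA": -2.24,
    "GA/CU": -2.35,
    "CG/GC": -2.36,
    "GG/CC": -3.26,
    "GC/CG": -3.42,
}

# G:U wobble stacks (same key convention); representative values.
_GU_STACKS = {
    "AG/UU": -0.55,
    "AU/UG": -1.36,
    "CG/GU": -1.41,
    "CU/GG": -2.11,
    "GG/CU": -1.53,
    "GU/CG": -2.51,
    "UG/AU": -1.00,
    "UU/AG": -0.76,
    "GG/UU": -0.50,
    "GU/UG": 0.47,
    "UG/GU": -0.30,
}


def _expand_stacks() -> dict[str, float]:
    """Fill the full 6x6 pair-combination table via rotational symmetry.

    Reading a stack from the opposite strand maps key "XY/WZ" to "ZW/YX" and
    must give the same energy.
    """
    table: dict[str, float] = {}
    for src in (_WC_STACKS, _GU_STACKS):
        for key, e in src.items():
            x, y = key[0], key[1]
            w, z = key[3], key[4]
            table[key] = e
            table[f"{z}{w}/{y}{x}"] = e
    return table


STACK_TABLE = _expand_stacks()


@dataclass(frozen=True)
class NearestNeighborParams:
    """Energy model parameters (kcal/mol)."""

    stacks: dict = field(default_factory=lambda: dict(STACK_TABLE))
    initiation: float = 4.09
    bulge_per_nt: float = 2.0
    internal_per_nt: float = 1.0
    max_loop: int = 10

    def __post_init__(self):
        if self.initiation <= 0:
            raise ValueError("initiation penalty must be positive")
        if self.bulge_per_nt < 0 or self.internal_per_nt < 0:
            raise ValueError("loop penalties must be non-negative")


DEFAULT_PARAMS = NearestNeighborParams()
DEFAULT_WINDOW_CAP = 48  # fits the default 30 nt upstream + 6 nt seed + 5 nt downstream
DEFAULT_ENERGY_CUTOFF = -5.0


def normalize_rna(seq: str) -> str:
    """Uppercase, T->U; reject anything outside {A,C,G,U}."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"invalid nucleotide(s) {sorted(bad)} in sequence")
    return s


def revcomp(seq: str) -> str:
    """Watson-Crick reverse complement of an RNA string."""
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRABLE


# -- seed scanning -------------------------------------------------------------

DEFAULT_SEED = (1, 7)  # miR nt 2-7, 0-based half-open


def seed_matches(mir_seq: str, utr_seq: str, seed_def: tuple[int, int] = DEFAULT_SEED) -> list[int]:
    """UTR start positions of exact Watson-Crick complements of the miR seed.

    The seed (miR nt 2-7 by default) binds the UTR as its reverse complement;
    overlapping matches are all reported.  Wobble pairs do not count in the
    seed.
    """
    mir = normalize_rna(mir_seq)
    utr = normalize_rna(utr_seq)
    lo, hi = seed_def
    if not 0 <= lo < hi <= len(mir):
        raise ValueError(f"seed definition {seed_def} outside miR length {len(mir)}")
    probe = revcomp(mir[lo:hi])
    k = len(probe)
    return [i for i in range(len(utr) - k + 1) if utr[i : i + k] == probe]


# -- duplex dynamic programming ------------------------------------------------


@dataclass(frozen=True)
class DuplexStructure:
    """An intermolecular duplex between a miR and a target window.

    ``pairs`` lists (mir index, target index), 0-based, with mir indices
    strictly increasing and target indices strictly decreasing (antiparallel
    strands).  ``delta_g`` is the structure free energy; a non-negative value
    with empty pairs is the "no stable duplex" sentinel.
    """

    pairs: tuple[tuple[int, int], ...]
    delta_g: float

    @property
    def stable(self) -> bool:
        return self.delta_g < 0 and bool(self.pairs)

    def render(self, mir: str, target: str) -> str:
        """Three-line text rendering of the paired region."""
        if not self.pairs:
            return "(no stable duplex)"
        top, mid, bot = [], [], []
        prev = None
        for (i, j) in self.pairs:
            if prev is not None:
                gi = list(range(prev[0] + 1, i))
                gj = list(range(j + 1, prev[1]))[::-1]
                for a in range(max(len(gi), len(gj))):
                    top.append(mir[gi[a]].lower() if a < len(gi) else "-")
                    bot.append(target[gj[a]].lower() if a < len(gj) else "-")
                    mid.append(" ")
            top.append(mir[i])
            bot.append(target[j])
            mid.append("|")
            prev = (i, j)
        return (
            f"miR    5'-{''.join(top)}-3'\n"
            f"          {''.join(mid)}\n"
            f"target 3'-{''.join(bot)}-5'"
        )


NO_DUPLEX = DuplexStructure(pairs=(), delta_g=0.0)


def _loop_cost(gap_a: int, gap_b: int, params: NearestNeighborParams) -> float | None:
    """Cost of the unpaired region between two consecutive pairs, or None."""
    total = gap_a + gap_b
    if total == 0:
        return 0.0  # stack handled separately
    if total > params.max_loop:
        return None
    if gap_a == 0 or gap_b == 0:
        return params.bulge_per_nt * total
    return params.internal_per_nt * total


def duplex_mfe(
    mir_seq: str,
    target_window: str,
    params: NearestNeighborParams = DEFAULT_PARAMS,
    window_cap: int = DEFAULT_WINDOW_CAP,
) -> DuplexStructure:
    """Minimum-free-energy intermolecular duplex between miR and a UTR window.

    Dynamic program over "last base pair" states: E[i][k] is the best energy of
    a duplex whose 3'-most miR pair is (miR i, window position mapped from k),
    where the window is traversed 3'->5' so both indices increase together.
    Returns :data:`NO_DUPLEX` when no negative-energy structure exists.
    """
    mir = normalize_rna(mir_seq)
    tgt = normalize_rna(target_window)
    if len(tgt) > window_cap:
        raise ValueError(f"target window of {len(tgt)} nt exceeds cap {window_cap}")
    if len(mir) < 2 or len(tgt) < 2:
        return NO_DUPLEX
    rev = tgt[::-1]  # rev[k] == tgt[len(tgt)-1-k]
    n, m = len(mir), len(rev)
    stacks = params.stacks
    NEG = float("inf")
    E = [[NEG] * m for _ in range(n)]
    back: list[list[tuple[int, int] | None]] = [[None] * m for _ in range(n)]
    pairable = [[can_pair(mir[i], rev[k]) for k in range(m)] for i in range(n)]
    max_skip = params.max_loop + 1
    for i in range(n):
        for k in range(m):
            if not pairable[i][k]:
                continue
            best = params.initiation
            best_prev = None
            for i0 in range(max(0, i - max_skip), i):
                gap_a = i - i0 - 1
                for k0 in range(max(0, k - (params.max_loop - gap_a) - 1), k):
                    if E[i0][k0] == NEG:
                        continue
                    gap_b = k - k0 - 1
                    if gap_a == 0 and gap_b == 0:
                        key = f"{mir[i0]}{mir[i]}/{rev[k0]}{rev[k]}"
                        step = stacks[key]
                    else:
                        cost = _loop_cost(gap_a, gap_b, params)
                        if cost is None:
                            continue
                        step = cost
                    cand = E[i0][k0] + step
                    if cand < best:
                        best = cand
                        best_prev = (i0, k0)
            E[i][k] = best
            back[i][k] = best_prev
    best_val = params.initiation
    best_cell = None
    for i in range(n):
        for k in range(m):
            if E[i][k] < best_val:
                best_val = E[i][k]
                best_cell = (i, k)
    if best_cell is None or best_val >= 0:
        return NO_DUPLEX
    pairs_rev: list[tuple[int, int]] = []
    cell = best_cell
    while cell is not None:
        i, k = cell
        pairs_rev.append((i, len(tgt) - 1 - k))
        cell = back[i][k]
    pairs = tuple(sorted(pairs_rev))
    return DuplexStructure(pairs=pairs, delta_g=best_val)


# -- site scanning -------------------------------------------------------------


@dataclass(frozen=True)
class BindingSite:
    mir_id: str
    start: int  # UTR coords, 0-based half-open
    end: int
    delta_g: float
    seed_class: str  # "7mer", "6mer" or "none"
    structure: DuplexStructure
    window_start: int


def _seed_class(mir: str, utr: str, pos: int) -> str:
    # a 7-mer (miR nt 2-8) extends the 6-mer match one nt upstream in the UTR
    if pos >= 1 and len(mir) >= 8 and utr[pos - 1 : pos + 6] == revcomp(mir[1:8]):
        return "7mer"
    if utr[pos : pos + 6] == revcomp(mir[1:7]):
        return "6mer"
    return "none"


def scan_sites(
    mir_seq: str,
    utr_seq: str,
    mir_id: str = "miR",
    params: NearestNeighborParams = DEFAULT_PARAMS,
    seed_def: tuple[int, int] = DEFAULT_SEED,
    energy_cutoff: float = DEFAULT_ENERGY_CUTOFF,
    upstream_context: int = 30,
    downstream_context: int = 5,
) -> list[BindingSite]:
    """Seed-anchored binding sites ranked by duplex free energy (ascending).

    For each seed match at UTR position p the duplex MFE is computed on the
    window [p - upstream_context, p + seed_len + downstream_context); 30 nt of
    5' UTR context accommodates 3'-compensatory pairing of a ~22 nt miR.  The
    reported interval is the UTR span actually paired in the MFE structure.
    Sites with delta_g <= energy_cutoff are returned.
    """
    mir = normalize_rna(mir_seq)
    utr = normalize_rna(utr_seq)
    seed_len = seed_def[1] - seed_def[0]
    sites = []
    for pos in seed_matches(mir, utr, seed_def):
        w0 = max(0, pos - upstream_context)
        w1 = min(len(utr), pos + seed_len + downstream_context)
        duplex = duplex_mfe(mir, utr[w0:w1], params)
        if not duplex.stable or duplex.delta_g > energy_cutoff:
            continue
        tgt_positions = [w0 + j for _, j in duplex.pairs]
        start, end = min(tgt_positions), max(tgt_positions) + 1
        shifted = DuplexStructure(
            pairs=tuple((i, w0 + j) for i, j in duplex.pairs),
            delta_g=duplex.delta_g,
        )
        sites.append(
            BindingSite(
                mir_id=mir_id,
                start=start,
                end=end,
                delta_g=duplex.delta_g,
                seed_class=_seed_class(mir, utr, pos),
                structure=shifted,
                window_start=w0,
            )
        )
    sites.sort(key=lambda s: (s.delta_g, s.start))
    return sites


def binding_energy(sites: list[BindingSite]) -> float | None:
    """Per-miR binding energy: the minimum delta_g over its sites."""
    if not sites:
        return None
    return min(s.delta_g for s in sites)


def delete_site(utr_seq: str, start: int, end: int) -> str:
    """Excise a UTR interval (0-based half-open), as in binding-site deletion
    mutants of reporter constructs."""
    utr = normalize_rna(utr_seq)
    if not 0 <= start <= end <= len(utr):
        raise ValueError(f"interval [{start}, {end}) out of UTR bounds (len {len(utr)})")
    return utr[:start] + utr[end:]
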
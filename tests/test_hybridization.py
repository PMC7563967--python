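import itertools

import numpy as np
import pytest

from mitrap.hybridization import (
    DEFAULT_PARAMS,
    NO_DUPLEX,
    STACK_TABLE,
    binding_energy,
    delete_site,
    duplex_mfe,
    normalize_rna,
    revcomp,
    scan_sites,
    seed_matches,
)
from conftest import brute_force_mfe

COMP = {"A": "U", "U": "A", "C": "G", "G": "C"}


class TestNormalization:
    def test_t_to_u_and_case(self):
        assert normalize_rna("acgt") == "ACGU"

    def test_invalid_symbol(self):
        with pytest.raises(ValueError, match="N"):
            normalize_rna("ACGN")

    def test_revcomp(self):
        assert revcomp("GAUC") == "GAUC"
        assert revcomp("AAGC") == "GCUU"


class TestSeedMatches:
    def test_constructed_single_match(self):
        mir = "UAGCUUAUCAGACUGAUGUUGA"  # seed = AGCUUA
        utr = "GGGG" + revcomp(mir[1:7]) + "GGGG"
        assert seed_matches(mir, utr) == [4]

    def test_no_complement_is_empty(self):
        assert seed_matches("UAGCUUAUCAGACUGAUGUUGA", "A" * 50) == []

    def test_agrees_with_brute_force_scan(self):
        rng = np.random.default_rng(42)
        nts = np.array(list("ACGU"))
        for _ in range(20):
            mir = "".join(rng.choice(nts, size=22))
            utr = "".join(rng.choice(nts, size=200))
            probe = revcomp(mir[1:7])
            expected = [
                i for i in range(len(utr) - 5) if utr[i : i + 6] == probe
            ]
            assert seed_matches(mir, utr) == expected

    def test_wobble_does_not_count_in_seed(self):
        mir = "AGGGGGA" + "A" * 15
        # G:U wobble-only "complement" of seed GGGGGA must not match
        utr = "AAAA" + "UUUUUU" + "AAAA"
        assert seed_matches(mir, utr) == []


class TestDuplexMfe:
    def test_no_complementarity_is_sentinel(self):
        assert duplex_mfe("AAAAAAAA", "AAAAAAAA") == NO_DUPLEX

    def test_perfect_8mer_matches_hand_sum(self):
        mir = "GCACGUUC"
        target = revcomp(mir)
        duplex = duplex_mfe(mir, target)
        bottom = "".join(COMP[b] for b in mir)  # 3'->5' under the miR
        hand = DEFAULT_PARAMS.initiation + sum(
            STACK_TABLE[f"{mir[i]}{mir[i+1]}/{bottom[i]}{bottom[i+1]}"]
            for i in range(7)
        )
        assert duplex.delta_g == pytest.approx(hand)
        assert len(duplex.pairs) == 8

    def test_dp_equals_brute_force_exhaustive_small(self):
        alphabet = "ACGU"
        seqs = [
            "".join(p)
            for n in (2, 3)
            for p in itertools.product(alphabet, repeat=n)
        ]
        params = DEFAULT_PARAMS
        for a in seqs[::3]:
            for b in seqs[::3]:
                dp = duplex_mfe(a, b, params).delta_g
                oracle = brute_force_mfe(a, b, params)
                assert dp == pytest.approx(oracle), (a, b)

    def test_dp_equals_brute_force_random_up_to_10nt(self):
        rng = np.random.default_rng(7)
        nts = np.array(list("ACGU"))
        params = DEFAULT_PARAMS
        for _ in range(120):
            la, lb = rng.integers(2, 11, size=2)
            a = "".join(rng.choice(nts, size=la))
            b = "".join(rng.choice(nts, size=lb))
            dp = duplex_mfe(a, b, params).delta_g
            oracle = brute_force_mfe(a, b, params)
            assert dp == pytest.approx(oracle), (a, b)

    def test_strand_swap_symmetry(self):
        rng = np.random.default_rng(13)
        nts = np.array(list("ACGU"))
        for _ in range(30):
            a = "".join(rng.choice(nts, size=12))
            b = "".join(rng.choice(nts, size=12))
            assert duplex_mfe(a, b).delta_g == pytest.approx(duplex_mfe(b, a).delta_g)

    def test_mismatch_raises_energy_of_perfect_helix(self):
        mir = "GCACGUUCGA"
        target = revcomp(mir)
        perfect = duplex_mfe(mir, target).delta_g
        for pos in range(1, len(mir) - 1):
            old = mir[pos]
            # replace with a base that cannot pair the partner at all
            partner = COMP[old]
            bad = next(
                b for b in "ACGU"
                if (b, partner) not in {("A","U"),("U","A"),("C","G"),("G","C"),("G","U"),("U","G")}
            )
            mutated = mir[:pos] + bad + mir[pos + 1 :]
            assert duplex_mfe(mutated, target).delta_g > perfect

    def test_window_cap_enforced(self):
        with pytest.raises(ValueError, match="cap"):
            duplex_mfe("GCGC", "A" * 100)

    def test_monotone_pairs_invariant(self):
        rng = np.random.default_rng(3)
        nts = np.array(list("ACGU"))
        for _ in range(25):
            a = "".join(rng.choice(nts, size=15))
            b = "".join(rng.choice(nts, size=15))
            duplex = duplex_mfe(a, b)
            mirs = [i for i, _ in duplex.pairs]
            tgts = [j for _, j in duplex.pairs]
            assert mirs == sorted(mirs)
            assert tgts == sorted(tgts, reverse=True)
            assert len(set(mirs)) == len(mirs) and len(set(tgts)) == len(tgts)


def make_planted_utr(mir):
    """UTR with one embedded site: 3' block complement + spacer + seed complement.

    The background is poly-A with non-pairing flanks, so the only stable duplex
    pairs exactly the planted interval.
    """
    site = revcomp(mir[13:19]) + "A" + revcomp(mir[1:7])
    flank5 = "C" if mir[19] == "U" else "A"
    flank3 = "C" if mir[0] == "U" else "A"
    utr = "A" * 59 + flank5 + site + flank3 + "A" * 59
    assert seed_matches(mir, utr) == [60 + 7]
    return utr, (60, 60 + len(site))


class TestScanSites:
    MIR = "UAGCUUAUCAGACGCGGCCGGA"

    def test_planted_site_recovered(self):
        utr, (start, end) = make_planted_utr(self.MIR)
        sites = scan_sites(self.MIR, utr, energy_cutoff=-5.0)
        assert len(sites) == 1
        assert (sites[0].start, sites[0].end) == (start, end)
        assert sites[0].seed_class in {"6mer", "7mer"}

    def test_infinite_cutoff_empties_output(self):
        utr, _ = make_planted_utr(self.MIR)
        assert scan_sites(self.MIR, utr, energy_cutoff=float("-inf")) == []

    def test_reported_energy_is_min_over_sites(self):
        utr, _ = make_planted_utr(self.MIR)
        sites = scan_sites(self.MIR, utr)
        assert binding_energy(sites) == min(s.delta_g for s in sites)
        assert sites == sorted(sites, key=lambda s: s.delta_g)

    def test_no_sites_energy_is_none(self):
        assert binding_energy([]) is None

    def test_deletion_removes_planted_site(self):
        utr, (start, end) = make_planted_utr(self.MIR)
        assert scan_sites(self.MIR, utr) != []
        mutated = delete_site(utr, start, end)
        assert len(mutated) == len(utr) - (end - start)
        assert scan_sites(self.MIR, mutated) == []


class TestDeleteSite:
    def test_empty_interval_is_identity(self):
        assert delete_site("ACGU", 2, 2) == "ACGU"

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            delete_site("ACGU", 2, 9)


def test_stack_table_is_complete_and_wc_negative():
    pairs = ["AU", "UA", "CG", "GC", "GU", "UG"]
    wc = {"AU", "UA", "CG", "GC"}
    for p1 in pairs:
        for p2 in pairs:
            key = f"{p1[0]}{p2[0]}/{p1[1]}{p2[1]}"
            assert key in STACK_TABLE, key
            if p1 in wc and p2 in wc:
                assert STACK_TABLE[key] < 0
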
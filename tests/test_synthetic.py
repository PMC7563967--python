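import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from mitrap.enrichment import build_enrichment_table
from mitrap.hybridization import can_pair, revcomp, scan_sites, seed_matches
from mitrap.qpcr import mitrap_ratio_table
from mitrap.quantify import aggregate_loci, counts_to_tpm
from mitrap.synthetic import (
    PlantedTruth,
    SimulationConfig,
    simulate_mitrap_counts,
    simulate_patients,
    simulate_predictions,
    simulate_qpcr,
    simulate_sequences,
)

SMALL = SimulationConfig(
    n_mirs=300, n_enriched=4, depth_per_sample=1_000_000, rng_seed=17,
    planted_ratio_range=(100.0, 100.0),
)


class TestCounts:
    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_mirs=10, n_enriched=11)
        with pytest.raises(ValueError):
            SimulationConfig(depth_per_sample=0)
        with pytest.raises(ValueError):
            SimulationConfig(planted_ratio_range=(0.5, 2.0))

    def test_counts_conserve_depth_per_sample(self):
        counts, _ = simulate_mitrap_counts(SMALL)
        totals = counts.groupby("sample_id")["count"].sum()
        assert (totals == SMALL.depth_per_sample).all()
        assert len(totals) == 3 * SMALL.n_replicates

    def test_deterministic_under_seed(self):
        a, _ = simulate_mitrap_counts(SMALL)
        b, _ = simulate_mitrap_counts(SMALL)
        pd.testing.assert_frame_equal(a, b)
        c, _ = simulate_mitrap_counts(dataclasses.replace(SMALL, rng_seed=18))
        assert not a["count"].equals(c["count"])

    def test_tpm_sums_to_scale_after_quantification(self):
        counts, _ = simulate_mitrap_counts(SMALL)
        tpm = counts_to_tpm(aggregate_loci(counts))
        sums = tpm.groupby("sample_id")["tpm"].sum()
        assert np.allclose(sums, 1e6, rtol=1e-9)

    def test_no_planted_signal_means_ratios_near_one(self):
        cfg = SimulationConfig(
            n_mirs=200, n_enriched=0, depth_per_sample=500_000, rng_seed=3
        )
        counts, truth = simulate_mitrap_counts(cfg)
        assert truth.enriched_mirs == ()
        tpm = counts_to_tpm(aggregate_loci(counts))
        records = build_enrichment_table(tpm)
        # realized ratios scatter around 1: median within 10% of unity
        assert abs(np.median(records["ratio"]) - 1.0) < 0.1

    def test_realized_ratio_matches_expectation(self):
        counts, truth = simulate_mitrap_counts(SMALL)
        tpm = counts_to_tpm(aggregate_loci(counts))
        records = build_enrichment_table(tpm).set_index("mir_id")
        for mir, expected in truth.expected_ratios.items():
            realized = records.loc[mir, "ratio"]
            assert abs(realized - expected) / expected < 0.30


class TestSequences:
    def test_planted_sites_match_truth_on_scan(self):
        mirs, utr, truth = simulate_sequences(SMALL)
        assert len(truth.site_coords) == SMALL.n_planted_sites
        for mir_id, coords in truth.site_coords.items():
            sites = scan_sites(mirs[mir_id], utr, mir_id=mir_id)
            assert [(s.start, s.end) for s in sites] == coords

    def test_planted_interval_pairs_with_seed(self):
        mirs, utr, truth = simulate_sequences(SMALL)
        for mir_id, [(start, end)] in truth.site_coords.items():
            seq = mirs[mir_id]
            seed = seq[1:7]
            # seed complement sits at the 3' end of the planted interval
            assert utr[end - 6 : end] == revcomp(seed)
            for a, b in zip(seed, reversed(utr[end - 6 : end])):
                assert can_pair(a, b)

    def test_background_has_no_stray_seed_match(self):
        mirs, utr, truth = simulate_sequences(SMALL)
        for mir_id, [(start, end)] in truth.site_coords.items():
            matches = seed_matches(mirs[mir_id], utr)
            assert matches == [end - 6]

    def test_zero_sites_gives_seed_free_utr(self):
        cfg = dataclasses.replace(SMALL, n_planted_sites=0)
        mirs, utr, truth = simulate_sequences(cfg)
        assert truth.site_coords == {}
        for seq in mirs.values():
            assert seed_matches(seq, utr) == []

    def test_too_short_utr_rejected(self):
        cfg = dataclasses.replace(SMALL, utr_length=50, n_planted_sites=2)
        with pytest.raises(ValueError):
            simulate_sequences(cfg)


class TestQpcr:
    def noiseless(self):
        return dataclasses.replace(SMALL, ct_noise_sd=0.0)

    def test_fold_one_gives_identical_cts(self):
        cfg = self.noiseless()
        truth = PlantedTruth(planted_folds={"miR-x": 1.0})
        ct = simulate_qpcr(truth, cfg)
        mir_ct = ct.loc[~ct["is_reference"], "ct"]
        assert mir_ct.nunique() == 1

    def test_fold_700_shifts_ct_by_log2(self):
        cfg = self.noiseless()
        truth = PlantedTruth(planted_folds={"miR-x": 700.0})
        ct = simulate_qpcr(truth, cfg).groupby(["sample_id", "assay_id"])["ct"].mean()
        diff = ct[("eluate_target", "miR-x")] - ct[("input", "miR-x")]
        assert diff == pytest.approx(-math.log2(700), abs=1e-12)
        assert math.log2(700) == pytest.approx(9.4512, abs=1e-4)

    def test_noiseless_fold_recovery_is_exact(self):
        cfg = self.noiseless()
        _, truth = simulate_mitrap_counts(cfg)
        ratios = mitrap_ratio_table(simulate_qpcr(truth, cfg)).set_index(
            ["assay_id", "sample_id"]
        )
        for mir, fold in truth.planted_folds.items():
            assert ratios.loc[(mir, "eluate_target"), "fold"] == pytest.approx(
                fold, rel=1e-12
            )
            assert ratios.loc[(mir, "eluate_control"), "fold"] == pytest.approx(1.0)

    def test_reference_ct_constant_per_sample(self):
        _, truth = simulate_mitrap_counts(SMALL)
        ct = simulate_qpcr(truth, SMALL)
        ref = ct.loc[ct["is_reference"]]
        assert (ref.groupby("sample_id")["ct"].nunique() == 1).all()

    def test_non_positive_fold_rejected(self):
        with pytest.raises(ValueError):
            simulate_qpcr(PlantedTruth(planted_folds={"m": 0.0}), SMALL)


class TestPatients:
    def test_balanced_groups(self):
        patients = simulate_patients(SimulationConfig(n_patients=20, rng_seed=1))
        per_patient = patients.drop_duplicates("patient_id")
        assert (per_patient["tap1_group"] == "high").sum() == 10
        assert (per_patient["tap1_group"] == "low").sum() == 10

    def test_group_frequency_ranges(self):
        patients = simulate_patients(SimulationConfig(n_patients=20, rng_seed=2))
        high = patients.loc[patients["tap1_group"] == "high", "tap1_frequency_pct"]
        low = patients.loc[patients["tap1_group"] == "low", "tap1_frequency_pct"]
        assert (high > 30).all() and (low <= 10).all()

    def test_zero_effect_means_equal_expression_in_expectation(self):
        cfg = SimulationConfig(n_patients=400, rng_seed=4, patient_effect_size=0.0)
        patients = simulate_patients(cfg)
        log_expr = np.log2(patients["mir_rel_expr"])
        high = log_expr[patients["tap1_group"] == "high"]
        low = log_expr[patients["tap1_group"] == "low"]
        assert abs(high.mean() - low.mean()) < 0.15

    def test_odd_cohort_rejected(self):
        with pytest.raises(ValueError):
            simulate_patients(SimulationConfig(n_patients=7))


class TestPredictions:
    def test_planted_mirs_get_planted_votes(self):
        _, truth = simulate_mitrap_counts(SMALL)
        tables = simulate_predictions(truth, SMALL)
        from mitrap.predictions import load_tool_predictions

        votes = load_tool_predictions(tables).vote_counts()
        for mir in truth.enriched_mirs:
            assert votes[mir] == SMALL.planted_votes
        background = [m for m in votes if m not in truth.enriched_mirs]
        assert max(votes[m] for m in background) <= 3
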
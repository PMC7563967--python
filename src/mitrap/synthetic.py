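"""Synthetic miTRAP-seq study generator with planted ground truth.

Emulates the statistical structure of a pull-down screen against a bait 3'UTR:

* a miRBase-scale miR universe (2693 miRs by default) with a small planted
  subset enriched on the target bait by a tpm-ratio multiplier;
* library-size-constrained multinomial counts per sample (fixed sequencing
  depth), with a fraction of miRs encoded by two loci;
* miR and UTR sequences where planted UTR intervals carry a full
  reverse-complement of the miR seed (nt 2-7) plus partial 3' complementarity,
  and the background contains no stray seed complement of any planted miR;
* Ct tables encoding planted fold changes under the ΔCt model with constant
  reference-assay Cts;
* a patient cohort split into TAP1-high and TAP1-low groups with inverse miR
  expression and CD8 infiltration;
* noiseless per-tool prediction votes for the planted miRs.

Everything is deterministic under ``rng_seed``; each generator draws from its
own seed stream so the outputs are independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hybridization import revcomp, scan_sites, seed_matches
from .predictions import DEFAULT_TOOLS

_NUCS = np.array(list("ACGU"))


class GenerationError(RuntimeError):
    """Raised when a constrained synthetic object cannot be produced."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic screen.

    Counts: ``n_mirs`` miRs sequenced to ``depth_per_sample`` reads per sample
    for baits {target, control, input} x ``n_replicates``.  ``n_enriched``
    planted miRs get their target-bait abundance multiplied by a draw from
    ``planted_ratio_range``; their baseline abundance is set so the expected
    control-eluate tpm is ``planted_control_tpm`` (candidate miRs in this kind
    of screen are rare in the control eluate).  qPCR folds default to the
    published miTRAP enrichments (700x and 50x) for the first two planted miRs.
    """

    n_mirs: int = 2693
    n_enriched: int = 5
    depth_per_sample: int = 1_000_000
    planted_ratio_range: tuple[float, float] = (60.0, 200.0)
    n_replicates: int = 2
    utr_length: int = 400
    n_planted_sites: int = 2
    planted_fold_changes: dict[str, float] | None = None
    n_patients: int = 20
    rng_seed: int = 0
    # secondary knobs
    planted_control_tpm: float = 30.0
    abundance_sigma: float = 1.2
    two_locus_fraction: float = 0.15
    ct_noise_sd: float = 0.2
    ct_baseline: float = 25.0
    reference_ct: float = 18.0
    n_qpcr_replicates: int = 3
    control_bait_fold: float = 1.0
    patient_effect_size: float = 1.5  # log2 units, low-TAP1 minus high-TAP1
    patient_noise_sd: float = 0.5
    cd8_high_mean: float = 25.0
    cd8_low_mean: float = 8.0
    cd8_sd: float = 4.0
    n_decoy_mirs: int = 3
    planted_votes: int = 5

    def __post_init__(self):
        if self.n_enriched > self.n_mirs:
            raise ValueError("n_enriched cannot exceed n_mirs")
        if self.depth_per_sample <= 0:
            raise ValueError("depth_per_sample must be positive")
        if self.planted_ratio_range[0] <= 1:
            raise ValueError("planted ratio multipliers must exceed 1")
        if self.planted_ratio_range[0] > self.planted_ratio_range[1]:
            raise ValueError("planted_ratio_range must be a (low, high) interval")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass
class PlantedTruth:
    """Ground truth of a simulated screen, for recovery tests."""

    enriched_mirs: tuple[str, ...] = ()
    site_coords: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    planted_folds: dict[str, float] = field(default_factory=dict)
    expected_ratios: dict[str, float] = field(default_factory=dict)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.rng_seed, stream])


def _mir_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"hsa-miR-sim-{i + 1:0{width}d}" for i in range(n)]


def _planted_folds(config: SimulationConfig, enriched: tuple[str, ...]) -> dict[str, float]:
    if config.planted_fold_changes is not None:
        folds = dict(config.planted_fold_changes)
    else:
        defaults = (700.0, 50.0)
        folds = {m: f for m, f in zip(enriched, defaults)}
    for mir, fold in folds.items():
        if fold <= 0:
            raise ValueError(f"planted fold for {mir} must be positive, got {fold}")
    return folds


# -- counts --------------------------------------------------------------------


def simulate_mitrap_counts(config: SimulationConfig) -> tuple[pd.DataFrame, PlantedTruth]:
    """Multinomial locus-level counts for target/control/input x replicates.

    Control and input samples share the baseline abundance vector; the target
    bait multiplies each planted miR's abundance by its drawn ratio.  Every
    sample's counts sum to exactly ``depth_per_sample``.
    """
    rng = _rng(config, 0)
    mirs = _mir_ids(config.n_mirs)
    enriched_idx = np.sort(
        rng.choice(config.n_mirs, size=config.n_enriched, replace=False)
    )
    enriched = tuple(mirs[i] for i in enriched_idx)

    raw = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=config.n_mirs)
    w = raw.copy()
    planted_w = config.planted_control_tpm / 1e6
    is_planted = np.zeros(config.n_mirs, dtype=bool)
    is_planted[enriched_idx] = True
    background_mass = 1.0 - planted_w * config.n_enriched
    if background_mass <= 0:
        raise ValueError("planted_control_tpm too large for n_enriched")
    w[~is_planted] = raw[~is_planted] / raw[~is_planted].sum() * background_mass
    w[is_planted] = planted_w

    mult = np.ones(config.n_mirs)
    mult[enriched_idx] = rng.uniform(*config.planted_ratio_range, size=config.n_enriched)
    w_target = w * mult
    s_target = w_target.sum()
    expected_ratios = {
        mirs[i]: float(mult[i] / s_target) for i in enriched_idx
    }

    # a fraction of miRs are encoded by two loci; counts split across loci
    n_two = int(round(config.two_locus_fraction * config.n_mirs))
    two_locus_idx = set(
        rng.choice(config.n_mirs, size=n_two, replace=False).tolist()
    )
    locus_mir: list[int] = []
    locus_ids: list[str] = []
    locus_share: list[float] = []
    for i, m in enumerate(mirs):
        if i in two_locus_idx:
            locus_mir += [i, i]
            locus_ids += [f"{m}_L1", f"{m}_L2"]
            locus_share += [0.6, 0.4]
        else:
            locus_mir.append(i)
            locus_ids.append(f"{m}_L1")
            locus_share.append(1.0)
    locus_mir_arr = np.array(locus_mir)
    share = np.array(locus_share)

    frames = []
    for bait, weights in (("target", w_target), ("control", w), ("input", w)):
        p = weights[locus_mir_arr] * share
        p = p / p.sum()
        for rep in range(1, config.n_replicates + 1):
            counts = rng.multinomial(config.depth_per_sample, p)
            frames.append(
                pd.DataFrame(
                    {
                        "mir_id": [mirs[i] for i in locus_mir_arr],
                        "locus_id": locus_ids,
                        "sample_id": f"{bait}_rep{rep}",
                        "bait": bait,
                        "replicate": rep,
                        "count": counts,
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)
    truth = PlantedTruth(
        enriched_mirs=enriched,
        planted_folds=_planted_folds(config, enriched),
        expected_ratios=expected_ratios,
    )
    return table, truth


# -- sequences -------------------------------------------------------------------

_SITE_SPACER = 1
_SEED_LEN = 6
_SITE_LEN = 2 * _SEED_LEN + _SITE_SPACER  # 3' block + spacer + seed complement


def _draw_mir(rng: np.random.Generator, length: int = 22) -> str:
    # mild GC bias overall; the 3'-pairing block (nt 14-19) is GC-only so the
    # planted compensatory helix is always worth its internal loop
    probs = [0.2, 0.3, 0.3, 0.2]
    seq = rng.choice(_NUCS, size=length, p=probs)
    seq[13:19] = rng.choice(np.array(list("GC")), size=6)
    return "".join(seq)


def _nonpairing_flank(mir_nt: str) -> str:
    # A pairs only U; C pairs only G — pick whichever cannot pair the miR nt
    return "C" if mir_nt == "U" else "A"


def _build_site(mir: str) -> str:
    return revcomp(mir[13:19]) + "A" * _SITE_SPACER + revcomp(mir[1:7])


def simulate_sequences(
    config: SimulationConfig, truth: PlantedTruth | None = None
) -> tuple[dict[str, str], str, PlantedTruth]:
    """miR sequences and a UTR with planted, seed-anchored binding sites.

    One site is planted per miR for the first ``n_planted_sites`` enriched
    miRs.  Planted intervals carry the reverse complement of the miR seed
    (nt 2-7) preceded by a 6-nt reverse complement of the miR 3' region
    (partial 3' complementarity); flanks are chosen so the minimum-free-energy
    duplex pairs exactly the planted interval.  The background contains no
    seed complement of any planted miR outside the planted intervals.
    """
    if config.utr_length < 30 * config.n_planted_sites:
        raise ValueError("utr_length must be at least 30 x n_planted_sites")
    rng = _rng(config, 1)
    truth = truth or PlantedTruth(
        enriched_mirs=tuple(f"planted-miR-{i + 1}" for i in range(config.n_planted_sites))
    )
    site_mirs = list(truth.enriched_mirs[: config.n_planted_sites])
    if len(site_mirs) < config.n_planted_sites:
        raise GenerationError("not enough enriched miRs to carry the planted sites")

    mir_seqs = {m: _draw_mir(rng) for m in site_mirs}
    for d in range(config.n_decoy_mirs):
        mir_seqs[f"decoy-miR-{d + 1}"] = _draw_mir(rng)

    n = config.n_planted_sites
    if n == 0:
        utr = "".join(rng.choice(_NUCS, size=config.utr_length))
        # even with no planted sites, keep the planted miRs' seeds out of the UTR
        for attempt in range(200):
            if all(not seed_matches(s, utr) for s in mir_seqs.values()):
                break
            utr = "".join(rng.choice(_NUCS, size=config.utr_length))
        else:
            raise GenerationError("could not build a seed-free background UTR")
        truth.site_coords = {}
        return mir_seqs, utr, truth

    pitch = config.utr_length // (n + 1)
    starts = [pitch * (k + 1) - _SITE_LEN // 2 for k in range(n)]
    if any(s < 1 or s + _SITE_LEN + 1 > config.utr_length for s in starts):
        raise GenerationError("cannot place sites without overlap")

    for attempt in range(500):
        utr = list(rng.choice(_NUCS, size=config.utr_length))
        coords: dict[str, list[tuple[int, int]]] = {}
        for m, s in zip(site_mirs, starts):
            site = _build_site(mir_seqs[m])
            utr[s : s + _SITE_LEN] = list(site)
            # block duplex extension beyond the planted interval
            utr[s - 1] = _nonpairing_flank(mir_seqs[m][19])
            utr[s + _SITE_LEN] = _nonpairing_flank(mir_seqs[m][0])
            coords[m] = [(s, s + _SITE_LEN)]
        utr_str = "".join(utr)
        ok = True
        for m, s in zip(site_mirs, starts):
            if seed_matches(mir_seqs[m], utr_str) != [s + _SEED_LEN + _SITE_SPACER]:
                ok = False
                break
            # the MFE duplex must pair exactly the planted interval, so scan
            # output coordinates match the recorded truth
            found = scan_sites(mir_seqs[m], utr_str, mir_id=m)
            if len(found) != 1 or (found[0].start, found[0].end) != (s, s + _SITE_LEN):
                ok = False
                break
        if ok:
            truth.site_coords = coords
            return mir_seqs, utr_str, truth
    raise GenerationError("could not build a seed-free background UTR")


# -- qPCR ------------------------------------------------------------------------

QPCR_SAMPLES = ("input", "eluate_target", "eluate_control")
REFERENCE_ASSAY = "RNU6A"


def simulate_qpcr(truth: PlantedTruth, config: SimulationConfig) -> pd.DataFrame:
    """Ct table encoding the planted eluate-vs-input folds.

    Ct(eluate) = Ct(input baseline) - log2(fold) + Gaussian noise; the
    reference assay (RNU6A) is constant per sample.  Columns: sample_id,
    assay_id, replicate, ct, is_reference.
    """
    rng = _rng(config, 2)
    rows = []
    folds_per_sample = {
        "input": 1.0,
        "eluate_control": config.control_bait_fold,
    }
    for mir, fold in truth.planted_folds.items():
        if fold <= 0:
            raise ValueError(f"planted fold for {mir} must be positive")
        for sample in QPCR_SAMPLES:
            fold_here = truth.planted_folds[mir] if sample == "eluate_target" else folds_per_sample[sample]
            base = config.ct_baseline - math.log2(fold_here)
            for rep in range(1, config.n_qpcr_replicates + 1):
                noise = rng.normal(0.0, config.ct_noise_sd) if config.ct_noise_sd > 0 else 0.0
                rows.append(
                    {
                        "sample_id": sample,
                        "assay_id": mir,
                        "replicate": rep,
                        "ct": float(np.clip(base + noise, 0.0, 40.0)),
                        "is_reference": False,
                    }
                )
    for sample in QPCR_SAMPLES:
        for rep in range(1, config.n_qpcr_replicates + 1):
            rows.append(
                {
                    "sample_id": sample,
                    "assay_id": REFERENCE_ASSAY,
                    "replicate": rep,
                    "ct": config.reference_ct,
                    "is_reference": True,
                }
            )
    return pd.DataFrame(rows)


# -- patients --------------------------------------------------------------------


def simulate_patients(config: SimulationConfig, truth: PlantedTruth | None = None) -> pd.DataFrame:
    """Patient cohort with inverse miR expression across TAP1 groups.

    Half the patients are TAP1-high (>30% positivity, high CD8 counts, low miR
    expression), half TAP1-low (0-10%, low CD8, miR expression elevated by
    ``patient_effect_size`` log2 units).  Columns: patient_id, tap1_group,
    tap1_frequency_pct, cd8_per_hpf, mir_id, mir_rel_expr.
    """
    if config.n_patients % 2:
        raise ValueError("n_patients must be even (balanced groups)")
    rng = _rng(config, 3)
    mir_ids = list(truth.planted_folds) if truth and truth.planted_folds else ["miR-A", "miR-B"]
    half = config.n_patients // 2
    rows = []
    for p in range(config.n_patients):
        group = "high" if p < half else "low"
        if group == "high":
            freq = float(rng.uniform(31.0, 95.0))
            cd8 = float(max(0.0, rng.normal(config.cd8_high_mean, config.cd8_sd)))
            mu = 0.0
        else:
            freq = float(rng.uniform(0.0, 10.0))
            cd8 = float(max(0.0, rng.normal(config.cd8_low_mean, config.cd8_sd)))
            mu = config.patient_effect_size
        for mir in mir_ids:
            expr = 2.0 ** rng.normal(mu, config.patient_noise_sd)
            rows.append(
                {
                    "patient_id": f"P{p + 1:02d}",
                    "tap1_group": group,
                    "tap1_frequency_pct": freq,
                    "cd8_per_hpf": cd8,
                    "mir_id": mir,
                    "mir_rel_expr": float(expr),
                }
            )
    return pd.DataFrame(rows)


# -- prediction votes --------------------------------------------------------------


def simulate_predictions(
    truth: PlantedTruth, config: SimulationConfig, all_mirs: list[str] | None = None
) -> dict[str, pd.DataFrame]:
    """Noiseless per-tool vote tables: planted miRs get ``planted_votes``
    positive calls, background miRs at most 3."""
    rng = _rng(config, 4)
    mirs = all_mirs if all_mirs is not None else _mir_ids(config.n_mirs)
    planted = set(truth.enriched_mirs)
    n_tools = len(DEFAULT_TOOLS)
    votes = {}
    for m in mirs:
        votes[m] = config.planted_votes if m in planted else int(rng.integers(0, 4))
    tables = {}
    for t_idx, tool in enumerate(DEFAULT_TOOLS):
        token_true = "Yes" if tool == "microrna.org" else "yes"
        predicted = [
            token_true if t_idx < votes[m] else "no" for m in mirs
        ]
        tables[tool] = pd.DataFrame({"mir_id": mirs, "predicted": predicted})
    return tables


# -- one-call convenience -----------------------------------------------------------


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    counts: pd.DataFrame
    truth: PlantedTruth
    mir_seqs: dict[str, str]
    utr: str
    ct_table: pd.DataFrame
    patients: pd.DataFrame
    predictions: dict[str, pd.DataFrame]


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate every pipeline input with one shared ground truth."""
    counts, truth = simulate_mitrap_counts(config)
    mir_seqs, utr, truth = simulate_sequences(config, truth)
    ct_table = simulate_qpcr(truth, config)
    patients = simulate_patients(config, truth)
    predictions = simulate_predictions(truth, config)
    return SyntheticStudy(
        config=config,
        counts=counts,
        truth=truth,
        mir_seqs=mir_seqs,
        utr=utr,
        ct_table=ct_table,
        patients=patients,
        predictions=predictions,
    )
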
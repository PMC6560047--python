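"""Synthetic cohorts: voxel patterns, BOLD time series, behavior, metabolites.

The generator plants, per simulated participant, the statistical structure
the analysis is designed to detect:

- stimulus-by-context voxel patterns whose correlations are higher within
  than between contexts, with extra cross-context separation for the two
  swapped stimuli;
- event-related BOLD in two regions of interest, where the second stimulus
  of a directly-associated pair is suppressed (cross-stimulus suppression),
  hidden pairs acquire additional suppression in block 2 in proportion to
  the participant's GABA drop, and unstable-pair trials add a univariate
  hippocampal response;
- training to criterion, and a memory test whose foil-choice rate grows
  with an interference weight;
- a three-timepoint metabolite series with a GABA:Cr dip during
  stimulation and a late glutamate rise.

A single latent interference trait per participant couples the GABA drop,
the foil weight, the memory-test strength, and the block-1 hippocampal
response, so the cross-subject correlation chain the analysis reports is
present by construction when the coupling parameters are nonzero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import glm as _glm
from .design import (
    DesignParams,
    TrialSequence,
    generate_memory_test,
    generate_scan_block,
    generate_training_block,
)
from .rings import (
    CONTEXTS,
    LinkTaxonomy,
    PairCategory,
    RingStructure,
    build_memory_rings,
    link_taxonomy,
)
from .stats import BehavioralRecord

ROI_LABELS = ("hippocampus", "aLOC")

METABOLITES = (
    "Ala", "Asp", "Asc", "GPC", "PCho", "Cr", "PCr", "GABA", "Glc", "Gln",
    "Glu", "GSH", "myo-Ins", "Lac", "NAA", "NAAG", "PE", "scyllo-Ins", "Tau",
)

_BASELINE_RATIOS = {
    "Ala": 0.05, "Asp": 0.25, "Asc": 0.10, "GPC": 0.10, "PCho": 0.05,
    "Cr": 0.55, "PCr": 0.45, "GABA": 0.10, "Glc": 0.08, "Gln": 0.35,
    "Glu": 1.20, "GSH": 0.15, "myo-Ins": 0.70, "Lac": 0.06, "NAA": 1.35,
    "NAAG": 0.15, "PE": 0.10, "scyllo-Ins": 0.04, "Tau": 0.12,
}


@dataclass
class GroundTruth:
    """Generator parameters: planted effects, noise, and cohort couplings.

    Pattern correlations (``rho_*``) act on the multivoxel component of the
    stimulus patterns; amplitude effects (``beta_unstable``,
    ``delta_suppress``) are in the same signal units as the fitted betas
    (the HRF is unit peak). ``kappa_couple`` converts a participant's
    GABA:Cr drop into the extra fractional suppression of hidden pairs in
    block 2. ``trait`` / ``trait_b2`` are per-subject latent realizations
    filled in by the cohort generator.
    """

    # multivoxel pattern structure
    rho_within: float = 0.25
    rho_between: float = 0.05
    rho_same_cross: float = 0.30
    delta_swap: float = 0.25
    # univariate effects (signal units)
    beta_unstable: float = 0.35
    hippo_slope: float = 0.15
    delta_suppress: float = 0.15
    # stimulation and neural-metabolite coupling
    gaba_drop: float = 0.02
    gaba_drop_sd: float = 0.02
    kappa_couple: float = 10.0
    # behavior
    lambda_interfere: float = 1.0
    lambda_slope: float = 0.8
    choice_strength: float = 2.2
    strength_slope: float = 0.4
    learn_rate: float = 0.05
    initial_exposures: float = 8.0
    max_training_blocks: int = 12
    # temporal noise
    noise_sd: float = 1.0
    ar1_coef: float = 0.3
    drift_sd: float = 0.5
    mrs_noise_sd: float = 0.005
    # geometry / cohort
    n_voxels: int = 200
    n_subjects: int = 24
    baseline_amplitude: float = 1.0
    pattern_scale: float = 1.0
    gaba_baseline: float = 0.10
    glu_baseline: float = 1.20
    glu_rise: float = 0.04
    inestimable_fraction: float = 6.0 / 26.0
    low_scan_accuracy_fraction: float = 2.0 / 26.0
    scan_accuracy_mean: float = 0.95
    scan_accuracy_sd: float = 0.03
    # realized per-subject latent state
    trait: float = 0.0
    trait_b2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("rho_within", "rho_between", "rho_same_cross"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a correlation in [-1, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not abs(self.ar1_coef) < 1:
            raise ValueError("|ar1_coef| must be < 1")


def null_truth(**overrides) -> GroundTruth:
    """A GroundTruth with every planted effect and coupling set to zero.

    Under the null a stimulus evokes the *same* pattern in both contexts
    (same-stimulus cross-context correlation 1), so within- and
    between-context trial pairs are statistically exchangeable and the
    context-separation model has nothing to detect.
    """
    base = dict(
        rho_within=0.10,
        rho_between=0.10,
        rho_same_cross=1.0,
        delta_swap=0.0,
        beta_unstable=0.0,
        hippo_slope=0.0,
        delta_suppress=0.0,
        gaba_drop=0.0,
        kappa_couple=0.0,
        lambda_slope=0.0,
        strength_slope=0.0,
    )
    base.update(overrides)
    return GroundTruth(**base)


@dataclass
class VoxelTimeSeries:
    data: np.ndarray  # voxels x volumes
    tr: float
    roi_label: str

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


@dataclass
class MetaboliteMeasurement:
    timepoint: str  # {"t1", "t2", "t3"}
    metabolite: str
    ratio: float  # concentration relative to total creatine
    crlb: float  # percent
    fwhm: float  # linewidth, arbitrary units


@dataclass
class BehaviorData:
    training_block_accuracy: Dict[str, List[float]]  # context -> per-block mean
    training_assoc_accuracy: Dict[str, List[np.ndarray]]  # per-block per-pair
    learning_accuracy: Dict[str, float]  # context -> best-block accuracy
    records: List[BehavioralRecord]
    scan_accuracy: Tuple[float, float]


@dataclass
class Patterns:
    """Stimulus-by-context voxel patterns with the planted correlations."""

    array: np.ndarray  # 14 x voxels
    conditions: List[Tuple[int, str]]

    def of(self, stimulus: int, context: str) -> np.ndarray:
        return self.array[self.conditions.index((int(stimulus), context))]


@dataclass
class SyntheticSubject:
    subject_id: int
    seed: Tuple[int, ...]
    truth: GroundTruth  # realized (per-subject) parameters
    rings: Tuple[RingStructure, RingStructure]
    tax: LinkTaxonomy
    events: Dict[int, TrialSequence]
    bold: Dict[Tuple[str, int], VoxelTimeSeries]
    behavior: BehaviorData
    mrs: List[MetaboliteMeasurement]
    gaba_inestimable: bool


# --------------------------------------------------------------------------
# Patterns

def _target_correlation(truth: GroundTruth, conds, swapped) -> np.ndarray:
    n = len(conds)
    C = np.empty((n, n))
    for i, (si, ci) in enumerate(conds):
        for j, (sj, cj) in enumerate(conds):
            if i == j:
                C[i, j] = 1.0
            elif ci == cj:
                C[i, j] = truth.rho_within
            elif si == sj:
                C[i, j] = truth.rho_same_cross - (
                    truth.delta_swap if si in swapped else 0.0
                )
            else:
                C[i, j] = truth.rho_between
    return C


def simulate_patterns(
    truth: GroundTruth, tax: LinkTaxonomy, rng: np.random.Generator
) -> Patterns:
    """Draw the 14 condition patterns with the planted correlation matrix.

    Each pattern is a constant evoked amplitude plus a zero-mean multivoxel
    component; the target correlations apply to the multivoxel component.
    """
    stimuli = sorted(tax.ring1.stimuli)
    conds = [(int(s), c) for c in CONTEXTS for s in stimuli]
    C = _target_correlation(truth, conds, tax.swapped)
    w, V = np.linalg.eigh(C)
    if w.min() < -1e-8:
        raise ValueError(
            "requested pattern correlation structure is not positive semidefinite"
        )
    L = V * np.sqrt(np.clip(w, 0.0, None))
    Z = rng.standard_normal((len(conds), truth.n_voxels))
    array = truth.baseline_amplitude + truth.pattern_scale * (L @ Z)
    return Patterns(array=array, conditions=conds)


# --------------------------------------------------------------------------
# BOLD

def n_volumes_for(events: TrialSequence, tr: float, tail: float = 16.0) -> int:
    last = max(t.onset + t.duration for t in events.trials)
    return int(np.ceil((last + tail) / tr))


def _second_stim_suppression(
    trial, truth: GroundTruth, tax: LinkTaxonomy, block: int
) -> float:
    if trial.oddball or trial.is_repeat:
        return 0.0
    cat = tax.category_of(trial.pair, trial.context)
    s = 0.0
    if cat is PairCategory.ASSOCIATED_BOTH:
        s += truth.delta_suppress
    if block == 2 and cat is PairCategory.HIDDEN:
        s += truth.kappa_couple * truth.gaba_drop
    return s


def simulate_bold(
    events: TrialSequence,
    patterns: Patterns,
    truth: GroundTruth,
    block: int,
    rng: np.random.Generator,
    roi_label: str = "aLOC",
    tax: Optional[LinkTaxonomy] = None,
    n_volumes: Optional[int] = None,
    bases: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> VoxelTimeSeries:
    """Forward-model one block: per trial, both stimulus patterns enter as
    an HRF-convolved delta at trial onset.

    The trial's combined response is the first stimulus's pattern plus the
    second's scaled by one minus the planted suppression; modeling both at
    the trial onset (the 300 ms gap is short on the HRF's timescale) keeps
    the forward model within the span of the trial-level GLM, so planted
    amplitude effects map onto contrasts exactly in the noiseless limit. In
    the hippocampus, unstable-pair trials add a spatially uniform response.
    Noise is AR(1) plus white plus linear drift.
    """
    if tax is None:
        raise ValueError("simulate_bold requires the subject's link taxonomy")
    tr = events.params.tr
    if n_volumes is None:
        n_volumes = n_volumes_for(events, tr)
    if bases is None:
        frame_times = np.arange(n_volumes) * tr
        onsets = np.array([t.onset for t in events.trials])
        X1 = _glm.hrf_regressors(onsets, frame_times)
    else:
        X1 = bases[0] if isinstance(bases, tuple) else bases
        if X1.shape != (n_volumes, len(events.trials)):
            raise ValueError("precomputed bases do not match events/volumes")

    idx1 = [patterns.conditions.index((t.stim_first, t.context)) for t in events.trials]
    idx2 = [patterns.conditions.index((t.stim_second, t.context)) for t in events.trials]
    a2 = np.array(
        [1.0 - _second_stim_suppression(t, truth, tax, block) for t in events.trials]
    )
    P1 = patterns.array[idx1]
    P2 = a2[:, None] * patterns.array[idx2]
    signal = X1 @ (P1 + P2)

    if roi_label == "hippocampus":
        boost = truth.beta_unstable + truth.hippo_slope * (
            truth.trait if block == 1 else truth.trait_b2
        )
        amp = np.array(
            [
                boost
                if (not t.oddball and not t.is_repeat and t.pair in tax.unstable)
                else 0.0
                for t in events.trials
            ]
        )
        signal = signal + (X1 @ amp)[:, None]

    V = truth.n_voxels
    if truth.noise_sd > 0:
        white = rng.standard_normal((n_volumes, V)) * truth.noise_sd
        noise = lfilter([1.0], [1.0, -truth.ar1_coef], white, axis=0)
    else:
        noise = 0.0
    if truth.drift_sd > 0:
        slopes = rng.standard_normal(V) * truth.drift_sd
        drift = np.linspace(-0.5, 0.5, n_volumes)[:, None] * slopes[None, :]
    else:
        drift = 0.0
    data = (signal + noise + drift).T
    return VoxelTimeSeries(data=np.ascontiguousarray(data), tr=tr, roi_label=roi_label)


# --------------------------------------------------------------------------
# Behavior

def simulate_behavior(
    rings: Tuple[RingStructure, RingStructure],
    truth: GroundTruth,
    rng: np.random.Generator,
    foil_fraction: float = 0.5,
) -> BehaviorData:
    """Training to criterion plus the no-feedback memory test.

    Training accuracy follows a saturating exposure curve; blocks continue
    until at least five are done and every association is at or above 90%
    within a block (capped with a warning). Memory-test choices come from
    a softmax over {correct, foil, other} in which the foil's utility is
    the participant's interference weight.
    """
    tax = link_taxonomy(*rings)
    block_acc: Dict[str, List[float]] = {}
    assoc_acc: Dict[str, List[np.ndarray]] = {}
    learning: Dict[str, float] = {}
    for ring in rings:
        links = sorted(ring.links)
        link_index = {p: k for k, p in enumerate(links)}
        exposures = np.full(len(links), float(truth.initial_exposures))
        accs: List[float] = []
        per_assoc: List[np.ndarray] = []
        while True:
            seed = int(rng.integers(0, 2**31 - 1))
            seq = generate_training_block(ring, seed=seed)
            pair_idx = np.array([link_index[t.pair] for t in seq.trials])
            # accuracy saturates with accumulated exposures (chance = 1/3)
            p = 1.0 - (2.0 / 3.0) * np.exp(-truth.learn_rate * exposures[pair_idx])
            correct = rng.random(len(seq.trials)) < p
            counts = np.bincount(pair_idx, minlength=len(links))
            hits = np.bincount(pair_idx, weights=correct.astype(float), minlength=len(links))
            acc_by_pair = hits / np.maximum(counts, 1)
            per_assoc.append(acc_by_pair)
            accs.append(float(correct.mean()))
            exposures += counts
            done = len(accs) >= 5 and np.all(acc_by_pair >= 0.9)
            if done:
                break
            if len(accs) >= truth.max_training_blocks:
                warnings.warn(
                    f"training did not converge within {truth.max_training_blocks} "
                    f"blocks for context {ring.context}",
                    stacklevel=2,
                )
                break
        block_acc[ring.context] = accs
        assoc_acc[ring.context] = per_assoc
        learning[ring.context] = max(accs)

    test_trials = generate_memory_test(
        tax, seed=int(rng.integers(0, 2**31 - 1)), foil_fraction=foil_fraction
    )
    U = np.zeros((len(test_trials), 3))
    for k, t in enumerate(test_trials):
        for o_i, o in enumerate(t.options):
            if o == t.correct_option:
                U[k, o_i] = truth.choice_strength
            elif o == t.foil_option:
                U[k, o_i] = truth.lambda_interfere
    P = np.exp(U - U.max(axis=1, keepdims=True))
    P /= P.sum(axis=1, keepdims=True)
    draws = rng.random(len(test_trials))
    picks = (draws[:, None] > np.cumsum(P, axis=1)).sum(axis=1)
    records: List[BehavioralRecord] = []
    for k, t in enumerate(test_trials):
        choice = t.options[min(int(picks[k]), 2)]
        if choice == t.correct_option:
            kind = "none"
        elif t.foil_option is not None and choice == t.foil_option:
            kind = "foil"
        else:
            kind = "other"
        records.append(
            BehavioralRecord(
                trial=t,
                response=choice,
                correct=choice == t.correct_option,
                error_kind=kind,
                context=t.context,
            )
        )

    acc = np.clip(
        rng.normal(truth.scan_accuracy_mean, truth.scan_accuracy_sd, size=2), 0.0, 1.0
    )
    if rng.random() < truth.low_scan_accuracy_fraction:
        acc[rng.integers(0, 2)] = rng.uniform(0.5, 0.79)
    return BehaviorData(
        training_block_accuracy=block_acc,
        training_assoc_accuracy=assoc_acc,
        learning_accuracy=learning,
        records=records,
        scan_accuracy=(float(acc[0]), float(acc[1])),
    )


# --------------------------------------------------------------------------
# MRS

def simulate_mrs(
    truth: GroundTruth,
    rng: np.random.Generator,
    inestimable: Optional[bool] = None,
) -> Tuple[List[MetaboliteMeasurement], bool]:
    """Three-timepoint metabolite ratios with the planted GABA dip.

    GABA:Cr at t2 (during stimulation) is the baseline minus the subject's
    realized drop; t3 returns to baseline. Glu:Cr rises at t3. Subjects
    flagged inestimable get a broadened linewidth (FWHM), mirroring
    lipid-contaminated spectra whose GABA fit fails.
    """
    if inestimable is None:
        inestimable = bool(rng.random() < truth.inestimable_fraction)
    fwhm_mu = 14.0 if inestimable else 10.0
    out: List[MetaboliteMeasurement] = []
    for tp in ("t1", "t2", "t3"):
        for met in METABOLITES:
            base = _BASELINE_RATIOS[met]
            if met == "GABA":
                ratio = truth.gaba_baseline + rng.normal(0.0, truth.mrs_noise_sd)
                if tp == "t2":
                    ratio -= truth.gaba_drop
                crlb = float(np.clip(rng.normal(15.0, 4.0), 2.0, None))
            elif met == "Glu":
                ratio = truth.glu_baseline + rng.normal(0.0, 5 * truth.mrs_noise_sd)
                if tp == "t3":
                    ratio += truth.glu_rise
                crlb = float(np.clip(rng.normal(4.0, 1.5), 1.0, None))
            else:
                ratio = base * (1.0 + rng.normal(0.0, 0.03))
                crlb = float(np.clip(rng.normal(8.0, 3.0), 1.0, None))
            out.append(
                MetaboliteMeasurement(
                    timepoint=tp,
                    metabolite=met,
                    ratio=float(max(ratio, 1e-6)),
                    crlb=crlb,
                    fwhm=float(rng.normal(fwhm_mu, 1.0)),
                )
            )
    return out, inestimable


# --------------------------------------------------------------------------
# Subjects and cohorts

def realize_subject_truth(
    truth: GroundTruth, rng: np.random.Generator
) -> GroundTruth:
    """Draw one participant's parameters from the cohort-level truth.

    A single standard-normal interference trait drives the GABA drop, the
    foil weight, the memory strength, and the block-1 hippocampal response;
    block 2's hippocampal coupling uses an independent trait, so only
    block 1 predicts behavior.
    """
    q = float(rng.standard_normal())
    q2 = float(rng.standard_normal())
    return replace(
        truth,
        trait=q,
        trait_b2=q2,
        gaba_drop=truth.gaba_drop + truth.gaba_drop_sd * q,
        lambda_interfere=truth.lambda_interfere + truth.lambda_slope * q,
        choice_strength=truth.choice_strength - truth.strength_slope * q,
    )


def simulate_subject(
    truth: GroundTruth,
    seed,
    subject_id: int = 0,
    params: Optional[DesignParams] = None,
    base_order: Sequence[int] = (1, 2, 3, 4, 5, 6, 7),
    swap: Tuple[int, int] = (3, 6),
    randomize_rings: bool = True,
    foil_fraction: float = 0.5,
    rois: Sequence[str] = ROI_LABELS,
) -> SyntheticSubject:
    """Generate one participant: rings, events, BOLD, behavior, metabolites."""
    params = params or DesignParams()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    if randomize_rings:
        # randomize which stimulus occupies which ring position by a label
        # bijection, so the swapped pair keeps its structural role (ring
        # distance 3) and the taxonomy's category counts are preserved
        labels = list(base_order)
        sigma = dict(zip(labels, (int(x) for x in rng.permutation(labels))))
        order = tuple(sigma[s] for s in base_order)
        swap = (sigma[swap[0]], sigma[swap[1]])
    else:
        order = tuple(int(s) for s in base_order)
    rings = build_memory_rings(order, swap)
    tax = link_taxonomy(*rings)
    truth_r = realize_subject_truth(truth, rng)

    events = {
        b: generate_scan_block(
            tax, params, seed=int(rng.integers(0, 2**31 - 1)), block=b
        )
        for b in (1, 2)
    }
    bases: Dict[int, np.ndarray] = {}
    n_vols: Dict[int, int] = {}
    for b in (1, 2):
        n_vols[b] = n_volumes_for(events[b], params.tr)
        frame_times = np.arange(n_vols[b]) * params.tr
        onsets = np.array([t.onset for t in events[b].trials])
        bases[b] = _glm.hrf_regressors(onsets, frame_times)
    bold: Dict[Tuple[str, int], VoxelTimeSeries] = {}
    for roi in rois:
        patterns = simulate_patterns(truth_r, tax, rng)
        for b in (1, 2):
            bold[(roi, b)] = simulate_bold(
                events[b], patterns, truth_r, b, rng, roi_label=roi, tax=tax,
                n_volumes=n_vols[b], bases=bases[b],
            )
    behavior = simulate_behavior(rings, truth_r, rng, foil_fraction=foil_fraction)
    mrs, inest = simulate_mrs(truth_r, rng)
    return SyntheticSubject(
        subject_id=subject_id,
        seed=tuple(ss.spawn_key) if ss.spawn_key else (int(ss.entropy),),
        truth=truth_r,
        rings=rings,
        tax=tax,
        events=events,
        bold=bold,
        behavior=behavior,
        mrs=mrs,
        gaba_inestimable=inest,
    )


def simulate_cohort(
    n: int,
    truth: GroundTruth,
    master_seed: int,
    **subject_kwargs,
) -> List[SyntheticSubject]:
    """Simulate ``n`` participants on independent seed substreams."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    root = np.random.SeedSequence(master_seed)
    return [
        simulate_subject(truth, child, subject_id=i, **subject_kwargs)
        for i, child in enumerate(root.spawn(n))
    ]
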
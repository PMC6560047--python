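"""Trial-sequence generators for the scan, training, and memory-test blocks.

The scan block presents every unordered non-repeating stimulus pair 4 times
per context and every repeating pair twice per context (196 trials at the
defaults), with rotations counterbalanced so each stimulus is seen equally
often at each of its four rotations, and inter-trial intervals drawn from a
truncated gamma distribution. Training blocks are 100-trial three-alternative
forced-choice runs probing each ring association at least 14 times. The
memory test is a 100-trial no-feedback variant split evenly between the two
contexts, in which a configurable fraction of trials carry a "foil" option:
a stimulus that is wrong in the cued context but correct in the alternative
one — choosing it is the behavioral signature of memory interference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .rings import (
    CONTEXTS,
    LinkTaxonomy,
    RingStructure,
    canonical_pair,
)

ROTATIONS = (0, 90, 180, 270)


@dataclass(frozen=True)
class DesignParams:
    """Timing and counterbalancing parameters of the scan task.

    Units are seconds throughout. The inter-trial interval follows a gamma
    distribution with fixed shape ``iti_shape`` truncated to
    [``iti_min``, ``iti_max``]; the scale is solved numerically so the
    truncated mean equals ``iti_mean``.
    """

    tr: float = 1.512
    stim_duration: float = 0.8
    isi: float = 0.3
    iti_mean: float = 2.9
    iti_min: float = 1.5
    iti_max: float = 9.7
    iti_shape: float = 4.0
    oddball_rate: float = 0.07
    nonrepeat_reps_per_context: int = 4
    repeat_reps_per_context: int = 2

    def __post_init__(self) -> None:
        if not (self.iti_min < self.iti_mean < self.iti_max):
            raise ValueError("require iti_min < iti_mean < iti_max")
        if not 0.0 <= self.oddball_rate < 1.0:
            raise ValueError("oddball_rate must be in [0, 1)")

    @property
    def trial_span(self) -> float:
        """Stimulus-on span of one trial: two stimuli plus the gap between."""
        return 2 * self.stim_duration + self.isi


@dataclass
class Trial:
    """One scan-task trial: two consecutively presented stimuli in a context."""

    onset: float
    context: str
    stim_first: int
    rot_first: int
    stim_second: int
    rot_second: int
    pair: Tuple[int, int]
    is_repeat: bool
    oddball: bool
    block: int
    duration: float
    category_current: Optional[str] = None


@dataclass
class TrainingTrial:
    """Three-alternative forced-choice training trial with feedback."""

    probe: int
    context: str
    options: Tuple[int, int, int]
    correct_option: int
    pair: Tuple[int, int]


@dataclass
class MemoryTestTrial:
    """Surprise-memory-test trial; may carry a cross-context foil option."""

    probe: int
    context: str
    options: Tuple[int, int, int]
    correct_option: int
    foil_option: Optional[int]
    is_foil_trial: bool


@dataclass
class TrialSequence:
    trials: list
    kind: str  # {"scan", "training", "memory_test"}
    params: DesignParams
    block: int = 1

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        if self.kind != "scan":
            return pd.DataFrame([t.__dict__ for t in self.trials])
        rows = []
        for t in self.trials:
            rows.append(
                {
                    "onset": t.onset,
                    "duration": t.duration,
                    "context": t.context,
                    "stim_first": t.stim_first,
                    "rot_first": t.rot_first,
                    "stim_second": t.stim_second,
                    "rot_second": t.rot_second,
                    "pair": f"{t.pair[0]}-{t.pair[1]}",
                    "category_current": t.category_current or "",
                    "is_repeat": t.is_repeat,
                    "oddball": t.oddball,
                    "block": t.block,
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, params: Optional[DesignParams] = None) -> "TrialSequence":
        df = pd.read_csv(path, sep="\t")
        required = {"onset", "duration", "context", "stim_first", "stim_second", "pair"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"events table missing required columns: {sorted(missing)}")
        params = params or DesignParams()
        trials = []
        for _, r in df.iterrows():
            a, b = (int(x) for x in str(r["pair"]).split("-"))
            trials.append(
                Trial(
                    onset=float(r["onset"]),
                    context=str(r["context"]),
                    stim_first=int(r["stim_first"]),
                    rot_first=int(r.get("rot_first", 0)),
                    stim_second=int(r["stim_second"]),
                    rot_second=int(r.get("rot_second", 0)),
                    pair=(a, b),
                    is_repeat=bool(r.get("is_repeat", a == b)),
                    oddball=bool(r.get("oddball", False)),
                    block=int(r.get("block", 1)),
                    duration=float(r["duration"]),
                    category_current=str(r.get("category_current", "")) or None,
                )
            )
        return cls(trials=trials, kind="scan", params=params)


# --------------------------------------------------------------------------
# Inter-trial intervals: gamma with fixed shape, truncated, mean-matched.

def _truncated_gamma_mean(shape: float, scale: float, lo: float, hi: float) -> float:
    g = sps.gamma(a=shape, scale=scale)
    gp = sps.gamma(a=shape + 1.0, scale=scale)
    mass = g.cdf(hi) - g.cdf(lo)
    if mass <= 1e-300:
        # degenerate truncation: essentially all mass on one side
        return lo if g.cdf(lo) > 0.5 else hi
    # E[X; lo<X<hi] = shape*scale * (F_{k+1}(hi) - F_{k+1}(lo))
    return shape * scale * (gp.cdf(hi) - gp.cdf(lo)) / mass


def solve_iti_scale(params: DesignParams) -> float:
    """Scale of the gamma ITI distribution matching the truncated mean."""

    def f(scale: float) -> float:
        return _truncated_gamma_mean(
            params.iti_shape, scale, params.iti_min, params.iti_max
        ) - params.iti_mean

    lo, hi = 1e-3, 50.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("iti_mean is unreachable given the truncation bounds")
    return optimize.brentq(f, lo, hi, xtol=1e-10)


_SCALE_CACHE: dict = {}


def sample_iti(params: DesignParams, rng: np.random.Generator, size=None):
    """Draw ITIs by rejection from the truncated gamma distribution."""
    key = (params.iti_shape, params.iti_mean, params.iti_min, params.iti_max)
    scale = _SCALE_CACHE.get(key)
    if scale is None:
        scale = _SCALE_CACHE[key] = solve_iti_scale(params)
    n = 1 if size is None else int(size)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.gamma(params.iti_shape, scale, size=max(2 * (n - filled), 16))
        ok = draw[(draw >= params.iti_min) & (draw <= params.iti_max)]
        take = min(ok.size, n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return float(out[0]) if size is None else out


# --------------------------------------------------------------------------
# Scan block

def generate_scan_block(
    tax: LinkTaxonomy,
    params: DesignParams,
    seed: int,
    block: int = 1,
) -> TrialSequence:
    """Generate one fully randomized, counterbalanced scan block.

    At the defaults this yields 21x4x2 + 7x2x2 = 196 trials; each stimulus
    occurs in 52 trials, 13 at each rotation. Oddballs are inserted at
    ``params.oddball_rate`` (flagging existing trials; the trial count is
    unchanged). Raises if the per-stimulus occurrence counts are not
    divisible by four, in which case exact rotation balancing is infeasible.
    """
    rng = np.random.default_rng(seed)
    stimuli = tax.stimuli

    slots: List[Tuple[str, Tuple[int, int], bool]] = []
    for context in CONTEXTS:
        for pair in tax.all_pairs:
            slots.extend([(context, pair, False)] * params.nonrepeat_reps_per_context)
        for s in stimuli:
            slots.extend([(context, (s, s), True)] * params.repeat_reps_per_context)

    occurrences = {s: 0 for s in stimuli}
    for _, pair, is_repeat in slots:
        occurrences[pair[0]] += 1
        if not is_repeat:
            occurrences[pair[1]] += 1
    for s, count in occurrences.items():
        if count % len(ROTATIONS):
            raise ValueError(
                f"rotation balancing infeasible: stimulus {s} occurs {count} "
                f"times, not divisible by {len(ROTATIONS)}"
            )

    rotation_queue = {}
    for s, count in occurrences.items():
        rots = np.repeat(ROTATIONS, count // len(ROTATIONS))
        rng.shuffle(rots)
        rotation_queue[s] = list(rots)

    order = rng.permutation(len(slots))
    itis = sample_iti(params, rng, size=len(slots))
    trials = []
    t = itis[0]
    for k, idx in enumerate(order):
        context, pair, is_repeat = slots[idx]
        if is_repeat:
            first = second = pair[0]
            rot_first = rot_second = rotation_queue[first].pop()
        else:
            first, second = pair if rng.random() < 0.5 else (pair[1], pair[0])
            rot_first = rotation_queue[first].pop()
            rot_second = rotation_queue[second].pop()
        category = None if is_repeat else tax.category_of(pair, context).value
        trials.append(
            Trial(
                onset=float(t),
                context=context,
                stim_first=first,
                rot_first=int(rot_first),
                stim_second=second,
                rot_second=int(rot_second),
                pair=pair,
                is_repeat=is_repeat,
                oddball=False,
                block=block,
                duration=params.trial_span,
                category_current=category,
            )
        )
        if k + 1 < len(order):
            t += params.trial_span + itis[k + 1]

    seq = TrialSequence(trials=trials, kind="scan", params=params, block=block)
    if params.oddball_rate > 0:
        # keep at least one modelable trial per pair-x-context cell so the
        # pairwise GLM never loses a regressor to oddball routing
        for _ in range(50):
            cand = insert_oddballs(seq, params.oddball_rate, rng)
            kept = {(t.context, t.pair) for t in cand.trials if not t.oddball and not t.is_repeat}
            needed = {(c, p) for c in CONTEXTS for p in tax.all_pairs}
            if needed <= kept:
                seq = cand
                break
        else:  # pragma: no cover - vanishingly unlikely
            raise RuntimeError("could not place oddballs without emptying a design cell")
    return seq


def insert_oddballs(
    seq: TrialSequence, rate: float, rng: np.random.Generator
) -> TrialSequence:
    """Flag round(rate * n) trials as oddball trials.

    An oddball replaces one of the trial's stimuli with a shape outside the
    trained set, so flagged trials are routed to nuisance regressors
    downstream; onsets and the trial count are unchanged.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    n = len(seq.trials)
    k = int(round(rate * n))
    if k == 0:
        return seq
    chosen = set(rng.choice(n, size=k, replace=False).tolist())
    trials = [
        replace_trial(t, oddball=True) if i in chosen else t
        for i, t in enumerate(seq.trials)
    ]
    return TrialSequence(trials=trials, kind=seq.kind, params=seq.params, block=seq.block)


def replace_trial(trial: Trial, **kw) -> Trial:
    d = dict(trial.__dict__)
    d.update(kw)
    return Trial(**d)


# --------------------------------------------------------------------------
# Training block

def generate_training_block(
    ring: RingStructure, seed: int, n_trials: int = 100, min_per_pair: int = 14
) -> TrialSequence:
    """100-trial three-alternative forced-choice block for one memory.

    Each of the ring's associated pairs is probed at least ``min_per_pair``
    times; the remaining trials probe uniformly random associations. Each
    trial offers the probe's ring neighbor plus two stimuli not associated
    with the probe.
    """
    rng = np.random.default_rng(seed)
    links = sorted(ring.links)
    if n_trials < min_per_pair * len(links):
        raise ValueError("n_trials too small to probe every pair min_per_pair times")
    pair_ids = list(range(len(links))) * min_per_pair
    pair_ids += rng.integers(0, len(links), size=n_trials - len(pair_ids)).tolist()
    rng.shuffle(pair_ids)

    stimuli = sorted(ring.stimuli)
    non_assoc = {
        s: [x for x in stimuli if x != s and x not in ring.neighbors(s)]
        for s in stimuli
    }
    m = len(stimuli) - 3  # non-associated candidates per probe on a cycle
    if m < 2:
        raise ValueError("ring too small for two non-associated lures")
    lure_pairs = [(a, b) for a in range(m) for b in range(m) if a != b]
    sides = rng.random(n_trials) < 0.5
    lure_idx = rng.integers(0, len(lure_pairs), size=n_trials)
    slot = rng.integers(0, 3, size=n_trials)  # position of the correct option
    trials = []
    for k, pid in enumerate(pair_ids):
        pair = links[pid]
        probe, correct = pair if sides[k] else (pair[1], pair[0])
        ia, ib = lure_pairs[lure_idx[k]]
        cands = non_assoc[probe]
        options = [cands[ia], cands[ib]]
        options.insert(slot[k], correct)
        trials.append(
            TrainingTrial(
                probe=probe,
                context=ring.context,
                options=tuple(options),
                correct_option=correct,
                pair=pair,
            )
        )
    return TrialSequence(trials=trials, kind="training", params=DesignParams())


# --------------------------------------------------------------------------
# Memory test

def _foil_candidates(tax: LinkTaxonomy, probe: int, context: str) -> list:
    own = tax.ring(context).neighbors(probe)
    alt = tax.other_ring(context).neighbors(probe)
    return sorted(alt - own)


def generate_memory_test(
    tax: LinkTaxonomy,
    seed: int,
    foil_fraction: float = 0.5,
    n_trials: int = 100,
) -> List[MemoryTestTrial]:
    """No-feedback memory test: ``n_trials`` trials, half per context.

    Every association of each context is probed at least
    ``n_trials // (2 * n_links)`` times. Where the probe admits a foil (a
    stimulus correct only in the alternative context), the trial is made a
    foil trial with probability ``foil_fraction``.
    """
    if not 0.0 <= foil_fraction <= 1.0:
        raise ValueError("foil_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    per_context = n_trials // 2
    stimuli = sorted(tax.ring1.stimuli)
    trials: List[MemoryTestTrial] = []
    for context in CONTEXTS:
        ring = tax.ring(context)
        links = sorted(ring.links)
        base = n_trials // (2 * len(links))
        pair_ids = list(range(len(links))) * base
        pair_ids += rng.integers(0, len(links), size=per_context - len(pair_ids)).tolist()
        rng.shuffle(pair_ids)
        for pid in pair_ids:
            pair = links[pid]
            probe, correct = pair if rng.random() < 0.5 else (pair[1], pair[0])
            foils = _foil_candidates(tax, probe, context)
            never = [
                s
                for s in stimuli
                if s != probe
                and s not in ring.neighbors(probe)
                and s not in tax.other_ring(context).neighbors(probe)
            ]
            make_foil = bool(foils) and rng.random() < foil_fraction
            if make_foil:
                foil = int(rng.choice(foils))
                third = int(rng.choice(never))
                options = [correct, foil, third]
            else:
                foil = None
                lures = rng.choice(never, size=2, replace=False)
                options = [correct, int(lures[0]), int(lures[1])]
            rng.shuffle(options)
            trials.append(
                MemoryTestTrial(
                    probe=probe,
                    context=context,
                    options=tuple(options),
                    correct_option=correct,
                    foil_option=foil,
                    is_foil_trial=foil is not None,
                )
            )
    idx = rng.permutation(len(trials))
    return [trials[i] for i in idx]


def flag_foil_trials(trial: MemoryTestTrial, tax: LinkTaxonomy) -> bool:
    """True iff an option is a ring neighbor of the probe only in the
    alternative context (independent of how the trial was constructed)."""
    own = tax.ring(trial.context).neighbors(trial.probe)
    alt = tax.other_ring(trial.context).neighbors(trial.probe)
    return any(opt in alt and opt not in own for opt in trial.options)
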
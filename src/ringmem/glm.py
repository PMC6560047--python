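"""Event-related design matrices, OLS fitting, and the principal contrasts.

Two model kinds are supported, mirroring the two analyses the pipeline
runs. The *pairwise* model has one regressor per unordered stimulus pair
per context (42 for seven stimuli), plus four nuisance regressors
(repeat/oddball x context) and optional motion columns; it feeds the
univariate contrasts. The *trialwise* model has one regressor per trial
and feeds the representational similarity analysis. Events are modeled as
delta functions at trial onset convolved with the canonical SPM
double-gamma hemodynamic response. Low-frequency drift is removed by
regressing a discrete-cosine basis (128 s cutoff by default) out of both
the data and the design before the least-squares fit.

The three principal contrasts:

- ``expression``   — unassociated-in-both minus associated-in-both pairs:
  cross-stimulus suppression as an index of memory expression.
- ``interference`` — unassociated-in-both (control) minus hidden pairs
  (associated only in the alternative context): larger values mean more
  suppression on hidden pairs, i.e. more neural memory interference.
- ``opportunity``  — unstable minus stable pairs: the BOLD increase on
  trials where the two memories conflict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from nilearn.glm.first_level.hemodynamic_models import spm_hrf
from scipy.linalg import solve_triangular

from .design import TrialSequence
from .rings import CONTEXTS, LinkTaxonomy, PairCategory

# Canonical double-gamma HRF sampled on a fine grid; normalized to unit
# peak so fitted betas are on the scale of the simulated response amplitudes.
_HRF_DT = 0.05
_HRF_LENGTH = 32.0
_HRF = spm_hrf(_HRF_DT, oversampling=1, time_length=_HRF_LENGTH)
_HRF = _HRF / _HRF.max()
_HRF_T = np.arange(_HRF.size) * _HRF_DT


def hrf(t: np.ndarray) -> np.ndarray:
    """Canonical HRF evaluated at times ``t`` (seconds); zero outside [0, 32]."""
    return np.interp(t, _HRF_T, _HRF, left=0.0, right=0.0)


def hrf_regressors(onsets: np.ndarray, frame_times: np.ndarray) -> np.ndarray:
    """Matrix (n_frames, n_onsets) of delta-function events convolved with
    the HRF: column j is the response to a unit event at ``onsets[j]``."""
    return hrf(frame_times[:, None] - np.asarray(onsets)[None, :])


def dct_highpass_basis(n_volumes: int, tr: float, cutoff: float) -> np.ndarray:
    """Constant plus discrete-cosine drift regressors below 1/cutoff Hz."""
    T = n_volumes * tr
    k_max = int(np.floor(2.0 * T / cutoff))
    t = (np.arange(n_volumes) + 0.5) / n_volumes
    cols = [np.ones(n_volumes)]
    for k in range(1, k_max + 1):
        cols.append(np.cos(np.pi * k * t))
    return np.column_stack(cols)


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # volumes x regressors
    labels: List[str]
    tr: float
    highpass_cutoff: float
    model_kind: str  # {"pairwise", "trialwise"}

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.matrix[:, self.labels.index(label)]


def pair_label(pair: Tuple[int, int], context: str) -> str:
    return f"pair_{pair[0]}-{pair[1]}_{context}"


def build_design_matrix(
    events: TrialSequence,
    model_kind: str,
    tr: float,
    n_volumes: int,
    motion: Optional[np.ndarray] = None,
    highpass_cutoff: float = 128.0,
) -> DesignMatrix:
    """Build the pairwise or trialwise design for one scan block."""
    frame_times = np.arange(n_volumes) * tr
    onsets = np.array([t.onset for t in events.trials])
    if onsets.size and onsets.max() >= n_volumes * tr:
        raise ValueError(
            f"trial onset {onsets.max():.1f}s beyond scan end {n_volumes * tr:.1f}s"
        )

    per_event = hrf_regressors(onsets, frame_times)

    cols: List[np.ndarray] = []
    labels: List[str] = []
    if model_kind == "pairwise":
        groups: Dict[str, List[int]] = {}
        pairs = sorted(
            {t.pair for t in events.trials if not t.is_repeat}
        )
        for context in CONTEXTS:
            for pair in pairs:
                groups[pair_label(pair, context)] = []
        for context in CONTEXTS:
            groups[f"repeat_{context}"] = []
            groups[f"oddball_{context}"] = []
        for i, t in enumerate(events.trials):
            if t.oddball:
                key = f"oddball_{t.context}"
            elif t.is_repeat:
                key = f"repeat_{t.context}"
            else:
                key = pair_label(t.pair, t.context)
            groups[key].append(i)
        for label, idx in groups.items():
            labels.append(label)
            cols.append(
                per_event[:, idx].sum(axis=1) if idx else np.zeros(n_volumes)
            )
        # a category with no events would make the design singular
        empty = [l for l, c in zip(labels, cols) if not np.any(c)]
        for l in empty:
            i = labels.index(l)
            labels.pop(i)
            cols.pop(i)
    elif model_kind == "trialwise":
        for i in range(len(events.trials)):
            labels.append(f"trial_{events.trials[i].block:02d}_{i:03d}")
            cols.append(per_event[:, i])
    else:
        raise ValueError(f"unknown model_kind {model_kind!r}")

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (n_volumes, 6):
            raise ValueError("motion must be a volumes x 6 matrix")
        for j in range(6):
            labels.append(f"motion_{j + 1}")
            cols.append(motion[:, j])

    if len(set(labels)) != len(labels):
        raise ValueError("duplicate regressor labels")
    return DesignMatrix(
        matrix=np.column_stack(cols),
        labels=labels,
        tr=tr,
        highpass_cutoff=highpass_cutoff,
        model_kind=model_kind,
    )


@dataclass
class GlmFit:
    betas: np.ndarray  # regressors x voxels
    residuals: np.ndarray  # volumes x voxels
    dof: int
    labels: List[str]

    def beta(self, label: str) -> np.ndarray:
        return self.betas[self.labels.index(label)]


def fit_glm(bold, design: DesignMatrix, compute_residuals: bool = True) -> GlmFit:
    """Ordinary least squares after high-pass filtering data and design.

    Raises a ``ValueError`` naming the collinear columns if the filtered
    design is rank deficient. ``compute_residuals=False`` skips the
    residual matrix (an empty array is stored) when only betas are needed.
    """
    Y = np.asarray(bold.data, dtype=float).T  # volumes x voxels
    X = np.asarray(design.matrix, dtype=float)
    if Y.shape[0] != X.shape[0]:
        raise ValueError(
            f"BOLD has {Y.shape[0]} volumes but design has {X.shape[0]} rows"
        )
    F = dct_highpass_basis(X.shape[0], design.tr, design.highpass_cutoff)
    Qf, _ = np.linalg.qr(F)
    Xf = X - Qf @ (Qf.T @ X)
    Yf = Y - Qf @ (Qf.T @ Y)

    Q, R = np.linalg.qr(Xf)
    diag = np.abs(np.diag(R))
    tol = max(Xf.shape) * np.finfo(float).eps * max(diag.max(), 1.0)
    if diag.min() <= max(tol, 1e-10 * diag.max()):
        bad = [design.labels[j] for j in np.nonzero(diag <= max(tol, 1e-10 * diag.max()))[0]]
        raise ValueError(f"rank-deficient design; collinear columns include {bad}")
    betas = solve_triangular(R, Q.T @ Yf)
    if compute_residuals:
        residuals = Yf - Xf @ betas
    else:
        residuals = np.empty((0, Yf.shape[1]))
    dof = X.shape[0] - X.shape[1] - F.shape[1]
    return GlmFit(betas=betas, residuals=residuals, dof=dof, labels=list(design.labels))


# --------------------------------------------------------------------------
# Contrasts

@dataclass
class ContrastSpec:
    name: str
    weights: Dict[str, float]

    def vector(self, labels: Sequence[str]) -> np.ndarray:
        missing = [l for l in self.weights if l not in labels]
        if missing:
            raise ValueError(f"contrast labels missing from fit: {missing}")
        w = np.zeros(len(labels))
        for l, v in self.weights.items():
            w[list(labels).index(l)] = v
        return w


@dataclass
class ContrastResult:
    name: str
    values: np.ndarray  # per voxel
    roi_mean: float
    block: Optional[int] = None
    subject: Optional[int] = None


def _mean_weights(pos, neg) -> Dict[str, float]:
    w = {l: 1.0 / len(pos) for l in pos}
    w.update({l: -1.0 / len(neg) for l in neg})
    return w


def contrast_specs(
    tax: LinkTaxonomy, interference_context: Optional[str] = None
) -> Dict[str, ContrastSpec]:
    """The three principal contrasts over pair-x-context regressors.

    ``interference_context`` restricts the interference contrast to one
    context; the default pools both.
    """
    def labels(category: PairCategory, contexts=CONTEXTS):
        out = []
        for c in contexts:
            out.extend(pair_label(p, c) for p in sorted(tax.pairs_in(category, c)))
        return out

    unassoc = labels(PairCategory.UNASSOCIATED_BOTH)
    assoc = labels(PairCategory.ASSOCIATED_BOTH)
    if not unassoc or not assoc:
        raise ValueError("empty contrast category")
    expression = ContrastSpec("expression", _mean_weights(unassoc, assoc))

    ctxs = CONTEXTS if interference_context is None else (interference_context,)
    hid = labels(PairCategory.HIDDEN, ctxs)
    una = labels(PairCategory.UNASSOCIATED_BOTH, ctxs)
    if not hid:
        raise ValueError("empty contrast category: no hidden pairs")
    interference = ContrastSpec("interference", _mean_weights(una, hid))

    unstable = [
        pair_label(p, c) for c in CONTEXTS for p in sorted(tax.unstable)
    ]
    stable = [
        pair_label(p, c) for c in CONTEXTS for p in sorted(tax.stable_pairs())
    ]
    if not unstable or not stable:
        raise ValueError("empty contrast category for opportunity contrast")
    opportunity = ContrastSpec("opportunity", _mean_weights(unstable, stable))
    return {
        "expression": expression,
        "interference": interference,
        "opportunity": opportunity,
    }


def compute_contrast(
    fit: GlmFit,
    spec: ContrastSpec,
    roi_mask: Optional[np.ndarray] = None,
    block: Optional[int] = None,
    subject: Optional[int] = None,
) -> ContrastResult:
    """Voxelwise weighted combination of betas plus its ROI mean."""
    w = spec.vector(fit.labels)
    values = w @ fit.betas
    if roi_mask is None:
        roi = values
    else:
        roi = values[np.asarray(roi_mask)]
    return ContrastResult(
        name=spec.name,
        values=values,
        roi_mean=float(roi.mean()),
        block=block,
        subject=subject,
    )
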
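"""Noise-normalized representational similarity analysis.

Trial-level activity patterns (betas from the trialwise GLM) are whitened
by a shrinkage estimate of the voxel noise covariance; pairwise pattern
dissimilarities form a trial RDM, which is pooled into a 14-condition
(7 stimuli x 2 contexts) RDM where each condition collects all trials of a
context that contain the stimulus. Two model RDMs are tested against the
condition RDM with the Kendall tau-a rank correlation:

- *context separation*: within-context cells 0, between-context cells 1 —
  evidence that the two memories are pattern separated by context;
- *relational separation*: among the cross-context same-stimulus cells,
  swapped stimuli 1, all others 0 (remaining cells masked) — evidence that
  separation is largest for the stimuli whose ring position differs.

Group inference on the per-subject coefficients uses a two-sided Wilcoxon
signed-rank test (exact null for small samples, normal approximation with
continuity correction otherwise).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular

from .rings import CONTEXTS


# --------------------------------------------------------------------------
# Noise covariance

def estimate_noise_covariance(
    residuals: np.ndarray, shrinkage="auto"
) -> np.ndarray:
    """Shrinkage covariance of GLM residuals, shrunk toward its diagonal.

    ``shrinkage`` is a fraction in [0, 1] or ``"auto"``, in which case the
    analytic optimal intensity for a diagonal target (Schafer & Strimmer
    style) is used: the ratio of the summed sampling variances of the
    off-diagonal entries to their summed squares.
    """
    X = np.asarray(residuals, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("residuals must be a volumes x voxels matrix with >= 2 rows")
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    S = (Xc.T @ Xc) / (n - 1)
    if shrinkage == "auto":
        wbar = S * (n - 1) / n
        sq = ((Xc**2).T @ (Xc**2)) / n
        var_s = (n / float((n - 1) ** 3)) * (sq - wbar**2) * n
        off = ~np.eye(S.shape[0], dtype=bool)
        denom = float((S[off] ** 2).sum())
        lam = 1.0 if denom == 0 else float(np.clip(var_s[off].sum() / denom, 0.0, 1.0))
    else:
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("shrinkage must be in [0, 1]")
    sigma = (1.0 - lam) * S + lam * np.diag(np.diag(S))
    # guard against numerically semi-definite output
    eps = 1e-10 * float(np.trace(sigma)) / sigma.shape[0]
    sigma[np.diag_indices_from(sigma)] += eps
    return sigma


# --------------------------------------------------------------------------
# Trial RDM

@dataclass
class RDM:
    matrix: np.ndarray
    trial_info: pd.DataFrame  # columns: stim_first, stim_second, context, oddball
    distance_kind: str  # {"mahalanobis", "whitened_correlation"}


def whiten_patterns(patterns: np.ndarray, noise_cov: np.ndarray) -> np.ndarray:
    """Multiply patterns (trials x voxels) by the inverse Cholesky factor of
    the noise covariance (multivariate noise normalization)."""
    if noise_cov.shape[0] != patterns.shape[1]:
        raise ValueError("noise covariance dimension must match voxel count")
    try:
        L = cholesky(noise_cov, lower=True)
    except np.linalg.LinAlgError as e:  # pragma: no cover
        raise ValueError("singular noise covariance; increase shrinkage") from e
    return solve_triangular(L, patterns.T, lower=True).T


def trial_rdm(
    trial_betas: np.ndarray,
    noise_cov: np.ndarray,
    trial_info: pd.DataFrame,
    distance_kind: str = "whitened_correlation",
) -> RDM:
    """Pairwise dissimilarities between noise-normalized trial patterns.

    ``mahalanobis`` is the Euclidean distance between whitened patterns;
    ``whitened_correlation`` is one minus their Pearson correlation.
    """
    W = whiten_patterns(np.asarray(trial_betas, dtype=float), noise_cov)
    if distance_kind == "mahalanobis":
        sq = np.sum(W**2, axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (W @ W.T)
        D = np.sqrt(np.clip(d2, 0.0, None))
    elif distance_kind == "whitened_correlation":
        D = 1.0 - np.corrcoef(W)
    else:
        raise ValueError(f"unknown distance_kind {distance_kind!r}")
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return RDM(matrix=D, trial_info=trial_info.reset_index(drop=True),
               distance_kind=distance_kind)


# --------------------------------------------------------------------------
# Condition averaging

def condition_labels(stimuli: Sequence[int] = range(1, 8)) -> List[Tuple[int, str]]:
    return [(int(s), c) for c in CONTEXTS for s in stimuli]


@dataclass
class ConditionRDM:
    matrix: np.ndarray  # 14 x 14
    conditions: List[Tuple[int, str]]

    def cross_context(self) -> np.ndarray:
        """7x7 block of memory1 stimuli (rows) x memory2 stimuli (columns)."""
        n = len(self.conditions) // 2
        return self.matrix[:n, n:]


def condition_average_rdm(rdm: RDM, exclude_same_pair: bool = True) -> ConditionRDM:
    """Average the trial RDM into stimulus-x-context conditions.

    A condition pools every non-oddball trial of its context that contains
    the stimulus (in either presentation position, including repeats, which
    contribute once). Trial self-pairs are always excluded. By default,
    pairs of trials presenting the *same unordered stimulus pair* are also
    excluded: a trial's self-pair can only occur in within-context cells,
    so dropping self-pairs alone deflates within-context dissimilarity
    relative to between-context cells; excluding identical-content pairs
    everywhere restores the symmetry (within- and between-context cells
    then average over the same population of stimulus pairings).
    ``exclude_same_pair=False`` gives the plain self-pair-only exclusion.
    """
    info = rdm.trial_info
    stimuli = sorted(
        set(info["stim_first"].tolist()) | set(info["stim_second"].tolist())
    )
    conds = condition_labels(stimuli)
    T = len(info)
    M = np.zeros((T, len(conds)))
    usable = ~info["oddball"].to_numpy(dtype=bool)
    for j, (s, c) in enumerate(conds):
        member = (
            usable
            & (info["context"] == c).to_numpy()
            & (
                (info["stim_first"] == s).to_numpy()
                | (info["stim_second"] == s).to_numpy()
            )
        )
        M[:, j] = member
    counts = M.sum(axis=0)
    if np.any(counts == 0):
        empty = [conds[j] for j in np.nonzero(counts == 0)[0]]
        raise ValueError(f"empty conditions: {empty}")
    if exclude_same_pair:
        lo = np.minimum(info["stim_first"].to_numpy(), info["stim_second"].to_numpy())
        hi = np.maximum(info["stim_first"].to_numpy(), info["stim_second"].to_numpy())
        content = lo * 1000 + hi
        include = (content[:, None] != content[None, :]).astype(float)
    else:
        include = 1.0 - np.eye(T)
    num = M.T @ (rdm.matrix * include) @ M
    n_pairs = M.T @ include @ M
    with np.errstate(invalid="ignore", divide="ignore"):
        matrix = np.where(n_pairs > 0, num / np.where(n_pairs > 0, n_pairs, 1), np.nan)
    return ConditionRDM(matrix=matrix, conditions=conds)


# --------------------------------------------------------------------------
# Model RDMs and their fit

@dataclass
class ModelRDM:
    matrix: np.ndarray
    mask: np.ndarray  # True where the cell enters the comparison
    kind: str
    conditions: List[Tuple[int, str]]


def context_separation_model(
    exclude_stimuli: Sequence[int] = (), stimuli: Sequence[int] = range(1, 8)
) -> ModelRDM:
    """Within-context cells 0, between-context cells 1.

    Same-stimulus cross-context cells are masked: they index stimulus
    identity rather than context, have no within-context counterpart (the
    excluded diagonal), and would otherwise bias the within-versus-between
    comparison. ``exclude_stimuli`` additionally masks every cell involving
    those stimuli (used to check that context separation does not hinge on
    the swapped pair).
    """
    conds = condition_labels(stimuli)
    n = len(conds)
    mat = np.zeros((n, n))
    mask = np.ones((n, n), dtype=bool)
    for i, (si, ci) in enumerate(conds):
        for j, (sj, cj) in enumerate(conds):
            mat[i, j] = 0.0 if ci == cj else 1.0
            if si in exclude_stimuli or sj in exclude_stimuli:
                mask[i, j] = False
            if si == sj and ci != cj:
                mask[i, j] = False
    np.fill_diagonal(mask, False)
    return ModelRDM(matrix=mat, mask=mask, kind="context_separation", conditions=conds)


def relational_separation_model(
    swapped: Sequence[int] = (3, 6),
    stimuli: Sequence[int] = range(1, 8),
    graded: bool = False,
) -> ModelRDM:
    """Cross-context same-stimulus cells: swapped stimuli 1, others 0.

    All other cells are masked. With ``graded=True`` every cross-context
    cell is included instead, valued 1 when the cell involves a swapped
    stimulus — a softer encoding of relational separation.
    """
    conds = condition_labels(stimuli)
    n = len(conds)
    mat = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    for i, (si, ci) in enumerate(conds):
        for j, (sj, cj) in enumerate(conds):
            if ci == cj:
                continue
            if graded:
                mask[i, j] = True
                mat[i, j] = 1.0 if (si in swapped or sj in swapped) else 0.0
            elif si == sj:
                mask[i, j] = True
                mat[i, j] = 1.0 if si in swapped else 0.0
    return ModelRDM(
        matrix=mat, mask=mask, kind="relational_separation", conditions=conds
    )


def kendall_tau_a(x: np.ndarray, y: np.ndarray) -> float:
    """Kendall tau-a: (concordant - discordant) / (m(m-1)/2), ties uncounted.

    Chosen over tau-b because model RDMs are predominantly tied.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    m = x.size
    return float(np.sum(np.triu(dx * dy, k=1)) / (m * (m - 1) / 2.0))


def rdm_model_fit(cond_rdm: ConditionRDM, model: ModelRDM) -> float:
    """Kendall tau-a between data and model over unmasked upper-triangle cells."""
    if [c for c in cond_rdm.conditions] != [c for c in model.conditions]:
        raise ValueError("condition sets of data and model RDMs differ")
    sel = model.mask & np.triu(np.ones_like(model.mask, dtype=bool), k=1)
    if sel.sum() < 3:
        raise ValueError("fewer than 3 unmasked cells")
    return kendall_tau_a(cond_rdm.matrix[sel], model.matrix[sel])


# --------------------------------------------------------------------------
# Group-level inference

def group_signrank(values: Sequence[float], exact_max_n: int = 12) -> Tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test of median zero; returns (Z, p).

    Zero differences are dropped (Wilcoxon's convention). For n up to
    ``exact_max_n`` the p-value is exact by sign enumeration (valid under
    ties via midranks); larger samples use the normal approximation with
    continuity and tie corrections. Z is always reported from the normal
    approximation, signed so that a positive median gives positive Z.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 5:
        raise ValueError("signed-rank test needs at least 5 values")
    v = v[v != 0]
    if v.size == 0:
        raise ValueError("all values are zero")
    absv = np.abs(v)
    order = absv.argsort()
    ranks = np.empty(v.size)
    ranks[order] = np.arange(1, v.size + 1)
    # midranks for ties
    for val in np.unique(absv):
        tied = absv == val
        if tied.sum() > 1:
            ranks[tied] = ranks[tied].mean()
    w_plus = float(ranks[v > 0].sum())
    m = v.size
    mu = m * (m + 1) / 4.0
    ties = np.array([np.sum(absv == val) for val in np.unique(absv)])
    sigma2 = m * (m + 1) * (2 * m + 1) / 24.0 - np.sum(ties**3 - ties) / 48.0
    sigma = np.sqrt(sigma2)
    diff = w_plus - mu
    z = 0.0 if sigma == 0 else (diff - 0.5 * np.sign(diff)) / sigma
    if m <= exact_max_n:
        stats = []
        for signs in itertools.product((0, 1), repeat=m):
            stats.append(float(np.dot(signs, ranks)))
        stats = np.asarray(stats)
        p = float(np.mean(np.abs(stats - mu) >= abs(diff) - 1e-12))
    else:
        from scipy.stats import norm

        p = float(2.0 * norm.sf(abs(z)))
    return float(z), min(p, 1.0)
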
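"""Gaussian cohort regions on PC1, Naive Bayes staging, and the
permutation test of manifold separability.

Each diagnostic group gets a univariate Gaussian fitted to its PC1
coordinates; the μ±σ intervals define *manifold cohorts* (a subject may
fall in several intervals, or none).  Staging of held-out subjects is a
maximum-density (equal-prior) Naive Bayes assignment on PC1 alone.
Whole-manifold separability is tested by the in-sample macro
one-vs-rest ROC-AUC of a multinomial logistic classifier on the 2-D
coordinates, against a label-permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .core import GROUPS


@dataclass(frozen=True)
class GroupGaussian:
    mean: float
    sd: float

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.mean - self.sd, self.mean + self.sd)


@dataclass(frozen=True)
class CohortModel:
    """Per-group PC1 Gaussians with μ±σ cohort intervals."""

    groups: Mapping[str, GroupGaussian]

    def ordered_labels(self) -> list[str]:
        known = [g for g in GROUPS if g in self.groups]
        extra = sorted(set(self.groups) - set(known))
        return known + extra


@dataclass(frozen=True)
class StagingResult:
    assigned: tuple[str, ...]
    fractions: Mapping[str, float]  # percent per target group, 2-decimal


@dataclass(frozen=True)
class PermutationTestResult:
    observed: float
    p_value: float
    n_permutations: int


def fit_group_gaussians(
    pc1_by_group: Mapping[str, Sequence[float]]
) -> CohortModel:
    """Sample mean and SD (ddof=1) of PC1 per group."""
    groups = {}
    for label, values in pc1_by_group.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {label!r} needs >=2 values, "
                             f"got {arr.size}")
        sd = float(arr.std(ddof=1))
        if sd == 0:
            raise ValueError(f"group {label!r} has zero variance")
        groups[label] = GroupGaussian(float(arr.mean()), sd)
    return CohortModel(groups)


def cohort_membership(
    model: CohortModel,
    pc1_values: Sequence[float],
    subject_ids: Sequence[str] | None = None,
) -> dict[str, list[str]]:
    """Subjects whose PC1 falls inside each group's μ±σ interval.

    Membership is interval-based, so a subject may appear under
    multiple groups or under none; both are reported as-is.
    """
    values = np.asarray(list(pc1_values), dtype=float)
    if subject_ids is None:
        subject_ids = [str(i) for i in range(values.size)]
    out: dict[str, list[str]] = {}
    for label in model.ordered_labels():
        lo, hi = model.groups[label].bounds
        out[label] = [sid for sid, v in zip(subject_ids, values)
                      if lo <= v <= hi]
    return out


def naive_bayes_assign(model: CohortModel,
                       pc1_values: Sequence[float]) -> StagingResult:
    """Assign each PC1 value to the group with maximal Gaussian density.

    Equal priors; density ties break toward the earlier stage (lower
    group index).  ``fractions`` reports the percentage of the input
    values assigned to each group, rounded to 2 decimals.
    """
    labels = model.ordered_labels()
    values = np.asarray(list(pc1_values), dtype=float)
    logpdf = np.stack([
        stats.norm.logpdf(values, model.groups[g].mean, model.groups[g].sd)
        for g in labels
    ])  # (n_groups, n)
    assigned = tuple(labels[i] for i in np.argmax(logpdf, axis=0))
    n = max(values.size, 1)
    fractions = {
        g: round(100.0 * sum(a == g for a in assigned) / n, 2)
        for g in labels
    }
    return StagingResult(assigned, fractions)


def fit_multinomial_logistic(x: np.ndarray, y_index: np.ndarray,
                             n_classes: int, l2: float = 1.0) -> np.ndarray:
    """L2-regularized multinomial logistic fit (L-BFGS).

    Returns class probabilities (n, n_classes) on the training points.
    The ridge penalty ``l2/2·‖W‖²`` (intercepts unpenalized) keeps the
    optimum finite on linearly separable configurations.  Lightweight
    on purpose: the permutation test refits it thousands of times.
    """
    n, d = x.shape
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), y_index] = 1.0

    def objective(theta):
        w = theta[: d * n_classes].reshape(d, n_classes)
        b = theta[d * n_classes:]
        logits = x @ w + b
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        p = e / e.sum(axis=1, keepdims=True)
        nll = -np.sum(np.log(p[np.arange(n), y_index] + 1e-300))
        loss = nll + 0.5 * l2 * np.sum(w * w)
        diff = p - onehot
        grad_w = x.T @ diff + l2 * w
        grad_b = diff.sum(axis=0)
        return loss, np.concatenate([grad_w.ravel(), grad_b])

    theta0 = np.zeros(d * n_classes + n_classes)
    result = optimize.minimize(objective, theta0, jac=True, method="L-BFGS-B")
    w = result.x[: d * n_classes].reshape(d, n_classes)
    b = result.x[d * n_classes:]
    logits = x @ w + b
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def _binary_auc(y: np.ndarray, scores: np.ndarray) -> float:
    # Mann-Whitney with average ranks for ties
    ranks = stats.rankdata(scores)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    rank_sum = float(ranks[y > 0].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def _macro_ovr_auc(coords: np.ndarray, labels: np.ndarray) -> float:
    """In-sample macro one-vs-rest ROC-AUC of a multinomial logistic
    model fit on the coordinates."""
    classes, y_index = np.unique(labels, return_inverse=True)
    proba = fit_multinomial_logistic(coords, y_index, classes.size)
    aucs = [_binary_auc((y_index == k).astype(float), proba[:, k])
            for k in range(classes.size)]
    return float(np.mean(aucs))


def permutation_test_separability(
    coordinates: np.ndarray,
    labels: Sequence[str],
    n_permutations: int = 10000,
    seed: int = 0,
) -> PermutationTestResult:
    """Permutation test of multi-class separability on the manifold.

    The observed statistic is the in-sample macro one-vs-rest ROC-AUC of
    a multinomial logistic model fit on the 2-D coordinates; the null
    refits on label-shuffled copies.  The plus-one estimator
    ``p = (1 + #{null ≥ observed}) / (1 + B)`` never returns zero.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    coords = np.asarray(coordinates, dtype=float)
    labels = np.asarray([str(lab) for lab in labels])
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValueError(
            f"need >=2 classes with >=2 members each, got "
            f"{dict(zip(classes.tolist(), counts.tolist()))}"
        )
    observed = _macro_ovr_auc(coords, labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _macro_ovr_auc(coords, perm) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermutationTestResult(observed, float(p), n_permutations)
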
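"""Normative edge template and per-region structural divergence scores.

A reference cohort (typically the subjects inside the earliest-stage
manifold region) defines a per-edge Gaussian template: mean and SD of
the *weighted* connectivity across reference subjects, with a floor on
the SD so zero-variance edges cannot dominate.  Each comparison subject
is then scored edge-by-edge with the two-sided Gaussian tail
probability of its deviation, and per-region evidence is accumulated
Fisher-style: ``S_r = −Σ_{e∋r} ln p_e``, every edge contributing to
both of its endpoints.  High scores mark regions whose connections
diverge most from the normative profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Connectome

P_FLOOR = 1e-12
SIGMA_FLOOR_FRAC = 1e-6


@dataclass(frozen=True)
class DivergenceTemplate:
    """Per-edge Gaussian summary of the reference cohort."""

    mean: np.ndarray  # (N, N) symmetric
    sd: np.ndarray    # (N, N) symmetric, floored at sigma_floor
    n_reference: int
    sigma_floor: float
    region_labels: tuple[str, ...] = ()

    @property
    def n_nodes(self) -> int:
        return self.mean.shape[0]


@dataclass(frozen=True)
class RegionScoreTable:
    """Per-subject and group-mean region divergence scores."""

    per_subject: pd.DataFrame  # subject_id, region_index, region_label, score
    group_means: pd.DataFrame  # group, region_index, region_label, mean_score


def build_template(reference: Sequence[Connectome],
                   sigma_floor: float | None = None) -> DivergenceTemplate:
    """Per-edge sample mean and SD (ddof=1) across reference subjects.

    ``sigma_floor`` defaults to 1e-6 × the global mean positive weight
    of the reference stack; SDs below the floor are raised to it.
    """
    if len(reference) < 2:
        raise ValueError(
            f"need >=2 reference subjects, got {len(reference)}")
    stack = np.stack([c.weights for c in reference])
    if sigma_floor is None:
        positive = stack[stack > 0]
        scale = float(positive.mean()) if positive.size else 1.0
        sigma_floor = SIGMA_FLOOR_FRAC * scale
    if sigma_floor <= 0:
        raise ValueError("sigma_floor must be positive")
    mean = stack.mean(axis=0)
    sd = np.maximum(stack.std(axis=0, ddof=1), sigma_floor)
    return DivergenceTemplate(mean=mean, sd=sd, n_reference=len(reference),
                              sigma_floor=float(sigma_floor),
                              region_labels=reference[0].region_labels)


def edge_deviation_probs(subject: Connectome,
                         template: DivergenceTemplate,
                         p_floor: float = P_FLOOR) -> np.ndarray:
    """Two-sided Gaussian tail probability per edge, clipped to
    [p_floor, 1].

    ``p_e = 2·(1 − Φ(|w_e − μ_e|/σ_e))``: the probability, under the
    reference Gaussian, of a deviation at least as large as observed.
    The diagonal is fixed at 1 (self-pairs carry no evidence).
    """
    if subject.n_nodes != template.n_nodes:
        raise ValueError(
            f"subject has {subject.n_nodes} nodes, template "
            f"{template.n_nodes}"
        )
    z = np.abs(subject.weights - template.mean) / template.sd
    p = np.clip(2.0 * stats.norm.sf(z), p_floor, 1.0)
    np.fill_diagonal(p, 1.0)
    return p


def region_scores(edge_probs: np.ndarray,
                  n_nodes: int | None = None) -> np.ndarray:
    """Fisher-style accumulation: ``S_r = −Σ_{e incident to r} ln p_e``.

    Each unordered edge contributes to both endpoints; with all
    probabilities at 1 every score is exactly 0.
    """
    p = np.asarray(edge_probs, dtype=float)
    if n_nodes is not None and p.shape != (n_nodes, n_nodes):
        raise ValueError(f"edge_probs shape {p.shape} != "
                         f"({n_nodes}, {n_nodes})")
    logp = np.log(p)
    np.fill_diagonal(logp, 0.0)
    return -logp.sum(axis=1)


def group_divergence_map(
    subjects: Sequence[Connectome],
    template: DivergenceTemplate,
    cohort_assignment: Mapping[str, str] | None = None,
) -> RegionScoreTable:
    """Region score table for a comparison cohort against the template.

    ``cohort_assignment`` maps subject_id → cohort label; by default
    each subject's own group label is used.  Group means are sorted
    descending within each group.
    """
    if len(subjects) == 0:
        raise ValueError("empty comparison cohort")
    labels = template.region_labels or subjects[0].region_labels
    rows = []
    for subj in subjects:
        cohort = (cohort_assignment.get(subj.subject_id, subj.group)
                  if cohort_assignment else subj.group)
        scores = region_scores(edge_deviation_probs(subj, template))
        for r, score in enumerate(scores):
            rows.append({
                "subject_id": subj.subject_id,
                "group": cohort,
                "region_index": r,
                "region_label": labels[r] if r < len(labels) else str(r),
                "score": float(score),
            })
    per_subject = pd.DataFrame(rows)
    group_means = (
        per_subject
        .groupby(["group", "region_index", "region_label"], as_index=False)
        ["score"].mean()
        .rename(columns={"score": "mean_score"})
        .sort_values(["group", "mean_score"],
                     ascending=[True, False], ignore_index=True)
    )
    return RegionScoreTable(per_subject=per_subject,
                            group_means=group_means)
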
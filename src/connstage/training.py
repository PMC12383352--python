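"""Supervised training of the encoder and its LOOCV/ablation protocols.

The encoder is never trained to be a classifier per se: a temporary MLP
head provides the supervisory signal on a two-group task (typically the
two clinical extremes), after which the head is discarded and the
encoder reused as an embedding module.  Evaluation follows the
small-cohort protocol: leave-one-out cross-validation with one pooled
ROC-AUC per run, aggregated over independently seeded runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from ._nn import Adam, softmax_cross_entropy
from .core import BinarizedGraph
from .encoder import VARIANTS, EncoderModel

ABLATION_VARIANTS = VARIANTS
DEFAULT_TASKS = (("G1", "G2"), ("G0", "G2"))


@dataclass(frozen=True)
class TrainConfig:
    """Full-batch Adam training settings (defaults follow the study
    protocol: lr and weight decay 0.001, 100 epochs)."""

    learning_rate: float = 0.001
    weight_decay: float = 0.001
    epochs: int = 100
    seed: int = 0
    class_pair: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass(frozen=True)
class EmbeddingSet:
    """n×D embedding matrix with aligned subject ids and group labels."""

    matrix: np.ndarray
    subject_ids: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError("embedding matrix must be 2-D")
        if len(self.subject_ids) != m.shape[0] or \
                len(self.labels) != m.shape[0]:
            raise ValueError("ids/labels must match embedding rows")
        object.__setattr__(self, "matrix", m)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def select(self, groups: Sequence[str]) -> "EmbeddingSet":
        keep = [i for i, g in enumerate(self.labels) if g in groups]
        return EmbeddingSet(self.matrix[keep],
                            tuple(self.subject_ids[i] for i in keep),
                            tuple(self.labels[i] for i in keep))


@dataclass(frozen=True)
class LoocvResult:
    mean: float
    sd: float
    per_run: tuple[float, ...]


def _resolve_classes(labels: Sequence[str],
                     class_pair: tuple[str, str] | None) -> tuple[str, str]:
    present = sorted(set(labels))
    if len(present) < 2:
        raise ValueError(f"need two classes, got {present}")
    if len(present) > 2:
        raise ValueError(f"expected exactly two classes, got {present}")
    if class_pair is None:
        # canonical labels sort in stage order, so the later stage is
        # the positive class
        return present[0], present[1]
    if sorted(class_pair) != present:
        raise ValueError(f"class_pair {class_pair} does not match "
                         f"labels {present}")
    return class_pair


def _stack(graphs: Sequence[BinarizedGraph]) -> tuple[np.ndarray, np.ndarray]:
    adj = np.stack([g.adjacency for g in graphs])
    feat = np.stack([g.features for g in graphs])
    return adj, feat


def train_classifier(
    graphs: Sequence[BinarizedGraph],
    labels: Sequence[str] | None = None,
    config: TrainConfig = TrainConfig(),
    variant: str = "baseline",
) -> EncoderModel:
    """Train encoder+head on a two-class task with full-batch Adam.

    ``labels`` default to each graph's own group label.  The returned
    model records the (negative, positive) class pair on ``classes_``
    and the per-epoch loss trace on ``train_history_``.
    """
    if len(graphs) == 0:
        raise ValueError("empty dataset")
    if labels is None:
        labels = [g.group for g in graphs]
    if len(labels) != len(graphs):
        raise ValueError("labels must align with graphs")
    neg, pos = _resolve_classes(labels, config.class_pair)
    y = np.array([1 if lab == pos else 0 for lab in labels])
    adj, feat = _stack(graphs)
    model = EncoderModel(variant=variant, n_nodes=adj.shape[-1],
                         seed=config.seed)
    opt = Adam(model.params(), lr=config.learning_rate,
               weight_decay=config.weight_decay)
    history = []
    for _ in range(config.epochs):
        opt.zero_grad()
        logits = model.forward_logits(adj, feat, train=True)
        loss, _, d_logits = softmax_cross_entropy(logits, y)
        model.backward(d_logits)
        opt.step()
        history.append(loss)
    model.classes_ = (neg, pos)
    model.train_history_ = history
    return model


def embed_dataset(graphs: Sequence[BinarizedGraph],
                  model: EncoderModel) -> EmbeddingSet:
    """One embedding row per graph, dataset order preserved."""
    sizes = {g.n_nodes for g in graphs}
    if len(sizes) > 1:
        raise ValueError(f"mixed node counts in dataset: {sorted(sizes)}")
    matrix = model.embed(list(graphs))
    return EmbeddingSet(matrix,
                        tuple(g.subject_id for g in graphs),
                        tuple(g.group for g in graphs))


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """P(score_pos > score_neg) + ½·P(tie) over positive–negative pairs."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("roc_auc needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def loocv_auc(
    graphs: Sequence[BinarizedGraph],
    labels: Sequence[str] | None = None,
    config: TrainConfig = TrainConfig(),
    n_runs: int = 10,
    variant: str = "baseline",
) -> LoocvResult:
    """Pooled-LOOCV ROC-AUC, mean ± SD over independently seeded runs.

    Per run ``r`` (seed = base+r): every sample is held out once, the
    model retrained on the remainder, and the held-out positive-class
    probability recorded; the run's AUC pools all held-out scores.
    """
    if labels is None:
        labels = [g.group for g in graphs]
    neg, pos = _resolve_classes(labels, config.class_pair)
    counts = {lab: list(labels).count(lab) for lab in (neg, pos)}
    if min(counts.values()) < 2:
        raise ValueError(f"need >=2 samples per class, got {counts}")
    y = np.array([1 if lab == pos else 0 for lab in labels])
    aucs = []
    for r in range(n_runs):
        run_cfg = replace(config, seed=config.seed + r,
                          class_pair=(neg, pos))
        scores = np.empty(len(graphs))
        for i in range(len(graphs)):
            train_graphs = [g for j, g in enumerate(graphs) if j != i]
            train_labels = [lab for j, lab in enumerate(labels) if j != i]
            model = train_classifier(train_graphs, train_labels, run_cfg,
                                     variant)
            scores[i] = model.predict_proba([graphs[i]])[0, 1]
        aucs.append(roc_auc(y, scores))
    arr = np.asarray(aucs)
    sd = float(arr.std(ddof=1)) if n_runs > 1 else 0.0
    return LoocvResult(float(arr.mean()), sd, tuple(arr.tolist()))


def run_ablation(
    graphs: Sequence[BinarizedGraph],
    labels: Sequence[str] | None = None,
    config: TrainConfig = TrainConfig(),
    n_runs: int = 10,
    variants: Sequence[str] = ABLATION_VARIANTS,
    tasks: Sequence[tuple[str, str]] = DEFAULT_TASKS,
) -> pd.DataFrame:
    """LOOCV AUC grid over encoder variants × two-group tasks.

    Rows: variant; columns: task (named "pos/neg" by stage order),
    with ``auc_mean``/``auc_sd`` per cell in tidy long form.
    """
    if labels is None:
        labels = [g.group for g in graphs]
    present = set(labels)
    rows = []
    for neg, pos in tasks:
        if not {neg, pos} <= present:
            raise ValueError(f"missing group for task {pos}/{neg}: "
                             f"have {sorted(present)}")
        keep = [i for i, lab in enumerate(labels) if lab in (neg, pos)]
        sub_graphs = [graphs[i] for i in keep]
        sub_labels = [labels[i] for i in keep]
        task_cfg = replace(config, class_pair=(neg, pos))
        for variant in variants:
            res = loocv_auc(sub_graphs, sub_labels, task_cfg,
                            n_runs=n_runs, variant=variant)
            rows.append({"variant": variant, "task": f"{pos}/{neg}",
                         "auc_mean": res.mean, "auc_sd": res.sd})
    return pd.DataFrame(rows)
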
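"""Synthetic cohorts with a planted progression axis.

The clinical dataset the framework targets (three ordered stages of
cognitive decline, 148-parcel structural connectomes) cannot be shipped,
so this module emulates its essential structure: every subject shares
one population skeleton of plausible anatomical connections with
heavy-tailed (log-normal) base weights, and disease stage expresses
itself as a progressive attenuation — and eventual dropout — of the
edges incident to a small set of *vulnerable* regions (echoing the
parietal/precuneus hubs implicated in early dementia).  Because the
encoder consumes binarized topology, dropout (not mere attenuation) is
what makes stages distinguishable.

Per subject, a latent progression score ``t`` is drawn around the
subject's group mean, so the intermediate group straddles the axis
between the two extremes rather than forming a tight third cluster —
mimicking the clinical heterogeneity of the middle stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import GROUPS, Connectome

_MEANLOG = 0.0
_SDLOG = 0.5  # heavy-tailed like streamline counts; scale is arbitrary


@dataclass(frozen=True)
class CohortConfig:
    """Generative settings for a three-group synthetic cohort.

    ``n_per_group`` is ordered (G0, G1, G2); defaults 24/46/18 mirror an
    SCI/MCI/ADD cohort.  ``attenuation_strength`` (β) scales vulnerable
    edge weights by ``1 − β·t`` where ``t`` is the subject's progression
    score; ``dropout_cutoff_frac`` × (base-weight median) is the floor
    below which an edge weight is zeroed so that binarized topology,
    not just weight magnitude, changes with stage.
    """

    n_per_group: tuple[int, int, int] = (24, 46, 18)
    n_nodes: int = 148
    base_density: float = 0.30
    n_vulnerable_regions: int = 12
    group_progression_means: tuple[float, float, float] = (0.0, 0.5, 1.0)
    progression_sd: float = 0.15
    attenuation_strength: float = 0.6
    weight_noise_cv: float = 0.2
    dropout_cutoff_frac: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.base_density < 1:
            raise ValueError(f"base_density must be in (0,1), "
                             f"got {self.base_density}")
        if not 0 <= self.attenuation_strength <= 1:
            raise ValueError(f"attenuation_strength must be in [0,1], "
                             f"got {self.attenuation_strength}")
        if not 0 < self.n_vulnerable_regions < self.n_nodes:
            raise ValueError("n_vulnerable_regions must be in (0, n_nodes)")
        if any(n < 1 for n in self.n_per_group):
            raise ValueError("each group needs at least one subject")
        if self.progression_sd < 0 or self.weight_noise_cv < 0:
            raise ValueError("spread parameters must be nonnegative")

    @property
    def dropout_cutoff(self) -> float:
        """Absolute cutoff: fraction of the base-weight median."""
        return self.dropout_cutoff_frac * float(np.exp(_MEANLOG))


def generate_cohort(config: CohortConfig) -> list[Connectome]:
    """Draw a fully seeded three-group cohort on one shared skeleton.

    Steps: (1) one population skeleton with edge probability
    ``base_density`` and log-normal base weights; (2) the first
    ``n_vulnerable_regions`` node indices form the vulnerable set, an
    edge being vulnerable iff either endpoint is; (3) each subject draws
    ``t ~ N(group mean, progression_sd)`` clipped to [0,1]; (4) the
    subject's weight on edge *e* is ``W0_e·(1−β·t if vulnerable else
    1)·(1 + cv·z_e)`` floored at 0; (5) weights below the dropout
    cutoff are set to exactly 0.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    skeleton = rng.random(iu.size) < config.base_density
    base_w = rng.lognormal(_MEANLOG, _SDLOG, iu.size) * skeleton
    vulnerable = (iu < config.n_vulnerable_regions) | (
        ju < config.n_vulnerable_regions)

    beta = config.attenuation_strength
    cutoff = config.dropout_cutoff
    cohort: list[Connectome] = []
    subj = 0
    for group, n_group, t_mean in zip(
            GROUPS, config.n_per_group, config.group_progression_means):
        for _ in range(n_group):
            t = float(np.clip(rng.normal(t_mean, config.progression_sd),
                              0.0, 1.0))
            factor = np.where(vulnerable, 1.0 - beta * t, 1.0)
            noise = 1.0 + config.weight_noise_cv * rng.standard_normal(
                iu.size)
            w = np.maximum(base_w * factor * noise, 0.0)
            w[w < cutoff] = 0.0
            mat = np.zeros((n, n))
            mat[iu, ju] = w
            mat[ju, iu] = w
            cohort.append(Connectome(
                subject_id=f"subj_{subj:03d}", group=group, weights=mat))
            subj += 1
    return cohort


def generate_random_networks(
    n_graphs: int,
    density_samples: Sequence[float],
    n_nodes: int,
    seed: int,
) -> list[Connectome]:
    """Uniform random graphs at densities resampled from a reference set.

    Each graph draws its edge probability (with replacement) from
    ``density_samples``; present edges get unit weight.  These carry no
    group structure and serve as the sparsity-matched null for the
    manifold-dimensionality control experiment.
    """
    densities = np.asarray(list(density_samples), dtype=float)
    if densities.size == 0:
        raise ValueError("density_samples must be nonempty")
    if ((densities < 0) | (densities > 1)).any():
        raise ValueError("densities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n_nodes, k=1)
    graphs = []
    for g in range(n_graphs):
        p = float(rng.choice(densities))
        w = (rng.random(iu.size) < p).astype(float)
        mat = np.zeros((n_nodes, n_nodes))
        mat[iu, ju] = w
        mat[ju, iu] = w
        graphs.append(Connectome(
            subject_id=f"rand_{g:03d}", group="G0", weights=mat))
    return graphs


def empirical_densities(
    dataset: Sequence[Connectome], threshold: float = 0.0
) -> list[float]:
    """Per-graph fraction of unordered node pairs with weight > threshold."""
    if len(dataset) == 0:
        raise ValueError("dataset must be nonempty")
    out = []
    for conn in dataset:
        n = conn.n_nodes
        iu, ju = np.triu_indices(n, k=1)
        present = conn.weights[iu, ju] > threshold
        out.append(float(present.mean()) if present.size else 0.0)
    return out
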
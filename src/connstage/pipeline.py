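"""End-to-end study orchestration.

``run_full_study`` chains the whole analysis deterministically from one
config: simulate a cohort → train the encoder on the two extreme groups
→ embed everyone → fit the PCA manifold → project the held-out
intermediate group → Gaussian cohort regions, Naive Bayes staging and
the permutation separability test → sparsity-matched random-network
control → divergence maps → (optionally) the LOOCV table and ablation
grid.  Every table is written as TSV and a machine-readable summary as
JSON; rerunning with the same config reproduces the summary byte for
byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import manifold as mf
from . import staging as st
from .core import GROUPS, BinarizedGraph, Connectome, binarize
from .divergence import build_template, group_divergence_map
from .synthetic import (CohortConfig, empirical_densities, generate_cohort,
                        generate_random_networks)
from .training import (TrainConfig, embed_dataset, loocv_auc,
                       run_ablation, train_classifier)

LOOCV_TASKS = (("G0", "G2"), ("G1", "G2"), ("G0", "G1"))


@dataclass(frozen=True)
class StudyConfig:
    """One-file description of a full study run."""

    cohort: CohortConfig = CohortConfig()
    train: TrainConfig = TrainConfig()
    binarize_threshold: float = 0.0
    extremes: tuple[str, str] = ("G0", "G2")
    held_out: str = "G1"
    anchor_label: str = "G2"
    variance_threshold: float = 0.99
    n_permutations: int = 1000
    run_loocv: bool = False
    run_ablation: bool = False
    loocv_runs: int = 10
    ablation_runs: int = 10
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StudyResult:
    summary: dict
    coordinates: pd.DataFrame
    cohorts: Mapping[str, list[str]]
    divergence_tables: Mapping[str, pd.DataFrame]


def train_extreme_model(graphs: Sequence[BinarizedGraph],
                        config: StudyConfig):
    """Train the baseline encoder on the two extreme groups only."""
    neg, pos = config.extremes
    subset = [g for g in graphs if g.group in (neg, pos)]
    cfg = replace(config.train, class_pair=(neg, pos))
    return train_classifier(subset, config=cfg), subset


def random_network_control(cohort: Sequence[Connectome],
                           config: StudyConfig) -> dict:
    """Re-run train→embed→PCA on sparsity-matched random graphs.

    Random graphs receive pseudo-group labels in the cohort's
    proportions (pure bookkeeping — they carry no signal), the encoder
    is trained on the pseudo-extremes, and the embedding spectrum is
    summarized.
    """
    densities = empirical_densities(cohort, config.binarize_threshold)
    sizes = [sum(1 for c in cohort if c.group == g) for g in GROUPS]
    rand = generate_random_networks(sum(sizes), densities,
                                    cohort[0].n_nodes,
                                    seed=config.cohort.seed + 10_000)
    labeled = []
    idx = 0
    for group, size in zip(GROUPS, sizes):
        for _ in range(size):
            conn = rand[idx]
            labeled.append(Connectome(conn.subject_id, group, conn.weights,
                                      conn.region_labels))
            idx += 1
    graphs = [binarize(c, config.binarize_threshold) for c in labeled]
    model, subset = train_extreme_model(graphs, config)
    emb = embed_dataset(subset, model)
    pca = mf.fit_pca(emb, k=2, anchor_label=config.extremes[1])
    return {
        "explained_variance_2pc": mf.explained_variance_2d(pca),
        "intrinsic_dim": mf.intrinsic_dim(emb, config.variance_threshold),
        "n_graphs": len(subset),
    }


def run_full_study(config: StudyConfig,
                   out_dir: str | Path | None = None) -> StudyResult:
    cohort = generate_cohort(config.cohort)
    graphs = [binarize(c, config.binarize_threshold) for c in cohort]

    # supervised stage on the two clinical extremes
    model, extreme_graphs = train_extreme_model(graphs, config)
    emb_extremes = embed_dataset(extreme_graphs, model)
    pca = mf.fit_pca(emb_extremes, k=2, anchor_label=config.anchor_label)

    emb_all = embed_dataset(graphs, model)
    coords_table = mf.project_table(pca, emb_all)
    coords = coords_table[["pc1", "pc2"]].to_numpy()

    # Gaussian cohort regions on PC1, per diagnostic label
    pc1_by_group = {
        g: coords_table.loc[coords_table.group == g, "pc1"].to_numpy()
        for g in GROUPS
    }
    cohort_model = st.fit_group_gaussians(pc1_by_group)
    cohorts = st.cohort_membership(
        cohort_model, coords_table.pc1.to_numpy(),
        coords_table.subject_id.tolist())

    held_pc1 = pc1_by_group[config.held_out]
    staging = st.naive_bayes_assign(cohort_model, held_pc1)
    perm = st.permutation_test_separability(
        coords, coords_table.group.tolist(),
        n_permutations=config.n_permutations, seed=config.seed)

    control = random_network_control(cohort, config)

    # divergence maps: manifold-defined reference and comparison cohorts
    reference_ids = set(cohorts[config.extremes[0]])
    by_id = {c.subject_id: c for c in cohort}
    reference = [by_id[s] for s in coords_table.subject_id
                 if s in reference_ids]
    template = build_template(reference)
    divergence_tables = {}
    for group in ("G1", "G2"):
        member_ids = [s for s in cohorts[group] if s not in reference_ids]
        members = [by_id[s] for s in member_ids]
        if members:
            table = group_divergence_map(
                members, template,
                cohort_assignment={s: group for s in member_ids})
            divergence_tables[group] = table.group_means

    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_subjects": len(cohort),
        "explained_variance_2pc": mf.explained_variance_2d(pca),
        "intrinsic_dim": mf.intrinsic_dim(emb_extremes,
                                          config.variance_threshold),
        "control": control,
        "group_pc1_means": {g: float(np.mean(v))
                            for g, v in pc1_by_group.items()},
        "cohort_sizes": {g: len(v) for g, v in cohorts.items()},
        "staging_fractions": dict(staging.fractions),
        "permutation_test": {
            "observed_auc": perm.observed,
            "p_value": perm.p_value,
            "n_permutations": perm.n_permutations,
        },
        "final_train_loss": model.train_history_[-1],
    }

    if config.run_loocv:
        loocv = {}
        for neg, pos in LOOCV_TASKS:
            keep = [g for g in graphs if g.group in (neg, pos)]
            cfg = replace(config.train, class_pair=(neg, pos))
            res = loocv_auc(keep, config=cfg, n_runs=config.loocv_runs)
            loocv[f"{pos}/{neg}"] = {"mean": res.mean, "sd": res.sd}
        summary["loocv_auc"] = loocv
    if config.run_ablation:
        ablation = run_ablation(graphs, config=config.train,
                                n_runs=config.ablation_runs)
        summary["ablation"] = ablation.to_dict(orient="records")

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        coords_table.to_csv(out / "coordinates.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(g, ";".join(members)) for g, members in cohorts.items()],
            columns=["group", "subject_ids"],
        ).to_csv(out / "cohorts.tsv", sep="\t", index=False)
        pd.DataFrame({
            "subject_id": [s for s, g in zip(coords_table.subject_id,
                                             coords_table.group)
                           if g == config.held_out],
            "assigned": staging.assigned,
        }).to_csv(out / "staging.tsv", sep="\t", index=False)
        for group, table in divergence_tables.items():
            table.to_csv(out / f"divergence_{group}.tsv", sep="\t",
                         index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)

    return StudyResult(summary=summary, coordinates=coords_table,
                       cohorts=cohorts,
                       divergence_tables=divergence_tables)
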
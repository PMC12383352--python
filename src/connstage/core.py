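"""Connectome containers and delimited-text I/O.

A structural connectome is modelled as a weighted, undirected, loop-free
graph over cortical parcels: the symmetric adjacency matrix ``A`` holds
nonnegative edge weights (streamline-count derived in real data) with a
zero diagonal.  Subjects belong to one of three ordered clinical stages,
carried as canonical group labels ``G0 < G1 < G2`` (SCI-, MCI- and
ADD-like, respectively).

The GNN front-end consumes *binarized* topology only: :func:`binarize`
thresholds the weights and attaches one-hot node-index features, so the
encoder sees which parcel pairs are connected, not how strongly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS: tuple[str, str, str] = ("G0", "G1", "G2")
"""Canonical ordered stage labels (G0 least, G2 most advanced)."""

GROUP_ALIASES: Mapping[str, str] = {
    "G0": "G0", "G1": "G1", "G2": "G2",
    "SCI": "G0", "MCI": "G1", "ADD": "G2",
}

SYMMETRY_TOL = 1e-8


class ConnectomeValidationError(ValueError):
    """Raised when an adjacency matrix violates a connectome invariant."""


def default_region_labels(n_nodes: int) -> tuple[str, ...]:
    return tuple(f"region_{i:03d}" for i in range(n_nodes))


# 74 cortical parcel names per hemisphere, following the Destrieux
# (2009) gyral/sulcal naming scheme.  Only used as human-readable row
# labels; nothing downstream depends on the specific strings.
_DESTRIEUX_74 = (
    "G_and_S_frontomargin", "G_and_S_occipital_inf", "G_and_S_paracentral",
    "G_and_S_subcentral", "G_and_S_transv_frontopol", "G_and_S_cingul-Ant",
    "G_and_S_cingul-Mid-Ant", "G_and_S_cingul-Mid-Post",
    "G_cingul-Post-dorsal", "G_cingul-Post-ventral", "G_cuneus",
    "G_front_inf-Opercular", "G_front_inf-Orbital", "G_front_inf-Triangul",
    "G_front_middle", "G_front_sup", "G_Ins_lg_and_S_cent_ins",
    "G_insular_short", "G_occipital_middle", "G_occipital_sup",
    "G_oc-temp_lat-fusifor", "G_oc-temp_med-Lingual", "G_oc-temp_med-Parahip",
    "G_orbital", "G_pariet_inf-Angular", "G_pariet_inf-Supramar",
    "G_parietal_sup", "G_postcentral", "G_precentral", "G_precuneus",
    "G_rectus", "G_subcallosal", "G_temp_sup-G_T_transv",
    "G_temp_sup-Lateral", "G_temp_sup-Plan_polar", "G_temp_sup-Plan_tempo",
    "G_temporal_inf", "G_temporal_middle", "Lat_Fis-ant-Horizont",
    "Lat_Fis-ant-Vertical", "Lat_Fis-post", "Pole_occipital",
    "Pole_temporal", "S_calcarine", "S_central", "S_cingul-Marginalis",
    "S_circular_insula_ant", "S_circular_insula_inf",
    "S_circular_insula_sup", "S_collat_transv_ant", "S_collat_transv_post",
    "S_front_inf", "S_front_middle", "S_front_sup", "S_interm_prim-Jensen",
    "S_intrapariet_and_P_trans", "S_oc_middle_and_Lunatus",
    "S_oc_sup_and_transversal", "S_occipital_ant", "S_oc-temp_lat",
    "S_oc-temp_med_and_Lingual", "S_orbital_lateral",
    "S_orbital_med-olfact", "S_orbital-H_Shaped", "S_parieto_occipital",
    "S_pericallosal", "S_postcentral", "S_precentral-inf-part",
    "S_precentral-sup-part", "S_suborbital", "S_subparietal",
    "S_temporal_inf", "S_temporal_sup", "S_temporal_transverse",
)


def destrieux_labels() -> tuple[str, ...]:
    """148 Destrieux-style parcel labels (``lh_``/``rh_`` prefixed)."""
    return tuple(f"{hemi}_{name}" for hemi in ("lh", "rh")
                 for name in _DESTRIEUX_74)


def canonical_group(label: str) -> str:
    try:
        return GROUP_ALIASES[str(label).strip()]
    except KeyError:
        raise ConnectomeValidationError(
            f"unknown group label {label!r}; expected one of "
            f"{sorted(set(GROUP_ALIASES))}"
        ) from None


def _validate_weights(weights: np.ndarray) -> np.ndarray:
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 2 or weights.shape[0] != weights.shape[1]:
        raise ConnectomeValidationError(
            f"adjacency must be square, got shape {weights.shape}"
        )
    asym = np.abs(weights - weights.T)
    if asym.size and asym.max() > SYMMETRY_TOL:
        i, j = np.unravel_index(int(np.argmax(asym)), asym.shape)
        raise ConnectomeValidationError(
            f"asymmetric adjacency: cell ({i},{j})={weights[i, j]!r} vs "
            f"({j},{i})={weights[j, i]!r}"
        )
    neg = np.argwhere(weights < 0)
    if len(neg):
        i, j = neg[0]
        raise ConnectomeValidationError(
            f"negative weight at cell ({i},{j}): {weights[i, j]!r}"
        )
    diag = np.flatnonzero(np.diagonal(weights))
    if len(diag):
        i = int(diag[0])
        raise ConnectomeValidationError(
            f"nonzero diagonal at cell ({i},{i}): {weights[i, i]!r}"
        )
    # enforce exact symmetry after the tolerance check
    return (weights + weights.T) / 2.0


@dataclass(frozen=True)
class Connectome:
    """One subject's weighted structural network.

    invariants: ``weights`` is symmetric (tol 1e-8 on input, exact after
    construction), nonnegative, zero-diagonal, and square with one row
    per entry of ``region_labels``.
    """

    subject_id: str
    group: str
    weights: np.ndarray
    region_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        weights = _validate_weights(self.weights)
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "group", canonical_group(self.group))
        labels = tuple(self.region_labels) or default_region_labels(
            weights.shape[0])
        if len(labels) != weights.shape[0]:
            raise ConnectomeValidationError(
                f"{len(labels)} region labels for {weights.shape[0]} nodes"
            )
        object.__setattr__(self, "region_labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class BinarizedGraph:
    """0/1 topology plus one-hot node-index features (GNN input)."""

    adjacency: np.ndarray
    features: np.ndarray
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        adjacency = np.asarray(self.adjacency, dtype=float)
        if not np.isin(adjacency, (0.0, 1.0)).all():
            raise ConnectomeValidationError("adjacency entries must be 0/1")
        adjacency = _validate_weights(adjacency)
        features = np.asarray(self.features, dtype=float)
        if features.shape[0] != adjacency.shape[0]:
            raise ConnectomeValidationError(
                f"feature rows {features.shape[0]} != nodes "
                f"{adjacency.shape[0]}"
            )
        object.__setattr__(self, "adjacency", adjacency)
        object.__setattr__(self, "features", features)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass(frozen=True)
class ManifestRecord:
    subject_id: str
    group: str
    path: str


@dataclass(frozen=True)
class DatasetManifest:
    records: tuple[ManifestRecord, ...]
    n_nodes: int


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    return " "


def read_adjacency(
    path: str | os.PathLike,
    delimiter: str | None = None,
    subject_id: str | None = None,
    group: str = "G0",
    region_labels: Sequence[str] = (),
) -> Connectome:
    """Parse a delimited N×N weight grid into a validated :class:`Connectome`.

    ``delimiter=None`` auto-detects comma vs tab (falling back to
    whitespace).  Validation failures name the offending cell.
    """
    path = Path(path)
    delim = delimiter or _sniff_delimiter(path)
    if delim == " ":
        grid = np.loadtxt(path, ndmin=2)
    else:
        grid = np.loadtxt(path, delimiter=delim, ndmin=2)
    return Connectome(
        subject_id=subject_id or path.stem,
        group=group,
        weights=grid,
        region_labels=tuple(region_labels),
    )


def write_adjacency(connectome: Connectome, path: str | os.PathLike) -> None:
    """Write weights as comma-separated text; round-trips to <1e-12."""
    np.savetxt(path, connectome.weights, delimiter=",", fmt="%.17g")


def binarize(connectome: Connectome, threshold: float = 0.0) -> BinarizedGraph:
    """Threshold weights to 0/1 presence and attach one-hot features.

    An edge is present iff its weight is strictly greater than
    ``threshold`` (default 0: presence of any fibers).
    """
    if threshold < 0:
        raise ValueError(f"threshold must be nonnegative, got {threshold}")
    n = connectome.n_nodes
    adjacency = (connectome.weights > threshold).astype(float)
    return BinarizedGraph(
        adjacency=adjacency,
        features=np.eye(n),
        subject_id=connectome.subject_id,
        group=connectome.group,
    )


def load_manifest(
    path: str | os.PathLike,
) -> tuple[DatasetManifest, list[Connectome]]:
    """Read a TSV manifest (subject_id, group, path) and all its files.

    Paths are resolved relative to the manifest's directory.  Duplicate
    subject ids, unknown group labels and node-count mismatches across
    files are rejected.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"subject_id", "group", "path"}
    if not required.issubset(table.columns):
        raise ConnectomeValidationError(
            f"manifest must have columns {sorted(required)}, "
            f"got {list(table.columns)}"
        )
    ids = table["subject_id"].tolist()
    dupes = sorted({s for s in ids if ids.count(s) > 1})
    if dupes:
        raise ConnectomeValidationError(f"duplicate subject ids: {dupes}")
    records, connectomes = [], []
    n_nodes: int | None = None
    for row in table.itertuples(index=False):
        group = canonical_group(row.group)
        file_path = Path(row.path)
        if not file_path.is_absolute():
            file_path = path.parent / file_path
        conn = read_adjacency(file_path, subject_id=row.subject_id,
                              group=group)
        if n_nodes is None:
            n_nodes = conn.n_nodes
        elif conn.n_nodes != n_nodes:
            raise ConnectomeValidationError(
                f"node-count mismatch: {row.subject_id} has "
                f"{conn.n_nodes} nodes, expected {n_nodes}"
            )
        records.append(ManifestRecord(row.subject_id, group, str(row.path)))
        connectomes.append(conn)
    return DatasetManifest(tuple(records), int(n_nodes or 0)), connectomes


def write_dataset(
    connectomes: Iterable[Connectome],
    out_dir: str | os.PathLike,
    manifest_name: str = "manifest.tsv",
) -> Path:
    """Write one CSV adjacency per subject plus a TSV manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for conn in connectomes:
        fname = f"{conn.subject_id}.csv"
        write_adjacency(conn, out_dir / fname)
        rows.append((conn.subject_id, conn.group, fname))
    manifest = out_dir / manifest_name
    pd.DataFrame(rows, columns=["subject_id", "group", "path"]).to_csv(
        manifest, sep="\t", index=False)
    return manifest
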
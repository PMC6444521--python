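"""Cohort data model, delimited-text I/O, and geometric utilities.

A cohort is a stack of T subject-level structural connectivity matrices
(weighted, symmetric, nonnegative, zero diagonal) defined over a common
parcellation of N brain areas.  The parcellation is described by a node
table with one row per area: a unique name, a centroid in mm, a hemisphere
label (L/R) and an optional cognitive-system label (e.g. a resting-state
network name).  The node table is the single source of truth for node
order; matrices are assumed to follow it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

NODE_COLUMNS = ("name", "x", "y", "z", "hemisphere")
HEMISPHERES = ("L", "R")
SYMMETRY_TOL = 1e-8

__all__ = [
    "CohortError",
    "EdgeClassPartition",
    "SubjectCohort",
    "euclidean_distances",
    "hemisphere_partition",
    "load_cohort",
    "load_group_network",
    "load_matrix",
    "load_node_table",
    "write_group_network",
    "write_matrix",
    "write_report",
]


class CohortError(ValueError):
    """Raised when cohort inputs violate the data-model invariants."""


# ---------------------------------------------------------------------------
# node table


def load_node_table(path: str | Path) -> pd.DataFrame:
    """Read a node metadata table (TSV: name, x, y, z, hemisphere[, system])."""
    df = pd.read_csv(path, sep="\t", dtype={"name": str})
    validate_node_table(df, source=str(path))
    return df.reset_index(drop=True)


def validate_node_table(nodes: pd.DataFrame, source: str = "node table") -> None:
    missing = [c for c in NODE_COLUMNS if c not in nodes.columns]
    if missing:
        raise CohortError(f"{source}: missing required columns {missing}")
    if nodes["name"].duplicated().any():
        dupes = nodes.loc[nodes["name"].duplicated(), "name"].tolist()
        raise CohortError(f"{source}: duplicate node names {dupes}")
    coords = nodes[["x", "y", "z"]].to_numpy(float)
    if not np.isfinite(coords).all():
        raise CohortError(f"{source}: non-finite centroid coordinates")
    bad = set(nodes["hemisphere"]) - set(HEMISPHERES)
    if bad:
        raise CohortError(
            f"{source}: hemisphere labels must be in {HEMISPHERES}, found {sorted(bad)}"
        )
    if "system" in nodes.columns and nodes["system"].isna().any():
        raise CohortError(f"{source}: system labels, when present, must cover all nodes")


# ---------------------------------------------------------------------------
# matrices


def _detect_delimiter(first_line: str) -> str:
    return "," if first_line.count(",") >= first_line.count("\t") else "\t"


def load_matrix(path: str | Path) -> np.ndarray:
    """Read a square delimited-text matrix (tab/comma autodetected).

    An optional header row/column of node ids is detected by the first cell
    being non-numeric, and stripped.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    sep = _detect_delimiter(first)
    first_cell = first.split(sep)[0].strip()
    try:
        float(first_cell) if first_cell else float("nan")
        header = False
    except ValueError:
        header = True
    if header:
        df = pd.read_csv(path, sep=sep, index_col=0)
        arr = df.to_numpy(dtype=float)
    else:
        arr = pd.read_csv(path, sep=sep, header=None).to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise CohortError(f"{path}: expected a square matrix, got shape {arr.shape}")
    return arr


def write_matrix(
    weights: np.ndarray, path: str | Path, node_ids: Sequence[str] | None = None
) -> None:
    """Write a matrix as TSV, with node ids as header row/column when given."""
    path = Path(path)
    with open(path, "w") as fh:
        if node_ids is not None:
            fh.write("node\t" + "\t".join(node_ids) + "\n")
        for i, row in enumerate(np.asarray(weights, dtype=float)):
            cells = "\t".join(format(v, ".12g") for v in row)
            if node_ids is not None:
                fh.write(f"{node_ids[i]}\t{cells}\n")
            else:
                fh.write(cells + "\n")


def validate_matrix(
    a: np.ndarray,
    n_nodes: int | None = None,
    source: str = "matrix",
    symmetry_tol: float = SYMMETRY_TOL,
    zero_diagonal: bool = True,
) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise CohortError(f"{source}: not square, shape {a.shape}")
    if n_nodes is not None and a.shape[0] != n_nodes:
        raise CohortError(
            f"{source}: has {a.shape[0]} nodes, expected {n_nodes} from node table"
        )
    if not np.isfinite(a).all():
        raise CohortError(f"{source}: non-finite entries")
    if np.abs(a - a.T).max(initial=0.0) > symmetry_tol:
        raise CohortError(f"{source}: asymmetric beyond tolerance {symmetry_tol}")
    if (a < 0).any():
        raise CohortError(f"{source}: negative entries")
    diag = np.abs(np.diag(a)).max(initial=0.0)
    if diag > 0:
        if zero_diagonal:
            raise CohortError(
                f"{source}: nonzero diagonal (max {diag}); pass zero_diagonal=False "
                "to zero it explicitly"
            )
        a = a.copy()
        np.fill_diagonal(a, 0.0)
    return a


# ---------------------------------------------------------------------------
# cohort


@dataclass(frozen=True)
class SubjectCohort:
    """T weighted symmetric connectivity matrices over a shared node table."""

    matrices: np.ndarray  # (T, N, N)
    nodes: pd.DataFrame
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrices, dtype=float)
        if m.ndim != 3:
            raise CohortError("matrices must be a (T, N, N) stack")
        object.__setattr__(self, "matrices", m)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        if len(self.subject_ids) != m.shape[0]:
            raise CohortError("subject_ids length does not match matrix count")
        if m.shape[0] < 1:
            raise CohortError("cohort needs at least one subject")
        validate_node_table(self.nodes)
        if len(self.nodes) != m.shape[1]:
            raise CohortError(
                f"node table has {len(self.nodes)} rows but matrices are "
                f"{m.shape[1]}x{m.shape[2]}"
            )
        for sid, a in zip(self.subject_ids, m):
            validate_matrix(a, n_nodes=m.shape[1], source=f"subject {sid}")

    @property
    def n_subjects(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.matrices.shape[1]

    @property
    def node_ids(self) -> tuple[str, ...]:
        return tuple(self.nodes["name"])


def load_cohort(
    matrix_paths: Sequence[str | Path],
    node_table_path: str | Path,
    zero_diagonal: bool = True,
) -> SubjectCohort:
    """Load per-subject matrices plus node metadata into a validated cohort.

    Subject order follows the order of ``matrix_paths``; subject ids are the
    file stems.  Set ``zero_diagonal=False`` to silently zero nonzero
    diagonals instead of rejecting them.
    """
    nodes = load_node_table(node_table_path)
    mats = []
    for p in matrix_paths:
        a = load_matrix(p)
        a = validate_matrix(
            a, n_nodes=len(nodes), source=str(p), zero_diagonal=zero_diagonal
        )
        mats.append(a)
    if not mats:
        raise CohortError("no matrix files given")
    ids = [Path(p).stem for p in matrix_paths]
    return SubjectCohort(np.stack(mats), nodes, tuple(ids))


# ---------------------------------------------------------------------------
# geometry and edge classes


def euclidean_distances(nodes: pd.DataFrame) -> np.ndarray:
    """Pairwise Euclidean distances (mm) between node centroids."""
    coords = nodes[["x", "y", "z"]].to_numpy(float)
    if not np.isfinite(coords).all():
        raise CohortError("non-finite centroid coordinates")
    return squareform(pdist(coords))


@dataclass(frozen=True)
class EdgeClassPartition:
    """Assignment of every unordered node pair to one of K edge classes.

    ``labels`` is an (N, N) symmetric array of class names (diagonal
    entries are meaningless and set to the empty string).
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or lab.shape[0] != lab.shape[1]:
            raise CohortError("labels must be square")
        if not (lab == lab.T).all():
            raise CohortError("labels must be symmetric")
        off = ~np.eye(lab.shape[0], dtype=bool)
        if (lab[off] == "").any():
            raise CohortError("every off-diagonal pair must have a class label")
        object.__setattr__(self, "labels", lab)

    @property
    def n_nodes(self) -> int:
        return self.labels.shape[0]

    @property
    def class_names(self) -> tuple[str, ...]:
        off = ~np.eye(self.n_nodes, dtype=bool)
        return tuple(sorted(set(self.labels[off].tolist())))

    def mask(self, name: str) -> np.ndarray:
        """Symmetric boolean mask of the pairs in class ``name`` (diag False)."""
        m = self.labels == name
        np.fill_diagonal(m, False)
        return m


def single_class_partition(n_nodes: int, name: str = "all") -> EdgeClassPartition:
    lab = np.full((n_nodes, n_nodes), name, dtype=object)
    np.fill_diagonal(lab, "")
    return EdgeClassPartition(lab)


def hemisphere_partition(nodes: pd.DataFrame) -> EdgeClassPartition:
    """Split node pairs into intra- vs inter-hemispheric edge classes."""
    if nodes["hemisphere"].isna().any():
        raise CohortError("missing hemisphere labels")
    hemi = nodes["hemisphere"].to_numpy()
    same = hemi[:, None] == hemi[None, :]
    lab = np.where(same, "intra", "inter").astype(object)
    np.fill_diagonal(lab, "")
    return EdgeClassPartition(lab)


# ---------------------------------------------------------------------------
# outputs


def write_group_network(net, path: str | Path) -> None:
    """Write a group network's weight matrix as TSV with node-id headers."""
    write_matrix(net.weights, path, node_ids=list(net.node_ids))


def load_group_network(path: str | Path):
    """Round-trip reader for :func:`write_group_network` outputs."""
    from .builders import GroupNetwork  # local import avoids a cycle

    df = pd.read_csv(path, sep="\t", index_col=0)
    return GroupNetwork(
        weights=df.to_numpy(float),
        node_ids=tuple(str(c) for c in df.columns),
        method="loaded",
        params={"source": str(path)},
    )


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, pd.DataFrame):
        return {
            "index": _jsonable(list(obj.index)),
            "columns": _jsonable(list(obj.columns)),
            "values": _jsonable(obj.to_numpy()),
        }
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


def write_report(report: Mapping, path: str | Path) -> None:
    """Serialize an evaluation/provenance report as JSON (non-finite -> null)."""
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
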
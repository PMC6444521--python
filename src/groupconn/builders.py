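"""Group-representative network construction from multi-subject cohorts.

Four construction methods are implemented, all operating on the edge
consensus matrix C (the fraction of subjects expressing each edge):

* ``simple`` -- keep every edge expressed by at least one subject, weighted
  by the mean over the expressing subjects.
* ``tau_fixed`` -- uniform consensus threshold, keep edges with C >= tau
  (default tau = 0.5).
* ``tau_avg`` -- per edge class (intra-/inter-hemispheric by default), pick
  the consensus threshold whose retained edge count is closest to the mean
  subject edge count in that class.
* ``distance`` -- distance-dependent consensus threshold: pool subject
  edge lengths per class, cut them into M equal-occupancy length bins
  (M = mean subject edge count), and in each bin keep the single candidate
  edge with the greatest consensus (ties: greatest mean weight, then
  lexicographic pair order).  The group network thereby reproduces the
  pooled subject edge-length distribution instead of over-selecting
  short-range, high-consensus edges.

The three thresholding methods share a two-step weight assignment: retained
edges first carry their simple-average weight, then weights are remapped by
rank onto quantiles of the pooled subject-level weight distribution, so the
group weight distribution matches the typical subject's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cohort import (
    CohortError,
    EdgeClassPartition,
    SubjectCohort,
    euclidean_distances,
    hemisphere_partition,
    single_class_partition,
)

logger = logging.getLogger(__name__)

METHODS = ("simple", "tau_fixed", "tau_avg", "distance")

__all__ = [
    "METHODS",
    "ConsensusMatrix",
    "DistanceBinning",
    "GroupNetwork",
    "assign_weights",
    "build_group_network",
    "compute_consensus",
    "density_matched_tau",
    "distance_binning",
    "distance_dependent_edges",
    "pooled_weights",
    "simple_average",
    "uniform_threshold_edges",
]


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class ConsensusMatrix:
    """Per-edge fraction of subjects expressing the edge (C_ij in [0, 1])."""

    entries: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        c = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", c)

    @property
    def n_nodes(self) -> int:
        return self.entries.shape[0]


@dataclass(frozen=True)
class DistanceBinning:
    """Equal-occupancy length bins for one edge class.

    ``boundaries`` are the 0, 1/M, ..., 1 quantiles of ``pooled_lengths``,
    the multiset of expressed-edge lengths pooled over subjects (an edge
    expressed by k subjects contributes k copies).
    """

    class_name: str
    n_bins: int
    boundaries: np.ndarray
    pooled_lengths: np.ndarray

    @property
    def degenerate(self) -> bool:
        return self.n_bins > 0 and self.boundaries[0] == self.boundaries[-1]


@dataclass(frozen=True)
class GroupNetwork:
    """Weighted symmetric group matrix with method provenance."""

    weights: np.ndarray
    node_ids: tuple[str, ...]
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "node_ids", tuple(self.node_ids))

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def adjacency(self) -> np.ndarray:
        return (self.weights > 0).astype(float)

    @property
    def edge_mask(self) -> np.ndarray:
        return self.weights > 0

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    @property
    def density(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2)

    def edges(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.weights, 1))
        return list(zip(i.tolist(), j.tolist()))


# ---------------------------------------------------------------------------
# consensus and simple average


def compute_consensus(cohort: SubjectCohort) -> ConsensusMatrix:
    """C_ij = fraction of subjects with a nonzero connection between i and j."""
    c = (cohort.matrices > 0).mean(axis=0)
    np.fill_diagonal(c, 0.0)
    return ConsensusMatrix(c, cohort.n_subjects)


def simple_average(cohort: SubjectCohort) -> GroupNetwork:
    """Mean weight over expressing subjects; zero where no subject expresses."""
    expressed = cohort.matrices > 0
    counts = expressed.sum(axis=0)
    sums = np.where(expressed, cohort.matrices, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        w = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    np.fill_diagonal(w, 0.0)
    return GroupNetwork(
        w, cohort.node_ids, "simple", {"n_subjects": cohort.n_subjects}
    )


# ---------------------------------------------------------------------------
# uniform / density-matched thresholds


def _upper(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def uniform_threshold_edges(
    consensus: ConsensusMatrix,
    tau: float | Mapping[str, float],
    classes: EdgeClassPartition | None = None,
) -> np.ndarray:
    """Edges with C_ij >= tau (per class when given); zero-consensus pairs
    are never retainable, so tau = 0 retains exactly the expressed edges.

    Returns a symmetric boolean mask.
    """
    c = consensus.entries
    if classes is None:
        classes = single_class_partition(consensus.n_nodes)
    if not isinstance(tau, Mapping):
        tau = {name: float(tau) for name in classes.class_names}
    mask = np.zeros_like(c, dtype=bool)
    for name in classes.class_names:
        t = float(tau[name])
        if not 0.0 <= t <= 1.0:
            raise CohortError(f"tau for class {name!r} must be in [0, 1], got {t}")
        mask |= classes.mask(name) & (c >= t) & (c > 0)
    return mask


def _class_targets(
    cohort: SubjectCohort, classes: EdgeClassPartition
) -> dict[str, int]:
    """Target edge count per class: round(mean subject edge count in class)."""
    iu, ju = _upper(cohort.n_nodes)
    expressed = cohort.matrices[:, iu, ju] > 0  # (T, n_pairs)
    targets = {}
    for name in classes.class_names:
        sel = classes.mask(name)[iu, ju]
        targets[name] = int(np.rint(expressed[:, sel].sum(axis=1).mean()))
    return targets


def density_matched_tau(
    consensus: ConsensusMatrix,
    cohort: SubjectCohort,
    classes: EdgeClassPartition | None = None,
) -> tuple[np.ndarray, dict[str, float], dict[str, int]]:
    """Per class, the consensus threshold whose retained count is closest to
    the mean subject edge count (ties resolved toward the denser network).

    Returns (edge mask, tau per class, target count per class).
    """
    if classes is None:
        classes = hemisphere_partition(cohort.nodes)
    targets = _class_targets(cohort, classes)
    c = consensus.entries
    iu, ju = _upper(consensus.n_nodes)
    mask = np.zeros_like(c, dtype=bool)
    taus: dict[str, float] = {}
    for name in classes.class_names:
        sel = classes.mask(name)[iu, ju]
        cvals = c[iu, ju][sel]
        levels = np.unique(cvals[cvals > 0])
        if levels.size == 0:
            logger.warning("edge class %r has no expressed edges", name)
            taus[name] = float("nan")
            continue
        counts = np.array([(cvals >= t).sum() for t in levels])
        err = np.abs(counts - targets[name])
        # ties in |count - target| resolved toward the larger count (lower tau)
        best = min(range(levels.size), key=lambda k: (err[k], -counts[k]))
        taus[name] = float(levels[best])
        mask |= classes.mask(name) & (c >= levels[best])
    return mask, taus, targets


# ---------------------------------------------------------------------------
# distance-dependent threshold


def pooled_edge_lengths(
    cohort: SubjectCohort,
    dist: np.ndarray,
    class_mask: np.ndarray,
) -> np.ndarray:
    """Expressed-edge lengths of one class pooled over subjects, with
    per-subject multiplicity."""
    iu, ju = _upper(cohort.n_nodes)
    sel = class_mask[iu, ju]
    lengths = dist[iu, ju][sel]
    expressed = cohort.matrices[:, iu, ju][:, sel] > 0
    return np.concatenate([lengths[e] for e in expressed]) if expressed.size else lengths[:0]


def distance_binning(
    cohort: SubjectCohort,
    dist: np.ndarray,
    classes: EdgeClassPartition | None = None,
) -> dict[str, DistanceBinning]:
    """Build per-class equal-occupancy length bins from pooled subject edges."""
    if classes is None:
        classes = hemisphere_partition(cohort.nodes)
    targets = _class_targets(cohort, classes)
    out: dict[str, DistanceBinning] = {}
    for name in classes.class_names:
        pooled = pooled_edge_lengths(cohort, dist, classes.mask(name))
        m = targets[name]
        if pooled.size == 0 or m == 0:
            logger.warning("edge class %r has no expressed edges; empty binning", name)
            out[name] = DistanceBinning(name, 0, np.array([]), pooled)
            continue
        boundaries = np.quantile(pooled, np.linspace(0.0, 1.0, m + 1))
        b = DistanceBinning(name, m, boundaries, np.sort(pooled))
        if b.degenerate:
            logger.warning("edge class %r: all pooled lengths equal; degenerate bins", name)
        out[name] = b
    return out


def distance_dependent_edges(
    consensus: ConsensusMatrix,
    binnings: Mapping[str, DistanceBinning],
    simple: GroupNetwork,
    dist: np.ndarray,
    classes: EdgeClassPartition | None = None,
) -> tuple[np.ndarray, dict[str, int]]:
    """Select, per length bin, the candidate edge with maximal consensus.

    Bins are processed short to long; an edge is selectable once; ties go to
    the greater simple-average weight, then to lexicographic pair order.
    Returns (edge mask, skipped-bin count per class).
    """
    n = consensus.n_nodes
    if classes is None:
        classes = single_class_partition(n) if set(binnings) == {"all"} else None
        if classes is None:
            raise CohortError("classes required when binnings are class-specific")
    c = consensus.entries
    mask = np.zeros((n, n), dtype=bool)
    skipped: dict[str, int] = {}
    iu, ju = _upper(n)
    for name, binning in binnings.items():
        skipped[name] = 0
        if binning.n_bins == 0:
            continue
        sel = classes.mask(name)[iu, ju] & (c[iu, ju] > 0)
        ci, cj = iu[sel], ju[sel]
        lengths = dist[ci, cj]
        cons = c[ci, cj]
        weight = simple.weights[ci, cj]
        taken = np.zeros(ci.size, dtype=bool)
        b = binning.boundaries
        for k in range(binning.n_bins):
            in_bin = ~taken & (lengths >= b[k]) & (lengths <= b[k + 1])
            idx = np.nonzero(in_bin)[0]
            if idx.size == 0:
                skipped[name] += 1
                continue
            # max consensus; ties -> max mean weight -> smallest (i, j)
            best = min(idx, key=lambda t: (-cons[t], -weight[t], ci[t], cj[t]))
            taken[best] = True
        mask[ci[taken], cj[taken]] = True
        mask[cj[taken], ci[taken]] = True
    return mask, skipped


# ---------------------------------------------------------------------------
# weights


def pooled_weights(cohort: SubjectCohort) -> np.ndarray:
    """Sorted multiset of all positive subject-level edge weights."""
    iu, ju = _upper(cohort.n_nodes)
    w = cohort.matrices[:, iu, ju].ravel()
    return np.sort(w[w > 0])


def assign_weights(
    edge_mask: np.ndarray, cohort: SubjectCohort, simple: GroupNetwork
) -> np.ndarray:
    """Two-step weight assignment for a retained edge set.

    Step 1: each retained edge carries its simple-average weight.  Step 2:
    edges are ranked by that weight (ties by pair order) and rank r of M is
    reassigned the (r-1)/(M-1) quantile of the pooled subject weight
    distribution by linear interpolation (sorted-value convention, position
    q*(P-1)), preserving rank order and matching pooled min/max exactly.
    """
    n = cohort.n_nodes
    mask = np.asarray(edge_mask, dtype=bool)
    out = np.zeros((n, n), dtype=float)
    iu, ju = _upper(n)
    sel = mask[iu, ju]
    ei, ej = iu[sel], ju[sel]
    m = ei.size
    if m == 0:
        return out
    w_simple = simple.weights[ei, ej]
    if (w_simple <= 0).any():
        raise CohortError("every retained edge must have positive simple-average weight")
    pooled = pooled_weights(cohort)
    order = np.lexsort((ej, ei, w_simple))  # ascending weight, ties by pair
    if m == 1:
        vals = np.array([np.quantile(pooled, 0.5)])
    else:
        q = np.arange(m) / (m - 1)
        vals = np.quantile(pooled, q)
    w = np.empty(m)
    w[order] = vals
    out[ei, ej] = w
    out[ej, ei] = w
    return out


# ---------------------------------------------------------------------------
# dispatcher


def build_group_network(
    method: str,
    cohort: SubjectCohort,
    tau: float = 0.5,
    hemisphere_split: bool = True,
    dist: np.ndarray | None = None,
    seed: int | None = None,
) -> GroupNetwork:
    """Build a group-representative network with full provenance.

    ``tau`` applies to the ``tau_fixed`` method only.  ``tau_avg`` and
    ``distance`` threshold intra-/inter-hemispheric edges separately unless
    ``hemisphere_split`` is False.  All methods are deterministic; ``seed``
    is recorded in the provenance for pipeline bookkeeping.
    """
    if method not in METHODS:
        raise CohortError(f"unknown method {method!r}; choose from {METHODS}")
    simple = simple_average(cohort)
    params: dict = {"n_subjects": cohort.n_subjects, "seed": seed}
    if method == "simple":
        net = GroupNetwork(simple.weights, cohort.node_ids, "simple", params)
        params["achieved_edges"] = net.n_edges
        return net

    consensus = compute_consensus(cohort)
    classes = (
        hemisphere_partition(cohort.nodes)
        if hemisphere_split
        else single_class_partition(cohort.n_nodes)
    )
    if method == "tau_fixed":
        mask = uniform_threshold_edges(consensus, tau, classes)
        params["tau"] = {name: tau for name in classes.class_names}
    elif method == "tau_avg":
        mask, taus, targets = density_matched_tau(consensus, cohort, classes)
        params["tau"] = taus
        params["target_edges"] = targets
    else:  # distance
        if dist is None:
            dist = euclidean_distances(cohort.nodes)
        binnings = distance_binning(cohort, dist, classes)
        mask, skipped = distance_dependent_edges(
            consensus, binnings, simple, dist, classes
        )
        params["target_edges"] = {k: b.n_bins for k, b in binnings.items()}
        params["skipped_bins"] = skipped
    weights = assign_weights(mask, cohort, simple)
    iu, ju = _upper(cohort.n_nodes)
    params["achieved_edges"] = {
        name: int((mask & classes.mask(name))[iu, ju].sum())
        for name in classes.class_names
    }
    return GroupNetwork(weights, cohort.node_ids, method, params)
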
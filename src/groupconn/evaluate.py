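"""Statistical comparison of group-representative networks with cohorts.

Four families of comparisons:

* nodal / edge-level distributions -- two-sample Kolmogorov-Smirnov
  statistics between the group network and every subject, with a paired
  rank test (Bonferroni-corrected over measures) to contrast methods;
* global statistics -- the group value z-scored against the subject-level
  distribution (a good group network scores near 0);
* system-level connectivity -- within-/between-system (RSN) connection
  density matrices, their Pearson correlation with the subject average, and
  a permutation test for the within-minus-between density difference
  between two group networks (null: independent row/column permutation of
  each network, re-aggregated under the fixed system labels);
* hub redistribution -- rank-transformed centrality differences between two
  networks aggregated by system and z-scored against a node-to-system
  label-permutation null, with Benjamini-Hochberg FDR for significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import measures as gm
from .builders import GroupNetwork
from .cohort import CohortError

LOCAL_MEASURES = ("degree", "strength", "clustering", "betweenness", "edge_length")
HUB_MEASURES = ("betweenness", "degree", "clustering", "participation")

__all__ = [
    "HUB_MEASURES",
    "LOCAL_MEASURES",
    "HubComparison",
    "PermutationResult",
    "compare_local_measures",
    "fdr_significant",
    "hub_rank_comparison",
    "ks_statistic",
    "local_measure_ks",
    "paired_method_test",
    "rsn_correlation",
    "rsn_density_matrix",
    "subject_average_density",
    "within_between_permutation_test",
    "zscore_global_measures",
]


# ---------------------------------------------------------------------------
# KS comparison of local measures


def ks_statistic(sample_a, sample_b) -> float:
    """Two-sample Kolmogorov-Smirnov statistic: sup |ECDF_a - ECDF_b|."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise CohortError("KS statistic needs two nonempty samples")
    return float(stats.ks_2samp(a, b).statistic)


def _local_distribution(net, measure: str, dist: np.ndarray | None = None) -> np.ndarray:
    if measure == "degree":
        return gm.degrees(net)
    if measure == "strength":
        return gm.strengths(net)
    if measure == "clustering":
        return gm.clustering(net)
    if measure == "betweenness":
        return gm.betweenness(net)
    if measure == "edge_length":
        if dist is None:
            raise CohortError("edge_length comparison needs a distance matrix")
        return gm.edge_lengths(net, dist)
    raise CohortError(f"unknown local measure {measure!r}")


def local_measure_ks(
    group,
    cohort,
    measures=LOCAL_MEASURES,
    dist: np.ndarray | None = None,
) -> pd.DataFrame:
    """KS statistic between the group and each subject, per local measure.

    Rows are measures, columns subject ids.
    """
    rows = {}
    for m in measures:
        g_vals = _local_distribution(group, m, dist)
        row = []
        for s in range(cohort.n_subjects):
            s_vals = _local_distribution(cohort.matrices[s], m, dist)
            row.append(ks_statistic(g_vals, s_vals))
        rows[m] = row
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(cohort.subject_ids)
    )


def paired_method_test(ks_a: pd.DataFrame, ks_b: pd.DataFrame) -> pd.DataFrame:
    """Two-sided Wilcoxon signed-rank test of per-subject KS values between
    two methods, Bonferroni-corrected over measures.

    Returns a frame with the mean KS difference (a - b), raw and corrected
    p-values per measure.  With a single subject no test is possible and
    p is NaN (flagged by the ``testable`` column).
    """
    out = []
    n_measures = len(ks_a.index)
    for m in ks_a.index:
        d = ks_a.loc[m].to_numpy() - ks_b.loc[m].to_numpy()
        testable = d.size >= 2 and np.any(d != 0)
        if testable:
            p = float(stats.wilcoxon(ks_a.loc[m], ks_b.loc[m]).pvalue)
        else:
            p = float("nan")
        out.append(
            {
                "measure": m,
                "mean_diff": float(d.mean()),
                "p": p,
                "p_bonferroni": min(1.0, p * n_measures) if testable else float("nan"),
                "testable": testable,
            }
        )
    return pd.DataFrame(out).set_index("measure")


def compare_local_measures(
    groups: dict[str, GroupNetwork],
    cohort,
    measures=LOCAL_MEASURES,
    dist: np.ndarray | None = None,
) -> tuple[dict[str, pd.DataFrame], dict[tuple[str, str], pd.DataFrame]]:
    """Per-method KS tables plus all pairwise method contrasts."""
    tables = {
        name: local_measure_ks(net, cohort, measures, dist)
        for name, net in groups.items()
    }
    names = list(tables)
    contrasts = {
        (a, b): paired_method_test(tables[a], tables[b])
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    }
    return tables, contrasts


# ---------------------------------------------------------------------------
# global z-scores


def zscore_global_measures(
    group,
    cohort,
    gamma: float = 1.0,
    repetitions: int = 20,
    seed: int | None = None,
) -> pd.DataFrame:
    """Group global statistics z-scored against the subject distribution.

    z = (x_group - mean_s x_s) / sd_s(x_s); zero subject variance gives a
    NaN z (flagged).  A z near 0 means the group network sits at the
    typical subject's value.
    """
    if cohort.n_subjects < 2:
        raise CohortError("z-scoring needs at least two subjects")
    rng = np.random.default_rng(seed)
    g_vals = gm.global_measures(
        group, gamma=gamma, repetitions=repetitions, seed=int(rng.integers(2**31 - 1))
    )
    subj = [
        gm.global_measures(
            cohort.matrices[s],
            gamma=gamma,
            repetitions=repetitions,
            seed=int(rng.integers(2**31 - 1)),
        )
        for s in range(cohort.n_subjects)
    ]
    rows = []
    for key, gv in g_vals.items():
        xs = np.array([sv[key] for sv in subj], dtype=float)
        mean, sd = float(np.nanmean(xs)), float(np.nanstd(xs, ddof=1))
        z = (gv - mean) / sd if sd > 0 else float("nan")
        rows.append(
            {
                "measure": key,
                "group": gv,
                "subject_mean": mean,
                "subject_sd": sd,
                "z": z,
            }
        )
    return pd.DataFrame(rows).set_index("measure")


# ---------------------------------------------------------------------------
# system (RSN) density analysis


def _system_info(nodes: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    if "system" not in nodes.columns or nodes["system"].isna().any():
        raise CohortError("system labels are required for RSN analyses")
    systems = sorted(nodes["system"].unique())
    return nodes["system"].to_numpy(), systems


def _density_matrix(adj: np.ndarray, labels: np.ndarray, systems: list[str]) -> np.ndarray:
    indicator = (labels[:, None] == np.array(systems)[None, :]).astype(float)
    counts = indicator.T @ adj @ indicator
    n_per = indicator.sum(axis=0)
    possible = np.outer(n_per, n_per)
    np.fill_diagonal(possible, n_per * (n_per - 1))  # ordered within-system pairs
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = np.where(possible > 0, counts / np.where(possible > 0, possible, 1), np.nan)
    return dens


def rsn_density_matrix(net, nodes: pd.DataFrame, weighted: bool = False) -> pd.DataFrame:
    """S x S connection density within and between systems.

    Entry (a, b) is the number (or, with ``weighted=True``, mean weight) of
    edges between systems a and b over the number of possible pairs; the
    diagonal uses n_a (n_a - 1) / 2 possible pairs.  Systems with fewer
    than 2 nodes get an undefined (NaN) diagonal entry.
    """
    w = np.asarray(getattr(net, "weights", net), dtype=float)
    mat = w if weighted else (w > 0).astype(float)
    labels, systems = _system_info(nodes)
    dens = _density_matrix(mat, labels, systems)
    return pd.DataFrame(dens, index=systems, columns=systems)


def subject_average_density(cohort, weighted: bool = False) -> pd.DataFrame:
    """Elementwise average of the per-subject system density matrices."""
    mats = [
        rsn_density_matrix(cohort.matrices[s], cohort.nodes, weighted)
        for s in range(cohort.n_subjects)
    ]
    return sum(mats) / len(mats)


def rsn_correlation(group_density: pd.DataFrame, subject_density: pd.DataFrame) -> float:
    """Pearson r over the upper-triangle-plus-diagonal density entries."""
    a = group_density.to_numpy(float)
    b = subject_density.to_numpy(float)
    if a.shape != b.shape:
        raise CohortError("density matrices must have matching systems")
    iu, ju = np.triu_indices(a.shape[0], k=0)
    x, y = a[iu, ju], b[iu, ju]
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        import warnings

        warnings.warn("RSN density correlation undefined (zero variance)")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    null: np.ndarray
    p: float
    p_two_sided: float
    n_perm: int
    seed: int | None


def _within_between_delta(dens_a: np.ndarray, dens_b: np.ndarray) -> float:
    s = dens_a.shape[0]
    diff = dens_a - dens_b
    diag = np.diag(diff)
    iu, ju = np.triu_indices(s, k=1)
    off = diff[iu, ju]
    return float(np.nanmean(diag) - np.nanmean(off))


def within_between_permutation_test(
    net_a,
    net_b,
    nodes: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
    weighted: bool = False,
) -> PermutationResult:
    """Permutation test for the within-minus-between system density
    difference between two group networks.

    Observed statistic: mean within-system density difference (a - b) minus
    mean between-system density difference.  The null permutes the node
    order of each network independently and re-aggregates under the fixed
    system labels.  p uses the add-one estimator (never exactly zero).
    """
    if n_perm < 100:
        raise CohortError("n_perm must be >= 100")
    labels, systems = _system_info(nodes)
    wa = np.asarray(getattr(net_a, "weights", net_a), dtype=float)
    wb = np.asarray(getattr(net_b, "weights", net_b), dtype=float)
    mat_a = wa if weighted else (wa > 0).astype(float)
    mat_b = wb if weighted else (wb > 0).astype(float)
    observed = _within_between_delta(
        _density_matrix(mat_a, labels, systems),
        _density_matrix(mat_b, labels, systems),
    )
    rng = np.random.default_rng(seed)
    n = len(labels)
    null = np.empty(n_perm)
    for k in range(n_perm):
        pa, pb = rng.permutation(n), rng.permutation(n)
        null[k] = _within_between_delta(
            _density_matrix(mat_a, labels[pa], systems),
            _density_matrix(mat_b, labels[pb], systems),
        )
    p = (1 + int((null >= observed).sum())) / (1 + n_perm)
    p2 = (1 + int((np.abs(null) >= abs(observed)).sum())) / (1 + n_perm)
    return PermutationResult(observed, null, float(p), float(p2), n_perm, seed)


# ---------------------------------------------------------------------------
# hub rank redistribution


def fdr_significant(pvals, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg FDR at ``alpha``; NaN p-values are not significant."""
    p = np.asarray(pvals, dtype=float)
    ok = np.isfinite(p)
    out = np.zeros(p.shape, dtype=bool)
    if ok.any():
        out[ok] = multipletests(p[ok], alpha=alpha, method="fdr_bh")[0]
    return out


@dataclass(frozen=True)
class HubComparison:
    rank_diffs: pd.DataFrame  # measures x nodes, rank_a - rank_b
    system_means: pd.DataFrame  # measures x systems
    system_z: pd.DataFrame
    system_p: pd.DataFrame
    significant: pd.DataFrame
    n_perm: int
    seed: int | None


def _hub_measure(net, measure: str, partition) -> np.ndarray:
    if measure == "degree":
        return gm.degrees(net)
    if measure == "betweenness":
        return gm.betweenness(net)
    if measure == "clustering":
        return gm.clustering(net)
    if measure == "participation":
        return gm.participation(net, partition)
    raise CohortError(f"unknown hub measure {measure!r}")


def hub_rank_comparison(
    net_a,
    net_b,
    nodes: pd.DataFrame,
    measures=HUB_MEASURES,
    n_perm: int = 1000,
    seed: int | None = None,
    gamma: float = 1.0,
    repetitions: int = 20,
) -> HubComparison:
    """Rank-transformed hub redistribution between two networks, aggregated
    by system and z-scored against a node-to-system permutation null.

    Each measure is rank-transformed within each network (average ranks for
    ties); per-node difference is rank_a - rank_b.  System means are
    compared against the distribution obtained by shuffling the node-to-
    system assignment ``n_perm`` times; two-sided permutation p-values are
    corrected with Benjamini-Hochberg FDR at 5% across systems per measure.
    Participation uses a best-of-``repetitions`` Louvain partition at
    resolution ``gamma``, computed per network.
    """
    labels, systems = _system_info(nodes)
    rng = np.random.default_rng(seed)
    part_a = part_b = None
    if "participation" in measures:
        # one shared seed: identical networks then get identical partitions
        louvain_seed = int(rng.integers(2**31 - 1))
        part_a = gm.modularity_louvain(
            (np.asarray(getattr(net_a, "weights", net_a)) > 0).astype(float),
            gamma=gamma,
            seed=louvain_seed,
            repetitions=repetitions,
        )
        part_b = gm.modularity_louvain(
            (np.asarray(getattr(net_b, "weights", net_b)) > 0).astype(float),
            gamma=gamma,
            seed=louvain_seed,
            repetitions=repetitions,
        )
    diffs = {}
    for m in measures:
        va = _hub_measure(net_a, m, part_a)
        vb = _hub_measure(net_b, m, part_b)
        diffs[m] = stats.rankdata(va) - stats.rankdata(vb)
    rank_diffs = pd.DataFrame.from_dict(diffs, orient="index")

    indicator = labels[:, None] == np.array(systems)[None, :]
    n_per = indicator.sum(axis=0)
    obs = {
        m: (rank_diffs.loc[m].to_numpy() @ indicator) / n_per for m in measures
    }
    perms = np.stack([rng.permutation(len(labels)) for _ in range(n_perm)])
    z_rows, p_rows = {}, {}
    for m in measures:
        d = rank_diffs.loc[m].to_numpy()
        null = (d[perms] @ indicator) / n_per  # (n_perm, S)
        mu, sd = null.mean(axis=0), null.std(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, (obs[m] - mu) / np.where(sd > 0, sd, 1), 0.0)
        z = np.where((sd == 0) & (obs[m] != mu), np.nan, z)
        p = (1 + (np.abs(null - mu) >= np.abs(obs[m] - mu)[None, :]).sum(axis=0)) / (
            1 + n_perm
        )
        z_rows[m], p_rows[m] = z, p
    system_means = pd.DataFrame(obs, index=systems).T
    system_z = pd.DataFrame(z_rows, index=systems).T
    system_p = pd.DataFrame(p_rows, index=systems).T
    significant = pd.DataFrame(
        {m: fdr_significant(system_p.loc[m]) for m in system_p.index},
        index=systems,
    ).T
    return HubComparison(
        rank_diffs, system_means, system_z, system_p, significant, n_perm, seed
    )
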
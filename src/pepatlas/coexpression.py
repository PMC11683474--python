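"""Weighted coexpression network construction and module analysis.

The weighted-network recipe: Pearson correlation of log2(x+1) abundance
profiles, unsigned adjacency a_ij = |r_ij|^beta with the soft power beta
chosen as the smallest candidate whose scale-free topology fit R^2
exceeds a floor while mean connectivity stays below a ceiling; the
topological overlap matrix (TOM)

    w_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    L_ij = sum_{u != i,j} a_iu * a_uj

as clustering similarity; average-linkage hierarchical clustering on
1 - w with a deterministic static tree cut (the height maximizing the
number of clusters of at least ``min_module_size`` members, ties to the
lower height); first-principal-component module eigengenes; and
eigengene-tissue / eigengene-eigengene correlation summaries.  The
static cut replaces the dynamic hybrid tree cut of the canonical WGCNA
workflow - a deliberate simplification that keeps module detection fully
deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist

logger = logging.getLogger(__name__)

__all__ = [
    "SoftThresholdResult",
    "CoexpressionNetwork",
    "MODULE_COLORS",
    "filter_for_network",
    "adjacency_matrix",
    "scale_free_fit",
    "pick_soft_threshold",
    "topological_overlap",
    "build_network",
    "detect_modules",
    "intramodular_adjacency_summary",
    "module_eigengene",
    "module_tissue_correlation",
    "eigengene_adjacency_clustering",
]

#: Conventional module color names, assigned by descending module size.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
)
GREY = "grey"


@dataclass(frozen=True)
class SoftThresholdResult:
    powers: tuple[int, ...]
    fit_r2: tuple[float, ...]
    mean_connectivity: tuple[float, ...]
    chosen: int
    satisfied: bool


@dataclass
class CoexpressionNetwork:
    node_ids: list[str]
    beta: int
    adjacency: np.ndarray
    tom: np.ndarray

    @property
    def connectivity(self) -> np.ndarray:
        return self.adjacency.sum(axis=1) - 1.0  # diagonal excluded


def filter_for_network(matrix: pd.DataFrame, min_detected_tissues: int = 6) -> pd.DataFrame:
    """Keep broadly detected rows and move to log2(x+1) scale."""
    detected = (matrix > 0).sum(axis=1)
    kept = matrix[detected >= min_detected_tissues]
    if len(kept) < 3:
        raise ValueError(
            f"only {len(kept)} rows detected in >= {min_detected_tissues} tissues; "
            "network undefined")
    return np.log2(kept + 1.0)


def _correlation(matrix: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    values = matrix.to_numpy(dtype=float)
    sds = values.std(axis=1)
    keep = sds > 0
    if not keep.all():
        logger.warning("removed %d constant rows before correlation", (~keep).sum())
    values = values[keep]
    if len(values) < 3:
        raise ValueError("fewer than 3 non-constant rows; correlation undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(values)
    return np.clip(corr, -1.0, 1.0), list(matrix.index[keep])


def adjacency_matrix(matrix: pd.DataFrame, beta: int) -> tuple[np.ndarray, list[str]]:
    """Unsigned weighted adjacency |r|^beta with unit diagonal."""
    corr, ids = _correlation(matrix)
    adj = np.abs(corr) ** beta
    np.fill_diagonal(adj, 1.0)
    return adj, ids


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Scale-free topology fit index.

    Connectivities are binned into ``n_bins`` equal-count bins; R^2 is the
    squared correlation between log10(mean connectivity) and log10(bin
    frequency), set to 0 when the regression slope is positive (a
    scale-free degree distribution must decay).
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0
    order = np.argsort(k, kind="stable")
    bins = np.array_split(order, n_bins)
    mean_k = np.array([k[b].mean() for b in bins if len(b)])
    freq = np.array([len(b) / k.size for b in bins if len(b)])
    log_k, log_p = np.log10(mean_k), np.log10(freq)
    if np.ptp(log_k) == 0 or np.ptp(log_p) == 0:
        return 0.0
    r = np.corrcoef(log_k, log_p)[0, 1]
    if not np.isfinite(r):
        return 0.0
    slope = r * log_p.std() / log_k.std()
    return 0.0 if slope > 0 else float(r * r)


def pick_soft_threshold(
    matrix: pd.DataFrame,
    candidates: range | tuple[int, ...] = range(1, 21),
    fit_min: float = 0.80,
    k_max: float = 100.0,
) -> SoftThresholdResult:
    """Choose the soft power: smallest beta with fit R^2 > fit_min and mean
    connectivity below k_max; if none qualifies, fall back to the beta with
    the best fit and flag the result as unsatisfied."""
    if len(matrix) < 20:
        logger.warning("soft-threshold selection on only %d rows", len(matrix))
    corr, _ids = _correlation(matrix)
    abs_corr = np.abs(corr)
    np.fill_diagonal(abs_corr, 0.0)
    fits, mean_ks = [], []
    for beta in candidates:
        adj = abs_corr ** beta
        k = adj.sum(axis=1)
        fits.append(scale_free_fit(k))
        mean_ks.append(float(k.mean()))
    chosen, satisfied = None, True
    for beta, r2, mk in zip(candidates, fits, mean_ks):
        if r2 > fit_min and mk < k_max:
            chosen = beta
            break
    if chosen is None:
        satisfied = False
        chosen = list(candidates)[int(np.argmax(fits))]
        logger.warning("no candidate power met fit>%.2f and k<%g; "
                       "falling back to beta=%d", fit_min, k_max, chosen)
    return SoftThresholdResult(tuple(candidates), tuple(fits), tuple(mean_ks),
                               int(chosen), satisfied)


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a weighted adjacency (unit diagonal)."""
    a = np.asarray(adjacency, dtype=float)
    k = a.sum(axis=1) - 1.0
    # L_ij over u != i, j: full product minus the u = i and u = j terms
    L = a @ a - 2.0 * a  # uses a_ii = a_jj = 1
    min_k = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + a) / (min_k + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0, posinf=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def build_network(matrix: pd.DataFrame, beta: int) -> CoexpressionNetwork:
    adj, ids = adjacency_matrix(matrix, beta)
    return CoexpressionNetwork(ids, beta, adj, topological_overlap(adj))


def detect_modules(tom: np.ndarray, node_ids: list[str],
                   min_module_size: int = 30) -> pd.Series:
    """Static tree cut of the average-linkage TOM-dissimilarity dendrogram.

    The cut height is chosen among the merge heights as the one whose flat
    clustering maximizes the number of clusters with at least
    ``min_module_size`` members; ties are resolved by the fewest leftover
    (sub-threshold) nodes and then toward the lower height.
    Clusters below the size floor become "grey"; surviving modules get
    conventional color labels in order of decreasing size, ties broken by
    the lexicographically smallest member id.
    """
    n = len(node_ids)
    if n < min_module_size:
        raise ValueError("fewer nodes than min_module_size")
    diss = 1.0 - np.asarray(tom)
    np.fill_diagonal(diss, 0.0)
    Z = linkage(squareform(diss, checks=False), method="average")
    heights = np.unique(Z[:, 2])
    best_height, best_key = None, None
    for h in heights:
        labels = fcluster(Z, t=h, criterion="distance")
        sizes = np.bincount(labels)[1:]
        count = int((sizes >= min_module_size).sum())
        assigned = int(sizes[sizes >= min_module_size].sum())
        key = (count, assigned)  # more big clusters, then fewer grey nodes
        if best_key is None or key > best_key:
            best_key, best_height = key, h
    labels = fcluster(Z, t=best_height, criterion="distance")
    series = pd.Series(labels, index=node_ids)
    keep = [lab for lab, size in series.value_counts().items()
            if size >= min_module_size]
    # order modules by size desc, then smallest member id, for stable colors
    def sort_key(lab):
        members = series.index[series == lab]
        return (-len(members), min(members))
    ordered = sorted(keep, key=sort_key)
    color_of = {lab: MODULE_COLORS[i % len(MODULE_COLORS)]
                for i, lab in enumerate(ordered)}
    return series.map(lambda lab: color_of.get(lab, GREY))


def module_eigengene(matrix: pd.DataFrame, assignment: pd.Series):
    """First-PC eigengenes of each module's row-standardized submatrix.

    Returns ``(eigengenes, variance_explained)``: eigengenes is a module x
    tissue frame with unit-norm rows, sign-oriented so each eigengene
    correlates positively with its module's mean standardized profile.
    Grey (unassigned) nodes are skipped.  Also serves as the generic
    first-principal-component routine for dataset-level comparisons.
    """
    eig_rows, var_rows, names = [], [], []
    for module in sorted(set(assignment) - {GREY}):
        members = assignment.index[assignment == module]
        sub = matrix.loc[members].to_numpy(dtype=float)
        sds = sub.std(axis=1, ddof=1)
        sds[sds == 0] = 1.0
        standardized = (sub - sub.mean(axis=1, keepdims=True)) / sds[:, None]
        if standardized.shape[0] == 1:
            vec = standardized[0]
            vec = vec / np.linalg.norm(vec)
            var = 1.0
        else:
            _u, s, vt = np.linalg.svd(standardized, full_matrices=False)
            vec = vt[0]
            var = float(s[0] ** 2 / (s ** 2).sum())
        mean_profile = standardized.mean(axis=0)
        if np.dot(vec, mean_profile) < 0:
            vec = -vec
        eig_rows.append(vec)
        var_rows.append(var)
        names.append(module)
    eigengenes = pd.DataFrame(eig_rows, index=pd.Index(names, name="module"),
                              columns=matrix.columns)
    variance = pd.Series(var_rows, index=eigengenes.index, name="variance_explained")
    return eigengenes, variance


def module_tissue_correlation(eigengenes: pd.DataFrame):
    """Pearson r of each eigengene against each one-hot tissue indicator,
    with Student-t p-values; returns ``(r, p)`` module x tissue frames."""
    tissues = list(eigengenes.columns)
    if len(tissues) < 3:
        raise ValueError("need at least 3 tissues")
    n = len(tissues)
    r_mat = pd.DataFrame(index=eigengenes.index, columns=tissues, dtype=float)
    p_mat = r_mat.copy()
    for tissue in tissues:
        indicator = np.array([1.0 if t == tissue else 0.0 for t in tissues])
        for module in eigengenes.index:
            x = eigengenes.loc[module].to_numpy(dtype=float)
            r = float(np.corrcoef(x, indicator)[0, 1])
            r_clamped = min(max(r, -0.9999999), 0.9999999)
            stat = r_clamped * np.sqrt((n - 2) / (1 - r_clamped ** 2))
            p = 2.0 * t_dist.sf(abs(stat), df=n - 2)
            r_mat.at[module, tissue] = r
            p_mat.at[module, tissue] = p
    return r_mat, p_mat


def eigengene_adjacency_clustering(eigengenes: pd.DataFrame):
    """Eigengene adjacency (1 + cor) / 2 and its average-linkage dendrogram.

    Returns ``(adjacency, linkage_matrix)``; adjacency is 1 for identical
    and 0 for perfectly anti-correlated eigengenes.
    """
    if len(eigengenes) < 2:
        raise ValueError("need at least 2 module eigengenes")
    corr = np.corrcoef(eigengenes.to_numpy(dtype=float))
    adjacency = pd.DataFrame((1.0 + np.clip(corr, -1, 1)) / 2.0,
                             index=eigengenes.index, columns=eigengenes.index)
    diss = 1.0 - adjacency.to_numpy()
    np.fill_diagonal(diss, 0.0)
    Z = linkage(squareform(np.clip(diss, 0, None), checks=False), method="average")
    return adjacency, Z


def intramodular_adjacency_summary(network: CoexpressionNetwork,
                                   assignment: pd.Series) -> dict[str, float]:
    """Mean node adjacency within versus between modules (interaction
    strength summary); grey nodes are ignored."""
    idx = {nid: i for i, nid in enumerate(network.node_ids)}
    intra, inter = [], []
    nodes = [nid for nid in assignment.index if assignment[nid] != GREY and nid in idx]
    for a_pos, na in enumerate(nodes):
        for nb in nodes[a_pos + 1:]:
            val = network.adjacency[idx[na], idx[nb]]
            (intra if assignment[na] == assignment[nb] else inter).append(val)
    return {
        "mean_intramodular_adjacency": float(np.mean(intra)) if intra else float("nan"),
        "mean_intermodular_adjacency": float(np.mean(inter)) if inter else float("nan"),
    }
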
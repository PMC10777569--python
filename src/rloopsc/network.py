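"""Signed weighted coexpression network over a regulator gene list.

The pipeline mirrors the classical weighted-network workflow: a signed
adjacency ``a_ij = ((1 + cor_ij)/2)^beta`` with the soft power chosen by the
scale-free topology criterion, topological overlap (TOM) similarity,
average-linkage clustering of ``1 - TOM`` with a recursive tree cut, module
eigengenes (first principal component), eigengene-similarity merging, and
module-trait correlation to select the score gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from scipy import stats

logger = logging.getLogger(__name__)

GREY = "grey"


@dataclass
class ModuleAssignment:
    """Gene -> module labels plus module summaries and trait statistics."""

    labels: pd.Series  # gene -> module label; GREY = unassigned
    eigengenes: pd.DataFrame  # observations x modules, unit-norm columns
    beta: float | None = None
    trait_stats: pd.DataFrame | None = None
    warnings: list = field(default_factory=list)

    @property
    def modules(self) -> list:
        return [m for m in self.eigengenes.columns]

    def genes_in(self, module: str) -> list:
        return list(self.labels.index[self.labels == module])


def _safe_corr(X: np.ndarray) -> np.ndarray:
    """Pearson correlation between columns; constant columns correlate 0."""
    sd = X.std(axis=0)
    ok = sd > 0
    C = np.zeros((X.shape[1], X.shape[1]))
    if ok.any():
        C[np.ix_(ok, ok)] = np.corrcoef(X[:, ok], rowvar=False)
    np.fill_diagonal(C, 1.0)
    return np.clip(C, -1.0, 1.0)


def signed_adjacency(expr, beta: float) -> np.ndarray:
    """``((1 + cor)/2) ** beta`` over gene pairs; diagonal zeroed."""
    X = np.asarray(expr, dtype=float)
    A = ((1.0 + _safe_corr(X)) / 2.0) ** beta
    np.fill_diagonal(A, 0.0)
    return A


def scale_free_fit(k: np.ndarray, n_bins: int = 10):
    """Scale-free topology fit of a connectivity vector.

    Bins connectivities into ``n_bins`` equal-width bins and regresses
    log10(frequency) on log10(mean connectivity per bin). Returns
    ``(r_squared, slope)`` where the fit only supports scale-free topology
    when the slope is negative.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if len(k) < 3 or np.ptp(k) == 0:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq = np.bincount(which, minlength=n_bins).astype(float)
    mean_k = np.array(
        [k[which == b].mean() if freq[b] else np.nan for b in range(n_bins)]
    )
    ok = (freq > 0) & (mean_k > 0)
    if ok.sum() < 3:
        return 0.0, 0.0
    x, y = np.log10(mean_k[ok]), np.log10(freq[ok])
    slope, _, r, _, _ = stats.linregress(x, y)
    return float(r**2), float(slope)


def pick_soft_threshold(expr, powers=range(1, 21), r2_target: float = 0.85):
    """Smallest power whose signed network satisfies scale-free topology.

    Returns ``(beta, table)`` where ``table`` has one row per power with
    columns ``power``, ``r_squared``, ``slope``, ``mean_k``. If no power
    reaches ``r2_target`` (with negative slope), the power with the best fit
    is returned and a warning is logged.
    """
    X = np.asarray(expr, dtype=float)
    if X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("need >= 2 genes and >= 3 observations")
    rows = []
    for p in powers:
        A = signed_adjacency(X, p)
        k = A.sum(axis=1)
        r2, slope = scale_free_fit(k)
        rows.append({"power": p, "r_squared": r2, "slope": slope, "mean_k": k.mean()})
    table = pd.DataFrame(rows)
    ok = table[(table.r_squared >= r2_target) & (table.slope < 0)]
    if len(ok):
        beta = int(ok.iloc[0].power)
    else:
        signed_r2 = np.where(table.slope < 0, table.r_squared, -table.r_squared)
        beta = int(table.power.iloc[int(np.argmax(signed_r2))])
        logger.warning(
            "no power reached scale-free R^2 >= %g; using best fit beta=%d",
            r2_target, beta,
        )
    return beta, table


def build_tom(expr, beta: float, signed: bool = True) -> np.ndarray:
    """Topological overlap similarity of the signed network.

    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``,
    symmetric with unit diagonal, values in [0, 1].
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    A = signed_adjacency(expr, beta)
    k = A.sum(axis=1)
    shared = A @ A  # diagonal irrelevant: a_ii = 0
    numer = shared + A
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, numer / denom, 0.0)
    tom = (tom + tom.T) / 2.0
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def _tree_cut(Z: np.ndarray, n_leaves: int, min_size: int, cut_frac: float = 0.99):
    """Static cut near the dendrogram top, then recursive branch splitting.

    A branch is split whenever both children hold at least ``min_size``
    leaves; terminal pieces smaller than ``min_size`` become unassigned.
    """
    heights = Z[:, 2]
    cut_h = cut_frac * heights.max() if len(heights) else 0.0
    flat = sch.fcluster(Z, t=cut_h, criterion="distance")
    tree = sch.to_tree(Z)

    clusters = []

    def split(node):
        if node.is_leaf():
            clusters.append([node.id])
            return
        left, right = node.get_left(), node.get_right()
        if left.get_count() >= min_size and right.get_count() >= min_size:
            split(left)
            split(right)
        else:
            clusters.append(node.pre_order(lambda n: n.id))

    # recurse independently inside each top-level cluster
    def descend(node):
        ids = node.pre_order(lambda n: n.id)
        if len(set(flat[ids])) == 1:
            split(node)
        elif not node.is_leaf():
            descend(node.get_left())
            descend(node.get_right())
        else:
            clusters.append([node.id])

    descend(tree)
    labels = np.full(n_leaves, -1, dtype=int)
    next_label = 0
    for ids in clusters:
        if len(ids) >= min_size:
            labels[ids] = next_label
            next_label += 1
    return labels


def _eigengene(X: np.ndarray) -> np.ndarray:
    """First principal component of column-standardized expression.

    Unit norm, sign-oriented so correlation with mean expression is >= 0.
    """
    sd = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    u, s, _ = np.linalg.svd(Z, full_matrices=False)
    e = u[:, 0]
    mean_profile = X.mean(axis=1)
    if np.std(mean_profile) > 0 and np.corrcoef(e, mean_profile)[0, 1] < 0:
        e = -e
    return e


def detect_modules(
    tom: np.ndarray,
    expr,
    min_module_size: int = 10,
    merge_height: float = 0.25,
) -> ModuleAssignment:
    """Cluster ``1 - TOM``, prune small branches, merge similar eigengenes.

    ``expr`` is the observations x genes matrix (DataFrame or array) the TOM
    was built from; gene order must match the TOM axes.
    """
    tom = np.asarray(tom)
    if tom.ndim != 2 or tom.shape[0] != tom.shape[1]:
        raise ValueError("tom must be square")
    if not np.allclose(tom, tom.T, atol=1e-8):
        raise ValueError("tom must be symmetric")
    gene_names = (
        pd.Index(expr.columns) if isinstance(expr, pd.DataFrame)
        else pd.Index([f"g{i}" for i in range(tom.shape[0])])
    )
    X = np.asarray(expr, dtype=float)
    n = tom.shape[0]
    warnings = []
    if n < min_module_size:
        warnings.append("fewer genes than min_module_size; all grey")
        return ModuleAssignment(
            labels=pd.Series(GREY, index=gene_names),
            eigengenes=pd.DataFrame(index=range(X.shape[0])),
            warnings=warnings,
        )

    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    Z = sch.linkage(ssd.squareform(dissim, checks=False), method="average")
    raw = _tree_cut(Z, n, min_module_size)

    # iterative eigengene merge until no pair is closer than merge_height
    groups = {lab: np.flatnonzero(raw == lab) for lab in np.unique(raw) if lab >= 0}
    while len(groups) > 1:
        labs = sorted(groups)
        E = np.column_stack([_eigengene(X[:, groups[l]]) for l in labs])
        C = np.corrcoef(E, rowvar=False)
        np.fill_diagonal(C, -np.inf)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        if 1.0 - C[i, j] >= merge_height:
            break
        keep, drop = labs[min(i, j)], labs[max(i, j)]
        groups[keep] = np.sort(np.concatenate([groups[keep], groups[drop]]))
        del groups[drop]

    # stable naming: M1, M2, ... by decreasing size then first gene index
    ordered = sorted(groups.values(), key=lambda idx: (-len(idx), idx[0]))
    labels = pd.Series(GREY, index=gene_names, dtype=object)
    eig = {}
    for rank, idx in enumerate(ordered, start=1):
        name = f"M{rank}"
        labels.iloc[idx] = name
        eig[name] = _eigengene(X[:, idx])
    eigengenes = pd.DataFrame(eig, index=(
        expr.index if isinstance(expr, pd.DataFrame) else range(X.shape[0])
    ))
    if not eig:
        warnings.append("no module met min_module_size; all grey")
    return ModuleAssignment(labels=labels, eigengenes=eigengenes, warnings=warnings)


def module_trait_correlation(assignment: ModuleAssignment, traits: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and two-sided p per (module, trait); pairwise NA deletion.

    Binary traits should be coded 0/1 and ordered stages 1..4 by the caller.
    Constant traits yield missing statistics.
    """
    E = assignment.eigengenes
    if len(traits) != len(E):
        raise ValueError("traits must align with the eigengene observation axis")
    rows = []
    for module in E.columns:
        for trait in traits.columns:
            x = E[module].to_numpy(dtype=float)
            y = pd.to_numeric(traits[trait], errors="coerce").to_numpy(dtype=float)
            ok = ~np.isnan(x) & ~np.isnan(y)
            if ok.sum() < 3 or np.std(y[ok]) == 0 or np.std(x[ok]) == 0:
                rows.append({"module": module, "trait": trait, "r": np.nan, "p": np.nan})
                continue
            r, p = stats.pearsonr(x[ok], y[ok])
            rows.append({"module": module, "trait": trait, "r": r, "p": p})
    stats_table = pd.DataFrame(rows)
    assignment.trait_stats = stats_table
    return stats_table


def select_score_genes(
    assignment: ModuleAssignment,
    alpha: float = 0.05,
    traits: list | None = None,
) -> list:
    """Union of genes in modules significantly tied to any listed trait."""
    ts = assignment.trait_stats
    if ts is None:
        raise ValueError("run module_trait_correlation first")
    sub = ts if traits is None else ts[ts.trait.isin(traits)]
    chosen = sorted(set(sub.loc[sub.p < alpha, "module"]))
    if not chosen:
        logger.warning("no module significantly associated with the listed traits")
        return []
    genes = []
    for module in chosen:
        genes.extend(assignment.genes_in(module))
    return sorted(set(genes))
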
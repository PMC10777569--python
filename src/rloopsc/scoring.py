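"""Background-corrected gene-set scoring and high/low stratification.

The score of an observation (cell or bulk sample) for a gene set is
``S_center - S_random``: the mean centered expression of the set genes minus
the same quantity for expression-matched control genes. Controls are drawn
per set gene from its equal-frequency bin of the per-gene average
expression, so the correction removes the trivial effect of overall
expression level. Higher score = higher set expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class ScoreVector:
    """Per-observation score with its stratification and provenance."""

    scores: pd.Series
    subgroup: pd.Series | None = None  # {"high", "low"}
    gene_set_used: list = field(default_factory=list)
    n_bins: int = 25
    n_samplings: int | None = 1000
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"score": self.scores})
        if self.subgroup is not None:
            df["subgroup"] = self.subgroup
        return df


def _expression_matrix(m, layer: str):
    if isinstance(m, CountMatrix):
        if layer not in m.layers:
            raise ValueError(f"layer {layer!r} missing; run lognormalize first")
        return m.layers[layer], m.gene_names, m.cell_names
    X = np.asarray(m, dtype=float)
    return X, pd.Index([f"g{i}" for i in range(X.shape[1])]), pd.RangeIndex(X.shape[0])


def score_gene_set(
    m,
    gene_set,
    n_bins: int = 25,
    n_samplings: int | None = 1000,
    seed: int | None = 0,
    layer: str = "normalized",
) -> ScoreVector:
    """Bin-matched background-corrected set score per observation.

    Parameters
    ----------
    m
        :class:`CountMatrix` with a ``normalized`` layer, or a plain
        observations x genes array/DataFrame on a log scale.
    gene_set
        Gene symbols; members absent from the matrix are dropped with a
        warning, and at least 2 usable genes are required.
    n_bins
        Equal-frequency expression bins for control matching (reduced with a
        warning if it exceeds the gene count).
    n_samplings
        Monte-Carlo control draws; ``None`` computes the exact expectation
        over all control assignments (each set gene's whole bin, excluding
        itself when the bin has other members).
    seed
        Fully determines the Monte-Carlo draws.
    """
    if isinstance(m, pd.DataFrame):
        X, genes, obs = m.to_numpy(dtype=float), pd.Index(m.columns), m.index
    else:
        X, genes, obs = _expression_matrix(m, layer)
    n_obs, n_genes = X.shape

    set_idx = np.array(sorted({genes.get_loc(g) for g in gene_set if g in genes}))
    dropped = [g for g in gene_set if g not in genes]
    if dropped:
        logger.warning("dropping %d gene(s) absent from matrix: %s", len(dropped), dropped[:5])
    if len(set_idx) < 2:
        raise ValueError("fewer than 2 usable gene-set genes in the matrix")
    if n_bins > n_genes:
        logger.warning("n_bins=%d > %d genes; reducing", n_bins, n_genes)
        n_bins = n_genes

    gene_avg = X.mean(axis=0)
    centered = X - gene_avg

    # equal-frequency bins of the per-gene average (ties broken by index)
    order = np.lexsort((np.arange(n_genes), gene_avg))
    bin_of = np.empty(n_genes, dtype=int)
    bin_of[order] = (np.arange(n_genes) * n_bins) // n_genes
    bins = [np.flatnonzero(bin_of == b) for b in range(n_bins)]

    s_center = centered[:, set_idx].mean(axis=1)

    pools = []
    for g in set_idx:
        pool = bins[bin_of[g]]
        if len(pool) > 1:
            pool = pool[pool != g]
        pools.append(pool)

    if n_samplings is None:
        # exact expectation: mean over each gene's pool, averaged over genes
        pool_means = np.column_stack([centered[:, p].mean(axis=1) for p in pools])
        s_random = pool_means.mean(axis=1)
    else:
        rng = np.random.default_rng(seed)
        # aggregate all draws into per-gene weights: mean over samplings and
        # set genes of centered control expression
        weights = np.zeros(n_genes)
        for pool in pools:
            draws = rng.integers(0, len(pool), size=n_samplings)
            weights += np.bincount(pool[draws], minlength=n_genes)
        weights /= n_samplings * len(set_idx)
        s_random = centered @ weights

    scores = pd.Series(s_center - s_random, index=obs, name="score")
    return ScoreVector(
        scores=scores,
        gene_set_used=list(genes[set_idx]),
        n_bins=n_bins,
        n_samplings=n_samplings,
        seed=seed,
    )


def median_split(scores) -> pd.Series:
    """High/low labels at the median; values equal to the median go low."""
    s = scores.scores if isinstance(scores, ScoreVector) else pd.Series(scores)
    if len(s) < 2:
        raise ValueError("need >= 2 observations to split")
    med = float(np.median(s.to_numpy()))
    labels = pd.Series(np.where(s.to_numpy() > med, "high", "low"), index=s.index)
    if (labels == "low").all():
        logger.warning("all scores at or below the median; every observation labelled low")
    if isinstance(scores, ScoreVector):
        scores.subgroup = labels
    return labels


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by enumeration; handles ties."""
    from itertools import combinations

    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    obs_dev = abs(obs - mu)
    count = total = 0
    for comb in combinations(range(len(pooled)), n1):
        r = ranks[list(comb)].sum()
        total += 1
        if abs(r - mu) >= obs_dev - 1e-9:
            count += 1
    return count / total


def compare_groups(values, labels):
    """Two-sided Wilcoxon rank-sum test between two groups.

    Exact for small samples (enumeration when ties make scipy's exact method
    unavailable), normal approximation with tie correction otherwise.
    Returns ``(U statistic, p)``.
    """
    values = pd.Series(values)
    labels = pd.Series(labels, index=values.index)
    groups = [g for g in pd.unique(labels) if pd.notna(g)]
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    x = values[labels == groups[0]].to_numpy(dtype=float)
    y = values[labels == groups[1]].to_numpy(dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group")
    small = max(len(x), len(y)) <= 20
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if small and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    if small and len(x) + len(y) <= 14:
        u = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic
        return float(u), _exact_rank_sum_p(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
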
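"""Per-observation gene-set enrichment (ssGSEA) and group contrasts.

The enrichment score of a set in one observation is the running-sum
integral over the expression-ranked gene list of the difference between the
rank-weighted in-set ECDF and the unweighted out-of-set ECDF. Scores are
range-normalized across the whole matrix; high-vs-low contrasts use the
Wilcoxon rank-sum test with Benjamini-Hochberg adjustment across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix
from .scoring import compare_groups

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    es: pd.DataFrame  # observations x gene sets
    alpha: float
    normalization: str | None
    contrast: pd.DataFrame | None = None
    dropped_sets: list = field(default_factory=list)


def _single_obs_es(expr: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Running-sum ES for one observation; deterministic tie handling."""
    n = len(expr)
    ranks = stats.rankdata(expr)  # ascending, average ties
    order = np.lexsort((np.arange(n), -expr))  # descending, stable
    in_ordered = in_set[order]
    w = np.where(in_ordered, np.abs(ranks[order]) ** alpha, 0.0)
    total_in = w.sum()
    n_out = n - in_set.sum()
    if total_in == 0 or n_out == 0:
        return 0.0
    p_in = np.cumsum(w) / total_in
    p_out = np.cumsum(~in_ordered) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea_scores(
    m,
    gene_sets: dict,
    alpha: float = 0.25,
    normalization: str | None = "range",
    layer: str = "normalized",
) -> EnrichmentResult:
    """ssGSEA enrichment of every gene set in every observation.

    Sets intersecting the matrix in fewer than 2 genes are dropped with a
    log message; an all-empty intersection is an error. Fully deterministic.
    """
    if isinstance(m, CountMatrix):
        if layer not in m.layers:
            raise ValueError(f"layer {layer!r} missing; run lognormalize first")
        X, genes, obs = m.layers[layer], m.gene_names, m.cell_names
    elif isinstance(m, pd.DataFrame):
        X, genes, obs = m.to_numpy(dtype=float), pd.Index(m.columns), m.index
    else:
        X = np.asarray(m, dtype=float)
        genes = pd.Index([f"g{i}" for i in range(X.shape[1])])
        obs = pd.RangeIndex(X.shape[0])

    masks, dropped = {}, []
    for name, members in gene_sets.items():
        mask = genes.isin(members)
        if mask.sum() < 2:
            dropped.append(name)
        else:
            masks[name] = mask
    if dropped:
        logger.warning("dropped %d set(s) with <2 genes in matrix: %s", len(dropped), dropped[:5])
    if not masks:
        raise ValueError("no gene set overlaps the matrix in >= 2 genes")

    es = np.empty((X.shape[0], len(masks)))
    for j, mask in enumerate(masks.values()):
        for i in range(X.shape[0]):
            es[i, j] = _single_obs_es(X[i], mask, alpha)

    if normalization == "range":
        rng_ = es.max() - es.min()
        if rng_ > 0:
            es = es / rng_
    elif normalization is not None:
        raise ValueError(f"unknown normalization {normalization!r}")

    return EnrichmentResult(
        es=pd.DataFrame(es, index=obs, columns=list(masks)),
        alpha=alpha,
        normalization=normalization,
        dropped_sets=dropped,
    )


def differential_enrichment(res: EnrichmentResult, labels) -> pd.DataFrame:
    """Per-set Wilcoxon contrast of ES between two groups, BH-adjusted.

    Direction is the sign of the median ES difference (first group minus
    second; ``high`` minus ``low`` when those labels are present).
    """
    labels = pd.Series(labels, index=res.es.index) if not isinstance(labels, pd.Series) else labels
    labels = labels.reindex(res.es.index)
    groups = [g for g in pd.unique(labels.dropna())]
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    if set(groups) == {"high", "low"}:
        groups = ["high", "low"]
    rows = []
    for name in res.es.columns:
        vals = res.es[name]
        stat, p = compare_groups(vals, labels)
        diff = float(
            np.median(vals[labels == groups[0]]) - np.median(vals[labels == groups[1]])
        )
        rows.append({"gene_set": name, "direction": int(np.sign(diff)), "statistic": stat, "p": p})
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table.p.to_numpy(), method="fdr_bh")[1]
    res.contrast = table
    return table
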
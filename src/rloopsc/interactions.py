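"""Ligand-receptor communication testing with a permutation null.

For every ordered (sender type, receiver type) and ligand-receptor pair the
statistic is the average of the ligand's mean normalized expression in the
sender type and the receptor's mean in the receiver type. Significance comes
from permuting cell-type labels across cells; expressed-cell fractions gate
which pairs may be called significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class LRPairResult:
    ligand: str
    receptor: str
    sender_type: str
    receiver_type: str
    mean_stat: float
    frac_sender: float
    frac_receiver: float
    p_value: float
    significant: bool


def _prepare(m: CountMatrix, labels, pairs, layer: str):
    if layer not in m.layers:
        raise ValueError(f"layer {layer!r} missing; run lognormalize first")
    labels = pd.Series(labels, index=m.cell_names) if not isinstance(labels, pd.Series) else labels
    labels = labels.reindex(m.cell_names)
    pairs = pd.DataFrame(pairs, columns=["ligand", "receptor"]) if not isinstance(
        pairs, pd.DataFrame
    ) else pairs[["ligand", "receptor"]]
    present = pairs.ligand.isin(m.gene_names) & pairs.receptor.isin(m.gene_names)
    if (~present).any():
        logger.warning("dropping %d pair(s) with genes absent from matrix", (~present).sum())
    pairs = pairs[present].reset_index(drop=True)
    genes = pd.unique(pd.concat([pairs.ligand, pairs.receptor]))
    gi = {g: i for i, g in enumerate(genes)}
    X = m.layers[layer][:, m.gene_index(genes)]
    types = [t for t in pd.unique(labels.dropna())]
    return labels, pairs, X, gi, types


def _type_means(X: np.ndarray, codes: np.ndarray, n_types: int):
    """Per-type mean and expressed fraction of each column; empty types -> NaN."""
    onehot = np.zeros((n_types, len(codes)))
    ok = codes >= 0
    onehot[codes[ok], np.flatnonzero(ok)] = 1.0
    counts = onehot.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = (onehot @ X) / counts[:, None]
        fracs = (onehot @ (X > 0)) / counts[:, None]
    return means, fracs


def lr_mean_statistic(m: CountMatrix, labels, pairs, layer: str = "normalized") -> pd.DataFrame:
    """Observed mean statistic and expressed fractions for every ordered
    (sender, receiver) type pair and ligand-receptor pair."""
    labels, pairs, X, gi, types = _prepare(m, labels, pairs, layer)
    if len(types) < 1:
        raise ValueError("no cell types")
    codes = pd.Categorical(labels, categories=types).codes.astype(int)
    means, fracs = _type_means(X, codes, len(types))
    rows = []
    for s, sender in enumerate(types):
        for r, receiver in enumerate(types):
            for _, pr in pairs.iterrows():
                li, ri = gi[pr.ligand], gi[pr.receptor]
                rows.append(
                    {
                        "ligand": pr.ligand, "receptor": pr.receptor,
                        "sender_type": sender, "receiver_type": receiver,
                        "mean_stat": (means[s, li] + means[r, ri]) / 2.0,
                        "frac_sender": fracs[s, li], "frac_receiver": fracs[r, ri],
                    }
                )
    return pd.DataFrame(rows)


def permutation_pvalues(
    m: CountMatrix,
    labels,
    pairs,
    n_perm: int = 1000,
    seed: int = 0,
    min_frac: float = 0.1,
    alpha: float = 0.05,
    layer: str = "normalized",
) -> pd.DataFrame:
    """Permutation p-values for the LR mean statistic.

    ``p = (1 + #{perm >= observed}) / (n_perm + 1)`` with labels permuted
    across cells; ``significant`` additionally requires both expressed-cell
    fractions >= ``min_frac``.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is small; p-values will be coarse", n_perm)
    labels_s, pairs, X, gi, types = _prepare(m, labels, pairs, layer)
    if len(types) < 2:
        raise ValueError("need >= 2 cell types")
    obs = lr_mean_statistic(m, labels_s, pairs, layer)

    codes = pd.Categorical(labels_s, categories=types).codes.astype(int)
    li = np.array([gi[g] for g in pairs.ligand])
    ri = np.array([gi[g] for g in pairs.receptor])
    n_types = len(types)

    obs_stat = obs.mean_stat.to_numpy().reshape(n_types, n_types, len(pairs))
    exceed = np.zeros_like(obs_stat)
    rng = np.random.default_rng(seed)
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        means, _ = _type_means(X, perm, n_types)
        stat = (means[:, None, li] + means[None, :, ri]) / 2.0
        exceed += stat >= obs_stat - 1e-12
    pvals = (1.0 + exceed) / (n_perm + 1.0)

    out = obs.copy()
    out["p_value"] = pvals.ravel()
    out["significant"] = (
        (out.p_value < alpha) & (out.frac_sender >= min_frac) & (out.frac_receiver >= min_frac)
    )
    return out


def filter_significant(results: pd.DataFrame, alpha: float = 0.05, min_frac: float = 0.1):
    """Rows with p < alpha and both fractions >= min_frac, sorted by p then
    mean statistic descending (stable)."""
    if results.empty:
        return results.copy()
    keep = (
        (results.p_value < alpha)
        & (results.frac_sender >= min_frac)
        & (results.frac_receiver >= min_frac)
    )
    out = results[keep].copy()
    out["_neg"] = -out.mean_stat
    out = out.sort_values(["p_value", "_neg"], kind="stable").drop(columns="_neg")
    return out.reset_index(drop=True)
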
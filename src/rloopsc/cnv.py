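"""Expression-inferred copy-number profiles and malignancy calling.

Relative expression (normalized value minus the reference-cell mean per
gene, clipped) is smoothed along each chromosome with a centered moving
average, re-centered per cell at its median window, and summarized per cell
by the quadratic sum of window values. Malignant cells combine high CNV
score with epithelial identity (marker-set score above the median).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .scoring import ScoreVector, score_gene_set

logger = logging.getLogger(__name__)


@dataclass
class CNVProfile:
    """Smoothed relative-expression windows and per-cell quadratic-sum score."""

    windows: pd.DataFrame  # chrom, gene (window center), ordered by coordinate
    values: pd.DataFrame  # cells x windows
    cnv_scores: pd.Series  # per-cell sum of squared window values
    reference_cells: list


def _moving_average(X: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 1; edges use truncated windows."""
    n = X.shape[1]
    half = window // 2
    cs = np.cumsum(X, axis=1)
    cs = np.concatenate([np.zeros((X.shape[0], 1)), cs], axis=1)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (cs[:, hi] - cs[:, lo]) / (hi - lo)


def infer_cnv_profile(
    m: CountMatrix,
    coords: pd.DataFrame,
    reference_labels,
    window: int = 101,
    clip: float = 1.0,
    layer: str = "normalized",
) -> CNVProfile:
    """Per-cell smoothed relative expression along the genome.

    Parameters
    ----------
    coords
        BED-like table (chrom, start, end, gene); genes absent from the
        matrix are ignored, matrix genes without coordinates are dropped.
    reference_labels
        Boolean mask or id list of reference (presumed non-malignant,
        non-epithelial) cells whose mean defines the expression baseline.
    """
    if layer not in m.layers:
        raise ValueError(f"layer {layer!r} missing; run lognormalize first")
    ref_mask = _as_mask(reference_labels, m.cell_names)
    if not ref_mask.any():
        raise ValueError("no reference cells")

    coords = coords[coords.gene.isin(m.gene_names)]
    coords = coords.sort_values(["chrom", "start"], kind="stable")
    if coords.empty:
        raise ValueError("no overlap between coordinates and matrix genes")
    gene_idx = m.gene_index(coords.gene)
    X = m.layers[layer][:, gene_idx]

    rel = X - X[ref_mask].mean(axis=0)
    np.clip(rel, -clip, clip, out=rel)

    smoothed = np.empty_like(rel)
    chrom_arr = coords.chrom.to_numpy()
    for chrom in pd.unique(chrom_arr):
        cols = np.flatnonzero(chrom_arr == chrom)
        if len(cols) < window:
            logger.warning(
                "chromosome %s has %d genes < window %d; using truncated windows",
                chrom, len(cols), window,
            )
        smoothed[:, cols] = _moving_average(rel[:, cols], window)

    smoothed -= np.median(smoothed, axis=1, keepdims=True)

    windows = pd.DataFrame({"chrom": chrom_arr, "gene": coords.gene.to_numpy()})
    values = pd.DataFrame(smoothed, index=m.cell_names, columns=coords.gene.to_numpy())
    return CNVProfile(
        windows=windows,
        values=values,
        cnv_scores=cnv_score_from_values(values),
        reference_cells=list(m.cell_names[ref_mask]),
    )


def cnv_score_from_values(values: pd.DataFrame) -> pd.Series:
    """Quadratic sum of window values per cell."""
    return pd.Series((values.to_numpy() ** 2).sum(axis=1), index=values.index, name="cnv_score")


def cnv_score(profile: CNVProfile) -> pd.Series:
    return cnv_score_from_values(profile.values)


def epithelial_score(m: CountMatrix, marker_set, **params) -> ScoreVector:
    """Background-corrected score over epithelial marker genes."""
    return score_gene_set(m, marker_set, **params)


def call_malignant(
    cnv_scores: pd.Series,
    epi: ScoreVector,
    reference_cells,
    k: float = 2.0,
) -> pd.Series:
    """Malignant = CNV score above mean_ref + k*sd_ref AND epithelial score
    above the all-cell median."""
    epi_scores = epi.scores if isinstance(epi, ScoreVector) else pd.Series(epi)
    if not cnv_scores.index.equals(epi_scores.index):
        epi_scores = epi_scores.reindex(cnv_scores.index)
        if epi_scores.isna().any():
            raise ValueError("cnv and epithelial scores cover different cells")
    ref = cnv_scores.loc[list(reference_cells)]
    if len(ref) < 2 or ref.std(ddof=1) == 0:
        raise ValueError("reference CNV scores have zero variance")
    threshold = ref.mean() + k * ref.std(ddof=1)
    epi_median = float(np.median(epi_scores.to_numpy()))
    flags = (cnv_scores > threshold) & (epi_scores > epi_median)
    logger.info(
        "call_malignant: cnv threshold %.4g (mean_ref + %g*sd_ref), epithelial median %.4g; "
        "%d/%d cells called malignant",
        threshold, k, epi_median, int(flags.sum()), len(flags),
    )
    return flags.rename("malignant")


def _as_mask(labels, index: pd.Index) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype == bool and len(arr) == len(index):
        return arr
    return index.isin(arr)
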
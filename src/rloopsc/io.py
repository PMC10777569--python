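"""Readers and writers for the plain-text interchange formats.

Counts travel as Matrix-Market triplets plus gene/barcode name files;
metadata, survival tables and ligand-receptor pair lists are TSV; gene sets
are GMT; gene coordinates are BED-like TSV.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix

MTX_FILE = "matrix.mtx"
GENES_FILE = "genes.tsv"
BARCODES_FILE = "barcodes.tsv"
META_FILE = "cell_meta.tsv"


def write_fixture(matrix: CountMatrix, outdir: str) -> None:
    """Write counts + names + metadata so a round-trip read is exact."""
    os.makedirs(outdir, exist_ok=True)
    scipy.io.mmwrite(
        os.path.join(outdir, MTX_FILE), sp.coo_matrix(matrix.counts), field="integer"
    )
    with open(os.path.join(outdir, GENES_FILE), "w") as fh:
        fh.write("\n".join(matrix.gene_names) + ("\n" if len(matrix.gene_names) else ""))
    with open(os.path.join(outdir, BARCODES_FILE), "w") as fh:
        fh.write("\n".join(matrix.cell_names) + ("\n" if len(matrix.cell_names) else ""))
    matrix.cell_meta.to_csv(os.path.join(outdir, META_FILE), sep="\t", index_label="cell")


def read_fixture(indir: str) -> CountMatrix:
    counts = sp.csr_matrix(scipy.io.mmread(os.path.join(indir, MTX_FILE)))
    genes = _read_names(os.path.join(indir, GENES_FILE))
    barcodes = _read_names(os.path.join(indir, BARCODES_FILE))
    meta_path = os.path.join(indir, META_FILE)
    meta = None
    if os.path.exists(meta_path):
        meta = pd.read_csv(meta_path, sep="\t", index_col="cell")
        meta.index = meta.index.astype(str)
    return CountMatrix(counts, pd.Index(genes), pd.Index(barcodes), meta)


def _read_names(path: str) -> list:
    with open(path) as fh:
        return [line.strip().split("\t")[0] for line in fh if line.strip()]


def read_dense_tsv(path: str) -> CountMatrix:
    """Dense cells-as-rows TSV alternative to the sparse triplet layout."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(
        sp.csr_matrix(df.to_numpy()), pd.Index(df.columns), pd.Index(df.index.astype(str)), None
    )


def read_gene_list(path: str) -> list:
    """One symbol per line (e.g. the R-loop regulator list)."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_gmt(path: str) -> dict:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict, path: str) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def read_lr_pairs(path: str) -> pd.DataFrame:
    """Ligand-receptor pair list with columns ``ligand`` and ``receptor``."""
    df = pd.read_csv(path, sep="\t")
    if not {"ligand", "receptor"} <= set(df.columns):
        raise ValueError("pair list needs 'ligand' and 'receptor' columns")
    return df[["ligand", "receptor"]]


def read_gene_coords(path: str) -> pd.DataFrame:
    """BED-like gene coordinates: chrom, start, end, gene (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "gene"])
    return df


def write_gene_coords(coords: pd.DataFrame, path: str) -> None:
    coords[["chrom", "start", "end", "gene"]].to_csv(path, sep="\t", header=False, index=False)


def read_survival(path: str, time_col="time", event_col="event") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df = df.dropna(subset=[time_col, event_col])
    if (df[time_col] <= 0).any():
        raise ValueError("survival times must be positive")
    if not df[event_col].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return df
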
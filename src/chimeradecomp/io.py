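"""Readers and writers for the on-disk formats used across the pipeline.

Counts travel as MatrixMarket (.mtx) plus genes/barcodes TSVs per genome,
cell metadata and result tables as TSV, gene sets as GMT, pseudobulk tables
as wide TSV with a JSON sidecar, and images as multi-page TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import tifffile
from scipy import io as sio
from scipy import sparse

from .ingest import COMBOS, ComboCountTable

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_combo_table",
    "read_combo_table",
    "read_orthologs",
    "write_if_image",
    "read_if_image",
]


def write_dataset(adata: ad.AnnData, outdir) -> None:
    """Write a dual-genome dataset as per-genome MTX + genes/barcodes/metadata TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for genome in ("mouse", "rat"):
        mat = sparse.csr_matrix(np.asarray(adata.layers[genome]))
        sio.mmwrite(outdir / f"counts_{genome}.mtx", mat)
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    adata.obs.to_csv(outdir / "cell_metadata.tsv", sep="\t")


def read_dataset(indir) -> ad.AnnData:
    """Read a dataset written by :func:`write_dataset` (the external-data adapter).

    Any dual-genome experiment laid out as ``counts_mouse.mtx`` /
    ``counts_rat.mtx`` + ``genes.tsv`` + ``barcodes.tsv`` +
    ``cell_metadata.tsv`` (with environment / cell_type / mito_fraction /
    genes_detected columns) can enter the pipeline through this reader.
    """
    indir = Path(indir)
    layers = {}
    for genome in ("mouse", "rat"):
        layers[genome] = np.asarray(sio.mmread(indir / f"counts_{genome}.mtx").todense())
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    obs = pd.read_csv(indir / "cell_metadata.tsv", sep="\t", index_col=0)
    obs.index = obs.index.astype(str)
    obs = obs.loc[barcodes]
    return ad.AnnData(
        X=layers["mouse"] + layers["rat"],
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
        layers=layers,
    )


def write_combo_table(table: ComboCountTable, path) -> None:
    """Write a pseudobulk table as wide TSV with a JSON sidecar (n_cells, totals)."""
    path = Path(path)
    table.counts.to_csv(path, sep="\t")
    sidecar = {
        "cell_type": table.cell_type,
        "n_cells": {k: int(v) for k, v in table.n_cells.items()},
        "total_counts": {c: int(t) for c, t in table.total_counts.items()},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_combo_table(path) -> ComboCountTable:
    path = Path(path)
    counts = pd.read_csv(path, sep="\t", index_col=0)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ComboCountTable(
        cell_type=sidecar["cell_type"],
        counts=counts[list(COMBOS)],
        n_cells={k: int(v) for k, v in sidecar["n_cells"].items()},
    )


def read_orthologs(path) -> pd.Series:
    """Read a two-column TSV mapping (e.g. mouse symbol -> human symbol)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("ortholog map must have two columns")
    return pd.Series(df[1].to_numpy(), index=df[0].to_numpy())


def write_if_image(channels: np.ndarray, path) -> None:
    """Write a (C, H, W) image stack as multi-page TIFF."""
    tifffile.imwrite(path, np.asarray(channels, dtype=np.float32))


def read_if_image(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)
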
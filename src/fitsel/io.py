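"""Readers and writers for the on-disk formats the pipeline exchanges.

Images are multi-page TIFF (one z-plane per page, one file per channel),
ROIs are GeoJSON polygons in 0-based pixel coordinates, spot/measurement
tables are CSV, and count matrices are MatrixMarket MTX with sidecar
genes.tsv / cells.tsv / cellmeta.csv files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import io as spio
from scipy import sparse

from .synthetic_data import CountMatrix, SmfishScene


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a (z, y, x) stack as a multi-page TIFF (float32)."""
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32),
                     photometric="minisblack")


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF as a (z, y, x) array."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None, :, :]
    return np.asarray(arr, dtype=float)


def write_rois(path: str | Path, rois: list[dict]) -> None:
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": rois}, fh)


def read_rois(path: str | Path) -> list[dict]:
    with open(path) as fh:
        doc = json.load(fh)
    return doc["features"]


def write_scene(scene: SmfishScene, outdir: str | Path) -> dict[str, Path]:
    """Write a rendered smFISH scene (two TIFFs, truth CSV, ROI GeoJSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pan": outdir / "pan.tif",
        "fl": outdir / "fl.tif",
        "truth": outdir / "truth_spots.csv",
        "rois": outdir / "rois.geojson",
    }
    write_stack(paths["pan"], scene.pan)
    write_stack(paths["fl"], scene.fl)
    scene.truth.to_csv(paths["truth"], index=False)
    write_rois(paths["rois"], scene.rois)
    return paths


def write_count_matrix(cm: CountMatrix, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": outdir / "counts.mtx",
        "genes": outdir / "genes.tsv",
        "cells": outdir / "cells.tsv",
        "meta": outdir / "cellmeta.csv",
    }
    spio.mmwrite(str(paths["mtx"]), cm.X.tocoo())
    cm.genes["gene"].to_csv(paths["genes"], sep="\t", index=False, header=False)
    cm.cells["cell_id"].to_csv(paths["cells"], sep="\t", index=False, header=False)
    cm.cells.to_csv(paths["meta"], index=False)
    return paths


def read_count_matrix(mtx: str | Path, genes: str | Path, cells: str | Path,
                      meta: str | Path | None = None) -> CountMatrix:
    X = sparse.csr_matrix(spio.mmread(str(mtx)))
    gene_df = pd.read_csv(genes, sep="\t", header=None, names=["gene"])
    cell_ids = pd.read_csv(cells, sep="\t", header=None, names=["cell_id"])
    if meta is not None:
        cell_df = pd.read_csv(meta)
        if "cell_id" not in cell_df.columns:
            cell_df.insert(0, "cell_id", cell_ids["cell_id"])
    else:
        cell_df = cell_ids
    if X.shape != (len(gene_df), len(cell_df)):
        raise ValueError(
            f"matrix shape {X.shape} does not match {len(gene_df)} genes "
            f"x {len(cell_df)} cells")
    return CountMatrix(X=X.astype(np.int64), genes=gene_df, cells=cell_df)
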
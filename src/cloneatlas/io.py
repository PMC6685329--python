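"""Readers and writers for the package's on-disk formats.

Tissue maps travel as UTF-8 comma-separated CSV with a mandatory header
``cell_id,x,y,z,colour,vessel_id,edu,region,founder_id,section_id``
(0-based integer coordinates, booleans as 0/1, empty ``founder_id`` for
unlabelled cells); the optional non-endothelial background compartment is a
companion ``<stem>.background.csv``.  Count matrices travel as a 10x-style
MatrixMarket triplet (``matrix.mtx`` with genes as rows and cells as columns,
``genes.tsv``, ``cells.tsv`` with per-cell metadata).  All writers are
loss-free for their declared fields.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .params import COLOUR_VOCAB
from .tissue import TISSUE_COLUMNS, TissueMap

# ---------------------------------------------------------------------------
# tissue CSV
# ---------------------------------------------------------------------------


def write_tissue_csv(tissue: TissueMap, path) -> None:
    path = Path(path)
    df = tissue.cells.copy()
    df["edu"] = df["edu"].astype(int)
    df.to_csv(path, index=False)
    if tissue.background is not None:
        tissue.background.to_csv(path.with_suffix(".background.csv"), index=False)


def read_tissue_csv(path) -> TissueMap:
    """Read a tissue-map CSV, validating the dialect row by row.

    Malformed rows are reported with 1-based line numbers (header is line 1);
    duplicate cell ids and unknown colour tokens raise with the offenders
    listed.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"colour": str, "region": str})
    missing = [c for c in TISSUE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: header missing columns {missing}")

    bad_lines = []
    for col in ("cell_id", "x", "y", "z", "vessel_id", "section_id", "edu"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        bad_lines.extend((df.index[bad] + 2).tolist())
        df[col] = coerced
    if bad_lines:
        raise ValueError(f"{path}: malformed numeric fields at line(s) {sorted(set(bad_lines))[:20]}")
    nan_rows = df[["cell_id", "x", "y", "z", "vessel_id", "section_id", "edu"]].isna().any(axis=1)
    if nan_rows.any():
        raise ValueError(f"{path}: incomplete rows at line(s) {(df.index[nan_rows] + 2).tolist()[:20]}")

    dup = df.loc[df["cell_id"].duplicated(), "cell_id"].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate cell_id values {dup[:20]}")
    bad_colours = sorted(set(df["colour"]) - set(COLOUR_VOCAB))
    if bad_colours:
        raise ValueError(
            f"{path}: unknown colour token(s) {bad_colours}; valid tokens: {list(COLOUR_VOCAB)}"
        )

    for col in ("cell_id", "x", "y", "z", "vessel_id", "section_id"):
        df[col] = df[col].astype(np.int64)
    df["edu"] = df["edu"].astype(np.int64).astype(bool)
    df["founder_id"] = df["founder_id"].astype("Int64")

    bg_path = path.with_suffix(".background.csv")
    background = pd.read_csv(bg_path) if bg_path.exists() else None
    return TissueMap(cells=df[TISSUE_COLUMNS], background=background)


# ---------------------------------------------------------------------------
# counts MTX triplet
# ---------------------------------------------------------------------------


def write_counts_mtx(adata: ad.AnnData, outdir) -> None:
    """Write an AnnData as a 10x-style triplet (genes as MTX rows)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.layers["counts"] if "counts" in adata.layers else adata.X
    X = sparse.csr_matrix(X)
    spio.mmwrite(outdir / "matrix.mtx", X.T.tocoo(), field="integer")
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    meta = adata.obs.reset_index().rename(columns={"index": "cell_id"})
    meta.to_csv(outdir / "cells.tsv", sep="\t", index=False)


def read_counts_mtx(indir) -> ad.AnnData:
    """Read a 10x-style MTX triplet back into an AnnData (cells x genes)."""
    indir = Path(indir)
    for fname in ("matrix.mtx", "genes.tsv", "cells.tsv"):
        if not (indir / fname).exists():
            raise FileNotFoundError(f"{indir}: missing {fname}")
    X = sparse.csr_matrix(spio.mmread(indir / "matrix.mtx")).T
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].astype(str).tolist() \
        if (indir / "genes.tsv").stat().st_size else []
    meta = pd.read_csv(indir / "cells.tsv", sep="\t")
    if X.shape[1] != len(genes):
        raise ValueError(
            f"{indir}: matrix has {X.shape[1]} genes but genes.tsv lists {len(genes)}"
        )
    if X.shape[0] != len(meta):
        raise ValueError(
            f"{indir}: matrix has {X.shape[0]} cells but cells.tsv lists {len(meta)}"
        )
    meta = meta.set_index("cell_id") if "cell_id" in meta.columns else meta
    meta.index = meta.index.astype(str)
    adata = ad.AnnData(
        X=X.astype(np.int64),
        obs=meta,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    if "group" in adata.obs:
        adata.obs["group"] = pd.Categorical(adata.obs["group"].astype(str))
    return adata


# ---------------------------------------------------------------------------
# configs / reports
# ---------------------------------------------------------------------------


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def save_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
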
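"""Reading and writing the on-disk exchange formats.

Count matrices travel as a CellRanger-style triplet: ``matrix.mtx``
(genes x cells), ``genes.tsv`` (id, symbol, is_mito) and ``cells.tsv``
(barcode plus per-cell annotations). In memory everything is an AnnData
with cells as observations, so the MTX is transposed on the way in/out.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


def write_count_matrix(adata: ad.AnnData, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    spio.mmwrite(outdir / "matrix.mtx", X.T.tocoo())
    genes = adata.var.reset_index()
    genes.insert(0, "id", genes.iloc[:, 0])
    genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    adata.obs.reset_index().to_csv(outdir / "cells.tsv", sep="\t", index=False)


def read_count_matrix(indir: str | Path) -> ad.AnnData:
    indir = Path(indir)
    X = sparse.csr_matrix(spio.mmread(indir / "matrix.mtx")).T
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")
    cells = pd.read_csv(indir / "cells.tsv", sep="\t")
    var = genes.set_index(genes.columns[0])
    var.index.name = "gene"
    obs = cells.set_index(cells.columns[0])
    obs.index.name = "barcode"
    obs.index = obs.index.astype(str)
    if "is_mito" in var.columns:
        var["is_mito"] = var["is_mito"].astype(bool)
    return ad.AnnData(X=X.astype(np.int64), obs=obs, var=var)


def write_truth(truth, path: str | Path) -> None:
    """Serialize a SyntheticTruth to JSON (sets become sorted lists)."""
    payload = {
        "true_labels": {k: int(v) for k, v in truth.true_labels.items()},
        "planted_markers": {
            str(c): sorted(g) for c, g in truth.planted_markers.items()
        },
        "planted_lr_pairs": [
            {
                "ligand": p.ligand,
                "receptor": p.receptor,
                "source_cluster": p.source_cluster,
                "target_cluster": p.target_cluster,
                "fold": p.fold,
            }
            for p in truth.planted_lr_pairs
        ],
        "true_pseudotime": (
            None
            if truth.true_pseudotime is None
            else {k: float(v) for k, v in truth.true_pseudotime.items()}
        ),
        "cohort_truth": truth.cohort_truth,
    }
    Path(path).write_text(json.dumps(payload))


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"exposure": str})
    if "exposure" in df.columns:
        df["exposure"] = df["exposure"].fillna("")
    return df


def read_lr_database(path: str | Path) -> pd.DataFrame:
    """Ligand-receptor pair table: pair_id, ligand_components,
    receptor_components with pipe-separated multi-subunit partners."""
    db = pd.read_csv(path, sep="\t")
    required = {"pair_id", "ligand_components", "receptor_components"}
    if not required.issubset(db.columns):
        raise ValueError(f"LR database must have columns {sorted(required)}")
    if db["pair_id"].duplicated().any():
        raise ValueError("duplicate pair_id in LR database")
    for col in ("ligand_components", "receptor_components"):
        if (db[col].astype(str).str.len() == 0).any():
            raise ValueError(f"empty {col} in LR database")
    return db
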
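"""Reading and writing the pipeline's on-disk formats.

Count matrices travel as MTX triplets (matrix.mtx, barcodes.tsv,
features.tsv) or dense TSV; cell metadata, label maps, fate partitions
and pair lists as TSV; configs and ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


def save_matrix(adata: ad.AnnData, outdir: str | Path, fmt: str = "mtx") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = np.asarray(adata.layers.get("counts", adata.X))
    if fmt == "mtx":
        spio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(counts))
        pd.Series(adata.obs_names).to_csv(
            outdir / "barcodes.tsv", sep="\t", index=False, header=False
        )
        pd.Series(adata.var_names).to_csv(
            outdir / "features.tsv", sep="\t", index=False, header=False
        )
    elif fmt == "tsv":
        pd.DataFrame(
            counts, index=adata.obs_names, columns=adata.var_names
        ).to_csv(outdir / "counts.tsv", sep="\t")
    else:
        raise ValueError("fmt must be 'mtx' or 'tsv'")
    adata.obs.to_csv(outdir / "cell_metadata.tsv", sep="\t")


def load_matrix(indir: str | Path) -> ad.AnnData:
    indir = Path(indir)
    if (indir / "matrix.mtx").exists():
        counts = np.asarray(spio.mmread(indir / "matrix.mtx").todense())
        cells = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
        genes = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0]
        adata = ad.AnnData(
            X=counts.astype(np.int32),
            obs=pd.DataFrame(index=pd.Index(cells, name="cell_id")),
            var=pd.DataFrame(index=pd.Index(genes, name="gene")),
        )
    elif (indir / "counts.tsv").exists():
        df = pd.read_csv(indir / "counts.tsv", sep="\t", index_col=0)
        adata = ad.AnnData(X=df.to_numpy(dtype=np.int32), obs=pd.DataFrame(index=df.index),
                           var=pd.DataFrame(index=df.columns))
    else:
        raise FileNotFoundError(f"no matrix.mtx or counts.tsv under {indir}")
    meta = indir / "cell_metadata.tsv"
    if meta.exists():
        adata.obs = pd.read_csv(meta, sep="\t", index_col=0).loc[adata.obs_names]
    adata.layers["counts"] = np.asarray(adata.X).copy()
    return adata


def save_cell_labels(labels: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"cell_id": list(labels), "label": list(labels.values())}
    ).to_csv(path, sep="\t", index=False)


def load_cell_labels(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["cell_id"], df["label"]))


def load_reads(path: str | Path) -> list[tuple[str, str]]:
    """Plain-text read list: one `cell_id<TAB>sequence` per line."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "read"], dtype=str)
    return list(zip(df["cell_id"], df["read"]))


def save_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def load_drug_library(path: str | Path) -> pd.DataFrame:
    """Drug x gene TSV of differential-expression weights."""
    return pd.read_csv(path, sep="\t", index_col=0)
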
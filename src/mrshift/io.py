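"""Readers and writers for the plain-text interchange formats used throughout.

Counts travel as a 10x-style MTX triple (matrix.mtx genes x cells,
features.tsv, barcodes.tsv), gene sets as GMT, everything else as headered TSV.
"""

from __future__ import annotations

import os
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


def read_10x_dir(path: str | os.PathLike) -> ad.AnnData:
    """Read a 10x-style MTX triple into an AnnData (cells x genes).

    Expects ``matrix.mtx`` (genes x cells, the 10x convention), ``features.tsv``
    and ``barcodes.tsv`` in ``path``. The integer counts land in
    ``adata.layers['counts']`` and ``adata.X``.
    """
    path = Path(path)
    mat = sp.csr_matrix(scipy.io.mmread(path / "matrix.mtx")).T.tocsr()
    features = pd.read_csv(path / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)
    adata = ad.AnnData(
        X=mat,
        obs=pd.DataFrame(index=barcodes[0].astype(str).values),
        var=pd.DataFrame(index=features[0].astype(str).values),
    )
    adata.layers["counts"] = adata.X.copy()
    truth_path = path / "truth.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t").set_index("cell_id")
        for col in truth.columns:
            adata.obs[col] = truth.loc[adata.obs_names, col].values
    return adata


def write_10x_dir(adata: ad.AnnData, path: str | os.PathLike) -> None:
    """Write ``adata.layers['counts']`` as an uncompressed 10x MTX triple."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    counts = adata.layers.get("counts", adata.X)
    mat = sp.coo_matrix(counts).T  # genes x cells on disk
    scipy.io.mmwrite(str(path / "matrix.mtx"), mat, field="integer")
    pd.Series(adata.var_names).to_csv(
        path / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(adata.obs_names).to_csv(
        path / "barcodes.tsv", sep="\t", header=False, index=False
    )


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read gene sets from GMT (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "mrshift"] + list(genes)) + "\n")


def read_weights(path: str | os.PathLike) -> pd.Series:
    """Read a gene -> weight vector (TSV with columns gene, weight)."""
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["weight"].values, index=df["gene"].astype(str).values)


def write_weights(weights: pd.Series, path: str | os.PathLike) -> None:
    pd.DataFrame({"gene": weights.index, "weight": weights.values}).to_csv(
        path, sep="\t", index=False
    )


def read_tf_list(path: str | os.PathLike) -> list[str]:
    """Read a curated TF list: one gene id per line (extra columns ignored)."""
    out = []
    with open(path) as fh:
        for line in fh:
            token = line.strip().split("\t")[0]
            if token and token.lower() not in {"tf", "gene"}:
                out.append(token)
    return out


def read_edge_list(path: str | os.PathLike) -> pd.DataFrame:
    """Read an undirected interaction graph as a (source, target) TSV."""
    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if not {"source", "target"} <= set(cols):
        raise ValueError("edge list needs 'source' and 'target' columns")
    return df[["source", "target"]].astype(str)


def write_edge_list(edges: pd.DataFrame | list[tuple[str, str]], path) -> None:
    if not isinstance(edges, pd.DataFrame):
        edges = pd.DataFrame(edges, columns=["source", "target"])
    edges.to_csv(path, sep="\t", index=False)
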
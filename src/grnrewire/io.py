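"""Standard-format readers and writers.

Expression matrices travel as an MTX triplet (matrix.mtx, barcodes.tsv,
features.tsv) plus a metadata.tsv with per-cell labels; edge lists are
3-column TSVs (source, target, weight); gene sets are GMT lines or plain
one-gene-per-line files. All round-trips are exact for the values written.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import anndata as ad
from scipy import io as spio
from scipy import sparse

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_edges",
    "read_edges",
    "read_gene_sets",
    "edges_to_frame",
    "frame_to_matrix",
]

EDGE_COLUMNS = ["source", "target", "weight"]


def write_matrix(outdir: str | Path, adata: ad.AnnData) -> dict[str, Path]:
    """Write an MTX triplet + metadata TSV (genes x cells orientation,
    Cell Ranger style)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.mtx",
        "barcodes": outdir / "barcodes.tsv",
        "features": outdir / "features.tsv",
        "metadata": outdir / "metadata.tsv",
    }
    X = sparse.csr_matrix(np.asarray(adata.X))
    spio.mmwrite(str(paths["matrix"]), X.T)
    paths["barcodes"].write_text("\n".join(adata.obs_names) + "\n")
    paths["features"].write_text("\n".join(adata.var_names) + "\n")
    adata.obs.to_csv(paths["metadata"], sep="\t")
    return paths


def read_matrix(indir: str | Path) -> ad.AnnData:
    """Read the triplet written by :func:`write_matrix`."""
    indir = Path(indir)
    X = spio.mmread(str(indir / "matrix.mtx")).T.tocsr()
    barcodes = (indir / "barcodes.tsv").read_text().splitlines()
    features = (indir / "features.tsv").read_text().splitlines()
    obs = pd.read_csv(indir / "metadata.tsv", sep="\t", index_col=0)
    obs = obs.loc[barcodes]
    adata = ad.AnnData(
        X=np.asarray(X.todense()),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(features, name="gene")),
    )
    return adata


def write_edges(path: str | Path, edges: pd.DataFrame) -> Path:
    path = Path(path)
    cols = list(edges.columns)
    if len(cols) != 3:
        edges = edges[EDGE_COLUMNS]
    out = edges.copy()
    out.columns = EDGE_COLUMNS
    out.to_csv(path, sep="\t", index=False)
    return path


def read_edges(path: str | Path) -> pd.DataFrame:
    """Read a 3-column (source, target, weight) TSV, reporting malformed
    lines by number."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 3:
            raise ValueError(f"{path}: header must have 3 tab-separated columns")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}: line {ln}: expected 3 columns, got {len(parts)}")
            try:
                w = float(parts[2])
            except ValueError:
                raise ValueError(
                    f"{path}: line {ln}: non-numeric weight {parts[2]!r}"
                ) from None
            rows.append((parts[0], parts[1], w))
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """GMT (name <tab> description <tab> genes...) or a plain gene list
    (one per line, set named after the file stem)."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty gene set file")
    if any("\t" in ln for ln in lines):
        sets = {}
        for ln_no, ln in enumerate(lines, start=1):
            parts = ln.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {ln_no}: GMT lines need name, description, >=1 gene"
                )
            sets[parts[0]] = [g for g in parts[2:] if g]
        return sets
    return {path.stem: lines}


def edges_to_frame(edges: pd.DataFrame) -> pd.DataFrame:
    """Pivot a (source, target, weight) edge list to a dense matrix."""
    return edges.pivot_table(
        index="source", columns="target", values="weight", fill_value=0.0, aggfunc="sum"
    )


def frame_to_matrix(
    edges: pd.DataFrame, index: list[str], columns: list[str]
) -> pd.DataFrame:
    """Dense matrix on a fixed (index, columns) universe from an edge list."""
    mat = pd.DataFrame(0.0, index=index, columns=columns)
    for _, row in edges.iterrows():
        if row["source"] in mat.index and row["target"] in mat.columns:
            mat.loc[row["source"], row["target"]] = row["weight"]
    return mat
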
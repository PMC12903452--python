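"""Readers and writers for the on-disk formats the pipeline uses.

Expression counts travel as MatrixMarket + features/barcodes TSV in the 10x
convention (matrix is genes x cells, 1-based indices); guide UMIs as a
long-form TSV (cell, guide, umis); the guide library and all result tables
as TSV with ``#``-prefixed provenance headers; simulation truth as JSON.
"""

from __future__ import annotations

import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .simulate import GuideUmiTable

__all__ = [
    "write_cell_dataset",
    "read_cell_dataset",
    "write_guide_umis",
    "read_guide_umis",
    "write_library",
    "read_library",
    "write_table",
    "read_table",
    "load_dataset",
]

logger = logging.getLogger(__name__)


def _validate_mtx(path: Path) -> None:
    """Check that the declared nnz matches the number of entry lines."""
    with open(path) as fh:
        header = None
        n_entries = 0
        for line in fh:
            line = line.strip()
            if not line or line.startswith("%"):
                continue
            if header is None:
                header = line.split()
                if len(header) != 3:
                    raise ValueError(f"{path}: malformed MTX size header {line!r}")
                continue
            n_entries += 1
        if header is None:
            raise ValueError(f"{path}: no MTX size header found")
        if n_entries != int(header[2]):
            raise ValueError(
                f"{path}: header declares {header[2]} entries but file has {n_entries}"
            )


def write_cell_dataset(adata: ad.AnnData, outdir) -> None:
    """10x-style trio (matrix.mtx, features.tsv, barcodes.tsv) + metadata.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    spio.mmwrite(outdir / "matrix.mtx", X.T.tocoo(), field="integer")
    pd.Series(adata.var_names).to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    adata.obs.to_csv(outdir / "metadata.tsv", sep="\t", index_label="cell")


def read_cell_dataset(indir) -> ad.AnnData:
    indir = Path(indir)
    _validate_mtx(indir / "matrix.mtx")
    mat = spio.mmread(indir / "matrix.mtx").tocsr().T.tocsr()  # cells x genes
    genes = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0].astype(str)
    cells = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    if cells.duplicated().any():
        raise ValueError(f"{indir}: duplicate cell barcodes")
    if mat.shape != (len(cells), len(genes)):
        raise ValueError(
            f"{indir}: matrix is {mat.shape} but {len(cells)} barcodes x {len(genes)} features"
        )
    obs = pd.DataFrame(index=cells.to_numpy())
    meta_path = indir / "metadata.tsv"
    if meta_path.exists():
        obs = pd.read_csv(meta_path, sep="\t", index_col="cell")
        obs.index = obs.index.astype(str)
        obs = obs.loc[cells.to_numpy()]
    return ad.AnnData(X=mat, obs=obs, var=pd.DataFrame(index=genes.to_numpy()))


def write_guide_umis(table: GuideUmiTable, path) -> None:
    table.to_long().to_csv(path, sep="\t", index=False)


def read_guide_umis(path, cell_ids=None, guide_ids=None) -> GuideUmiTable:
    df = pd.read_csv(path, sep="\t", dtype={"cell": str, "guide": str, "umis": int})
    return GuideUmiTable.from_long(df, cell_ids=cell_ids, guide_ids=guide_ids)


def write_library(library: pd.DataFrame, path) -> None:
    library.to_csv(path, sep="\t", index=False)


def read_library(path) -> pd.DataFrame:
    lib = pd.read_csv(path, sep="\t", dtype={"guide_id": str, "target": str, "sequence": str})
    lib["is_control"] = lib["is_control"].astype(bool)
    return lib


def write_table(df: pd.DataFrame, path, provenance: dict | None = None, index: bool = False) -> None:
    """TSV with ``#``-prefixed provenance header lines."""
    with open(path, "w") as fh:
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def load_dataset(
    counts_dir,
    guide_umis_path,
    library_path,
) -> tuple[ad.AnnData, GuideUmiTable, pd.DataFrame]:
    """Load the three inputs and reconcile barcodes across matrices.

    Cells are restricted to the intersection of expression and guide-table
    barcodes (guide-only barcodes are dropped, expression-only cells keep an
    all-zero guide row); drop counts are logged.
    """
    adata = read_cell_dataset(counts_dir)
    library = read_library(library_path)
    raw = pd.read_csv(guide_umis_path, sep="\t", dtype={"cell": str, "guide": str, "umis": int})
    known = set(adata.obs_names)
    extra = set(raw["cell"]) - known
    if extra:
        logger.info("dropping %d guide-table barcode(s) absent from counts", len(extra))
        raw = raw[raw["cell"].isin(known)]
    unknown_guides = set(raw["guide"]) - set(library["guide_id"])
    if unknown_guides:
        raise ValueError(f"guide UMI table references unknown guides: {sorted(unknown_guides)[:5]}")
    table = GuideUmiTable.from_long(
        raw, cell_ids=list(adata.obs_names), guide_ids=list(library["guide_id"])
    )
    return adata, table, library
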
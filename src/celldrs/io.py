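"""Readers and writers for expression matrices and result tables.

Expression matrices travel either as a Matrix Market directory
(``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv`` + ``metadata.tsv``) or as
an h5ad container; in memory they are AnnData objects in the canonical
cells x genes orientation.  Result tables are TSV with a typed header, the
effective configuration echoed as ``#`` comment lines, floats at six
significant digits and missing values as ``NA``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "read_expression",
    "write_mtx_dir",
    "write_tables",
    "read_table",
]

MTX_FILES = ("matrix.mtx", "genes.tsv", "barcodes.tsv")


def _read_label_file(path: Path) -> list[str]:
    labels = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    return labels


def read_expression(path: str | Path, dialect: str = "auto") -> AnnData:
    """Load an expression matrix from an MTX directory or an h5ad file.

    The MTX dialect expects ``matrix.mtx``, ``genes.tsv``, ``barcodes.tsv``
    and optionally ``metadata.tsv`` (tab-separated per-cell annotations whose
    first column is the barcode).  Orientation is auto-detected from the
    label-file lengths; the returned AnnData is always cells x genes.
    Duplicate gene symbols are rejected.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "h5ad" if path.suffix == ".h5ad" else "mtx_dir"
    if dialect == "h5ad":
        import anndata
        adata = anndata.read_h5ad(path)
    elif dialect == "mtx_dir":
        missing = [f for f in MTX_FILES if not (path / f).exists()]
        if missing:
            raise FileNotFoundError(f"{path}: missing {missing}")
        mat = sp.csr_matrix(scipy.io.mmread(path / "matrix.mtx"))
        genes = _read_label_file(path / "genes.tsv")
        barcodes = _read_label_file(path / "barcodes.tsv")
        if mat.shape == (len(barcodes), len(genes)):
            pass
        elif mat.shape == (len(genes), len(barcodes)):
            mat = mat.T.tocsr()
        else:
            raise ValueError(
                f"{path}: matrix shape {mat.shape} matches neither "
                f"{len(barcodes)} barcodes x {len(genes)} genes nor its "
                "transpose")
        obs = pd.DataFrame(index=pd.Index(barcodes, name="cell_id"))
        meta_path = path / "metadata.tsv"
        if meta_path.exists():
            meta = pd.read_csv(meta_path, sep="\t", index_col=0, comment="#")
            if not meta.index.astype(str).equals(obs.index.astype(str)):
                raise ValueError(f"{meta_path}: cell ids do not match "
                                 "barcodes.tsv")
            obs = meta
            obs.index.name = "cell_id"
        adata = AnnData(X=mat, obs=obs,
                        var=pd.DataFrame(index=pd.Index(genes,
                                                        name="symbol")))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    dupes = adata.var_names[adata.var_names.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate gene symbols: {dupes}")
    dupes = adata.obs_names[adata.obs_names.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate cell barcodes: {dupes}")
    return adata


def write_mtx_dir(adata: AnnData, out_dir: str | Path) -> Path:
    """Write counts + labels + annotations as an MTX directory (text only)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    scipy.io.mmwrite(out / "matrix.mtx", sp.coo_matrix(X), field="integer"
                     if np.issubdtype(X.dtype, np.integer) else "real")
    (out / "genes.tsv").write_text("\n".join(adata.var_names) + "\n")
    (out / "barcodes.tsv").write_text("\n".join(adata.obs_names) + "\n")
    if adata.obs.shape[1]:
        adata.obs.rename_axis("cell_id").to_csv(out / "metadata.tsv",
                                                sep="\t")
    return out


def _format_value(v) -> str:
    if v is None or (isinstance(v, float) and not np.isfinite(v)):
        return "NA"
    if isinstance(v, (float, np.floating)):
        return f"{v:.6g}"
    return str(v)


def write_tables(results, path: str | Path,
                 config: Mapping | None = None) -> Path:
    """Write a result object (or DataFrame) as an annotated TSV.

    ``results`` may be any object with a ``to_frame()`` method (CellScores,
    GroupStats, GenePriority, ContrastResult, CorrelationComparison) or a
    DataFrame.  ``config`` entries are echoed as ``# key = value`` comment
    lines.  Empty results are an error and create no file.
    """
    frame = results.to_frame() if hasattr(results, "to_frame") else results
    if not isinstance(frame, pd.DataFrame):
        raise TypeError(f"cannot serialize {type(results).__name__}")
    if frame.empty:
        raise ValueError("refusing to write an empty result table")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    meta = dict(config or {})
    for key in ("n_ctrl", "seed", "weighting", "group_key"):
        if key not in meta and hasattr(results, key):
            meta[key] = getattr(results, key)
    for key, value in meta.items():
        lines.append(f"# {key} = {value}")
    lines.append("\t".join(map(str, frame.columns)))
    for _, row in frame.iterrows():
        lines.append("\t".join(_format_value(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tables` ('NA' -> NaN)."""
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
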
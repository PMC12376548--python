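"""Reading and writing the standard on-disk formats.

Count matrices travel either as a 10x-style MatrixMarket triplet directory
(``matrix.mtx`` with genes as rows, ``genes.tsv``, ``barcodes.tsv``) or as
a dense TSV with a header row of cell ids and gene ids in the first
column.  All other artifacts are TSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .matrix import CountMatrix


class FormatError(ValueError):
    pass


def read_counts(path: str | Path) -> CountMatrix:
    """Read a count matrix from a triplet directory or a dense TSV file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such input: {path}")
    if path.is_dir():
        return _read_triplet(path)
    return _read_dense_tsv(path)


def _read_triplet(d: Path) -> CountMatrix:
    for required in ("matrix.mtx", "genes.tsv", "barcodes.tsv"):
        if not (d / required).exists():
            raise FormatError(f"triplet directory {d} is missing {required}")
    mat = spio.mmread(d / "matrix.mtx")
    genes = pd.read_csv(d / "genes.tsv", sep="\t", header=None).iloc[:, 0].astype(str)
    cells = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None).iloc[:, 0].astype(str)
    mat = np.asarray(mat.todense()) if sparse.issparse(mat) else np.asarray(mat)
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"matrix.mtx is {mat.shape} but ids give "
            f"{len(genes)} genes x {len(cells)} cells"
        )
    if not np.allclose(mat, np.round(mat)):
        raise FormatError("matrix.mtx contains non-integer values")
    return CountMatrix(pd.Index(genes), pd.Index(cells), mat.astype(np.int64))


def _read_dense_tsv(path: Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy()
    if not np.allclose(vals, np.round(vals)):
        raise FormatError(f"{path} contains non-integer values")
    return CountMatrix(
        pd.Index(df.index.astype(str)),
        pd.Index(df.columns.astype(str)),
        vals.astype(np.int64),
    )


def write_counts(counts: CountMatrix, outdir: str | Path) -> Path:
    """Write a triplet directory (genes as rows of matrix.mtx)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.coo_matrix(counts.values))
    pd.Series(counts.gene_ids).to_csv(
        outdir / "genes.tsv", sep="\t", header=False, index=False
    )
    pd.Series(counts.cell_ids).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    return outdir


def write_truth(truth: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = ["type", "subtype", "bihormonal_pair", "is_doublet", "parent1", "parent2"]
    extra = [c for c in truth.columns if c not in cols]
    truth.loc[:, cols + extra].to_csv(path, sep="\t", index=True)
    return path


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False,
                       dtype={"is_doublet": bool})


def read_signal_tsv(path: str | Path, groups_path: str | Path):
    """Read a region x cell SI TSV plus a two-column cell->group TSV."""
    from .atac import SignalMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    groups = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0]
    return SignalMatrix(
        region_ids=pd.Index(df.index.astype(str)),
        cell_ids=pd.Index(df.columns.astype(str)),
        values=df.to_numpy(),
        cell_groups=groups,
    )


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    return path


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.ndarray, pd.Index)):
        return list(x)
    if isinstance(x, (set, tuple)):
        return list(x)
    raise TypeError(f"not JSON serializable: {type(x)}")
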
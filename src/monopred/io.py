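"""Plain-text and TIFF I/O for the pipeline's tables, matrices and images.

Tables travel as TSV with header; expression as MatrixMarket triplet text
plus gene/cell index files; images as multi-page 16-bit TIFF in page order
DAPI, CD14, CD16, APOBEC3A; simulation/gating parameters as YAML or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import io as sio
from scipy import sparse

__all__ = [
    "read_table",
    "write_table",
    "read_expression",
    "write_expression",
    "read_stack",
    "write_stack",
    "load_params",
    "dump_json",
]


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def write_expression(expr, genes, cell_ids, outdir) -> None:
    """Write a cells x genes sparse matrix as matrix.mtx + genes/barcodes TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(str(outdir / "matrix.mtx"), sparse.coo_matrix(expr))
    pd.Series(genes, name="gene").to_csv(outdir / "genes.tsv", sep="\t", index=False)
    pd.Series(cell_ids, name="cell_id").to_csv(outdir / "barcodes.tsv", sep="\t", index=False)


def read_expression(indir):
    indir = Path(indir)
    expr = sparse.csr_matrix(sio.mmread(str(indir / "matrix.mtx")))
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")["gene"].tolist()
    cells = pd.read_csv(indir / "barcodes.tsv", sep="\t")["cell_id"].tolist()
    return expr, genes, cells


def write_stack(stack: np.ndarray, path) -> None:
    """Multi-page 16-bit TIFF, page order DAPI, CD14, CD16, APOBEC3A."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint16),
                     photometric="minisblack")


def read_stack(path) -> np.ndarray:
    stack = tifffile.imread(path)
    if stack.ndim != 3:
        raise ValueError("expected a multi-page TIFF with one page per channel")
    return stack


def load_params(path) -> dict:
    """Load a YAML or JSON parameter file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def dump_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
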
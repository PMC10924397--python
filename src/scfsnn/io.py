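"""Readers and writers for counts, labels, configs and run artifacts.

Counts are accepted either as a Matrix Market triplet in the 10x convention
(matrix.mtx with genes as rows on disk, plus genes.tsv and barcodes.tsv
sidecars; transposed to cells x genes on load) or as a dense CSV/TSV with a
header row of gene ids and a first column of cell ids.  Labels are a
two-column TSV (cell_id, class).  All tabular outputs are TSV with header
rows; scalar results go to JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .preprocess import CountMatrix, Labels, ProcessedMatrix
from .selector import SelectionResult

__all__ = [
    "load_counts",
    "load_labels",
    "write_counts_mtx",
    "write_counts_csv",
    "write_labels",
    "write_processed_tsv",
    "write_result",
]


def load_counts(path: str | Path, format: str | None = None) -> CountMatrix:
    """Load a counts matrix; format inferred from the path when not given.

    ``mtx_triplet``: ``path`` is the .mtx file or its directory; ``genes.tsv``
    and ``barcodes.tsv`` must sit next to it.  ``csv``/``tsv``: dense matrix,
    first column cell ids, header gene ids.
    """
    path = Path(path)
    if format is None:
        if path.is_dir() or path.suffix == ".mtx":
            format = "mtx_triplet"
        elif path.suffix == ".csv":
            format = "csv"
        elif path.suffix in (".tsv", ".txt"):
            format = "tsv"
        else:
            raise ValueError(f"cannot infer counts format from {path.name!r}")
    if format == "mtx_triplet":
        mtx = path / "matrix.mtx" if path.is_dir() else path
        base = mtx.parent
        mat = spio.mmread(mtx)
        genes = pd.read_csv(base / "genes.tsv", sep="\t", header=None)
        cells = pd.read_csv(base / "barcodes.tsv", sep="\t", header=None)
        dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat).T  # genes-on-rows on disk
        if dense.shape != (len(cells), len(genes)):
            raise ValueError(
                f"matrix is {dense.shape} after transpose but sidecars give "
                f"{len(cells)} barcodes x {len(genes)} genes"
            )
        return CountMatrix(dense, genes.iloc[:, 0].to_numpy(), cells.iloc[:, 0].to_numpy())
    if format in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if format == "csv" else "\t", index_col=0)
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            frac = values != np.floor(values)
            if frac.any():
                i, j = np.argwhere(frac)[0]
                raise ValueError(
                    f"non-integer count {values[i, j]!r} at row {df.index[i]!r}, "
                    f"column {df.columns[j]!r}"
                )
        return CountMatrix(values.astype(np.int64), df.columns.to_numpy(), df.index.to_numpy())
    raise ValueError(f"unknown counts format {format!r}")


def load_labels(path: str | Path, cell_ids: np.ndarray | None = None) -> Labels:
    """Read a two-column TSV (cell_id, class); classes are coded 0..K-1.

    When ``cell_ids`` is given, labels are reordered to match and every cell
    must be present.  String class names are mapped to codes in sorted order.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "label"], dtype=str)
    if df["cell_id"].iloc[0] == "cell_id":  # tolerate a header row
        df = df.iloc[1:].reset_index(drop=True)
    if cell_ids is not None:
        mapping = dict(zip(df["cell_id"], df["label"]))
        missing = [c for c in cell_ids if c not in mapping]
        if missing:
            raise ValueError(f"labels missing for cells: {missing[:5]}")
        lab = pd.Series([mapping[c] for c in cell_ids])
    else:
        lab = df["label"]
    classes = sorted(lab.unique())
    codes = lab.map({c: k for k, c in enumerate(classes)}).to_numpy()
    return Labels(codes, len(classes))


def write_counts_mtx(counts: CountMatrix, out_dir: str | Path) -> None:
    """Write matrix.mtx (genes as rows, 10x convention) + genes.tsv + barcodes.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / "matrix.mtx", sparse.coo_matrix(counts.values.T))
    pd.Series(counts.gene_ids).to_csv(out / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(counts.cell_ids).to_csv(out / "barcodes.tsv", sep="\t", header=False, index=False)


def write_counts_csv(counts: CountMatrix, path: str | Path, sep: str = ",") -> None:
    pd.DataFrame(counts.values, index=counts.cell_ids, columns=counts.gene_ids).to_csv(
        path, sep=sep
    )


def write_labels(labels: Labels, cell_ids: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"cell_id": cell_ids, "label": labels.y}).to_csv(
        path, sep="\t", header=False, index=False
    )


def write_processed_tsv(proc: ProcessedMatrix, cell_ids: np.ndarray, path: str | Path) -> None:
    """Dump a processed matrix for debugging."""
    pd.DataFrame(proc.values, index=cell_ids, columns=proc.gene_ids).to_csv(path, sep="\t")


def write_result(result: SelectionResult, out_dir: str | Path) -> None:
    """Write selected_genes.tsv, trajectory.tsv and result.json for one run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"gene_id": result.selected_gene_ids, "score": result.selected_scores}
    ).to_csv(out / "selected_genes.tsv", sep="\t", index=False)
    result.trajectory.to_csv(out / "trajectory.tsv", sep="\t", index=False)
    cfg = dataclasses.asdict(result.config)
    summary = {
        "n_selected": len(result.selected_gene_ids),
        "final_test_accuracy": result.final_test_accuracy,
        "n_steps": result.n_steps,
        "n_genes_input": result.n_genes_input,
        "stopped_by_safeguard": result.stopped_by_safeguard,
        "seed": result.seed,
        "config": cfg,
    }
    (out / "result.json").write_text(json.dumps(summary, indent=2, default=str) + "\n")
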
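"""Reading and writing the standard on-disk formats.

Expression matrices come in as Matrix Market triplets with features /
barcodes sidecar tables (1-based on disk, 0-based in memory) or as dense
delimited text with genes as rows; both are gzip-transparent. Marker sets
round-trip through JSON ({tissue, cell_types: {name: [genes]}}) or a
two-column long CSV (cell_type, gene).
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .cv import CVReport
from .markers import MarkerSet
from .matrix import ExpressionMatrix
from .optimize import OptimizationResult
from .scoring import EnrichmentResult


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _validate_mtx(path) -> None:
    """Locate the first malformed triplet line so the error can cite it."""
    with _open_text(path) as fh:
        lineno = 0
        header_seen = False
        for raw in fh:
            lineno += 1
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            parts = line.split()
            expected = 3
            ok = len(parts) == expected and all(_is_number(p) for p in parts)
            if not ok:
                raise ValueError(
                    f"{path}: malformed Matrix Market triplet at line {lineno}: "
                    f"{line!r}")
            if not header_seen:
                header_seen = True  # dimensions line, same shape as triplets


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


def _read_sidecar(path, what: str) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 1 or df.isna().all(axis=None):
        raise ValueError(f"{path}: empty {what} sidecar")
    return df.iloc[:, 0].astype(str).to_numpy(dtype=object)


def read_expression(path, genes_path=None, cells_path=None, fmt=None,
                    layer_tag: str = "raw") -> ExpressionMatrix:
    """Read an expression matrix.

    ``fmt`` is inferred from the suffix when not given: ``.mtx``(.gz) reads
    a sparse Matrix Market triplet file with ``genes_path`` / ``cells_path``
    sidecars (default: ``features.tsv`` and ``barcodes.tsv`` next to the
    matrix), anything else a dense delimited table with gene ids in the
    first column and cell ids in the header.
    """
    path = Path(path)
    if fmt is None:
        stem = path.name[:-3] if path.suffix == ".gz" else path.name
        fmt = "mtx" if stem.endswith(".mtx") else "dense"
    if fmt == "mtx":
        genes_path = genes_path or path.parent / "features.tsv"
        cells_path = cells_path or path.parent / "barcodes.tsv"
        try:
            with _open_text(path, "rb") as fh:
                mat = scipy.io.mmread(fh)
        except Exception:
            _validate_mtx(path)   # produce a line-numbered error if malformed
            raise
        values = sp.csr_matrix(mat)
        genes = _read_sidecar(genes_path, "features")
        cells = _read_sidecar(cells_path, "barcodes")
        return ExpressionMatrix(values, genes, cells, layer_tag=layer_tag)
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return ExpressionMatrix(df.to_numpy(dtype=np.float64),
                            df.index.astype(str).to_numpy(dtype=object),
                            df.columns.astype(str).to_numpy(dtype=object),
                            layer_tag=layer_tag)


def write_expression(X: ExpressionMatrix, path, genes_path=None, cells_path=None,
                     fmt=None) -> None:
    """Write a matrix as Matrix Market + sidecars or as dense TSV."""
    path = Path(path)
    if fmt is None:
        stem = path.name[:-3] if path.suffix == ".gz" else path.name
        fmt = "mtx" if stem.endswith(".mtx") else "dense"
    if fmt == "mtx":
        genes_path = genes_path or path.parent / "features.tsv"
        cells_path = cells_path or path.parent / "barcodes.tsv"
        with _open_text(path, "wb") as fh:
            scipy.io.mmwrite(fh, sp.coo_matrix(X.values))
        pd.Series(X.gene_ids).to_csv(genes_path, sep="\t", index=False, header=False)
        pd.Series(X.cell_ids).to_csv(cells_path, sep="\t", index=False, header=False)
    else:
        vals = X.values.toarray() if sp.issparse(X.values) else X.values
        df = pd.DataFrame(vals, index=X.gene_ids, columns=X.cell_ids)
        sep = "," if path.name.rstrip(".gz").endswith(".csv") else "\t"
        df.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# marker sets
# ---------------------------------------------------------------------------

def read_markers(path) -> MarkerSet:
    """Read a marker set from JSON or two-column long CSV/TSV."""
    path = Path(path)
    stem = path.name[:-3] if path.suffix == ".gz" else path.name
    if stem.endswith(".json"):
        with _open_text(path) as fh:
            payload = json.load(fh)
        bounds = tuple(payload.get("size_bounds", (1, 30)))
        return MarkerSet(payload.get("tissue", "unknown"),
                         {ct: tuple(genes) for ct, genes in payload["cell_types"].items()},
                         size_bounds=bounds)
    df = pd.read_csv(path, sep=None, engine="python")
    if not {"cell_type", "gene"} <= set(df.columns):
        raise ValueError(f"{path}: marker CSV needs 'cell_type' and 'gene' columns")
    per_type: dict[str, list[str]] = {}
    for ct, gene in zip(df["cell_type"], df["gene"]):
        per_type.setdefault(str(ct), []).append(str(gene))
    return MarkerSet("unknown", {ct: tuple(g) for ct, g in per_type.items()})


def write_markers(S: MarkerSet, path) -> None:
    path = Path(path)
    stem = path.name[:-3] if path.suffix == ".gz" else path.name
    if stem.endswith(".json"):
        payload = {"tissue": S.tissue_tag,
                   "size_bounds": list(S.size_bounds),
                   "cell_types": {ct: list(S[ct]) for ct in S.cell_types}}
        with _open_text(path, "wt") as fh:
            json.dump(payload, fh, indent=1)
    else:
        rows = [{"cell_type": ct, "gene": g} for ct in S.cell_types for g in S[ct]]
        pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def write_annotation(result: EnrichmentResult, path, scores_path=None) -> None:
    """Write per-cell labels as TSV (cell_id, label, top_score); optionally
    the full score matrix as a separate TSV."""
    result.label_frame().to_csv(path, sep="\t", index=False)
    if scores_path is not None:
        result.to_frame().to_csv(scores_path, sep="\t")


def write_cv_report(report: CVReport, path, summary_path=None) -> None:
    report.to_frame().to_csv(path, sep="\t", index=False)
    if summary_path is not None:
        with open(summary_path, "w") as fh:
            json.dump(report.summary(), fh, indent=1)


def write_optimization_result(result: OptimizationResult, path,
                              trace_path=None) -> None:
    payload = {
        "best_objective": result.best_objective,
        "budget_used": result.budget_used,
        "seed": result.seed,
        "size_bounds": list(result.best_set.size_bounds),
        "best_set": {ct: list(result.best_set[ct]) for ct in result.best_set.cell_types},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
    if trace_path is not None:
        pd.DataFrame(result.trace).to_csv(trace_path, sep="\t", index=False)
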
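"""Reading and writing the package's file formats.

Expression matrices travel as delimited text (TSV/CSV) with sample ids in
the first column and gene ids in the header (samples x genes by default; a
transpose flag accepts genes x samples). Graphs are two-column edge lists
with an optional weight column; hub and core-gene lists are one identifier
per line. Matrices are written as CSV with gene ids as both header and row
labels. All writers order rows and columns deterministically so outputs
are diffable.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_edge_list",
    "write_edge_list",
    "read_gene_list",
    "write_gene_list",
    "read_matrix_csv",
    "write_matrix_csv",
    "write_json_report",
]


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression_matrix(path, transpose: bool = False):
    """Load an expression matrix; returns ``(values, gene_ids, sample_ids)``."""
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if not transpose:
        dupes = sorted({g for g in header if header.count(g) > 1})
        if dupes:
            raise ValueError(
                f"duplicated gene identifier(s): {', '.join(dupes)}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if transpose:
        df = df.T
    genes = [str(g) for g in df.columns]
    dupes = sorted({g for g in genes if genes.count(g) > 1})
    if dupes:
        raise ValueError(f"duplicated gene identifier(s): {', '.join(dupes)}")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"missing values in column(s): {bad}")
    values = df.to_numpy(dtype=float)
    return values, genes, [str(s) for s in df.index]


def write_expression_matrix(path, values, gene_ids, sample_ids) -> None:
    df = pd.DataFrame(np.asarray(values), index=list(sample_ids),
                      columns=list(gene_ids))
    df.to_csv(path, sep=_sep_for(path))


def read_edge_list(path):
    """Edge list with columns gene_a, gene_b [, weight]; '#' starts a comment.

    Reversed duplicates collapse to one undirected edge; self-loops are
    dropped with a warning. Returns ``(edges, weights)`` where weights is a
    dict keyed by the unordered pair (or empty when no weight column).
    """
    edges = []
    weights = {}
    have_weights = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", "\t").split("\t")
            parts = [t.strip() for t in parts if t.strip()]
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            a, b = parts[0], parts[1]
            if lineno == 1 and {a.lower(), b.lower()} & {"gene_a", "source", "from"}:
                continue  # header row
            if a == b:
                warnings.warn(f"{path}:{lineno}: self-loop on {a} dropped",
                              RuntimeWarning)
                continue
            key = (a, b) if a <= b else (b, a)
            if key not in weights:
                edges.append(key)
            if len(parts) >= 3:
                try:
                    weights[key] = float(parts[2])
                except ValueError as err:
                    raise ValueError(
                        f"{path}:{lineno}: bad weight {parts[2]!r}") from err
                have_weights = True
            else:
                weights.setdefault(key, None)
    if not have_weights:
        return edges, {}
    return edges, {k: v for k, v in weights.items() if v is not None}


def write_edge_list(path, edges, weights: dict | None = None,
                    extra_columns: dict | None = None) -> None:
    """Write an undirected edge list TSV with optional per-edge columns."""
    rows = []
    for e in edges:
        a, b = e[0], e[1]
        key = (a, b) if str(a) <= str(b) else (b, a)
        row = {"gene_a": key[0], "gene_b": key[1]}
        if weights is not None:
            row["weight"] = weights.get(key, "")
        if extra_columns:
            for name, mapping in extra_columns.items():
                row[name] = mapping.get(key, "")
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["gene_a", "gene_b"], key=lambda s: s.astype(str))
    df.to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list:
    with open(path) as fh:
        return [line.strip() for line in fh
                if line.strip() and not line.startswith("#")]


def write_gene_list(path, genes) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_matrix_csv(path):
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_matrix_csv(path, m, ids) -> None:
    pd.DataFrame(np.asarray(m), index=list(ids), columns=list(ids)).to_csv(path)


def write_json_report(path, report: dict) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True,
                                     default=_default) + "\n")
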
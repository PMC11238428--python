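"""Expression-matrix container, CSV/TSV I/O and the input transform.

The universal input of the toolkit is a numeric samples x genes matrix
(e.g. TPM or z-scores) with unique sample and gene identifiers.  The only
preprocessing applied by the pipeline itself is the inverse hyperbolic
sine transform, a variance-compressing map defined on all reals (unlike
``arcsin(sqrt(x))`` it accepts negative values such as z-scores), so that
genes with low expression are accommodated without a pseudocount.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "MatrixLoadError",
    "load_expression_matrix",
    "write_expression_matrix",
    "asinh_transform",
    "write_json_report",
]


class MatrixLoadError(ValueError):
    """Raised when an input file does not parse into a valid matrix."""


@dataclass(eq=False)
class ExpressionMatrix:
    """A samples x genes numeric matrix with row/column identifiers.

    Invariants enforced at construction: all entries finite, identifier
    lists unique and matching the matrix dimensions.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise MatrixLoadError("expression matrix must be 2-D and non-empty")
        n, m = self.values.shape
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1}" for i in range(n)]
        if not self.gene_ids:
            self.gene_ids = [f"G{j + 1}" for j in range(m)]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(self.sample_ids) != n or len(self.gene_ids) != m:
            raise MatrixLoadError(
                f"identifier counts ({len(self.sample_ids)}, {len(self.gene_ids)}) "
                f"do not match matrix shape {self.values.shape}"
            )
        for name, ids in (("sample", self.sample_ids), ("gene", self.gene_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise MatrixLoadError(f"duplicate {name} identifier: {i!r}")
                seen.add(i)
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise MatrixLoadError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        """Column-restrict to ``genes`` (kept in the given order)."""
        pos = {g: j for j, g in enumerate(self.gene_ids)}
        try:
            cols = [pos[g] for g in genes]
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown gene identifier {exc.args[0]!r}") from None
        return ExpressionMatrix(self.values[:, cols], list(self.sample_ids), list(genes))

    def transpose(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.T, list(self.gene_ids), list(self.sample_ids))


def _detect_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def load_expression_matrix(
    path: str | Path,
    orientation: str = "samples_in_rows",
    delimiter: str | None = None,
) -> ExpressionMatrix:
    """Read a delimited matrix with one header row and one leading ID column.

    ``orientation`` is either ``samples_in_rows`` (default) or
    ``genes_in_rows``; the returned matrix is always samples x genes.
    The delimiter is inferred from the extension (.tsv/.tab/.txt -> tab,
    otherwise comma) unless given explicitly.
    """
    if orientation not in {"samples_in_rows", "genes_in_rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    sep = _detect_delimiter(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:
        raise MatrixLoadError(f"cannot parse {path}: {exc}") from exc
    if df.empty:
        raise MatrixLoadError(f"{path} contains an empty matrix")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna().to_numpy()
    if bad.to_numpy().any() or numeric.isna().to_numpy().any():
        mask = numeric.isna().to_numpy()
        i, j = np.argwhere(mask)[0]
        raise MatrixLoadError(
            f"non-numeric or missing cell at row {df.index[i]!r}, "
            f"column {df.columns[j]!r} in {path}"
        )
    em = ExpressionMatrix.from_frame(numeric)
    if orientation == "genes_in_rows":
        em = em.transpose()
    return em


def write_expression_matrix(em: ExpressionMatrix, path: str | Path, delimiter: str | None = None) -> None:
    path = Path(path)
    em.to_frame().to_csv(path, sep=_detect_delimiter(path, delimiter))


def asinh_transform(X):
    """Elementwise inverse hyperbolic sine, ``ln(x + sqrt(x^2 + 1))``.

    Odd, strictly monotone and defined on all reals; identifiers are
    preserved when applied to an :class:`ExpressionMatrix`.
    """
    if isinstance(X, ExpressionMatrix):
        return ExpressionMatrix(np.arcsinh(X.values), list(X.sample_ids), list(X.gene_ids))
    return np.arcsinh(np.asarray(X, dtype=float))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_json_report(report, path: str | Path) -> None:
    """Write a report dict as deterministic (sorted-key) JSON."""
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
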
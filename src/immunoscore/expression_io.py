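"""Reading, validation and scale normalization of expression and signature matrices.

Bulk expression is represented gene-by-sample on the linear TPM scale
(transcripts per million).  Matrices stored as ``log2(TPM + 1)`` are accepted
as an input encoding and inverted back to linear scale before deconvolution,
since signature-regression deconvolution is defined on linear mixtures.

Text dialect: first row holds sample identifiers, first column holds gene
symbols, tab-separated by default (comma accepted).  An optional leading
directive line ``#scale=log2p1`` marks log-encoded files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SCALE_LINEAR = "linear"
SCALE_LOG2P1 = "log2p1"
_VALID_SCALES = (SCALE_LINEAR, SCALE_LOG2P1)

_SCALE_DIRECTIVE = "#scale="


class MatrixLoadError(ValueError):
    """Raised when a matrix file is malformed (names the offending cell)."""


def _check_unique(names, what: str) -> None:
    seen: dict[str, int] = {}
    for n in names:
        if n in seen:
            raise ValueError(f"duplicate {what}: {n!r}")
        seen[n] = 1


@dataclass
class ExpressionMatrix:
    """A gene-by-sample abundance matrix.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene symbols (row labels).
    sample_ids : list of str
        Unique sample identifiers (column labels).
    values : ndarray of shape (n_genes, n_samples)
        Abundances; non-negative when ``scale_tag == "linear"``.
    scale_tag : {"linear", "log2p1"}
        Whether ``values`` are linear TPM or ``log2(TPM + 1)``.
    """

    gene_ids: list
    sample_ids: list
    values: np.ndarray
    scale_tag: str = SCALE_LINEAR

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.scale_tag not in _VALID_SCALES:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if self.scale_tag == SCALE_LINEAR and np.any(self.values < 0):
            g, s = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r} on linear scale"
            )

    @property
    def shape(self):
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, scale_tag: str = SCALE_LINEAR) -> "ExpressionMatrix":
        return cls(
            gene_ids=list(frame.index),
            sample_ids=list(frame.columns),
            values=frame.to_numpy(dtype=float),
            scale_tag=scale_tag,
        )


@dataclass
class SignatureMatrix:
    """Reference expression profiles per immune cell type (LM22 layout).

    ``t_cell_types`` declares which columns are CD3+ T-cell subsets (the
    pan-T compartment) and ``cd8_type`` the single CD8+ cytotoxic subset.
    """

    gene_ids: list
    cell_types: list
    values: np.ndarray
    t_cell_types: tuple = field(default_factory=tuple)
    cd8_type: str = ""

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self.cell_types = list(self.cell_types)
        self.t_cell_types = tuple(self.t_cell_types)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_types)):
            raise ValueError("values shape does not match gene/cell-type labels")
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.cell_types, "cell type")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("signature values must be finite and non-negative")
        missing = [t for t in self.t_cell_types if t not in self.cell_types]
        if missing:
            raise ValueError(f"declared T-cell types not in columns: {missing}")
        if self.cd8_type and self.cd8_type not in self.t_cell_types:
            raise ValueError(
                f"cd8_type {self.cd8_type!r} must be one of the declared T-cell types"
            )

    @property
    def shape(self):
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_types)


def _parse_table(path, delimiter: str):
    """Read a labelled numeric table, returning (header directives, DataFrame).

    Raises :class:`MatrixLoadError` naming the first offending cell on
    non-numeric or missing entries.
    """
    directives = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            if line.strip().lower().startswith(_SCALE_DIRECTIVE):
                directives["scale"] = line.strip()[len(_SCALE_DIRECTIVE):]
            pos = fh.tell()
            line = fh.readline()
        header = line.rstrip("\n").split(delimiter)
        dup_cols = pd.Index(header[1:]).duplicated()
        if dup_cols.any():
            raise MatrixLoadError(
                f"duplicate column id {header[1:][int(np.argmax(dup_cols))]!r} in {path}"
            )
        fh.seek(pos)
        try:
            frame = pd.read_csv(fh, sep=delimiter, index_col=0, dtype=str)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise MatrixLoadError(f"malformed table {path}: {exc}") from exc
    if frame.columns.size == 0:
        raise MatrixLoadError(f"malformed header in {path}: no sample columns")
    cols = [str(c) for c in frame.columns]
    dup = pd.Index(cols).duplicated()
    if dup.any():
        raise MatrixLoadError(f"duplicate column id {cols[int(np.argmax(dup))]!r} in {path}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~frame.isna().to_numpy()
    if bad.to_numpy().any() or frame.isna().to_numpy().any():
        mask = numeric.isna().to_numpy()
        g, s = np.argwhere(mask)[0]
        raise MatrixLoadError(
            f"non-numeric or missing value at row {frame.index[g]!r}, "
            f"column {cols[s]!r} in {path}"
        )
    numeric.columns = cols
    numeric.index = [str(i) for i in numeric.index]
    return directives, numeric


def read_expression_matrix(path, delimiter: str = "\t") -> ExpressionMatrix:
    """Load a gene-by-sample expression matrix from a delimited text file.

    The scale defaults to linear TPM unless the file carries a
    ``#scale=log2p1`` directive line.  Duplicate gene rows are collapsed by
    arithmetic mean (deterministic and order-independent); duplicate sample
    columns are an error.
    """
    directives, frame = _parse_table(path, delimiter)
    scale = directives.get("scale", SCALE_LINEAR)
    if scale not in _VALID_SCALES:
        raise MatrixLoadError(f"unknown scale directive {scale!r} in {path}")
    if frame.index.duplicated().any():
        frame = frame.groupby(level=0, sort=False).mean()
    if scale == SCALE_LINEAR and (frame.to_numpy() < 0).any():
        g, s = np.argwhere(frame.to_numpy() < 0)[0]
        raise MatrixLoadError(
            f"negative value at gene {frame.index[g]!r}, "
            f"sample {frame.columns[s]!r} in {path}"
        )
    return ExpressionMatrix.from_frame(frame, scale_tag=scale)


def read_signature_matrix(path, t_cell_types, cd8_type, delimiter: str = "\t") -> SignatureMatrix:
    """Load an LM22-layout signature matrix and record the T-cell declarations.

    The gene column is either named ``Gene symbol`` or is the first column;
    every remaining column is one cell type.  Declared ``t_cell_types`` and
    ``cd8_type`` must all be present among the columns.
    """
    _, frame = _parse_table(path, delimiter)
    if frame.index.name and frame.index.name.strip().lower() not in ("gene symbol", "gene", ""):
        # first column is still treated as the gene column regardless of name
        pass
    if frame.index.duplicated().any():
        frame = frame.groupby(level=0, sort=False).mean()
    unknown = [t for t in t_cell_types if t not in frame.columns]
    if unknown:
        raise ValueError(f"declared T-cell types not found in signature columns: {unknown}")
    if cd8_type not in frame.columns:
        raise ValueError(f"cd8_type {cd8_type!r} not found in signature columns")
    return SignatureMatrix(
        gene_ids=list(frame.index),
        cell_types=list(frame.columns),
        values=frame.to_numpy(dtype=float),
        t_cell_types=tuple(t_cell_types),
        cd8_type=cd8_type,
    )


def write_expression_matrix(matrix: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        if matrix.scale_tag != SCALE_LINEAR:
            fh.write(f"{_SCALE_DIRECTIVE}{matrix.scale_tag}\n")
        matrix.to_frame().to_csv(fh, sep=delimiter, index_label="Gene symbol")


def write_signature_matrix(signature: SignatureMatrix, path, delimiter: str = "\t") -> None:
    signature.to_frame().to_csv(path, sep=delimiter, index_label="Gene symbol")


def to_linear_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Return the matrix on linear TPM scale.

    A ``log2p1`` matrix is inverted cell-wise as ``2**v - 1``; tiny negatives
    from floating-point rounding are clamped to 0.  A linear matrix is
    returned unchanged.
    """
    if matrix.scale_tag == SCALE_LINEAR:
        return matrix
    if matrix.scale_tag == SCALE_LOG2P1:
        values = np.exp2(matrix.values) - 1.0
        values[(values < 0) & (values > -1e-9)] = 0.0
        return replace(matrix, values=values, scale_tag=SCALE_LINEAR)
    raise ValueError(f"unknown scale_tag {matrix.scale_tag!r}")


def log2p1(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Encode a linear matrix as ``log2(TPM + 1)`` (inverse of to_linear_tpm)."""
    if matrix.scale_tag != SCALE_LINEAR:
        raise ValueError("input must be on linear scale")
    return replace(matrix, values=np.log2(matrix.values + 1.0), scale_tag=SCALE_LOG2P1)
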
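"""Reading and writing somatic-mutation cohorts.

The central container is the binary gene × sample incidence matrix
``A ∈ {0,1}^(m×n)``: entry ``(g, s)`` is 1 when sample ``s`` carries at
least one somatic point mutation in gene ``g``.  Mutation calls arrive as
MAF-like tab-separated records (gene symbol, tumor sample barcode, variant
classification) and are binarized here; dense TSV and MatrixMarket round
trips are provided for persistence.

Gene rows are sorted lexicographically at load time and that order fixes
the canonical 1-based gene index used by every downstream step (the index
0 is reserved as the padding symbol of the sparsity-reduction encoding).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

#: gene-symbol placeholders dropped (with a logged count) during MAF parsing
_BLANK_GENE_SYMBOLS = {"", ".", "-", "unknown", "nan"}


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class EmptyInputError(ValueError):
    """No records remain after parsing/filtering."""


@dataclass
class BinaryMutationMatrix:
    """Gene × sample 0/1 mutation incidence matrix.

    Attributes
    ----------
    values : (m, n) uint8 array over {0, 1}
    gene_ids : m unique gene symbols; row order defines the canonical
        1-based gene index.
    sample_ids : n unique sample barcodes.
    """

    values: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2:
            raise ValueError("matrix must be 2-dimensional")
        m, n = self.values.shape
        if m < 1 or n < 1:
            raise ValueError("matrix must have at least one gene and one sample")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("matrix entries must be 0 or 1")
        self.gene_ids = list(self.gene_ids) or [f"G{i + 1}" for i in range(m)]
        self.sample_ids = list(self.sample_ids) or [f"S{j + 1}" for j in range(n)]
        if len(self.gene_ids) != m:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {m} rows")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} columns")
        if len(set(self.gene_ids)) != m:
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")

    @property
    def m(self) -> int:
        """Number of genes (rows)."""
        return self.values.shape[0]

    @property
    def n(self) -> int:
        """Number of samples (columns)."""
        return self.values.shape[1]

    def select_samples(self, column_idx: np.ndarray) -> "BinaryMutationMatrix":
        """Column-sliced copy keeping the full gene space (0-based columns)."""
        column_idx = np.asarray(column_idx)
        return BinaryMutationMatrix(
            values=self.values[:, column_idx],
            gene_ids=self.gene_ids,
            sample_ids=[self.sample_ids[j] for j in column_idx],
        )


@dataclass
class CohortLabels:
    """Integer cancer-type labels 1..n_cancer aligned to a matrix's samples."""

    labels: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        k = len(self.class_names)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        if k < 1:
            raise ValueError("need at least one class")
        if self.labels.min(initial=1) < 1 or self.labels.max(initial=1) > k:
            raise ValueError(f"labels must lie in 1..{k}")

    @property
    def n_cancer(self) -> int:
        return len(self.class_names)

    def select(self, idx: np.ndarray) -> "CohortLabels":
        return CohortLabels(self.labels[np.asarray(idx)], list(self.class_names))

    @classmethod
    def from_names(cls, names: list[str]) -> "CohortLabels":
        """Encode raw per-sample class names as integers 1..K.

        Classes are numbered in first-appearance order, which keeps the
        encoding deterministic for a fixed sample order.
        """
        seen: dict[str, int] = {}
        labels = []
        for name in names:
            if name not in seen:
                seen[name] = len(seen) + 1
            labels.append(seen[name])
        return cls(np.array(labels), list(seen))


def read_maf_to_matrix(
    maf_path,
    gene_column: str = "Hugo_Symbol",
    sample_column: str = "Tumor_Sample_Barcode",
    class_column: str = "Variant_Classification",
    class_filter: set[str] | None = None,
) -> BinaryMutationMatrix:
    """Binarize a MAF-like tab-separated mutation file.

    Entry (g, s) of the result is 1 iff at least one retained record maps
    gene ``g`` to sample ``s``; repeated calls for the same pair collapse
    to a single 1.  Genes are sorted lexicographically, samples kept in
    first-appearance order.

    Parameters
    ----------
    class_filter : optional set of variant classifications to RETAIN.
        ``None`` keeps every record (silent mutations included — the
        totals of typical cohort summaries count them); pass an explicit
        set to restrict, e.g. all non-silent classes.
    """
    try:
        df = pd.read_csv(maf_path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{maf_path}: no records") from None
    for col in (gene_column, sample_column):
        if col not in df.columns:
            raise FormatError(f"{maf_path}: missing required column {col!r}")
    if class_filter is not None:
        if class_column not in df.columns:
            raise FormatError(f"{maf_path}: missing required column {class_column!r}")
        df = df[df[class_column].isin(class_filter)]
    genes = df[gene_column]
    blank = genes.isna() | genes.str.strip().str.lower().isin(_BLANK_GENE_SYMBOLS)
    if blank.any():
        logger.info("dropping %d records with blank/unknown gene symbol", int(blank.sum()))
        df = df[~blank]
    if df.empty:
        raise EmptyInputError(f"{maf_path}: no records left after filtering")

    sample_ids = list(dict.fromkeys(df[sample_column]))  # first appearance
    gene_ids = sorted(set(df[gene_column]))
    g_index = {g: i for i, g in enumerate(gene_ids)}
    s_index = {s: j for j, s in enumerate(sample_ids)}
    values = np.zeros((len(gene_ids), len(sample_ids)), dtype=np.uint8)
    values[
        df[gene_column].map(g_index).to_numpy(),
        df[sample_column].map(s_index).to_numpy(),
    ] = 1
    return BinaryMutationMatrix(values, gene_ids, sample_ids)


def write_matrix_tsv(matrix: BinaryMutationMatrix, path) -> None:
    """Dense TSV: header row of sample ids, first column ``gene_id``."""
    pd.DataFrame(
        matrix.values, index=pd.Index(matrix.gene_ids, name="gene_id"),
        columns=matrix.sample_ids,
    ).to_csv(path, sep="\t")


def read_matrix_tsv(path) -> BinaryMutationMatrix:
    """Inverse of :func:`write_matrix_tsv`; ``read ∘ write`` is the identity."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    bad = np.argwhere(~np.isin(values, (0, 1)))
    if bad.size:
        i, j = bad[0]
        raise FormatError(
            f"{path}: non-binary value {values[i, j]!r} at gene "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return BinaryMutationMatrix(values, list(df.index.astype(str)), list(df.columns.astype(str)))


def write_matrix_mtx(matrix: BinaryMutationMatrix, path) -> None:
    """Sparse MatrixMarket alternative; ids go to ``<path>.genes.txt`` /
    ``<path>.samples.txt`` sidecars."""
    path = str(path)
    scipy.io.mmwrite(path, scipy.sparse.coo_matrix(matrix.values))
    _write_lines(path + ".genes.txt", matrix.gene_ids)
    _write_lines(path + ".samples.txt", matrix.sample_ids)


def read_matrix_mtx(path) -> BinaryMutationMatrix:
    path = str(path)
    values = np.asarray(scipy.io.mmread(path).todense())
    if not np.isin(values, (0, 1)).all():
        raise FormatError(f"{path}: matrix is not binary")
    return BinaryMutationMatrix(
        values, _read_lines(path + ".genes.txt"), _read_lines(path + ".samples.txt")
    )


def write_labels_tsv(labels: CohortLabels, sample_ids: list[str], path) -> None:
    pd.DataFrame(
        {"sample_id": sample_ids,
         "label": [labels.class_names[v - 1] for v in labels.labels]}
    ).to_csv(path, sep="\t", index=False)


def read_labels(path, matrix: BinaryMutationMatrix) -> CohortLabels:
    """Read a two-column TSV (sample_id, class) aligned to ``matrix``.

    Class names (strings or integers alike) are encoded 1..K in
    first-appearance order along the matrix's sample order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (sample_id, label)")
    if "sample_id" not in df.columns:  # headerless file: first row was data
        df = pd.read_csv(path, sep="\t", dtype=str, header=None,
                         names=["sample_id", "label"])
    mapping = dict(zip(df["sample_id"], df[df.columns[1]]))
    missing = [s for s in matrix.sample_ids if s not in mapping]
    if missing:
        raise FormatError(f"{path}: no label for sample(s) {', '.join(missing)}")
    return CohortLabels.from_names([mapping[s] for s in matrix.sample_ids])


def _write_lines(path, lines) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _read_lines(path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]
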
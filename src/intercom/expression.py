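"""Count-matrix loading and per-population expression summaries.

The matrix is held cells x genes in CSR form.  Every downstream stage consumes
either a :class:`PopulationProfile` (per-gene summaries) or a per-population
submatrix, both produced here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: populations smaller than this are analysed but flagged
DEFAULT_MIN_CELLS = 20

#: a value >= 1 counts as "expressed" (the rule is defined on raw counts and
#: applied literally to whatever values are supplied)
EXPRESSION_THRESHOLD = 1.0


@dataclass
class ExpressionMatrix:
    """Cells x genes non-negative count matrix with unique string ids."""

    counts: sp.csr_matrix
    cell_ids: list[str]
    gene_ids: list[str]
    _gene_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise FormatError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("count matrix contains negative entries")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if not self.cell_ids or not self.gene_ids:
            raise ValidationError("matrix must have at least 1 cell and 1 gene")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, gene: str) -> int:
        return self._gene_index[gene]

    def has_gene(self, gene: str) -> bool:
        return gene in self._gene_index

    def gene_counts(self, gene: str) -> np.ndarray:
        """Dense count vector for one gene across all cells."""
        return np.asarray(self.counts[:, self._gene_index[gene]].todense()).ravel()

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        ids = [c for c, keep in zip(self.cell_ids, mask) if keep]
        return ExpressionMatrix(self.counts[mask], ids, list(self.gene_ids))

    def looks_normalized(self) -> bool:
        """Heuristic: any non-integer entry suggests normalized data."""
        if self.counts.nnz == 0:
            return False
        data = self.counts.data
        return bool(np.any(data != np.round(data)))


@dataclass
class PopulationAnnotation:
    """cell id -> population label; validated against a matrix on use."""

    labels: dict[str, str]

    def populations(self) -> list[str]:
        seen: list[str] = []
        for lab in self.labels.values():
            if lab not in seen:
                seen.append(lab)
        return seen


@dataclass
class PopulationProfile:
    """Per-gene summaries for one population.

    ``binary_state`` follows the expression binarization rule at population
    level: +1 when at least one cell has a count >= 1, else -1.
    """

    population: str
    n_cells: int
    gene_ids: list[str]
    n_expressing: np.ndarray
    expressed_fraction: np.ndarray
    mean_expressing: np.ndarray
    binary_state: np.ndarray
    _gene_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    def fraction(self, gene: str, default: float = 0.0) -> float:
        i = self._gene_index.get(gene)
        return float(self.expressed_fraction[i]) if i is not None else default

    def mean(self, gene: str, default: float = 0.0) -> float:
        i = self._gene_index.get(gene)
        return float(self.mean_expressing[i]) if i is not None else default

    def state(self, gene: str, default: int = -1) -> int:
        i = self._gene_index.get(gene)
        return int(self.binary_state[i]) if i is not None else default

    def has_gene(self, gene: str) -> bool:
        return gene in self._gene_index


def binarize(values) -> np.ndarray:
    """Map expression values to {+1, -1}: >= 1 count becomes +1, else -1."""
    values = np.asarray(values)
    if values.size and values.min() < 0:
        raise ValidationError("negative expression values cannot be binarized")
    return np.where(values >= EXPRESSION_THRESHOLD, 1, -1).astype(np.int8)


def _read_name_file(path) -> list[str]:
    """One identifier per line; multi-column files (10x-style features with
    id<TAB>symbol) yield the second column."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    col = 1 if df.shape[1] > 1 else 0
    return [str(v).strip() for v in df.iloc[:, col]]


def load_counts(matrix_path, cells_path=None, genes_path=None, fmt="auto") -> ExpressionMatrix:
    """Load an expression matrix.

    ``fmt='mtx'`` reads a MatrixMarket triplet (matrix + barcodes + features);
    MTX input is assumed genes x cells, as in common single-cell exports, and
    transposed on load.  ``fmt='dense'`` reads a single CSV/TSV with cells as
    rows and a header of gene names; the first column holds cell ids.
    """
    matrix_path = str(matrix_path)
    if fmt == "auto":
        fmt = "mtx" if matrix_path.endswith((".mtx", ".mtx.gz")) else "dense"

    if fmt == "mtx":
        if cells_path is None or genes_path is None:
            raise FormatError("MTX input requires barcode and feature name files")
        try:
            mat = scipy.io.mmread(matrix_path)
        except Exception as exc:
            raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
        genes = _read_name_file(genes_path)
        cells = _read_name_file(cells_path)
        if mat.shape != (len(genes), len(cells)):
            raise FormatError(
                f"MTX shape {mat.shape} does not match {len(genes)} features "
                f"x {len(cells)} barcodes"
            )
        return ExpressionMatrix(sp.csr_matrix(mat.T), cells, genes)

    sep = "\t" if matrix_path.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(matrix_path, sep=sep, index_col=0)
    return ExpressionMatrix(
        sp.csr_matrix(df.to_numpy(dtype=float)),
        [str(c) for c in df.index],
        [str(g) for g in df.columns],
    )


def split_populations(
    matrix: ExpressionMatrix,
    annotation: PopulationAnnotation,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> dict[str, ExpressionMatrix]:
    """Partition cells by population label; unannotated cells are dropped."""
    unknown = set(annotation.labels) - set(matrix.cell_ids)
    if unknown:
        raise ValidationError(
            f"{len(unknown)} annotated cell(s) missing from the matrix, "
            f"e.g. {sorted(unknown)[:3]}"
        )
    unannotated = [c for c in matrix.cell_ids if c not in annotation.labels]
    if unannotated:
        logger.warning("dropping %d unannotated cell(s)", len(unannotated))
    out: dict[str, ExpressionMatrix] = {}
    cell_arr = np.array(matrix.cell_ids)
    for pop in annotation.populations():
        members = {c for c, lab in annotation.labels.items() if lab == pop}
        mask = np.fromiter((c in members for c in cell_arr), bool, matrix.n_cells)
        n = int(mask.sum())
        if n == 0:
            logger.warning("population %r has no cells after split; excluded", pop)
            continue
        if n < min_cells:
            logger.warning("population %r has only %d cells (< %d)", pop, n, min_cells)
        out[pop] = matrix.subset_cells(mask)
    if not out:
        raise ValidationError("no non-empty populations after split")
    return out


def profile_population(
    matrix: ExpressionMatrix,
    annotation: PopulationAnnotation,
    population: str,
) -> PopulationProfile:
    """Compute per-gene summaries over the cells of one population."""
    members = {c for c, lab in annotation.labels.items() if lab == population}
    if not members:
        raise KeyError(f"unknown population {population!r}")
    mask = np.fromiter((c in members for c in matrix.cell_ids), bool, matrix.n_cells)
    return profile_matrix(matrix.subset_cells(mask), population)


def profile_matrix(sub: ExpressionMatrix, population: str) -> PopulationProfile:
    """Profile a matrix already subset to one population's cells."""
    counts = sub.counts
    expressed = counts >= EXPRESSION_THRESHOLD
    n_expressing = np.asarray(expressed.sum(axis=0)).ravel().astype(int)
    total_expressed = np.asarray(counts.multiply(expressed).sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_expressing = np.where(n_expressing > 0, total_expressed / np.maximum(n_expressing, 1), 0.0)
    fraction = n_expressing / sub.n_cells
    state = np.where(n_expressing >= 1, 1, -1).astype(np.int8)
    return PopulationProfile(
        population=population,
        n_cells=sub.n_cells,
        gene_ids=list(sub.gene_ids),
        n_expressing=n_expressing,
        expressed_fraction=fraction,
        mean_expressing=mean_expressing,
        binary_state=state,
    )


def joint_expression_fraction(
    sub: ExpressionMatrix,
    required: list[str],
    any_of: list[str] | None = None,
) -> float:
    """Fraction of cells expressing every gene in ``required`` and, when
    ``any_of`` is given and non-empty, at least one gene from it.

    Genes absent from the matrix count as never expressed.
    """
    ok = np.ones(sub.n_cells, dtype=bool)
    for gene in required:
        if not sub.has_gene(gene):
            return 0.0
        ok &= sub.gene_counts(gene) >= EXPRESSION_THRESHOLD
    if any_of is not None:
        if not any_of:
            return 0.0
        any_mask = np.zeros(sub.n_cells, dtype=bool)
        for gene in any_of:
            if sub.has_gene(gene):
                any_mask |= sub.gene_counts(gene) >= EXPRESSION_THRESHOLD
        ok &= any_mask
    return float(ok.mean())
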
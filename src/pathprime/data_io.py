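"""Expression matrices, labels, gene-set collections and the prior mask.

The central object tying everything together is the :class:`PriorMask`: a
binary genes × nodes incidence matrix derived from a gene-set collection
(e.g. KEGG signaling pathways in GMT format). A first-hidden-layer weight
may be nonzero only where the mask is 1, so each hidden node aggregates
exactly the genes of one biological unit.

Gene identifiers are matched by exact string equality after stripping
surrounding whitespace; no symbol aliasing is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import mmread


class DataFormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A cells × genes numeric matrix with ordered cell and gene identifiers."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g).strip() for g in self.gene_ids]
        self.cell_ids = [str(c).strip() for c in self.cell_ids]
        if self.values.ndim != 2:
            raise DataFormatError("expression values must be a 2-D matrix")
        n_cells, n_genes = self.values.shape
        if n_cells != len(self.cell_ids):
            raise DataFormatError(
                f"matrix has {n_cells} rows but {len(self.cell_ids)} cell ids"
            )
        if n_genes != len(self.gene_ids):
            raise DataFormatError(
                f"matrix has {n_genes} columns but {len(self.gene_ids)} gene ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise DataFormatError(f"duplicate gene ids: {dupes[:5]}")
        if np.isnan(self.values).any():
            raise DataFormatError("expression matrix contains missing values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        """Return a copy restricted to ``genes`` in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not present in matrix: {missing[:5]}")
        cols = [index[g] for g in genes]
        return ExpressionMatrix(self.values[:, cols], list(genes), list(self.cell_ids))


@dataclass
class LabelVector:
    """Cell-type labels aligned to the rows of an :class:`ExpressionMatrix`."""

    labels: list[str]
    classes: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = [str(v).strip() for v in self.labels]
        if self.classes is None:
            self.classes = sorted(set(self.labels))
        unknown = set(self.labels) - set(self.classes)
        if unknown:
            raise ValueError(f"labels outside declared classes: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)

    def indices(self) -> np.ndarray:
        """Integer class codes following the ``classes`` ordering."""
        lut = {c: i for i, c in enumerate(self.classes)}
        return np.array([lut[v] for v in self.labels], dtype=int)

    def subset(self, rows: np.ndarray) -> "LabelVector":
        arr = self.as_array()[rows]
        return LabelVector(list(arr), classes=list(self.classes))


@dataclass
class GeneSetCollection:
    """An ordered list of named gene sets (pathways, PPI clusters, modules)."""

    sets: list[tuple[str, str, frozenset[str]]]

    def __post_init__(self) -> None:
        names = [name for name, _, _ in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise DataFormatError(f"duplicate gene-set names: {dupes}")
        for name, _, members in self.sets:
            if not members:
                raise DataFormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.sets]

    def members(self, name: str) -> frozenset[str]:
        for set_name, _, genes in self.sets:
            if set_name == name:
                return genes
        raise KeyError(name)

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for _, _, genes in self.sets:
            out |= genes
        return out


@dataclass
class PriorMask:
    """Binary genes × nodes incidence matrix constraining first-layer weights."""

    matrix: np.ndarray
    gene_ids: list[str]
    node_names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("mask entries must be 0 or 1")
        self.matrix = self.matrix.astype(float)
        if self.matrix.shape != (len(self.gene_ids), len(self.node_names)):
            raise ValueError("mask shape inconsistent with gene/node lists")
        empty = np.flatnonzero(self.matrix.sum(axis=0) == 0)
        if empty.size:
            bad = [self.node_names[j] for j in empty]
            raise ValueError(f"mask nodes with no member genes: {bad}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one tab-separated gene set per line.

    Fields are ``name<TAB>description<TAB>gene1<TAB>gene2...``. Duplicate
    member genes within a line are collapsed; duplicate set names are an
    error.
    """
    sets: list[tuple[str, str, frozenset[str]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataFormatError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected >= 3 "
                    "(name, description, genes...)"
                )
            name, description = fields[0].strip(), fields[1].strip()
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                raise DataFormatError(f"{path}: line {lineno} ({name!r}) has no genes")
            sets.append((name, description, genes))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write a collection back to GMT (members sorted for stable output)."""
    with open(path, "w") as fh:
        for name, description, genes in collection.sets:
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def read_expression(
    path,
    format: str = "dense_tsv",
    *,
    genes_path=None,
    cells_path=None,
    transpose: bool = False,
    sep: str = "\t",
) -> ExpressionMatrix:
    """Load an expression matrix as cells × genes.

    ``dense_tsv``: delimited text with a header row of gene ids and a first
    column of cell ids. ``mtx_triplet``: MatrixMarket coordinate format with
    1-based indices, plus one-id-per-line sidecar files for genes (rows) and
    cells (columns are cells unless ``transpose``).

    Set ``transpose=True`` when the source is stored genes × cells.
    """
    if format == "dense_tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        stripped = [h.strip() for h in header]
        if len(set(stripped)) != len(stripped):
            dupes = sorted({h for h in stripped if stripped.count(h) > 1})
            raise DataFormatError(f"duplicate gene ids in header: {dupes[:5]}")
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy(dtype=float)
        gene_ids = [str(c) for c in df.columns]
        cell_ids = [str(i) for i in df.index]
    elif format == "mtx_triplet":
        if genes_path is None or cells_path is None:
            raise DataFormatError("mtx_triplet requires genes_path and cells_path")
        values = np.asarray(mmread(path).todense(), dtype=float)
        gene_ids = _read_id_list(genes_path)
        cell_ids = _read_id_list(cells_path)
        # rows of the triplet file are cells unless told otherwise
        if not transpose:
            if values.shape != (len(cell_ids), len(gene_ids)):
                raise DataFormatError(
                    f"mtx shape {values.shape} does not match "
                    f"{len(cell_ids)} cells x {len(gene_ids)} genes"
                )
            return ExpressionMatrix(values, gene_ids, cell_ids)
        values = values.T
        if values.shape != (len(cell_ids), len(gene_ids)):
            raise DataFormatError(
                f"transposed mtx shape {values.shape} does not match "
                f"{len(cell_ids)} cells x {len(gene_ids)} genes"
            )
        return ExpressionMatrix(values, gene_ids, cell_ids)
    else:
        raise ValueError(f"unknown expression format: {format!r}")

    if transpose:
        values = values.T
        gene_ids, cell_ids = cell_ids, gene_ids
    if values.shape != (len(cell_ids), len(gene_ids)):
        raise DataFormatError("matrix dimensions do not match id lists")
    return ExpressionMatrix(values, gene_ids, cell_ids)


def _read_id_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_labels(path, cell_ids: list[str] | None = None) -> LabelVector:
    """Read a two-column TSV of (cell id, cell type).

    When ``cell_ids`` is given the labels are reordered to match it and every
    cell must be present.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["cell", "label"], dtype=str)
    if cell_ids is not None:
        lut = dict(zip(df["cell"].str.strip(), df["label"]))
        missing = [c for c in cell_ids if c not in lut]
        if missing:
            raise DataFormatError(f"labels missing for cells: {missing[:5]}")
        return LabelVector([lut[c] for c in cell_ids])
    return LabelVector(list(df["label"]))


def write_labels(labels: LabelVector, cell_ids: list[str], path) -> None:
    with open(path, "w") as fh:
        for cell, label in zip(cell_ids, labels.labels):
            fh.write(f"{cell}\t{label}\n")


def write_expression(expr: ExpressionMatrix, path, sep: str = "\t") -> None:
    df = pd.DataFrame(expr.values, index=expr.cell_ids, columns=expr.gene_ids)
    df.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# gene-space handling
# ---------------------------------------------------------------------------


def intersect_gene_space(
    expr: ExpressionMatrix,
    collection: GeneSetCollection,
    mode: str = "biological_only",
) -> tuple[ExpressionMatrix, GeneSetCollection]:
    """Reconcile a measured gene space with a gene-set collection.

    ``biological_only`` keeps only measured genes that belong to at least one
    set (the reduced input space of a pure pathway-primed network);
    ``full`` keeps every measured gene and merely restricts the sets to the
    measured space (needed for hybrid architectures whose dense nodes see all
    genes). Sets left with no measured member are dropped with a warning.
    """
    if mode not in ("biological_only", "full"):
        raise ValueError(f"unknown mode {mode!r}")
    measured = set(expr.gene_ids)
    if mode == "biological_only":
        covered = collection.all_genes() & measured
        if not covered:
            raise ValueError("no measured gene belongs to any gene set")
        kept_genes = [g for g in expr.gene_ids if g in covered]
        expr_out = expr.subset_genes(kept_genes)
        keep = set(kept_genes)
    else:
        expr_out = expr
        keep = measured

    new_sets = []
    for name, description, genes in collection.sets:
        restricted = frozenset(genes & keep)
        if restricted:
            new_sets.append((name, description, restricted))
        else:
            warnings.warn(
                f"gene set {name!r} has no measured member gene; dropped",
                stacklevel=2,
            )
    if not new_sets:
        raise ValueError("no gene set survives intersection with the measured genes")
    return expr_out, GeneSetCollection(new_sets)


def build_mask(gene_ids: list[str], collection: GeneSetCollection) -> PriorMask:
    """Build the binary genes × nodes mask: 1 iff gene i belongs to set j."""
    gene_ids = [str(g).strip() for g in gene_ids]
    index = {g: i for i, g in enumerate(gene_ids)}
    matrix = np.zeros((len(gene_ids), len(collection)), dtype=float)
    for j, (name, _, genes) in enumerate(collection.sets):
        rows = [index[g] for g in genes if g in index]
        if not rows:
            raise ValueError(
                f"gene set {name!r} covers no input gene; intersect the gene "
                "space before building the mask"
            )
        matrix[rows, j] = 1.0
    return PriorMask(matrix, gene_ids, list(collection.names))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def preprocess(
    expr: ExpressionMatrix,
    method: str = "zscore",
    fit_stats: dict | None = None,
) -> tuple[ExpressionMatrix, dict]:
    """Transform expression values, optionally reusing training statistics.

    Methods
    -------
    ``log1p``
        Elementwise log(1 + x); rejects negative input. Stateless.
    ``zscore``
        Per-gene standardisation (x − mean) / sd; genes with zero training
        standard deviation map to 0. The normalisation used before training.
    ``minmax_sym``
        Per-gene affine map of the training range onto [−1, 1]; out-of-range
        test values are clipped. Constant genes map to 0.
    ``none``
        Identity.

    On a test split, pass the ``fit_stats`` returned from the training split
    so that no test information leaks into the transform.
    """
    x = expr.values
    if method == "none":
        return expr, {"method": "none"}
    if method == "log1p":
        if (x < 0).any():
            raise ValueError("log1p preprocessing requires non-negative input")
        out = np.log1p(x)
        stats = {"method": "log1p"}
    elif method == "zscore":
        if fit_stats is None:
            mean = x.mean(axis=0)
            sd = x.std(axis=0, ddof=0)
            stats = {"method": "zscore", "mean": mean, "sd": sd}
        else:
            _check_stats(fit_stats, "zscore", expr.n_genes)
            mean, sd = fit_stats["mean"], fit_stats["sd"]
            stats = fit_stats
        safe_sd = np.where(sd == 0, 1.0, sd)
        out = (x - mean) / safe_sd
        out[:, sd == 0] = 0.0
    elif method == "minmax_sym":
        if fit_stats is None:
            lo = x.min(axis=0)
            hi = x.max(axis=0)
            stats = {"method": "minmax_sym", "min": lo, "max": hi}
        else:
            _check_stats(fit_stats, "minmax_sym", expr.n_genes)
            lo, hi = fit_stats["min"], fit_stats["max"]
            stats = fit_stats
        span = hi - lo
        safe_span = np.where(span == 0, 1.0, span)
        out = 2.0 * (x - lo) / safe_span - 1.0
        out[:, span == 0] = 0.0
        out = np.clip(out, -1.0, 1.0)
    else:
        raise ValueError(f"unknown preprocessing method {method!r}")
    return ExpressionMatrix(out, list(expr.gene_ids), list(expr.cell_ids)), stats


def _check_stats(stats: dict, method: str, n_genes: int) -> None:
    if stats.get("method") != method:
        raise ValueError(
            f"fit_stats were computed for {stats.get('method')!r}, not {method!r}"
        )
    for key, value in stats.items():
        if key != "method" and len(np.atleast_1d(value)) != n_genes:
            raise ValueError("fit_stats dimension does not match gene count")
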
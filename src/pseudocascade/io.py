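"""Input and output: expression matrices, cell orderings, sample assignments,
gene-set annotations, marker lists, and the cascade results table.

Identifiers are case-sensitive exact strings throughout; no symbol aliasing.
All externally visible indices ("the i-th cell") are 1-based.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "CellOrdering",
    "SampleAssignment",
    "TermAnnotation",
    "read_expression_matrix",
    "read_cell_ordering",
    "read_sample_assignment",
    "align_matrix_to_ordering",
    "read_annotation",
    "read_marker_list",
    "write_results_table",
    "read_results_table",
]


def _check_unique(ids, kind: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen[x] = 1
    if dups:
        raise ValueError(f"duplicate {kind} identifiers: {sorted(set(dups))}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x cells matrix of normalized expression with identifiers."""

    gene_ids: tuple[str, ...]
    cell_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "cell_ids", tuple(str(c) for c in self.cell_ids))
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"values shape {v.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if not np.all(np.isfinite(v)):
            i, j = np.argwhere(~np.isfinite(v))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"cell {self.cell_ids[j]!r}"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)), df.to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.cell_ids))


@dataclass(frozen=True)
class CellOrdering:
    """Ordered cell identifiers with strictly increasing pseudotime values.

    When only an ordering is given, the i-th cell receives pseudotime i
    (1-based), the default convention for rank pseudotime.
    """

    cell_ids: tuple[str, ...]
    pseudotime: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "cell_ids", tuple(str(c) for c in self.cell_ids))
        t = np.asarray(self.pseudotime, dtype=float)
        object.__setattr__(self, "pseudotime", t)
        if t.size != len(self.cell_ids):
            raise ValueError("pseudotime length does not match number of cells")
        _check_unique(self.cell_ids, "cell")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("pseudotime must be strictly increasing (ties not allowed)")

    @classmethod
    def from_ranks(cls, cell_ids) -> "CellOrdering":
        ids = tuple(cell_ids)
        return cls(ids, np.arange(1, len(ids) + 1, dtype=float))

    def __len__(self) -> int:
        return len(self.cell_ids)


@dataclass(frozen=True)
class SampleAssignment:
    """Mapping from cell identifier to sample label."""

    mapping: dict

    @property
    def samples(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def cells_of(self, sample: str) -> list[str]:
        return [c for c, s in self.mapping.items() if s == sample]

    def validate_against(self, ordering: CellOrdering, min_cells: int = 10) -> None:
        missing = [c for c in ordering.cell_ids if c not in self.mapping]
        if missing:
            raise ValueError(f"cells without a sample label: {missing[:5]}")
        counts: dict[str, int] = {}
        for c in ordering.cell_ids:
            s = self.mapping[c]
            counts[s] = counts.get(s, 0) + 1
        small = {s: n for s, n in counts.items() if n < min_cells}
        if small:
            raise ValueError(f"samples with fewer than {min_cells} cells: {small}")


@dataclass(frozen=True)
class TermAnnotation:
    """Flat gene-set annotation: term id -> (name, member genes)."""

    terms: dict

    @property
    def universe(self) -> frozenset:
        out: set[str] = set()
        for _, members in self.terms.values():
            out |= set(members)
        return frozenset(out)

    def members(self, term_id: str) -> frozenset:
        return frozenset(self.terms[term_id][1])

    def name(self, term_id: str) -> str:
        return self.terms[term_id][0]


def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "mtx_dir"
    suffix = path.suffix.lower()
    return {".csv": "csv", ".tsv": "tsv", ".txt": "tsv", ".h5ad": "h5", ".h5": "h5"}.get(
        suffix, "csv"
    )


def read_expression_matrix(path, format: str | None = None) -> ExpressionMatrix:
    """Read a genes x cells matrix from an MTX triplet directory, a dense
    CSV/TSV (first column gene IDs, header cell IDs), or an h5ad container.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression matrix not found: {path}")
    fmt = format or _infer_format(path)
    if fmt == "mtx_dir":
        return _read_mtx_dir(path)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        num = df.apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere(num.isna().to_numpy())
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"non-numeric entry at row {df.index[i]!r}, column {df.columns[j]!r} "
                f"of {path}"
            )
        return ExpressionMatrix.from_dataframe(num)
    if fmt == "h5":
        return _read_h5(path)
    raise ValueError(f"unknown expression matrix format: {fmt}")


def _read_mtx_dir(path: Path) -> ExpressionMatrix:
    def find(*names):
        for n in names:
            p = path / n
            if p.exists():
                return p
        raise FileNotFoundError(f"missing {names[0]} in MTX directory {path}")

    mtx = find("matrix.mtx")
    features = find("features.tsv", "genes.tsv")
    barcodes = find("barcodes.tsv")
    values = np.asarray(mmread(mtx).todense(), dtype=float)
    genes = pd.read_csv(features, sep="\t", header=None)[0].astype(str).tolist()
    cells = pd.read_csv(barcodes, sep="\t", header=None)[0].astype(str).tolist()
    return ExpressionMatrix(tuple(genes), tuple(cells), values)


def _read_h5(path: Path) -> ExpressionMatrix:
    import anndata as ad

    adata = ad.read_h5ad(path)
    X = adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    # AnnData stores cells x genes; our container is genes x cells
    return ExpressionMatrix(
        tuple(map(str, adata.var_names)), tuple(map(str, adata.obs_names)), np.asarray(X).T
    )


def read_cell_ordering(path) -> CellOrdering:
    """Read a cell ordering: one cell ID per line (pseudotime 1..N in file
    order) or two tab-separated columns ``cell_id<TAB>pseudotime`` (sorted by
    pseudotime ascending; ties are an error)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ordering file not found: {path}")
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"ordering file is empty: {path}")
    if "\t" in lines[0]:
        ids, times = [], []
        for k, ln in enumerate(lines, start=1):
            parts = ln.split("\t")
            if len(parts) != 2:
                raise ValueError(f"line {k} of {path}: expected 2 tab-separated columns")
            try:
                times.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"line {k} of {path}: non-numeric pseudotime") from exc
            ids.append(parts[0])
        _check_unique(ids, "cell")
        order = np.argsort(times, kind="stable")
        ids = [ids[i] for i in order]
        times = [times[i] for i in order]
        return CellOrdering(tuple(ids), np.asarray(times))
    _check_unique(lines, "cell")
    return CellOrdering.from_ranks(lines)


def read_sample_assignment(path) -> SampleAssignment:
    """Read a two-column TSV ``cell_id<TAB>sample_label``."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell", "sample"], dtype=str)
    _check_unique(df["cell"].tolist(), "cell")
    return SampleAssignment(dict(zip(df["cell"], df["sample"])))


def align_matrix_to_ordering(m: ExpressionMatrix, o: CellOrdering) -> ExpressionMatrix:
    """Reorder matrix columns to the ordering; matrix cells absent from the
    ordering are dropped (with a logged count)."""
    pos = {c: i for i, c in enumerate(m.cell_ids)}
    missing = [c for c in o.cell_ids if c not in pos]
    if missing:
        raise ValueError(f"ordering references cells absent from the matrix: {missing[:5]}")
    idx = [pos[c] for c in o.cell_ids]
    dropped = len(m.cell_ids) - len(idx)
    if dropped:
        logger.info("dropped %d matrix cells absent from the ordering", dropped)
    return ExpressionMatrix(m.gene_ids, tuple(o.cell_ids), m.values[:, idx])


def read_annotation(path, format: str | None = None) -> TermAnnotation:
    """Read a flat gene-set annotation from GMT or a two-column gene/term TSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    if format is None:
        format = "gmt" if path.suffix.lower() == ".gmt" else "two_column_tsv"
    terms: dict[str, tuple[str, frozenset]] = {}
    if format == "gmt":
        for k, ln in enumerate(path.read_text().splitlines(), start=1):
            if not ln.strip():
                continue
            parts = ln.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed GMT line {k} in {path}")
            term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                warnings.warn(f"GMT term {term!r} has no member genes; skipped")
                continue
            if term in terms:
                raise ValueError(f"duplicate term id {term!r} at line {k}")
            terms[term] = (desc, frozenset(genes))
    elif format == "two_column_tsv":
        df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], dtype=str)
        if df.isna().any().any():
            raise ValueError(f"malformed two-column annotation in {path}")
        for term, grp in df.groupby("term", sort=True):
            terms[str(term)] = (str(term), frozenset(grp["gene"]))
    else:
        raise ValueError(f"unknown annotation format: {format}")
    return TermAnnotation(terms)


def read_marker_list(path) -> list[str]:
    """One gene per line."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


_RESULT_COLUMNS = [
    "gene",
    "pattern",
    "n_switch_points",
    "first_switch_index",
    "first_switch_fraction",
    "pvalue",
    "qvalue",
    "cascade_rank",
]


def write_results_table(cascade, fits, path) -> None:
    """Write the per-gene cascade table as TSV, one row per gene in cascade
    order.  ``cascade`` is a CascadeResult; ``fits`` maps gene -> GeneFit."""
    rows = []
    for gene in cascade.genes:
        sw = cascade.switches[gene]
        pat = cascade.patterns[gene]
        fit = fits[gene]
        first_idx = sw.indices[0] if sw.indices else ""
        first_frac = f"{sw.fractions[0]:.10g}" if sw.fractions else ""
        rows.append(
            [
                gene,
                pat.label,
                len(sw.fractions),
                first_idx,
                first_frac,
                f"{fit.pvalue:.10g}",
                f"{fit.qvalue:.10g}",
                cascade.ranks[gene],
            ]
        )
    if not rows:
        warnings.warn("no significant genes; writing a header-only results table")
    df = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
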
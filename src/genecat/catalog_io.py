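"""Data model and I/O for gene catalogs.

A catalog is represented as a sparse binary :class:`PresenceMatrix`
(samples are rows, genes are columns — everywhere in this package),
optionally paired with an :class:`AbundanceMatrix` on the same axes and a
:class:`SampleTable` of per-sample ecology metadata.

On-disk formats are plain text: membership / metadata / annotation TSVs and
Matrix Market coordinate files with sidecar ``.rows`` / ``.cols`` index
files (one id per line).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "CatalogError",
    "PresenceMatrix",
    "AbundanceMatrix",
    "SampleTable",
    "CatalogFilter",
    "read_membership",
    "read_sample_table",
    "read_annotations",
    "apply_sample_filter",
    "singleton_counts",
    "write_matrix",
    "read_matrix",
]

METADATA_COLUMNS = [
    "sample_id",
    "ecology",
    "ecology_group",
    "disease_status",
    "westernized",
    "age_category",
]


class CatalogError(ValueError):
    """Raised on malformed catalog inputs or invariant violations."""


def _as_id_array(ids) -> np.ndarray:
    return np.asarray(list(ids), dtype=object)


@dataclass
class PresenceMatrix:
    """Sparse binary samples x genes incidence matrix.

    ``matrix[i, j] == 1`` means gene ``gene_ids[j]`` was assembled in sample
    ``sample_ids[i]``. Invariants: entries are 0/1, sample and gene ids are
    unique, and no column is all-zero (a gene absent from every sample does
    not exist in the catalog).
    """

    matrix: sp.csr_matrix
    sample_ids: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix, dtype=np.int8)
        self.matrix.eliminate_zeros()
        self.sample_ids = _as_id_array(self.sample_ids)
        self.gene_ids = _as_id_array(self.gene_ids)
        self.validate()

    def validate(self) -> None:
        n, g = self.matrix.shape
        if n != len(self.sample_ids) or g != len(self.gene_ids):
            raise CatalogError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.sample_ids)} sample ids / {len(self.gene_ids)} gene ids"
            )
        if len(np.unique(self.sample_ids)) != n:
            raise CatalogError("duplicate sample_ids")
        if len(np.unique(self.gene_ids)) != g:
            raise CatalogError("duplicate gene_ids")
        if self.matrix.nnz and not np.all(self.matrix.data == 1):
            raise CatalogError("presence matrix entries must be 0/1")
        if g and self.matrix.nnz:
            if (self.col_sums() == 0).any():
                raise CatalogError("presence matrix contains an all-zero gene column")
        elif g:
            raise CatalogError("presence matrix contains an all-zero gene column")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    def col_sums(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    def sample_index(self, sample_ids) -> np.ndarray:
        """Positions of the given sample_ids in row order."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise CatalogError(f"unknown sample_id {exc.args[0]!r}") from exc

    def gene_sets(self) -> list[set]:
        """Per-sample sets of gene ids (row supports)."""
        m = self.matrix.tocsr()
        return [
            set(self.gene_ids[m.indices[m.indptr[i] : m.indptr[i + 1]]])
            for i in range(self.n_samples)
        ]

    def subset_samples(self, sample_ids, prune_genes: bool = True) -> "PresenceMatrix":
        """Row-restricted copy; all-zero gene columns pruned by default."""
        idx = self.sample_index(sample_ids)
        sub = self.matrix[idx]
        gene_ids = self.gene_ids
        if prune_genes:
            keep = np.asarray(sub.sum(axis=0)).ravel() > 0
            sub = sub[:, keep]
            gene_ids = gene_ids[keep]
        return PresenceMatrix(sub, self.sample_ids[idx], gene_ids)


@dataclass
class AbundanceMatrix:
    """Nonnegative samples x features abundance matrix.

    Columns may be catalog genes or species labels; integer counts are
    required by the Chao1 estimator, continuous values elsewhere.
    """

    matrix: sp.csr_matrix
    sample_ids: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix, dtype=float)
        self.matrix.eliminate_zeros()
        self.sample_ids = _as_id_array(self.sample_ids)
        self.gene_ids = _as_id_array(self.gene_ids)
        if self.matrix.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise CatalogError("abundance matrix shape does not match ids")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise CatalogError("abundances must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def row(self, i: int) -> np.ndarray:
        return np.asarray(self.matrix[i].todense()).ravel()

    def sample_index(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([lookup[s] for s in sample_ids], dtype=int)


@dataclass
class SampleTable:
    """Per-sample metadata: ecology, ecology group, host facets, gene count."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in METADATA_COLUMNS:
            if col not in df.columns:
                if col in ("sample_id", "ecology", "ecology_group"):
                    raise CatalogError(f"sample table missing required column {col!r}")
                df[col] = pd.NA
        if "n_genes" not in df.columns:
            df["n_genes"] = 0
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise CatalogError(f"duplicate sample_id {dup!r} in sample table")
        eco_groups = df.groupby("ecology")["ecology_group"].nunique()
        bad = eco_groups[eco_groups > 1]
        if len(bad):
            raise CatalogError(
                f"ecology {bad.index[0]!r} maps to more than one ecology_group"
            )
        self.df = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.df["sample_id"].to_numpy(dtype=object)

    @property
    def ecologies(self) -> list:
        return sorted(self.df["ecology"].unique())

    def ecology_of(self) -> pd.Series:
        return self.df.set_index("sample_id")["ecology"]

    def group_of_ecology(self) -> dict:
        return dict(
            self.df.drop_duplicates("ecology")[["ecology", "ecology_group"]].values
        )

    def aligned_to(self, sample_ids) -> "SampleTable":
        """Reorder / subset rows to match the given sample id order."""
        sub = self.df.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleTable(sub)

    def samples_by_ecology(self) -> dict:
        return {
            eco: list(grp["sample_id"]) for eco, grp in self.df.groupby("ecology")
        }


@dataclass(frozen=True)
class CatalogFilter:
    """Sample-level quality filter: drop samples with too few assembled genes."""

    min_genes: int = 100

    def __post_init__(self) -> None:
        if self.min_genes < 1:
            raise CatalogError("min_genes must be >= 1")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_membership(path) -> tuple[PresenceMatrix, AbundanceMatrix | None]:
    """Read a (sample_id, gene_id[, abundance]) membership TSV.

    Duplicate (sample, gene) pairs collapse to presence 1; abundances are
    summed. Rows and columns are ordered lexicographically so the resulting
    matrices are platform-independent.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str}, on_bad_lines="error")
    except pd.errors.ParserError as exc:
        raise CatalogError(f"malformed membership file {path}: {exc}") from exc
    if not {"sample_id", "gene_id"}.issubset(df.columns):
        raise CatalogError(
            f"{path}: membership TSV requires columns sample_id, gene_id"
        )
    if df["sample_id"].isna().any() or df["gene_id"].isna().any():
        bad = int(df[df[["sample_id", "gene_id"]].isna().any(axis=1)].index[0]) + 2
        raise CatalogError(f"{path}: malformed membership line {bad}")
    has_abund = "abundance" in df.columns
    if has_abund:
        abund = pd.to_numeric(df["abundance"], errors="coerce")
        if abund.isna().any():
            bad = int(abund[abund.isna()].index[0]) + 2
            raise CatalogError(f"{path}: non-numeric abundance at line {bad}")
        if (abund < 0).any():
            bad = int(abund[abund < 0].index[0]) + 2
            raise CatalogError(f"{path}: negative abundance at line {bad}")
        df = df.assign(abundance=abund)

    samples = np.array(sorted(df["sample_id"].unique()), dtype=object)
    genes = np.array(sorted(df["gene_id"].unique()), dtype=object)
    si = pd.Categorical(df["sample_id"], categories=samples).codes
    gi = pd.Categorical(df["gene_id"], categories=genes).codes
    shape = (len(samples), len(genes))
    ones = sp.coo_matrix((np.ones(len(df), dtype=np.int8), (si, gi)), shape=shape)
    ones.sum_duplicates()
    ones.data[:] = 1
    pm = PresenceMatrix(ones.tocsr(), samples, genes)
    am = None
    if has_abund:
        vals = sp.coo_matrix((df["abundance"].to_numpy(float), (si, gi)), shape=shape)
        vals.sum_duplicates()
        am = AbundanceMatrix(vals.tocsr(), samples, genes)
    return pm, am


def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "westernized" in df.columns:
        df["westernized"] = df["westernized"].map(
            {"True": True, "False": False, True: True, False: False}
        )
    return SampleTable(df)


def read_annotations(path) -> pd.DataFrame:
    """Gene annotation TSV: gene_id, protein_product, cog_category, taxon_label."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in df.columns:
        raise CatalogError(f"{path}: annotation TSV requires a gene_id column")
    return df


def apply_sample_filter(
    pm: PresenceMatrix, st: SampleTable, f: CatalogFilter = CatalogFilter()
) -> tuple[PresenceMatrix, SampleTable]:
    """Drop samples with fewer than ``f.min_genes`` genes, prune emptied columns.

    The returned SampleTable has ``n_genes`` recomputed from the filtered
    matrix. Filtering is idempotent: column pruning cannot push a surviving
    row below the threshold because row supports are untouched.
    """
    st = st.aligned_to(pm.sample_ids)
    keep = pm.row_sums() >= f.min_genes
    if not keep.any():
        raise CatalogError(
            f"all {pm.n_samples} samples fall below min_genes={f.min_genes}"
        )
    sub = pm.matrix[keep]
    col_keep = np.asarray(sub.sum(axis=0)).ravel() > 0
    out = PresenceMatrix(sub[:, col_keep], pm.sample_ids[keep], pm.gene_ids[col_keep])
    df = st.df.loc[keep].reset_index(drop=True)
    df = df.assign(n_genes=out.row_sums())
    return out, SampleTable(df)


def singleton_counts(pm: PresenceMatrix) -> tuple[int, int, float]:
    """Count singleton genes (column sum exactly 1) and their fraction."""
    if pm.n_genes == 0:
        raise CatalogError("empty presence matrix")
    cs = pm.col_sums()
    n_single = int((cs == 1).sum())
    n_non = int(pm.n_genes - n_single)
    return n_single, n_non, n_single / pm.n_genes


# ---------------------------------------------------------------------------
# Matrix Market round-trip
# ---------------------------------------------------------------------------


def write_matrix(m: PresenceMatrix | AbundanceMatrix, directory, stem: str = "matrix") -> None:
    """Write Matrix Market coordinate file plus .rows/.cols id index files."""
    if isinstance(m, PresenceMatrix):
        m.validate()
    os.makedirs(directory, exist_ok=True)
    base = os.path.join(directory, stem)
    mat = m.matrix.tocoo()
    field_ = "integer" if isinstance(m, PresenceMatrix) else "real"
    if field_ == "integer":
        mat = mat.astype(np.int64)
    mmwrite(base + ".mtx", mat, field=field_)
    for ext, ids in ((".rows", m.sample_ids), (".cols", m.gene_ids)):
        with open(base + ext, "w") as fh:
            fh.writelines(f"{x}\n" for x in ids)


def read_matrix(directory, stem: str = "matrix", kind: str = "presence"):
    """Inverse of :func:`write_matrix`; ``kind`` is 'presence' or 'abundance'."""
    base = os.path.join(directory, stem)
    mat = sp.csr_matrix(mmread(base + ".mtx"))
    with open(base + ".rows") as fh:
        rows = np.array([line.rstrip("\n") for line in fh], dtype=object)
    with open(base + ".cols") as fh:
        cols = np.array([line.rstrip("\n") for line in fh], dtype=object)
    if mat.shape != (len(rows), len(cols)):
        raise CatalogError(
            f"{base}: matrix shape {mat.shape} does not match index files "
            f"({len(rows)} rows, {len(cols)} cols)"
        )
    cls = PresenceMatrix if kind == "presence" else AbundanceMatrix
    return cls(mat, rows, cols)
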
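"""Latent-semantic-indexing sample clustering of the presence matrix.

Pipeline: TF-IDF weighting of the binary samples x genes matrix
(TF = presence / per-sample gene count; IDF = ln((n_samples + 1) / gene
occurrence)), truncated SVD to k factors, UMAP to a 2-D embedding, and
hierarchical density clustering (HDBSCAN, via scikit-learn) with a reserved
noise label. A parameter grid over (k, n_neighbors, min_dist, min cluster
size) is scored by silhouette on the 2-D coordinates of non-noise samples;
the selected cell maximises silhouette subject to a cap on the unclustered
fraction, with deterministic lexicographic tie-breaking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import HDBSCAN
from sklearn.decomposition import TruncatedSVD
from sklearn.metrics import silhouette_score

from genecat.catalog_io import CatalogError, PresenceMatrix, SampleTable

__all__ = [
    "EmbeddingConfig",
    "ClusteringResult",
    "NOISE",
    "tfidf_transform",
    "lsi_embed",
    "embed_2d",
    "density_cluster",
    "select_model",
    "run_lsi_pipeline",
    "subcluster",
]

NOISE = -1  # reserved cluster label for unclustered samples


@dataclass(frozen=True)
class EmbeddingConfig:
    """Grid and selection parameters of the LSI pipeline."""

    k_grid: tuple = (10, 50, 100)
    n_neighbors_grid: tuple = (10, 15, 20, 30)
    min_dist_grid: tuple = (0.1, 0.25, 0.5)
    min_cluster_grid: tuple = (25, 50, 75, 100)
    noise_fraction_max: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k_grid", "n_neighbors_grid", "min_dist_grid", "min_cluster_grid"):
            if not getattr(self, name):
                raise CatalogError(f"{name} must be nonempty")


@dataclass
class ClusteringResult:
    """Chosen grid cell plus per-sample coordinates and labels.

    ``silhouette`` is NaN (undefined sentinel) when the chosen cell has
    fewer than two clusters; it is never reported as 0 in that case.
    """

    sample_ids: np.ndarray
    coords: np.ndarray  # n_samples x 2
    labels: np.ndarray  # cluster ids, NOISE for unclustered
    silhouette: float
    n_unclustered: int
    chosen_params: dict  # k, n_neighbors, min_dist, min_cluster_size
    grid_report: pd.DataFrame

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels[self.labels != NOISE]))

    def to_frame(self, st: SampleTable | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "cluster": self.labels,
            }
        )
        if st is not None:
            meta = st.aligned_to(self.sample_ids).df
            for col in ("ecology", "disease_status", "westernized", "age_category"):
                df[col] = meta[col].to_numpy()
        return df


def tfidf_transform(pm: PresenceMatrix) -> sp.csr_matrix:
    """TF-IDF weighting of the binary presence matrix.

    entry(s, g) = [presence(s, g) / rowsum(s)] * ln((n_samples + 1) / colsum(g)).
    The natural logarithm is used; base only rescales the matrix uniformly.
    Sparsity pattern is preserved.
    """
    rs = pm.row_sums()
    cs = pm.col_sums()
    if (rs == 0).any() or (cs == 0).any():
        raise CatalogError("TF-IDF requires no all-zero rows or columns")
    tf = sp.diags(1.0 / rs) @ pm.matrix.astype(float)
    idf = np.log((pm.n_samples + 1.0) / cs)
    return (tf @ sp.diags(idf)).tocsr()


def lsi_embed(weighted: sp.spmatrix, k: int, seed: int = 0) -> np.ndarray:
    """Truncated SVD factor scores (left singular vectors x singular values)."""
    n, g = weighted.shape
    if not 1 <= k < min(n, g):
        raise CatalogError(f"k={k} must satisfy 1 <= k < min(n_samples, n_genes)")
    svd = TruncatedSVD(n_components=k, algorithm="randomized", random_state=seed)
    return svd.fit_transform(weighted)


def embed_2d(scores: np.ndarray, n_neighbors: int, min_dist: float, seed: int = 0) -> np.ndarray:
    """UMAP 2-D embedding of factor scores; seeded, hence single-threaded
    and reproducible on a fixed platform. The contract is topological
    (neighbourhoods preserved), not metric."""
    import umap

    if scores.shape[0] < n_neighbors + 1:
        raise CatalogError(
            f"need at least n_neighbors+1={n_neighbors + 1} samples, "
            f"got {scores.shape[0]}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            random_state=seed,
        )
        return np.asarray(reducer.fit_transform(scores), dtype=float)


def density_cluster(coords: np.ndarray, min_cluster_size: int) -> np.ndarray:
    """HDBSCAN labels on 2-D coordinates; unassigned points get NOISE (-1)."""
    if min_cluster_size < 2:
        raise CatalogError("min cluster size must be >= 2")
    coords = np.asarray(coords, dtype=float)
    if len(coords) < min_cluster_size:
        return np.full(len(coords), NOISE)  # no cluster can reach the minimum
    model = HDBSCAN(min_cluster_size=min_cluster_size, copy=True)
    return model.fit_predict(coords)


def _cell_silhouette(coords: np.ndarray, labels: np.ndarray) -> float:
    mask = labels != NOISE
    if len(set(labels[mask])) < 2:
        return float("nan")
    return float(silhouette_score(coords[mask], labels[mask]))


def select_model(grid_report: pd.DataFrame, noise_fraction_max: float = 0.10) -> dict:
    """Pick the grid cell maximising silhouette under a noise-fraction cap.

    Cells whose unclustered fraction exceeds the cap are excluded; if no
    cell qualifies the cap relaxes to the minimum achieved noise fraction.
    Cells with undefined silhouette (< 2 clusters) can never win while any
    defined cell exists. Ties break toward fewer unclustered samples, then
    smaller min cluster size, k, n_neighbors, min_dist.
    """
    df = grid_report.copy()
    if df.empty:
        raise CatalogError("empty grid report")
    df["noise_fraction"] = df["n_unclustered"] / df["n_samples"]
    ok = df["noise_fraction"] <= noise_fraction_max
    if not ok.any():
        ok = df["noise_fraction"] <= df["noise_fraction"].min() + 1e-12
    cand = df[ok]
    defined = cand[cand["silhouette"].notna()]
    if len(defined):
        cand = defined
        best_sil = cand["silhouette"].max()
        cand = cand[cand["silhouette"] >= best_sil - 1e-12]
    cand = cand.sort_values(
        ["n_unclustered", "min_cluster_size", "k", "n_neighbors", "min_dist"]
    )
    row = cand.iloc[0]
    return {
        "k": int(row["k"]),
        "n_neighbors": int(row["n_neighbors"]),
        "min_dist": float(row["min_dist"]),
        "min_cluster_size": int(row["min_cluster_size"]),
    }


def run_lsi_pipeline(pm: PresenceMatrix, cfg: EmbeddingConfig = EmbeddingConfig()) -> ClusteringResult:
    """TF-IDF -> truncated SVD -> (UMAP x HDBSCAN) grid -> model selection."""
    weighted = tfidf_transform(pm)
    n = pm.n_samples
    records = []
    cells = {}
    for k in cfg.k_grid:
        scores = lsi_embed(weighted, k, seed=cfg.seed)
        for nn in cfg.n_neighbors_grid:
            for md in cfg.min_dist_grid:
                coords = embed_2d(scores, nn, md, seed=cfg.seed)
                for mcs in cfg.min_cluster_grid:
                    labels = density_cluster(coords, mcs)
                    sil = _cell_silhouette(coords, labels)
                    n_noise = int((labels == NOISE).sum())
                    records.append(
                        {
                            "k": k,
                            "n_neighbors": nn,
                            "min_dist": md,
                            "min_cluster_size": mcs,
                            "silhouette": sil,
                            "n_clusters": len(set(labels[labels != NOISE])),
                            "n_unclustered": n_noise,
                            "n_samples": n,
                        }
                    )
                    cells[(k, nn, md, mcs)] = (coords, labels)
    grid_report = pd.DataFrame(records)
    chosen = select_model(grid_report, cfg.noise_fraction_max)
    coords, labels = cells[
        (
            chosen["k"],
            chosen["n_neighbors"],
            chosen["min_dist"],
            chosen["min_cluster_size"],
        )
    ]
    return ClusteringResult(
        sample_ids=pm.sample_ids.copy(),
        coords=coords,
        labels=labels,
        silhouette=_cell_silhouette(coords, labels),
        n_unclustered=int((labels == NOISE).sum()),
        chosen_params=chosen,
        grid_report=grid_report,
    )


# Fixed parameters used when re-embedding a chosen cluster on its own:
# k=50 factors, n_neighbors=10, min_dist=0.1, min cluster size 50.
SUBCLUSTER_CONFIG = EmbeddingConfig(
    k_grid=(50,),
    n_neighbors_grid=(10,),
    min_dist_grid=(0.1,),
    min_cluster_grid=(50,),
)


def subcluster(
    pm: PresenceMatrix,
    st: SampleTable,
    parent: ClusteringResult,
    cluster_ids,
    cfg: EmbeddingConfig | None = None,
) -> dict:
    """Re-run the full LSI pipeline on each requested parent cluster.

    Rows are restricted to the cluster's member samples and emptied gene
    columns are pruned before re-embedding. Returns cluster id ->
    ClusteringResult."""
    cfg = cfg if cfg is not None else SUBCLUSTER_CONFIG
    out = {}
    present = set(parent.labels)
    for cid in cluster_ids:
        if cid not in present:
            raise CatalogError(f"cluster {cid} not found in parent result")
        members = parent.sample_ids[parent.labels == cid]
        if len(members) < min(cfg.min_cluster_grid):
            raise CatalogError(
                f"cluster {cid} has {len(members)} samples, fewer than the "
                f"minimum cluster size {min(cfg.min_cluster_grid)}"
            )
        sub_pm = pm.subset_samples(members)
        k_max = min(sub_pm.n_samples, sub_pm.n_genes)
        sub_cfg = replace(cfg, k_grid=tuple(k for k in cfg.k_grid if k < k_max))
        if not sub_cfg.k_grid:
            raise CatalogError(f"cluster {cid} too small for any k in the grid")
        out[cid] = run_lsi_pipeline(sub_pm, sub_cfg)
    return out
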
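"""Between-ecology gene-content comparison by equal-depth subsampling.

Ecologies differ wildly in sampling depth, so pairwise gene-set overlap is
estimated on repeated equal-depth draws: in each iteration ``m`` samples are
drawn (without replacement) from every ecology, each ecology's gene pool is
the union of its drawn samples' gene sets, and the pairwise Jaccard
distances plus per-ecology unique-gene counts are computed on those pools.
Results are averaged over iterations. A permutation null (shuffling the
sample -> ecology assignment while keeping per-sample gene content intact)
calibrates the observed within-group vs between-group distance gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from genecat.catalog_io import CatalogError, PresenceMatrix, SampleTable

__all__ = [
    "SubsampleConfig",
    "EcologyDistanceResult",
    "PermutationNullResult",
    "subsample_jaccard",
    "permutation_null",
    "order_distance_matrix",
    "group_gap",
    "write_distance_tsv",
]


@dataclass(frozen=True)
class SubsampleConfig:
    """Equal-depth subsampling: ``m`` samples per ecology per iteration."""

    m: int = 4
    iterations: int = 50
    seed: int = 0
    keep_iterations: bool = False

    def __post_init__(self) -> None:
        if self.m < 1:
            raise CatalogError("m must be >= 1")
        if self.iterations < 1:
            raise CatalogError("iterations must be >= 1")


@dataclass
class EcologyDistanceResult:
    """Averaged subsampled Jaccard distances and unique-gene counts."""

    ecologies: list
    distances: np.ndarray  # E x E, symmetric, zero diagonal
    unique_counts: np.ndarray  # per-ecology mean count of ecology-exclusive genes
    per_iteration: list = field(default_factory=list)  # optional E x E matrices

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.distances, index=self.ecologies, columns=self.ecologies)


def _ecology_indices(pm: PresenceMatrix, st: SampleTable, m: int) -> dict:
    st = st.aligned_to(pm.sample_ids)
    by_eco: dict = {}
    for i, eco in enumerate(st.df["ecology"]):
        by_eco.setdefault(eco, []).append(i)
    for eco, idx in by_eco.items():
        if len(idx) < m:
            raise CatalogError(
                f"ecology {eco!r} has {len(idx)} samples, fewer than m={m}"
            )
    return {eco: np.array(idx) for eco, idx in sorted(by_eco.items())}


def _iteration_stats(pm, by_eco, draws):
    """Union incidence per ecology for one iteration -> (distances, uniques)."""
    ecologies = list(by_eco)
    unions = np.zeros((len(ecologies), pm.n_genes), dtype=np.int8)
    for e, eco in enumerate(ecologies):
        rows = pm.matrix[draws[eco]]
        unions[e] = (np.asarray(rows.sum(axis=0)).ravel() > 0).astype(np.int8)
    sizes = unions.sum(axis=1).astype(float)
    inter = (unions.astype(np.int64) @ unions.T.astype(np.int64)).astype(float)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore"):
        dist = 1.0 - np.divide(inter, union, out=np.ones_like(inter), where=union > 0)
    np.fill_diagonal(dist, 0.0)
    coverage = unions.sum(axis=0)
    uniques = ((coverage == 1) & (unions == 1)).sum(axis=1).astype(float)
    return dist, uniques


def subsample_jaccard(
    pm: PresenceMatrix, st: SampleTable, cfg: SubsampleConfig = SubsampleConfig()
) -> EcologyDistanceResult:
    """Average pairwise Jaccard distance between ecology subsample gene pools.

    The unique count for ecology ``e`` in an iteration is the number of
    genes in its subsampled pool found in no other ecology's pool; the
    reported value is the mean over iterations.
    """
    by_eco = _ecology_indices(pm, st, cfg.m)
    rng = np.random.default_rng(cfg.seed)
    ecologies = list(by_eco)
    dist_sum = np.zeros((len(ecologies), len(ecologies)))
    uniq_sum = np.zeros(len(ecologies))
    kept = []
    for _ in range(cfg.iterations):
        draws = {
            eco: rng.choice(idx, size=cfg.m, replace=False)
            for eco, idx in by_eco.items()
        }
        dist, uniques = _iteration_stats(pm, by_eco, draws)
        dist_sum += dist
        uniq_sum += uniques
        if cfg.keep_iterations:
            kept.append(dist)
    return EcologyDistanceResult(
        ecologies=ecologies,
        distances=dist_sum / cfg.iterations,
        unique_counts=uniq_sum / cfg.iterations,
        per_iteration=kept,
    )


def group_gap(result: EcologyDistanceResult, group_of: dict) -> float:
    """Mean between-group minus mean within-group distance (positive when
    ecologies of a group share more genes with each other than across
    groups)."""
    E = len(result.ecologies)
    groups = np.array([group_of[e] for e in result.ecologies], dtype=object)
    iu = np.triu_indices(E, k=1)
    same = groups[iu[0]] == groups[iu[1]]
    vals = result.distances[iu]
    if same.all() or not same.any():  # pragma: no cover - degenerate
        raise CatalogError("need both within- and between-group ecology pairs")
    return float(vals[~same].mean() - vals[same].mean())


@dataclass
class PermutationNullResult:
    """Observed result plus the label-permutation null distribution."""

    observed: EcologyDistanceResult
    observed_gap: float
    permuted_gaps: np.ndarray
    permuted: list = field(default_factory=list)  # optional per-permutation results

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.permuted_gaps, q))


def permutation_null(
    pm: PresenceMatrix,
    st: SampleTable,
    cfg: SubsampleConfig,
    n_perm: int,
    keep_results: bool = False,
) -> PermutationNullResult:
    """Null distribution of the group gap under random sample -> ecology
    relabelling. Gene content per sample is kept intact; only the ecology
    labels (and with them the ecology -> group structure) are permuted.
    """
    if n_perm < 1:
        raise CatalogError("n_perm must be >= 1")
    group_of = st.group_of_ecology()
    observed = subsample_jaccard(pm, st, cfg)
    obs_gap = group_gap(observed, group_of)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA11]))
    st = st.aligned_to(pm.sample_ids)
    gaps = np.empty(n_perm)
    kept = []
    for p in range(n_perm):
        perm = rng.permutation(len(st.df))
        df = st.df.copy()
        df["ecology"] = st.df["ecology"].to_numpy()[perm]
        df["ecology_group"] = st.df["ecology_group"].to_numpy()[perm]
        perm_st = SampleTable(df)
        sub_cfg = SubsampleConfig(
            m=cfg.m, iterations=cfg.iterations, seed=int(rng.integers(2**31))
        )
        res = subsample_jaccard(pm, perm_st, sub_cfg)
        gaps[p] = group_gap(res, group_of)
        if keep_results:
            kept.append(res)
    return PermutationNullResult(observed, obs_gap, gaps, kept)


def order_distance_matrix(
    result: EcologyDistanceResult, method: str = "average"
) -> tuple[list, np.ndarray]:
    """Agglomerative ordering of the ecology distance matrix for display.

    Returns (leaf order as ecology names, scipy linkage matrix). ``method``
    is one of average / complete / single.
    """
    D = np.asarray(result.distances, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise CatalogError("distance matrix must be square and symmetric")
    Z = linkage(squareform(D, checks=False), method=method)
    order = leaves_list(Z)
    return [result.ecologies[i] for i in order], Z


def cut_groups(Z: np.ndarray, ecologies: list, k: int) -> dict:
    """Cut the dendrogram into k flat clusters: ecology -> cluster id."""
    labels = fcluster(Z, t=k, criterion="maxclust")
    return dict(zip(ecologies, (int(x) for x in labels)))


def to_newick(Z: np.ndarray, ecologies: list) -> str:
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(Z, ecologies)
    return str(tree).strip()


def write_distance_tsv(result: EcologyDistanceResult, path) -> None:
    result.to_frame().to_csv(path, sep="\t", float_format="%.10g")
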
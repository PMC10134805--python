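"""Per-cluster enrichment statistics with Benjamini-Yekutieli control.

Functional enrichment contrasts annotation counts inside vs outside a
cluster in a 2x2 table (chi-square without continuity correction, switching
to a two-sided Fisher exact test when any observed cell is small).
Taxonomic enrichment compares per-sample annotated-gene counts between a
cluster and all other clusters with a one-sided Welch t-test. Multiplicity
is controlled with the Benjamini-Yekutieli step-up procedure, valid under
arbitrary dependence between the tests of a family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from genecat.catalog_io import CatalogError, PresenceMatrix

__all__ = [
    "EnrichmentConfig",
    "by_adjust",
    "functional_enrichment",
    "taxonomic_enrichment",
    "genes_by_cluster",
    "per_sample_taxon_counts",
]


@dataclass(frozen=True)
class EnrichmentConfig:
    alpha: float = 0.05
    fisher_cell_threshold: int = 6

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise CatalogError("alpha must be in (0, 1)")


def by_adjust(pvals) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values (input order preserved).

    adjusted(i) = min over j >= rank(i) of min(1, p(j) * n * c(n) / j) with
    c(n) = sum_{k=1..n} 1/k.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise CatalogError("p-values must lie in [0, 1]")
    n = p.size
    c_n = np.sum(1.0 / np.arange(1, n + 1))
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n * c_n / np.arange(1, n + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(n)
    out[order] = adj
    return out


def genes_by_cluster(pm: PresenceMatrix, labels, noise_label=-1) -> dict:
    """Cluster id -> set of genes present in >= 1 member sample."""
    labels = np.asarray(labels)
    out = {}
    for cid in sorted(set(labels) - {noise_label}):
        rows = np.flatnonzero(labels == cid)
        support = np.asarray(pm.matrix[rows].sum(axis=0)).ravel() > 0
        out[cid] = set(pm.gene_ids[support])
    return out


def per_sample_taxon_counts(pm: PresenceMatrix, annotations: pd.DataFrame) -> pd.DataFrame:
    """Samples x taxa counts of genes annotated to each taxon_label.

    Row order follows ``pm.sample_ids``; unannotated genes are ignored."""
    ann = annotations.dropna(subset=["taxon_label"])
    taxa = sorted(ann["taxon_label"].unique())
    taxon_of = dict(ann[["gene_id", "taxon_label"]].values)
    gene_taxon_idx = np.full(pm.n_genes, -1)
    taxon_pos = {t: k for k, t in enumerate(taxa)}
    for j, g in enumerate(pm.gene_ids):
        t = taxon_of.get(g)
        if t is not None:
            gene_taxon_idx[j] = taxon_pos[t]
    counts = np.zeros((pm.n_samples, len(taxa)), dtype=np.int64)
    m = pm.matrix.tocsr()
    for i in range(pm.n_samples):
        cols = m.indices[m.indptr[i] : m.indptr[i + 1]]
        for k in gene_taxon_idx[cols]:
            if k >= 0:
                counts[i, k] += 1
    return pd.DataFrame(counts, index=pm.sample_ids, columns=taxa)


def _counts_by_feature(genes, annot_map) -> pd.Series:
    # sorted iteration keeps output independent of set hashing order
    vals = [annot_map[g] for g in sorted(genes) if annot_map.get(g) is not None]
    if not vals:
        return pd.Series(dtype=int)
    return pd.Series(vals, dtype=object).value_counts().sort_index()


def functional_enrichment(
    annotations: pd.DataFrame,
    cluster_genes: dict,
    cfg: EnrichmentConfig = EnrichmentConfig(),
    feature_types: tuple = ("protein_product", "cog_category"),
) -> pd.DataFrame:
    """Annotation enrichment per (cluster, feature value).

    For each feature value the 2x2 table is [genes with the annotation in /
    out of the cluster; other annotated genes in / out]. Chi-square (1 df,
    no continuity correction) unless any cell is below
    ``cfg.fisher_cell_threshold``, then a two-sided Fisher exact test.
    BY adjustment is applied within each feature-type family. Rows with
    ``significant`` require adjusted p < alpha and fold change > 1.
    """
    frames = []
    for ftype in feature_types:
        annot_map = dict(
            annotations.dropna(subset=[ftype])[["gene_id", ftype]].values
        )
        per_cluster = {c: _counts_by_feature(g, annot_map) for c, g in cluster_genes.items()}
        totals = {c: int(s.sum()) for c, s in per_cluster.items()}
        grand = sum(totals.values())
        overall = pd.Series(dtype=float)
        for s in per_cluster.values():
            overall = overall.add(s, fill_value=0)
        rows = []
        for cid, counts in sorted(per_cluster.items(), key=lambda kv: str(kv[0])):
            for feat, a in counts.items():
                a = int(a)
                b = int(overall[feat]) - a  # feature outside cluster
                c = totals[cid] - a  # other annotations inside
                d = (grand - int(overall[feat])) - c
                if min(a + b, c + d, a + c, b + d) == 0:
                    continue  # degenerate margin: feature or cluster empty
                table = np.array([[a, b], [c, d]])
                if table.min() < cfg.fisher_cell_threshold:
                    _, p = stats.fisher_exact(table, alternative="two-sided")
                    stat, test = float("nan"), "fisher"
                else:
                    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
                    test = "chisq"
                in_rate = a / totals[cid] if totals[cid] else np.nan
                out_rate = b / (grand - totals[cid]) if grand > totals[cid] else np.nan
                fold = in_rate / out_rate if out_rate and out_rate > 0 else np.inf
                rows.append(
                    {
                        "cluster_id": cid,
                        "feature_type": ftype,
                        "feature": feat,
                        "count_in": a,
                        "count_out": b,
                        "statistic": stat,
                        "p": float(p),
                        "fold_change": float(fold),
                        "test_used": test,
                    }
                )
        if rows:
            df = pd.DataFrame(rows)
            df["p_adj_by"] = by_adjust(df["p"].to_numpy())
            df["significant"] = (df["p_adj_by"] < cfg.alpha) & (df["fold_change"] > 1)
            frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=[
                "cluster_id", "feature_type", "feature", "count_in", "count_out",
                "statistic", "p", "fold_change", "test_used", "p_adj_by", "significant",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def _welch_one_sided(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 0.5
        return (np.inf, 0.0) if x.mean() > y.mean() else (-np.inf, 1.0)
    t, p = stats.ttest_ind(x, y, equal_var=False, alternative="greater")
    return float(t), float(p)


def taxonomic_enrichment(
    per_sample_taxon_counts: pd.DataFrame,
    labels,
    cfg: EnrichmentConfig = EnrichmentConfig(),
    noise_label=-1,
) -> pd.DataFrame:
    """One-sided (greater-in-cluster) Welch t-tests on per-sample counts of
    genes annotated to each taxon, cluster vs all other clusters.

    ``per_sample_taxon_counts``: samples x taxa count frame aligned with
    ``labels``. Zero variance on both sides with equal means reports
    p = 0.5 (an uninformative taxon, not an error)."""
    labels = np.asarray(labels)
    if len(labels) != len(per_sample_taxon_counts):
        raise CatalogError("labels must align with the count table rows")
    rows = []
    for cid in sorted(set(labels) - {noise_label}):
        inside = per_sample_taxon_counts[labels == cid]
        outside = per_sample_taxon_counts[(labels != cid) & (labels != noise_label)]
        if len(inside) < 2 or len(outside) < 2:
            raise CatalogError(f"cluster {cid}: need >= 2 samples on each side")
        for taxon in per_sample_taxon_counts.columns:
            x = inside[taxon].to_numpy(float)
            y = outside[taxon].to_numpy(float)
            t, p = _welch_one_sided(x, y)
            mean_out = y.mean()
            fold = x.mean() / mean_out if mean_out > 0 else np.inf
            rows.append(
                {
                    "cluster_id": cid,
                    "feature_type": "taxon_label",
                    "feature": taxon,
                    "mean_in": float(x.mean()),
                    "mean_out": float(mean_out),
                    "statistic": t,
                    "p": p,
                    "fold_change": float(fold),
                    "test_used": "t_one_sided",
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj_by"] = by_adjust(df["p"].to_numpy())
        df["significant"] = (df["p_adj_by"] < cfg.alpha) & (df["fold_change"] > 1)
    return df
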
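"""Conserved and ecology-set-specific gene identification.

A pan-ecologically conserved gene is present in at least one sample of
every ecology of the training catalog. Ecology-set-specific candidates are
genes exclusive to a target set of ecologies in the training catalog
(present there, absent from every other training sample); candidates are
then validated on an independent held-out sample set by a one-sided
abundance test (greater in the target ecologies) with Benjamini-Yekutieli
control across the candidates of a contrast. Prevalence/abundance profiles
of a gene set on the held-out samples summarise how conserved the set
really is per ecology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from genecat.catalog_io import (
    AbundanceMatrix,
    CatalogError,
    PresenceMatrix,
    SampleTable,
)

__all__ = [
    "ContrastSpec",
    "GeneSetResult",
    "conserved_genes",
    "prevalence_profile",
    "ecology_set_genes",
    "overlap_report",
]


@dataclass(frozen=True)
class ContrastSpec:
    """A target set of ecologies tested against all remaining ecologies.

    ``prevalence_rule``: 'each' (default) requires a candidate gene in >= 1
    training sample of every target ecology; 'any' requires >= 1 sample of
    at least one of them. ``test``: 'mannwhitney' (default; abundances are
    heavy-tailed) or 'welch'.
    """

    name: str
    target_ecologies: frozenset
    alpha: float = 0.05
    prevalence_rule: str = "each"
    test: str = "mannwhitney"

    def __post_init__(self) -> None:
        if not self.target_ecologies:
            raise CatalogError("target_ecologies must be nonempty")
        if self.prevalence_rule not in ("each", "any"):
            raise CatalogError("prevalence_rule must be 'each' or 'any'")
        if self.test not in ("mannwhitney", "welch"):
            raise CatalogError("test must be 'mannwhitney' or 'welch'")


@dataclass
class GeneSetResult:
    """A gene set with held-out prevalence/abundance context."""

    name: str
    gene_ids: set
    per_ecology_prevalence: pd.DataFrame = field(default_factory=pd.DataFrame)
    per_ecology_abundance: pd.DataFrame = field(default_factory=pd.DataFrame)
    p_adj: dict = field(default_factory=dict)
    overall_prevalence: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    median_prevalence: float = float("nan")


def _ecology_union(pm: PresenceMatrix, st: SampleTable) -> tuple[list, np.ndarray]:
    """Per-ecology gene incidence: (ecology names, E x G sample counts)."""
    eco = st.aligned_to(pm.sample_ids).df["ecology"].to_numpy(object)
    ecologies = sorted(set(eco))
    counts = np.zeros((len(ecologies), pm.n_genes), dtype=np.int64)
    for e, name in enumerate(ecologies):
        rows = np.flatnonzero(eco == name)
        counts[e] = np.asarray(pm.matrix[rows].sum(axis=0)).ravel()
    return ecologies, counts


def conserved_genes(pm: PresenceMatrix, st: SampleTable) -> set:
    """Genes present at least once in every ecology."""
    _, counts = _ecology_union(pm, st)
    mask = (counts > 0).all(axis=0)
    return set(pm.gene_ids[mask])


def prevalence_profile(
    genes,
    heldout_pm: PresenceMatrix,
    heldout_am: AbundanceMatrix | None,
    st: SampleTable,
    name: str = "gene_set",
) -> GeneSetResult:
    """Per-ecology prevalence and abundance summaries on held-out samples.

    Prevalence of a gene in an ecology is the fraction of that ecology's
    held-out samples carrying it; genes missing from the held-out catalog
    get prevalence 0 and no abundance summary. Ecologies without held-out
    samples report NaN. Also reports each gene's overall prevalence across
    all held-out samples and the median of those over genes.
    """
    genes = sorted(genes)
    eco = st.aligned_to(heldout_pm.sample_ids).df["ecology"].to_numpy(object)
    ecologies = sorted(set(eco))
    pos = {g: j for j, g in enumerate(heldout_pm.gene_ids)}
    prev = pd.DataFrame(0.0, index=genes, columns=ecologies)
    abund = pd.DataFrame(np.nan, index=genes, columns=[f"{e}_median" for e in ecologies] + [f"{e}_iqr" for e in ecologies])
    overall = pd.Series(0.0, index=genes)
    dense_p = heldout_pm.matrix.tocsc()
    dense_a = heldout_am.matrix.tocsc() if heldout_am is not None else None
    n_total = heldout_pm.n_samples
    for g in genes:
        j = pos.get(g)
        if j is None:
            continue
        col_rows = dense_p.indices[dense_p.indptr[j] : dense_p.indptr[j + 1]]
        overall[g] = len(col_rows) / n_total if n_total else np.nan
        present = np.zeros(n_total, dtype=bool)
        present[col_rows] = True
        for e in ecologies:
            eco_mask = eco == e
            n_eco = int(eco_mask.sum())
            prev.loc[g, e] = (present & eco_mask).sum() / n_eco if n_eco else np.nan
            if dense_a is not None:
                vals = np.asarray(dense_a[:, j][eco_mask & present].todense()).ravel()
                if vals.size:
                    abund.loc[g, f"{e}_median"] = float(np.median(vals))
                    q75, q25 = np.percentile(vals, [75, 25])
                    abund.loc[g, f"{e}_iqr"] = float(q75 - q25)
    return GeneSetResult(
        name=name,
        gene_ids=set(genes),
        per_ecology_prevalence=prev,
        per_ecology_abundance=abund,
        overall_prevalence=overall,
        median_prevalence=float(overall.median()) if len(overall) else float("nan"),
    )


def _candidate_genes(pm: PresenceMatrix, st: SampleTable, contrast: ContrastSpec) -> list:
    ecologies, counts = _ecology_union(pm, st)
    unknown = contrast.target_ecologies - set(ecologies)
    if unknown:
        raise CatalogError(f"contrast targets unknown ecologies {sorted(unknown)}")
    target = np.array([e in contrast.target_ecologies for e in ecologies])
    if target.all():
        raise CatalogError("contrast target must be a proper subset of ecologies")
    present = counts > 0
    in_target = (
        present[target].all(axis=0)
        if contrast.prevalence_rule == "each"
        else present[target].any(axis=0)
    )
    exclusive = ~present[~target].any(axis=0)
    return sorted(pm.gene_ids[in_target & exclusive])


def ecology_set_genes(
    pm: PresenceMatrix,
    st: SampleTable,
    heldout_am: AbundanceMatrix,
    heldout_st: SampleTable,
    contrast: ContrastSpec,
) -> GeneSetResult:
    """Training-exclusive candidates validated by held-out abundance.

    Candidates (training-exclusive to the target ecologies) are each tested
    one-sided for higher held-out abundance in target vs background
    samples; BY adjustment runs across the candidates of this contrast and
    genes with adjusted p < alpha are returned. Candidates absent from the
    held-out abundance matrix are never selected.
    """
    from genecat.enrichment import by_adjust

    candidates = _candidate_genes(pm, st, contrast)
    eco = heldout_st.aligned_to(heldout_am.sample_ids).df["ecology"].to_numpy(object)
    target_mask = np.array([e in contrast.target_ecologies for e in eco])
    if not target_mask.any() or target_mask.all():
        raise CatalogError("held-out set must contain target and background samples")
    pos = {g: j for j, g in enumerate(heldout_am.gene_ids)}
    testable, pvals = [], []
    dense = heldout_am.matrix.tocsc()
    for g in candidates:
        j = pos.get(g)
        if j is None:
            continue
        col = np.asarray(dense[:, j].todense()).ravel()
        x, y = col[target_mask], col[~target_mask]
        if contrast.test == "mannwhitney":
            if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
                p = 1.0
            else:
                _, p = stats.mannwhitneyu(x, y, alternative="greater")
        else:
            _, p = stats.ttest_ind(x, y, equal_var=False, alternative="greater")
            p = 1.0 if np.isnan(p) else p
        testable.append(g)
        pvals.append(float(p))
    if not testable:
        return GeneSetResult(name=contrast.name, gene_ids=set(), p_adj={})
    adj = by_adjust(np.array(pvals))
    p_adj = dict(zip(testable, adj))
    selected = {g for g, q in p_adj.items() if q < contrast.alpha}
    return GeneSetResult(name=contrast.name, gene_ids=selected, p_adj=p_adj)


def overlap_report(results: list) -> dict:
    """Exact-membership (upset-style) counts over a list of GeneSetResults.

    Returns {frozenset of result names: count of genes belonging to exactly
    that subset of results}. The counts partition the union of all sets.
    """
    membership: dict = {}
    for res in results:
        for g in res.gene_ids:
            membership.setdefault(g, set()).add(res.name)
    out: dict = {}
    for g, names in membership.items():
        key = frozenset(names)
        out[key] = out.get(key, 0) + 1
    return out
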
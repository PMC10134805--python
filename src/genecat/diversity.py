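"""Alpha and beta diversity on gene presence and species abundance.

Beta diversity: Jaccard distance on per-sample gene sets and Bray-Curtis
dissimilarity on per-sample relative abundances. Alpha diversity: the
classic nonparametric Chao richness estimators — Chao1 from the abundance
singleton/doubleton counts (f1, f2) of a single sample and Chao2 from the
incidence unique/duplicate counts (q1, q2) of a block of sampling units —
with the standard bias-corrected fallback when the doubleton count is zero.
:func:`within_ecology_diversity` pools all four measures over equal-depth
subsampling iterations, one distribution per ecology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from genecat.catalog_io import (
    AbundanceMatrix,
    CatalogError,
    PresenceMatrix,
    SampleTable,
)
from genecat.similarity import SubsampleConfig, _ecology_indices

__all__ = [
    "RichnessEstimate",
    "jaccard_distance",
    "bray_curtis",
    "chao1",
    "chao2",
    "within_ecology_diversity",
]


@dataclass(frozen=True)
class RichnessEstimate:
    """A Chao-type richness estimate: observed richness plus the unseen-
    species correction derived from rare-class counts."""

    s_obs: int
    estimate: float
    variant: str  # chao1 | chao1_bias_corrected | chao2 | chao2_bias_corrected
    f1_or_q1: int
    f2_or_q2: int

    def __post_init__(self) -> None:
        if self.estimate < self.s_obs - 1e-9:
            raise CatalogError("richness estimate below observed richness")


def jaccard_distance(a: set, b: set) -> float:
    """1 - |a n b| / |a u b| on gene sets; undefined when both are empty."""
    a, b = set(a), set(b)
    union = len(a | b)
    if union == 0:
        raise CatalogError("Jaccard distance undefined for two empty sets")
    return 1.0 - len(a & b) / union


def bray_curtis(x, y) -> float:
    """1 - 2 sum(min(x_i, y_i)) / (sum x + sum y) on abundance vectors.

    Not scale-invariant: callers comparing samples of different sequencing
    depth should pass identically normalised (e.g. relative) abundances.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise CatalogError("abundance vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise CatalogError("abundances must be nonnegative")
    sx, sy = x.sum(), y.sum()
    if sx == 0 or sy == 0:
        raise CatalogError("Bray-Curtis undefined for a zero-sum vector")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / (sx + sy))


def _chao(s_obs: int, r1: int, r2: int, which: str) -> RichnessEstimate:
    if r2 > 0:
        return RichnessEstimate(s_obs, s_obs + r1 * r1 / (2.0 * r2), which, r1, r2)
    return RichnessEstimate(
        s_obs, s_obs + r1 * (r1 - 1) / 2.0, which + "_bias_corrected", r1, r2
    )


def chao1(counts) -> RichnessEstimate:
    """Chao1 richness from one sample's integer species counts."""
    counts = np.asarray(counts)
    if counts.size == 0:
        raise CatalogError("empty count vector")
    if not np.all(np.equal(np.mod(counts, 1), 0)):
        raise CatalogError("Chao1 requires integer counts")
    counts = counts.astype(np.int64)
    if (counts < 0).any():
        raise CatalogError("counts must be nonnegative")
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return _chao(s_obs, f1, f2, "chao1")


def chao2(incidence) -> RichnessEstimate:
    """Chao2 richness from a units x species binary incidence matrix."""
    inc = np.asarray(incidence)
    if inc.ndim != 2 or inc.shape[0] < 2:
        raise CatalogError("Chao2 requires >= 2 incidence units")
    if not np.isin(inc, (0, 1)).all():
        raise CatalogError("incidence matrix must be binary")
    freq = inc.sum(axis=0)
    s_obs = int((freq > 0).sum())
    q1 = int((freq == 1).sum())
    q2 = int((freq == 2).sum())
    return _chao(s_obs, q1, q2, "chao2")


def within_ecology_diversity(
    pm: PresenceMatrix,
    am_species: AbundanceMatrix,
    st: SampleTable,
    cfg: SubsampleConfig = SubsampleConfig(),
) -> pd.DataFrame:
    """Per-ecology diversity distributions under equal-depth subsampling.

    Per iteration and ecology (m drawn samples): all m(m-1)/2 pairwise gene
    Jaccard distances; Bray-Curtis on species relative abundances; Chao1 per
    sample from raw integer species counts; Chao2 on the ecology's m-sample
    gene-incidence block. Returns a long-format frame with columns
    (ecology, iteration, metric, value), directly plottable.
    """
    by_eco = _ecology_indices(pm, st, cfg.m)
    am_rows = am_species.sample_index(pm.sample_ids)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for it in range(cfg.iterations):
        for eco, idx in by_eco.items():
            draw = rng.choice(idx, size=cfg.m, replace=False)
            block = pm.matrix[draw].toarray()
            gene_sets = [set(np.flatnonzero(r)) for r in block]
            counts = np.vstack(
                [np.asarray(am_species.matrix[am_rows[i]].todense()).ravel() for i in draw]
            )
            totals = counts.sum(axis=1)
            rel = counts / np.where(totals > 0, totals, 1.0)[:, None]
            for a in range(cfg.m):
                for b in range(a + 1, cfg.m):
                    rows.append((eco, it, "jaccard", jaccard_distance(gene_sets[a], gene_sets[b])))
                    rows.append((eco, it, "bray_curtis", bray_curtis(rel[a], rel[b])))
            for a in range(cfg.m):
                rows.append((eco, it, "chao1", chao1(counts[a]).estimate))
            rows.append((eco, it, "chao2", chao2(block).estimate))
    return pd.DataFrame(rows, columns=["ecology", "iteration", "metric", "value"])
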
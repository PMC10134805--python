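"""Synthetic multi-ecology gene catalogs with planted, recorded ground truth.

The generator emulates the statistical structure of a large cross-ecology
nonredundant gene catalog: ecologies organised into higher-level groups
(gut-associated, environmental, other host-associated), ecology-dependent
per-sample gene counts, a dominant fraction of singleton genes (genes
assembled in exactly one sample; ~0.66 of the catalog), a small planted set
of pan-ecologically conserved genes, per-group core pools, per-ecology
exclusive pools, and a lognormal per-sample abundance model.

Each sample's gene list is the union of

    (conserved genes, each kept with probability 1 - dropout)
  + (a draw from its group's core pool)
  + (a draw from its ecology's exclusive pool)
  + (fresh one-sample singleton genes appended to push the global singleton
     fraction to the configured target)

The planted structure is recorded in :class:`GroundTruth`, which downstream
recovery analyses are scored against.

Seed discipline: one master seed; per-stage child streams are spawned with
``numpy.random.SeedSequence(seed).spawn`` in a fixed order (catalog,
abundance, held-out), so stages can be rerun independently yet reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from genecat.catalog_io import AbundanceMatrix, CatalogError, PresenceMatrix, SampleTable

__all__ = [
    "EcologySpec",
    "GeneratorConfig",
    "GroundTruth",
    "default_config",
    "seven_group_config",
    "contrast_replicate_config",
    "generate_catalog",
    "generate_abundance",
    "generate_heldout",
    "validate_ground_truth",
    "write_ground_truth",
    "read_ground_truth",
]


@dataclass(frozen=True)
class EcologySpec:
    """One sampled environment class: name, higher-level group, sampling depth."""

    name: str
    group: str
    n_samples: int
    genes_per_sample: tuple[int, int]  # structured (non-singleton) draw range
    core_frac: float | None = None  # overrides GeneratorConfig.core_draw_frac


# Seventeen ecologies in three groups, mirroring the broad block structure
# of cross-ecology gene-content comparisons: gut-associated communities are
# gene-rich, human mucosal/skin sites are gene-poor with high turnover, and
# environmental samples sit in between. Per-sample structured gene counts
# are deliberately ecology-dependent (the nasal-like site is the sparsest).
_DEFAULT_ECOLOGIES = (
    EcologySpec("human_gut", "gut_associated", 8, (250, 400)),
    EcologySpec("mouse_gut", "gut_associated", 8, (220, 360)),
    EcologySpec("cow_gut", "gut_associated", 8, (260, 420)),
    EcologySpec("pig_gut", "gut_associated", 8, (230, 380)),
    EcologySpec("chicken_cecum", "gut_associated", 8, (200, 340)),
    EcologySpec("moose_gut", "gut_associated", 8, (240, 380)),
    EcologySpec("aquatic", "environmental", 8, (180, 300)),
    EcologySpec("aquatic_sediment", "environmental", 8, (200, 320)),
    EcologySpec("terrestrial_soil", "environmental", 8, (220, 340)),
    EcologySpec("plant_rhizosphere", "environmental", 8, (160, 280)),
    EcologySpec("coral_reef", "environmental", 8, (150, 260)),
    EcologySpec("human_oral", "other_host", 8, (140, 240)),
    EcologySpec("human_nasal", "other_host", 8, (40, 80), core_frac=0.25),
    EcologySpec("human_skin", "other_host", 8, (100, 180)),
    EcologySpec("human_vaginal", "other_host", 8, (60, 120), core_frac=0.25),
    EcologySpec("human_airways", "other_host", 8, (80, 150), core_frac=0.25),
    EcologySpec("insect_host", "other_host", 8, (120, 200)),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic catalog.

    ``singleton_target`` is the desired global fraction of singleton gene
    columns; fresh one-sample genes are appended after the structured pools
    to reach it. ``dropout`` is the per-(sample, conserved/core gene)
    probability that a gene that "should" occur is missed (e.g., failed to
    assemble). ``core_draw_frac`` splits each sample's structured draw
    between its group core pool and its ecology-exclusive pool. Abundances
    are lognormal(mu, sigma); genes of a planted contrast are shifted
    multiplicatively (``abundance_shift``) in their target ecologies of the
    held-out set.
    """

    ecologies: tuple[EcologySpec, ...] = _DEFAULT_ECOLOGIES
    n_conserved: int = 120
    core_sizes: dict = field(default_factory=lambda: {})  # group -> pool size
    ecology_specific_sizes: dict = field(default_factory=lambda: {})
    default_core_size: int = 400
    default_specific_size: int = 120
    core_draw_frac: float = 0.6
    singleton_target: float = 0.66
    dropout: float = 0.05
    abundance_mu: float = 1.0
    abundance_sigma: float = 1.0
    abundance_shift: float = 8.0
    heldout_per_ecology: int = 4
    heldout_background_detection: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ecologies:
            raise CatalogError("config needs at least one ecology")
        names = [e.name for e in self.ecologies]
        if len(set(names)) != len(names):
            raise CatalogError("duplicate ecology names")
        if not 0 <= self.singleton_target < 1:
            raise CatalogError("singleton_target must be in [0, 1)")
        if not 0 <= self.dropout < 1:
            raise CatalogError("dropout must be in [0, 1)")
        for eco in self.ecologies:
            lo, hi = eco.genes_per_sample
            if not (1 <= lo <= hi):
                raise CatalogError(f"empty genes_per_sample range for {eco.name}")
            if eco.n_samples < 1:
                raise CatalogError(f"ecology {eco.name} needs >= 1 sample")

    def core_size(self, group: str) -> int:
        return self.core_sizes.get(group, self.default_core_size)

    def specific_size(self, ecology: str) -> int:
        return self.ecology_specific_sizes.get(ecology, self.default_specific_size)

    @property
    def groups(self) -> list[str]:
        seen: dict = {}
        for e in self.ecologies:
            seen.setdefault(e.group, None)
        return list(seen)


def default_config(
    n_samples_per_ecology: int | None = None, **overrides
) -> GeneratorConfig:
    """The default 17-ecology, 3-group study configuration.

    ``n_samples_per_ecology`` overrides the sampling depth uniformly (e.g.
    30 per ecology for a ~500-sample catalog)."""
    if n_samples_per_ecology is not None and "ecologies" not in overrides:
        overrides["ecologies"] = tuple(
            replace(e, n_samples=n_samples_per_ecology) for e in _DEFAULT_ECOLOGIES
        )
    # sparse human mucosal sites show strong person-to-person strain
    # turnover: large exclusive pools relative to their small per-sample draws
    overrides.setdefault(
        "ecology_specific_sizes",
        {"human_nasal": 300, "human_vaginal": 260, "human_airways": 220},
    )
    return GeneratorConfig(**overrides)


def seven_group_config(
    n_samples: int = 100, seed: int = 0, **overrides
) -> GeneratorConfig:
    """Seven ecologies, each its own group: the planted seven-cluster layout
    used to exercise the LSI clustering pipeline."""
    ecologies = tuple(
        EcologySpec(f"type_{i}", f"grp_{i}", n_samples, (120, 220)) for i in range(7)
    )
    return GeneratorConfig(
        ecologies=ecologies,
        default_core_size=300,
        default_specific_size=80,
        seed=seed,
        **overrides,
    )


def contrast_replicate_config(
    n_target: int = 2,
    n_background: int = 2,
    samples_per_ecology: int = 10,
    heldout_per_ecology: int = 10,
    abundance_shift: float = 8.0,
    seed: int = 0,
) -> GeneratorConfig:
    """Small two-group layout for differential-abundance power/FDR replicates."""
    ecologies = tuple(
        [
            EcologySpec(f"target_{i}", "target", samples_per_ecology, (40, 80))
            for i in range(n_target)
        ]
        + [
            EcologySpec(f"bg_{i}", "background", samples_per_ecology, (40, 80))
            for i in range(n_background)
        ]
    )
    return GeneratorConfig(
        ecologies=ecologies,
        n_conserved=30,
        default_core_size=60,
        default_specific_size=30,
        singleton_target=0.4,
        heldout_per_ecology=heldout_per_ecology,
        abundance_shift=abundance_shift,
        seed=seed,
    )


@dataclass
class GroundTruth:
    """The generator's planted structure, the acceptance surface for recovery.

    ``enriched_contrasts`` lists (ecology set, gene set) pairs whose genes
    occur only in samples of those ecologies and receive the configured
    abundance shift there in held-out data.
    """

    conserved_gene_ids: set
    core_gene_ids: dict  # group -> set
    specific_gene_ids: dict  # ecology -> set
    singleton_fraction_realized: float
    group_labels: dict  # sample_id -> group
    enriched_contrasts: list  # [(frozenset of ecologies, frozenset of genes)]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _draw_sample_support(
    cfg: GeneratorConfig,
    eco: EcologySpec,
    rng: np.random.Generator,
    conserved: np.ndarray,
    core_pool: np.ndarray,
    spec_pool: np.ndarray,
) -> np.ndarray:
    lo, hi = eco.genes_per_sample
    n_struct = int(rng.integers(lo, hi + 1))
    core_frac = eco.core_frac if eco.core_frac is not None else cfg.core_draw_frac
    # an ecology's accessible core pool scales with its typical gene count:
    # gene-poor sites live on a genuinely smaller (nested) slice of the
    # group core, so their richness is low even though turnover is high
    window = min(len(core_pool), max(int(1.5 * core_frac * hi), 10))
    core_pool = core_pool[:window]
    n_core = min(int(round(core_frac * n_struct)), len(core_pool))
    n_spec = min(n_struct - n_core, len(spec_pool))
    parts = []
    if cfg.dropout > 0 and len(conserved):
        keep = rng.random(len(conserved)) >= cfg.dropout
        parts.append(conserved[keep])
    else:
        parts.append(conserved)
    core_draw = rng.choice(core_pool, size=n_core, replace=False)
    if cfg.dropout > 0 and n_core:
        core_draw = core_draw[rng.random(n_core) >= cfg.dropout]
    parts.append(core_draw)
    if n_spec:
        parts.append(rng.choice(spec_pool, size=n_spec, replace=False))
    return np.concatenate(parts)


def _build_catalog(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    sample_prefix: str,
    pools: dict,
    singleton_start: int,
    with_singletons: bool = True,
):
    """Realize a sample x gene support from the planted pools.

    Returns (sample records, per-sample gene-index lists, gene_index dict,
    gene id list) where gene indices refer to the returned id list.
    """
    conserved = pools["conserved"]
    gene_index: dict = {}
    gene_ids: list = []

    def gi(g: str) -> int:
        idx = gene_index.get(g)
        if idx is None:
            idx = gene_index[g] = len(gene_ids)
            gene_ids.append(g)
        return idx

    records = []
    supports = []
    for eco in cfg.ecologies:
        core_pool = pools["core"][eco.group]
        spec_pool = pools["specific"][eco.name]
        for j in range(eco.n_samples):
            sid = f"{sample_prefix}{eco.name}_{j:04d}"
            genes = _draw_sample_support(cfg, eco, rng, conserved, core_pool, spec_pool)
            supports.append([gi(g) for g in genes])
            records.append(
                {
                    "sample_id": sid,
                    "ecology": eco.name,
                    "ecology_group": eco.group,
                    "disease_status": rng.choice(["healthy", "diseased", "unknown"]),
                    "westernized": bool(rng.random() < 0.5),
                    "age_category": rng.choice(["infant", "adult", "senior"]),
                }
            )

    if with_singletons:
        col_counts = np.zeros(len(gene_ids), dtype=int)
        for sup in supports:
            col_counts[sup] += 1
        s0 = int((col_counts == 1).sum())
        n0 = int((col_counts > 1).sum())
        t = cfg.singleton_target
        n_extra = int(np.ceil((t * (s0 + n0) - s0) / (1 - t)))
        if n_extra < 0:
            raise CatalogError(
                f"singleton_target={t} unreachable: structured pools already "
                f"realize fraction {s0 / max(s0 + n0, 1):.3f}"
            )
        # deeper samples assemble more one-off genes: allocate singletons
        # proportionally to structured support size
        weights = np.array([len(s) for s in supports], dtype=float)
        owners = rng.choice(len(supports), size=n_extra, p=weights / weights.sum())
        for k, owner in enumerate(owners):
            g = f"sing_{sample_prefix}{singleton_start + k:07d}"
            supports[owner].append(gi(g))

    return records, supports, gene_ids


def _to_presence(records, supports, gene_ids) -> tuple[PresenceMatrix, SampleTable]:
    sample_ids = np.array([r["sample_id"] for r in records], dtype=object)
    gene_ids = np.array(gene_ids, dtype=object)
    # deterministic lexicographic ordering of both axes
    row_order = np.argsort(sample_ids)
    col_order = np.argsort(gene_ids)
    col_rank = np.empty(len(gene_ids), dtype=int)
    col_rank[col_order] = np.arange(len(gene_ids))
    rows, cols = [], []
    for new_r, old_r in enumerate(row_order):
        for g in supports[old_r]:
            rows.append(new_r)
            cols.append(col_rank[g])
    mat = sp.coo_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(sample_ids), len(gene_ids)),
    ).tocsr()
    pm = PresenceMatrix(mat, sample_ids[row_order], gene_ids[col_order])
    df = pd.DataFrame([records[i] for i in row_order])
    df["n_genes"] = pm.row_sums()
    return pm, SampleTable(df)


def _planted_pools(cfg: GeneratorConfig) -> dict:
    conserved = np.array([f"cons_{i:05d}" for i in range(cfg.n_conserved)], dtype=object)
    core = {
        g: np.array([f"core_{g}_{i:05d}" for i in range(cfg.core_size(g))], dtype=object)
        for g in cfg.groups
    }
    specific = {
        e.name: np.array(
            [f"spec_{e.name}_{i:05d}" for i in range(cfg.specific_size(e.name))],
            dtype=object,
        )
        for e in cfg.ecologies
    }
    return {"conserved": conserved, "core": core, "specific": specific}


def _annotations(cfg: GeneratorConfig, pools: dict, gene_ids) -> pd.DataFrame:
    """Annotation table with a distinguishable signature per planted set.

    Conserved genes carry 'conserved_marker' products, each core/specific
    pool carries a pool-specific product and a taxon drawn from a small
    group-specific genus list; singletons are mostly unannotated, mirroring
    the large novel fraction of real catalogs.
    """
    from zlib import crc32  # stable across processes, unlike builtin hash()

    cogs = list("JKLMNOPQRSTUVWC")
    rows = []
    taxon_pools = {
        g: [f"genus_{g}_{i}" for i in range(4)] for g in cfg.groups
    }
    product_of = {}
    cog_of = {}
    taxon_of = {}
    for i, g in enumerate(pools["conserved"]):
        product_of[g] = f"conserved_marker_{i % 40}"
        cog_of[g] = "J"
        taxon_of[g] = "genus_ubiquitous"
    for grp, pool in pools["core"].items():
        for i, g in enumerate(pool):
            product_of[g] = f"{grp}_core_protein_{i % 25}"
            cog_of[g] = cogs[crc32(grp.encode()) % len(cogs)]
            taxon_of[g] = taxon_pools[grp][i % len(taxon_pools[grp])]
    group_of = {e.name: e.group for e in cfg.ecologies}
    for eco, pool in pools["specific"].items():
        for i, g in enumerate(pool):
            product_of[g] = f"{eco}_marker_protein_{i % 10}"
            cog_of[g] = cogs[(crc32(eco.encode()) + 3) % len(cogs)]
            taxon_of[g] = f"genus_{eco}"
        group_of.setdefault(eco, None)
    for g in gene_ids:
        rows.append(
            {
                "gene_id": g,
                "protein_product": product_of.get(g),
                "cog_category": cog_of.get(g),
                "taxon_label": taxon_of.get(g),
            }
        )
    return pd.DataFrame(rows)


def generate_catalog(
    cfg: GeneratorConfig,
) -> tuple[SampleTable, PresenceMatrix, pd.DataFrame, GroundTruth]:
    """Generate the training catalog: metadata, presence matrix, annotations
    and the planted :class:`GroundTruth`. Identical seeds give bit-identical
    output."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_catalog, _, _ = (np.random.default_rng(s) for s in ss.spawn(3))
    pools = _planted_pools(cfg)
    records, supports, gene_ids = _build_catalog(cfg, rng_catalog, "S_", pools, 0)
    pm, st = _to_presence(records, supports, gene_ids)
    ann = _annotations(cfg, pools, pm.gene_ids)

    n_single, n_non, frac = _singleton_stats(pm)
    group_labels = dict(zip(st.df["sample_id"], st.df["ecology_group"]))
    ecology_names_by_group: dict = {}
    for e in cfg.ecologies:
        ecology_names_by_group.setdefault(e.group, []).append(e.name)
    contrasts = [
        (frozenset(ecology_names_by_group[g]), frozenset(pools["core"][g]) & set(pm.gene_ids))
        for g in cfg.groups
    ] + [
        (frozenset([e.name]), frozenset(pools["specific"][e.name]) & set(pm.gene_ids))
        for e in cfg.ecologies
    ]
    truth = GroundTruth(
        conserved_gene_ids=set(pools["conserved"]) & set(pm.gene_ids),
        core_gene_ids={g: set(pools["core"][g]) & set(pm.gene_ids) for g in cfg.groups},
        specific_gene_ids={
            e.name: set(pools["specific"][e.name]) & set(pm.gene_ids)
            for e in cfg.ecologies
        },
        singleton_fraction_realized=frac,
        group_labels=group_labels,
        enriched_contrasts=contrasts,
    )
    return st, pm, ann, truth


def _singleton_stats(pm: PresenceMatrix):
    cs = pm.col_sums()
    n_single = int((cs == 1).sum())
    return n_single, pm.n_genes - n_single, n_single / pm.n_genes


def generate_abundance(
    pm: PresenceMatrix,
    cfg: GeneratorConfig,
    truth: GroundTruth,
    counts: bool = False,
) -> AbundanceMatrix:
    """Lognormal abundances on the presence support.

    With ``counts=True`` values are integer (1 + Poisson around the
    lognormal level), suitable for abundance-based richness estimation.
    Genes of a planted contrast are shifted by ``cfg.abundance_shift`` in
    samples of their target ecologies.
    """
    ss = np.random.SeedSequence(cfg.seed)
    _, rng, _ = (np.random.default_rng(s) for s in ss.spawn(3))
    return _abundance_on_support(pm, cfg, truth, rng, counts=counts, shifted=True)


def _abundance_on_support(
    pm: PresenceMatrix,
    cfg: GeneratorConfig,
    truth: GroundTruth,
    rng: np.random.Generator,
    counts: bool,
    shifted: bool,
    st: SampleTable | None = None,
) -> AbundanceMatrix:
    mat = pm.matrix.tocoo()
    vals = rng.lognormal(cfg.abundance_mu, cfg.abundance_sigma, size=mat.nnz)
    if shifted and cfg.abundance_shift != 1.0:
        eco_of_row = _row_ecologies(pm, st)
        shift_mask = _contrast_mask(pm, truth, mat, eco_of_row)
        vals[shift_mask] *= cfg.abundance_shift
    if counts:
        vals = 1.0 + rng.poisson(vals)
    out = sp.coo_matrix((vals, (mat.row, mat.col)), shape=mat.shape).tocsr()
    return AbundanceMatrix(out, pm.sample_ids, pm.gene_ids)


def _row_ecologies(pm: PresenceMatrix, st: SampleTable | None) -> np.ndarray:
    if st is not None:
        return st.aligned_to(pm.sample_ids).df["ecology"].to_numpy(object)
    # sample ids are "<prefix><ecology>_<idx>"; recover the ecology token
    return np.array(
        ["_".join(s.split("_")[1:-1]) for s in pm.sample_ids], dtype=object
    )


def _contrast_mask(pm, truth, coo, eco_of_row) -> np.ndarray:
    gene_contrast: dict = {}
    for ecos, genes in truth.enriched_contrasts:
        for g in genes:
            gene_contrast[g] = ecos
    mask = np.zeros(coo.nnz, dtype=bool)
    gid = pm.gene_ids
    for k in range(coo.nnz):
        ecos = gene_contrast.get(gid[coo.col[k]])
        if ecos is not None and eco_of_row[coo.row[k]] in ecos:
            mask[k] = True
    return mask


def generate_heldout(
    cfg: GeneratorConfig, truth: GroundTruth, counts: bool = False
) -> tuple[SampleTable, PresenceMatrix, AbundanceMatrix]:
    """An independent validation set drawn from the same generative process.

    Sample ids are disjoint from the training catalog ("H_" prefix). The
    abundance matrix emulates read-mapping quantification against the full
    catalog rather than per-sample assembly: a planted contrast gene can
    therefore show abundance in background samples (with probability
    ``cfg.heldout_background_detection``) even when it never assembled
    there, while samples of its target ecologies see the configured
    multiplicative shift. Its support is hence a superset of the assembly
    presence support for contrast genes.
    """
    ss = np.random.SeedSequence(cfg.seed)
    _, _, rng = (np.random.default_rng(s) for s in ss.spawn(3))
    if cfg.heldout_per_ecology == 0:
        empty = sp.csr_matrix((0, 0), dtype=np.int8)
        st = SampleTable(
            pd.DataFrame(
                columns=[
                    "sample_id",
                    "ecology",
                    "ecology_group",
                    "disease_status",
                    "westernized",
                    "age_category",
                    "n_genes",
                ]
            )
        )
        pm = PresenceMatrix(empty, [], [])
        return st, pm, AbundanceMatrix(sp.csr_matrix((0, 0)), [], [])
    ho_cfg = replace(
        cfg,
        ecologies=tuple(
            replace(e, n_samples=cfg.heldout_per_ecology) for e in cfg.ecologies
        ),
    )
    pools = _planted_pools(cfg)
    records, supports, gene_ids = _build_catalog(ho_cfg, rng, "H_", pools, 10**6)
    pm, st = _to_presence(records, supports, gene_ids)

    am = _abundance_on_support(pm, cfg, truth, rng, counts=counts, shifted=False, st=st)
    am = _add_mapping_abundance(am, st, cfg, truth, rng, counts)
    return st, pm, am


def _add_mapping_abundance(
    am: AbundanceMatrix,
    st: SampleTable,
    cfg: GeneratorConfig,
    truth: GroundTruth,
    rng: np.random.Generator,
    counts: bool,
) -> AbundanceMatrix:
    """Overlay read-mapping detections of contrast genes onto the assembly-
    support abundances: every held-out sample may detect a contrast gene;
    target-ecology samples see the multiplicative shift."""
    eco_of_row = st.aligned_to(am.sample_ids).df["ecology"].to_numpy(object)
    gene_pos = {g: j for j, g in enumerate(am.gene_ids)}
    dense = am.matrix.tolil()
    for ecos, genes in truth.enriched_contrasts:
        present = [gene_pos[g] for g in sorted(genes) if g in gene_pos]
        if not present:
            continue
        for i, eco in enumerate(eco_of_row):
            in_target = eco in ecos
            detect = rng.random(len(present)) < (
                1.0 if in_target else cfg.heldout_background_detection
            )
            base = rng.lognormal(cfg.abundance_mu, cfg.abundance_sigma, len(present))
            if in_target:
                base = base * cfg.abundance_shift
            if counts:
                base = 1.0 + rng.poisson(base)
            for j, d, v in zip(present, detect, base):
                if d:
                    dense[i, j] = v
    return AbundanceMatrix(dense.tocsr(), am.sample_ids, am.gene_ids)


# ---------------------------------------------------------------------------
# validation & serialization
# ---------------------------------------------------------------------------


def validate_ground_truth(
    truth: GroundTruth, pm: PresenceMatrix, st: SampleTable
) -> None:
    """Check every GroundTruth invariant against the realized matrix."""
    planted = [("conserved", truth.conserved_gene_ids)]
    planted += [(f"core:{g}", s) for g, s in truth.core_gene_ids.items()]
    planted += [(f"specific:{e}", s) for e, s in truth.specific_gene_ids.items()]
    seen: set = set()
    for name, genes in planted:
        if genes & seen:
            raise CatalogError(f"planted set {name} overlaps another planted set")
        seen |= genes
    gene_set = set(pm.gene_ids)
    if not seen <= gene_set:
        raise CatalogError("planted gene ids missing from the realized matrix")

    # conserved genes occur in >=1 sample of every ecology
    eco = st.aligned_to(pm.sample_ids).df["ecology"].to_numpy(object)
    pos = {g: j for j, g in enumerate(pm.gene_ids)}
    dense = pm.matrix.tocsc()
    for g in truth.conserved_gene_ids:
        col_rows = dense.indices[dense.indptr[pos[g]] : dense.indptr[pos[g] + 1]]
        covered = set(eco[col_rows])
        missing = set(eco) - covered
        if missing:
            raise CatalogError(
                f"conserved gene {g} absent from ecologies {sorted(missing)}"
            )

    cs = pm.col_sums()
    frac = float((cs == 1).sum() / pm.n_genes)
    if abs(frac - truth.singleton_fraction_realized) > 1e-12:
        raise CatalogError("recorded singleton fraction does not match matrix")

    groups = dict(zip(st.df["sample_id"], st.df["ecology_group"]))
    if groups != truth.group_labels:
        raise CatalogError("group labels do not match sample table")


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Plain-text serialization: scalar key/value lines then [set] listings."""
    with open(path, "w") as fh:
        fh.write(
            f"singleton_fraction_realized\t{truth.singleton_fraction_realized:.10g}\n"
        )
        fh.write("[conserved]\n")
        fh.writelines(f"{g}\n" for g in sorted(truth.conserved_gene_ids))
        for grp in sorted(truth.core_gene_ids):
            fh.write(f"[core\t{grp}]\n")
            fh.writelines(f"{g}\n" for g in sorted(truth.core_gene_ids[grp]))
        for eco in sorted(truth.specific_gene_ids):
            fh.write(f"[specific\t{eco}]\n")
            fh.writelines(f"{g}\n" for g in sorted(truth.specific_gene_ids[eco]))
        fh.write("[group_labels]\n")
        fh.writelines(
            f"{s}\t{g}\n" for s, g in sorted(truth.group_labels.items())
        )
        for ecos, genes in truth.enriched_contrasts:
            fh.write(f"[contrast\t{','.join(sorted(ecos))}]\n")
            fh.writelines(f"{g}\n" for g in sorted(genes))


def read_ground_truth(path) -> GroundTruth:
    frac = 0.0
    conserved: set = set()
    core: dict = {}
    specific: dict = {}
    group_labels: dict = {}
    contrasts: list = []
    section: tuple | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                parts = line[1:-1].split("\t")
                section = tuple(parts)
                if parts[0] == "core":
                    core[parts[1]] = set()
                elif parts[0] == "specific":
                    specific[parts[1]] = set()
                elif parts[0] == "contrast":
                    contrasts.append((frozenset(parts[1].split(",")), set()))
                continue
            if section is None:
                key, val = line.split("\t")
                if key == "singleton_fraction_realized":
                    frac = float(val)
            elif section[0] == "conserved":
                conserved.add(line)
            elif section[0] == "core":
                core[section[1]].add(line)
            elif section[0] == "specific":
                specific[section[1]].add(line)
            elif section[0] == "group_labels":
                s, g = line.split("\t")
                group_labels[s] = g
            elif section[0] == "contrast":
                contrasts[-1][1].add(line)
    return GroundTruth(
        conserved_gene_ids=conserved,
        core_gene_ids=core,
        specific_gene_ids=specific,
        singleton_fraction_realized=frac,
        group_labels=group_labels,
        enriched_contrasts=[(e, frozenset(g)) for e, g in contrasts],
    )
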
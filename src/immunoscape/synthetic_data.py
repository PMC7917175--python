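"""Synthetic paired tumor cohorts with planted immune structure.

The generator emulates the kind of data the pipeline consumes from consortium
cohorts: an immune-gene FPKM expression matrix with k planted subtypes
(equidistant centroids in log space) and block-correlated gene modules,
subtype-dependent exponential survival with independent exponential censoring,
subtype-dependent Poisson mutation burden, antigen-presenting-cell
infiltration scores driven by planted antigen genes, tumor purity, and a
matched normal-tissue expression matrix for differential expression.  A
validation cohort can be drawn from the same model parameters so cross-cohort
reproducibility is testable.

Everything is deterministic given the integer seed: all substreams are spawned
from one ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_core import ExpressionMatrix, MutationCatalog, SignatureSet, RAW_FPKM

VARIANT_CLASSES = ("Missense_Mutation", "Nonsense_Mutation",
                   "Frame_Shift_Del", "Splice_Site")
VARIANT_PROBS = (0.7, 0.12, 0.1, 0.08)

APC_CELL_TYPES = ("macrophage", "dendritic_cell", "b_cell")
OTHER_CELL_TYPES = ("cd8_t_cell", "nk_cell")


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort pair.

    Sizes default to the discovery/validation cohort sizes of the motivating
    pancreatic-adenocarcinoma study (239 / 103 patients); separation and
    effect sizes default to the well-separated regime the pipeline's
    recovery guarantees are stated under.
    """

    n_samples: int = 239
    n_validation: int = 103
    n_genes: int = 500
    n_subtypes: int = 5
    subtype_proportions: tuple[float, ...] | None = None
    delta: float = 5.0              # centroid separation, units of noise SD
    noise_sd: float = 1.0
    baseline_log_range: tuple[float, float] = (2.0, 8.0)

    # gene modules (disjoint index blocks after the antigen genes)
    module_sizes: tuple[int, ...] = (60, 50, 40, 30)
    module_loading: float = 1.5     # factor loading, log2 units
    module_subtype_effect: float = 2.0  # shift of module factor mean by subtype

    # planted vaccine-antigen genes
    n_antigen_genes: int = 6
    antigen_log2fc: float = 2.0     # tumor-vs-normal offset, log2 units
    antigen_log_hazard: float = 0.7  # per-SD adverse effect of each antigen gene
    antigen_shared_loading: float = 1.0  # co-regulation of antigen genes, log2 units
    include_favorable_gene: bool = True
    favorable_log_hazard: float = -1.2
    antigen_extra_mutation_rate: float = 0.3  # per-sample mutation probability

    # survival
    baseline_hazard: float = 1 / 500.0   # events per day
    log_hazard_by_subtype: tuple[float, ...] = (-0.7, -0.4, 0.6, 0.2, 0.3)
    prognostic_module: int | None = 0
    module_log_hazard: float = 0.4
    censoring_rate: float = 0.3
    rfs_hazard_multiplier: float = 1.5
    rfs_missing_rate: float = 0.05

    # mutation burden (higher in the immunologically cold subtypes)
    tmb_mean_by_subtype: tuple[float, ...] = (30.0, 35.0, 40.0, 80.0, 90.0)

    # infiltration / purity
    apc_loading: float = 0.6
    apc_noise_sd: float = 0.4
    purity_effect: float = -0.2

    # normal tissue & near-silent genes (exercise FPKM preprocessing)
    n_normal: int = 50
    n_dropout_genes: int = 10
    dropout_log_mean: float = -1.5

    def __post_init__(self) -> None:
        if self.n_subtypes < 2:
            raise ValueError("k (n_subtypes) must be >= 2")
        k = self.n_subtypes
        if self.subtype_proportions is not None:
            if len(self.subtype_proportions) != k:
                raise ValueError("subtype_proportions length must equal n_subtypes")
            if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
                raise ValueError("subtype_proportions must sum to 1")
        if len(self.log_hazard_by_subtype) != k:
            raise ValueError("log_hazard_by_subtype length must equal n_subtypes")
        if len(self.tmb_mean_by_subtype) != k:
            raise ValueError("tmb_mean_by_subtype length must equal n_subtypes")
        if any(m <= 0 for m in self.tmb_mean_by_subtype):
            raise ValueError("TMB means must be positive")
        n_structured = (self.n_antigen_genes + int(self.include_favorable_gene)
                        + sum(self.module_sizes))
        if n_structured > self.n_genes:
            raise ValueError(
                f"module and antigen genes ({n_structured}) exceed n_genes ({self.n_genes})"
            )
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.prognostic_module is not None and self.module_sizes:
            if not 0 <= self.prognostic_module < len(self.module_sizes):
                raise ValueError("prognostic_module out of range")


@dataclass
class PlantedTruth:
    """Ground truth recorded alongside a generated cohort."""

    subtype_label: pd.Series                      # sample -> 1..k
    module_assignment: dict[str, str]             # gene -> "M1".. or "background"
    prognostic_genes: list[tuple[str, str]]       # (gene, "adverse"/"favorable")
    log_hazard_by_subtype: dict[int, float]
    tmb_mean_by_subtype: dict[int, float]
    antigen_genes: list[str] = field(default_factory=list)
    favorable_gene: str | None = None


@dataclass
class CohortBundle:
    expression: ExpressionMatrix          # raw_fpkm, genes x samples
    clinical: pd.DataFrame                # indexed by sample_id
    mutations: MutationCatalog
    infiltration: pd.DataFrame            # samples x cell types
    purity: pd.Series                     # sample -> (0, 1]
    truth: PlantedTruth
    normal_expression: ExpressionMatrix | None = None

    def __post_init__(self) -> None:
        samples = set(self.expression.sample_ids)
        for name, ids in (
            ("clinical", set(self.clinical.index)),
            ("infiltration", set(self.infiltration.index)),
            ("purity", set(self.purity.index)),
            ("truth labels", set(self.truth.subtype_label.index)),
        ):
            if ids != samples:
                raise ValueError(f"{name} sample ids do not match expression")


@dataclass
class _ModelParams:
    """Cohort-independent model parameters shared by paired cohorts."""

    gene_ids: list[str]
    mu: np.ndarray                 # baseline log2 expression per gene
    centroids: np.ndarray          # genes x k, row-centered, equidistant
    module_genes: dict[str, np.ndarray]   # module -> gene indices
    module_pattern: np.ndarray     # modules x k factor-mean pattern
    antigen_idx: np.ndarray
    favorable_idx: int | None
    marker_idx: np.ndarray         # genes carrying the subtype centroids
    background_idx: np.ndarray     # pure-noise genes (no subtype signal)
    dropout_ids: list[str]


def _allocate_subtypes(n: int, k: int, proportions, rng: np.random.Generator):
    props = np.full(k, 1.0 / k) if proportions is None else np.asarray(proportions)
    base = np.floor(n * props).astype(int)
    frac = n * props - base
    for i in np.argsort(-frac, kind="stable")[: n - base.sum()]:
        base[i] += 1
    labels = np.repeat(np.arange(1, k + 1), base)
    return labels[rng.permutation(n)]


def _draw_model(cfg: GeneratorConfig, rng: np.random.Generator) -> _ModelParams:
    g, k = cfg.n_genes, cfg.n_subtypes
    gene_ids = [f"G{i + 1:04d}" for i in range(g)]
    mu = rng.uniform(*cfg.baseline_log_range, size=g)

    pos = cfg.n_antigen_genes + int(cfg.include_favorable_gene)
    antigen_idx = np.arange(cfg.n_antigen_genes)
    favorable_idx = cfg.n_antigen_genes if cfg.include_favorable_gene else None
    module_genes: dict[str, np.ndarray] = {}
    for m, size in enumerate(cfg.module_sizes):
        module_genes[f"M{m + 1}"] = np.arange(pos, pos + size)
        pos += size
    # remaining genes split evenly into subtype markers and pure background
    free = np.arange(pos, g)
    n_marker = (free.size + 1) // 2
    marker_idx = free[:n_marker]
    background_idx = free[n_marker:]
    if n_marker < k:
        raise ValueError(
            f"too few free genes ({free.size}) to plant {k} subtype centroids")

    # equidistant subtype centroids supported on the marker genes: scaled
    # orthonormal directions, so every pair of subtypes is separated by
    # exactly delta noise-SDs per gene (RMS over the full gene universe)
    q, _ = np.linalg.qr(rng.standard_normal((n_marker, k)))
    scale = cfg.delta * cfg.noise_sd * np.sqrt(g) / np.sqrt(2.0)
    centroids = np.zeros((g, k))
    centroids[marker_idx] = scale * q[:, :k]
    centroids -= centroids.mean(axis=1, keepdims=True)  # no tumor-vs-normal shift

    module_pattern = rng.standard_normal((len(cfg.module_sizes), k))
    if k > 1:  # no net tumor-vs-normal shift from module factors
        module_pattern -= module_pattern.mean(axis=1, keepdims=True)
    dropout_ids = [f"G{g + i + 1:04d}" for i in range(cfg.n_dropout_genes)]
    return _ModelParams(gene_ids=gene_ids, mu=mu, centroids=centroids,
                        module_genes=module_genes, module_pattern=module_pattern,
                        antigen_idx=antigen_idx, favorable_idx=favorable_idx,
                        marker_idx=marker_idx, background_idx=background_idx,
                        dropout_ids=dropout_ids)


def _calibrate_censoring(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with mean P(censor) = c/(c+h) = target."""
    if target <= 0:
        return 0.0

    def mean_censored(log_c):
        c = np.exp(log_c)
        return float(np.mean(c / (c + hazards))) - target

    return float(np.exp(brentq(mean_censored, -30.0, 10.0)))


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def _sample_cohort(cfg: GeneratorConfig, model: _ModelParams, n: int,
                   prefix: str, ss: np.random.SeedSequence) -> CohortBundle:
    streams = [np.random.default_rng(s) for s in ss.spawn(8)]
    (rng_alloc, rng_expr, rng_surv, rng_mut, rng_inf,
     rng_clin, rng_norm, rng_drop) = streams
    k = cfg.n_subtypes
    sample_ids = [f"{prefix}{i + 1:03d}" for i in range(n)]
    subtype = _allocate_subtypes(n, k, cfg.subtype_proportions, rng_alloc)

    # --- expression (log2 space, then to FPKM) ---
    g = cfg.n_genes
    x = model.mu[:, None] + model.centroids[:, subtype - 1]
    if model.antigen_idx.size:
        x[model.antigen_idx] += cfg.antigen_log2fc
        # planted antigens are co-regulated: one shared latent program
        shared = rng_expr.standard_normal(n)
        x[model.antigen_idx] += cfg.antigen_shared_loading * shared
    if model.favorable_idx is not None:
        x[model.favorable_idx] += cfg.antigen_log2fc
    factors = np.zeros((len(cfg.module_sizes), n))
    for m, (name, idx) in enumerate(model.module_genes.items()):
        f = (cfg.module_subtype_effect * model.module_pattern[m, subtype - 1]
             + rng_expr.standard_normal(n))
        factors[m] = f
        x[idx] += cfg.module_loading * f
    x += cfg.noise_sd * rng_expr.standard_normal((g, n))

    # near-silent genes exercising the zero-FPKM filter
    x_drop = (cfg.dropout_log_mean
              + rng_drop.standard_normal((cfg.n_dropout_genes, n)))
    full = np.vstack([x, x_drop]) if cfg.n_dropout_genes else x
    fpkm = np.maximum(np.exp2(full) - 1.0, 0.0)
    gene_ids = model.gene_ids + model.dropout_ids
    expression = ExpressionMatrix(
        values=pd.DataFrame(fpkm, index=gene_ids, columns=sample_ids),
        scale_tag=RAW_FPKM,
    )

    # --- survival ---
    loghaz = np.asarray(cfg.log_hazard_by_subtype)[subtype - 1].astype(float)
    for i in model.antigen_idx:
        loghaz += cfg.antigen_log_hazard * _zscore(x[i])
    if model.favorable_idx is not None:
        loghaz += cfg.favorable_log_hazard * _zscore(x[model.favorable_idx])
    if cfg.prognostic_module is not None and len(cfg.module_sizes):
        loghaz += cfg.module_log_hazard * _zscore(factors[cfg.prognostic_module])
    hazards = cfg.baseline_hazard * np.exp(loghaz)
    t_event = rng_surv.exponential(1.0 / hazards)
    c_rate = _calibrate_censoring(hazards, cfg.censoring_rate)
    if c_rate > 0:
        t_cens = rng_surv.exponential(1.0 / c_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    os_time = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)

    rfs_haz = hazards * cfg.rfs_hazard_multiplier
    t_rel = rng_surv.exponential(1.0 / rfs_haz)
    c_rfs = _calibrate_censoring(rfs_haz, cfg.censoring_rate)
    t_rcens = rng_surv.exponential(1.0 / c_rfs, size=n) if c_rfs > 0 else np.full(n, np.inf)
    rfs_time = np.minimum(t_rel, t_rcens)
    rfs_event = (t_rel <= t_rcens).astype(float)
    miss = rng_surv.random(n) < cfg.rfs_missing_rate
    rfs_time[miss], rfs_event[miss] = np.nan, np.nan

    # ordinal stage/grade loosely tracking subtype aggressiveness
    st_raw = 2.5 + 0.6 * np.asarray(cfg.log_hazard_by_subtype)[subtype - 1]
    stage = np.clip(np.round(st_raw + 0.9 * rng_clin.standard_normal(n)), 1, 4)
    grade = np.clip(np.round(st_raw + 1.1 * rng_clin.standard_normal(n)), 1, 4)
    for arr in (stage, grade):
        arr[rng_clin.random(n) < 0.05] = np.nan

    clinical = pd.DataFrame(
        {
            "os_time": np.round(os_time, 1), "os_event": os_event,
            "rfs_time": np.round(rfs_time, 1), "rfs_event": rfs_event,
            "stage": stage, "grade": grade,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # --- mutations ---
    tmb_mean = np.asarray(cfg.tmb_mean_by_subtype)[subtype - 1]
    records = []
    antigen_ids = [model.gene_ids[i] for i in model.antigen_idx]
    if model.favorable_idx is not None:
        antigen_ids_all = antigen_ids + [model.gene_ids[model.favorable_idx]]
    else:
        antigen_ids_all = list(antigen_ids)
    for s_i, sid in enumerate(sample_ids):
        count = min(int(rng_mut.poisson(tmb_mean[s_i])), g)
        genes = rng_mut.choice(g, size=count, replace=False)
        hit = {model.gene_ids[j] for j in genes}
        for gene in antigen_ids_all:
            if gene not in hit and rng_mut.random() < cfg.antigen_extra_mutation_rate:
                hit.add(gene)
        classes = rng_mut.choice(VARIANT_CLASSES, size=len(hit), p=VARIANT_PROBS)
        for gene, vc in zip(sorted(hit), classes):
            records.append((sid, gene, vc))
    rec_df = pd.DataFrame(records, columns=["sample_id", "gene_id", "variant_class"])
    agf = np.clip(tmb_mean / (2.0 * max(cfg.tmb_mean_by_subtype))
                  + 0.05 * rng_mut.standard_normal(n), 0.0, 1.0)
    mutations = MutationCatalog(
        records=rec_df,
        altered_genome_fraction=pd.Series(agf, index=sample_ids, name="agf"),
    )

    # --- purity and infiltration ---
    purity = pd.Series(np.clip(rng_inf.beta(8, 3, size=n), 0.05, 1.0),
                       index=sample_ids, name="purity")
    antigen_z = np.vstack([_zscore(x[i]) for i in model.antigen_idx]) \
        if model.antigen_idx.size else np.zeros((1, n))
    apc_driver = _zscore(antigen_z.mean(axis=0))
    purity_z = _zscore(purity.to_numpy())
    cold = _zscore(np.asarray(cfg.log_hazard_by_subtype)[subtype - 1])
    inf = {}
    for ct in APC_CELL_TYPES:
        inf[ct] = (cfg.apc_loading * apc_driver + cfg.purity_effect * purity_z
                   + cfg.apc_noise_sd * rng_inf.standard_normal(n))
    for ct in OTHER_CELL_TYPES:
        inf[ct] = (-0.5 * cold + cfg.purity_effect * purity_z
                   + cfg.apc_noise_sd * rng_inf.standard_normal(n))
    infiltration = pd.DataFrame(inf, index=pd.Index(sample_ids, name="sample_id"))

    # --- matched normal tissue (baseline expression, no tumor structure) ---
    normal = None
    if cfg.n_normal > 0:
        xn = (model.mu[:, None]
              + cfg.noise_sd * rng_norm.standard_normal((g, cfg.n_normal)))
        xn_drop = (cfg.dropout_log_mean
                   + rng_norm.standard_normal((cfg.n_dropout_genes, cfg.n_normal)))
        fn = np.maximum(np.exp2(np.vstack([xn, xn_drop]) if cfg.n_dropout_genes else xn) - 1.0, 0.0)
        normal_ids = [f"{prefix}N{i + 1:03d}" for i in range(cfg.n_normal)]
        normal = ExpressionMatrix(
            values=pd.DataFrame(fn, index=gene_ids, columns=normal_ids),
            scale_tag=RAW_FPKM,
        )

    module_assignment = {gid: "background" for gid in gene_ids}
    for name, idx in model.module_genes.items():
        for i in idx:
            module_assignment[model.gene_ids[i]] = name
    prognostic = [(gid, "adverse") for gid in antigen_ids]
    favorable_gene = None
    if model.favorable_idx is not None:
        favorable_gene = model.gene_ids[model.favorable_idx]
        prognostic.append((favorable_gene, "favorable"))
    truth = PlantedTruth(
        subtype_label=pd.Series(subtype, index=sample_ids, name="subtype"),
        module_assignment=module_assignment,
        prognostic_genes=prognostic,
        log_hazard_by_subtype={i + 1: float(v)
                               for i, v in enumerate(cfg.log_hazard_by_subtype)},
        tmb_mean_by_subtype={i + 1: float(v)
                             for i, v in enumerate(cfg.tmb_mean_by_subtype)},
        antigen_genes=antigen_ids,
        favorable_gene=favorable_gene,
    )
    return CohortBundle(expression=expression, clinical=clinical,
                        mutations=mutations, infiltration=infiltration,
                        purity=purity, truth=truth, normal_expression=normal)


def generate_cohort(cfg: GeneratorConfig, seed: int) -> CohortBundle:
    """Generate one discovery cohort; bit-identical for identical seeds."""
    root = np.random.SeedSequence(seed)
    model_ss, cohort_ss, _ = root.spawn(3)
    model = _draw_model(cfg, np.random.default_rng(model_ss))
    return _sample_cohort(cfg, model, cfg.n_samples, "S", cohort_ss)


def generate_paired_cohorts(cfg: GeneratorConfig, seed: int) -> tuple[CohortBundle, CohortBundle]:
    """Discovery and independent validation cohorts from the same model."""
    root = np.random.SeedSequence(seed)
    model_ss, disc_ss, valid_ss = root.spawn(3)
    model = _draw_model(cfg, np.random.default_rng(model_ss))
    disc = _sample_cohort(cfg, model, cfg.n_samples, "S", disc_ss)
    valid = _sample_cohort(cfg, model, cfg.n_validation, "V", valid_ss)
    return disc, valid


def generate_signature_sets(
    cfg: GeneratorConfig,
    seed: int,
    n_null: int = 5,
    set_size: int = 30,
    aligned_overlap: float = 0.9,
) -> SignatureSet:
    """Gene sets emulating curated immune signatures.

    One "aligned" set per planted module (>= ``aligned_overlap`` of its genes
    drawn from the module, remainder from background) and ``n_null`` sets
    drawn uniformly from background genes.
    """
    root = np.random.SeedSequence(seed)
    model_ss, _, _ = root.spawn(3)
    model = _draw_model(cfg, np.random.default_rng(model_ss))
    rng = np.random.default_rng(root.spawn(1)[0].entropy % (2**32))
    background = [int(i) for i in model.background_idx]
    if set_size > cfg.n_genes:
        raise ValueError("set_size exceeds gene universe")
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    for name, idx in model.module_genes.items():
        n_in = min(int(np.ceil(aligned_overlap * set_size)), idx.size)
        n_out = set_size - n_in
        chosen = list(rng.choice(idx, size=n_in, replace=False))
        if n_out > 0:
            chosen += list(rng.choice(background, size=n_out, replace=False))
        sets[f"aligned_{name}"] = [model.gene_ids[i] for i in chosen]
        desc[f"aligned_{name}"] = f"signature aligned with module {name}"
    for j in range(n_null):
        chosen = rng.choice(background, size=min(set_size, len(background)),
                            replace=False)
        sets[f"null_{j + 1}"] = [model.gene_ids[i] for i in chosen]
        desc[f"null_{j + 1}"] = "background (null) signature"
    return SignatureSet(sets=sets, descriptions=desc)


def config_to_dict(cfg: GeneratorConfig) -> dict:
    return asdict(cfg)
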
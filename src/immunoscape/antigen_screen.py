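"""Vaccine-antigen nomination funnel.

Candidate antigens are genes that are (1) overexpressed in tumor versus
normal (|log2FC| > 1, BH q < 0.01, up-regulated), (2) somatically mutated,
(3) adverse for overall survival (median-split log-rank p < 0.05 with the
high-expression arm worse), (4) likewise for relapse-free survival, and
(5) positively correlated with infiltration of at least one
antigen-presenting cell type after tumor-purity adjustment (partial Spearman,
p < 0.05).  Genes that are significantly *favorable* (HR < 1) are excluded
from the candidate list and reported separately.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ExpressionMatrix, MutationCatalog
from .survival_stats import bh_fdr, cox_ph, logrank_test, median_split

logger = logging.getLogger(__name__)

DEFAULT_APC_TYPES = ("macrophage", "dendritic_cell", "b_cell")

FUNNEL_STAGES = ("overexpressed", "mutated", "os_adverse", "rfs_adverse",
                 "apc_correlated")


@dataclass
class ScreenThresholds:
    log2fc_min: float = 1.0
    de_q_max: float = 0.01
    mutation_freq_min: float = 0.0   # strict ">": mutated in >= 1 sample
    survival_p_max: float = 0.05
    correlation_p_max: float = 0.05
    apc_cell_types: tuple[str, ...] = DEFAULT_APC_TYPES


@dataclass
class ScreenResult:
    table: pd.DataFrame              # per gene: stage flags + final_candidate
    funnel_counts: dict[str, int]
    candidates: list[str]
    favorable: list[str]
    warnings: list[str] = field(default_factory=list)


def differential_expression(
    tumor: ExpressionMatrix,
    normal: ExpressionMatrix,
    log2fc_min: float = 1.0,
    q_max: float = 0.01,
) -> pd.DataFrame:
    """Tumor-vs-normal differential expression on log2(FPKM+1) scale.

    log2FC is the difference of group means on the log scale; p comes from
    one-way ANOVA (for two groups, identical to the equal-variance t-test);
    q is BH.  ``flag_overexpressed`` requires log2FC > ``log2fc_min`` (the
    magnitude screen is two-sided but antigens must be up-regulated) and
    q < ``q_max``.
    """
    if tumor.scale_tag != "log2p1" or normal.scale_tag != "log2p1":
        raise ValueError("differential_expression expects log2p1 matrices")
    shared = [g for g in tumor.gene_ids if g in set(normal.gene_ids)]
    if not shared:
        raise ValueError("tumor and normal share no genes")
    if tumor.shape[1] < 2 or normal.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")
    t = tumor.values.loc[shared].to_numpy()
    c = normal.values.loc[shared].to_numpy()
    log2fc = t.mean(axis=1) - c.mean(axis=1)
    f, p = stats.f_oneway(t, c, axis=1)
    p = np.where(np.isfinite(p), p, 1.0)
    q = bh_fdr(p)
    table = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "q": q},
        index=pd.Index(shared, name="gene_id"),
    )
    table["flag_overexpressed"] = (table["log2fc"] > log2fc_min) & (table["q"] < q_max)
    return table


def mutation_summary(
    cat: MutationCatalog,
    samples: list[str],
    top_k: int = 10,
) -> dict:
    """Per-gene mutated-sample frequencies and per-sample mutation counts.

    Samples absent from the catalog count zero; an empty catalog yields
    all-zero tables with a warning.  Top-K lists break frequency ties
    alphabetically.
    """
    if not samples:
        raise ValueError("sample list is empty")
    rec = cat.records[cat.records["sample_id"].isin(samples)]
    if rec.empty:
        warnings.warn("no mutation records for the given samples", stacklevel=2)
    per_sample = (
        rec.groupby("sample_id").size()
        .reindex(samples, fill_value=0).astype(int)
    )
    per_sample.name = "mutation_count"
    mutated = rec.drop_duplicates(["sample_id", "gene_id"])
    freq = (mutated.groupby("gene_id").size() / len(samples)).sort_index()
    freq.name = "frequency"
    ordered = freq.sort_values(ascending=False, kind="stable")
    # stable sort on alphabetical index then by -frequency => alphabetical ties
    top_by_freq = list(ordered.index[:top_k])
    top_by_count = list(
        per_sample.sort_values(ascending=False, kind="stable").index[:top_k]
    )
    return {
        "gene_frequency": freq,
        "sample_counts": per_sample,
        "top_genes_by_frequency": top_by_freq,
        "top_samples_by_count": top_by_count,
    }


def purity_adjusted_spearman(x, y, purity) -> tuple[float, float]:
    """Partial Spearman correlation of x and y given tumor purity.

    All three vectors are rank-transformed; the partial Pearson correlation
    of the ranks controls for purity.  p uses the t approximation with n - 3
    degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    purity = np.asarray(purity, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("need n >= 5")
    if y.size != n or purity.size != n:
        raise ValueError("length mismatch")
    if (purity <= 0).any() or (purity > 1).any():
        raise ValueError("purity must lie in (0, 1]")
    for name, v in (("x", x), ("y", y), ("purity", purity)):
        if np.ptp(v) == 0:
            raise ValueError(f"constant input vector {name!r}")
    rx, ry, rz = (stats.rankdata(v) for v in (x, y, purity))
    r = np.corrcoef(np.vstack([rx, ry, rz]))
    rxy, rxz, ryz = r[0, 1], r[0, 2], r[1, 2]
    denom = np.sqrt((1 - rxz**2) * (1 - ryz**2))
    rho = (rxy - rxz * ryz) / denom if denom > 0 else 0.0
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - 3
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1 - rho**2))
    return rho, float(2 * stats.t.sf(abs(t), df))


def screen_antigens(
    de: pd.DataFrame,
    mutation_freq: pd.Series,
    clinical: pd.DataFrame,
    expr: ExpressionMatrix,
    infiltration: pd.DataFrame,
    purity: pd.Series,
    thresholds: ScreenThresholds | None = None,
) -> ScreenResult:
    """Run the five-stage antigen funnel and intersect the flags.

    Stages are evaluated lazily: survival and correlation statistics are only
    computed for genes surviving the preceding stages, so funnel counts are
    non-increasing by construction.  Missing RFS columns skip stage 4 with a
    recorded warning.
    """
    th = thresholds or ScreenThresholds()
    warn_log: list[str] = []
    genes = list(de.index)
    samples = [s for s in expr.sample_ids if s in clinical.index]
    if not samples:
        raise ValueError("no samples shared between expression and clinical")
    flags = pd.DataFrame(False, index=pd.Index(genes, name="gene_id"),
                         columns=list(FUNNEL_STAGES))
    hr_dir = pd.Series(np.nan, index=flags.index, name="os_hr")

    flags["overexpressed"] = de["flag_overexpressed"].reindex(genes, fill_value=False)
    freq = mutation_freq.reindex(genes, fill_value=0.0)
    flags["mutated"] = flags["overexpressed"] & (freq > th.mutation_freq_min)

    os_t = clinical.loc[samples, "os_time"].to_numpy(dtype=float)
    os_e = clinical.loc[samples, "os_event"].to_numpy(dtype=float)
    has_rfs = ("rfs_time" in clinical.columns
               and clinical.loc[samples, "rfs_time"].notna().any())
    if not has_rfs:
        msg = "RFS columns missing/empty: stage 'rfs_adverse' skipped"
        warn_log.append(msg)
        logger.warning(msg)
    if has_rfs:
        rfs_ok = clinical.loc[samples, ["rfs_time", "rfs_event"]].notna().all(axis=1)
        rfs_samples = list(np.asarray(samples)[rfs_ok.to_numpy()])
        rfs_t = clinical.loc[rfs_samples, "rfs_time"].to_numpy(dtype=float)
        rfs_e = clinical.loc[rfs_samples, "rfs_event"].to_numpy(dtype=float)

    favorable: list[str] = []
    vals = expr.values
    for gene in flags.index[flags["mutated"]]:
        gexp = vals.loc[gene, samples].to_numpy(dtype=float)
        try:
            grp = median_split(gexp)
        except ValueError:
            continue
        _, p = logrank_test(os_t, os_e, grp)
        hr = _median_split_hr(os_t, os_e, grp)
        hr_dir.loc[gene] = hr
        if p < th.survival_p_max:
            if hr > 1:
                flags.loc[gene, "os_adverse"] = True
            else:
                favorable.append(gene)
    if has_rfs:
        for gene in flags.index[flags["os_adverse"]]:
            gexp = vals.loc[gene, rfs_samples].to_numpy(dtype=float)
            try:
                grp = median_split(gexp)
            except ValueError:
                continue
            _, p = logrank_test(rfs_t, rfs_e, grp)
            if p < th.survival_p_max and _median_split_hr(rfs_t, rfs_e, grp) > 1:
                flags.loc[gene, "rfs_adverse"] = True
    else:
        flags["rfs_adverse"] = flags["os_adverse"]

    apc_cols = [c for c in th.apc_cell_types if c in infiltration.columns]
    if not apc_cols:
        raise ValueError("no configured APC cell types present in infiltration table")
    pur = purity.loc[samples].to_numpy(dtype=float)
    for gene in flags.index[flags["rfs_adverse"]]:
        gexp = vals.loc[gene, samples].to_numpy(dtype=float)
        for ct in apc_cols:
            score = infiltration.loc[samples, ct].to_numpy(dtype=float)
            rho, p = purity_adjusted_spearman(gexp, score, pur)
            if rho > 0 and p < th.correlation_p_max:
                flags.loc[gene, "apc_correlated"] = True
                break

    flags["final_candidate"] = flags[list(FUNNEL_STAGES)].all(axis=1)
    funnel = {stage: int(flags[stage].sum()) for stage in FUNNEL_STAGES}
    funnel["final_candidate"] = int(flags["final_candidate"].sum())
    table = flags.copy()
    table["os_hr_direction"] = hr_dir
    return ScreenResult(
        table=table,
        funnel_counts=funnel,
        candidates=sorted(flags.index[flags["final_candidate"]]),
        favorable=sorted(favorable),
        warnings=warn_log,
    )


def _median_split_hr(times, events, grp) -> float:
    """Cox hazard ratio of the high- vs low-expression arm (> 1 = worse)."""
    indicator = (grp == "high").astype(float)
    try:
        fit = cox_ph(indicator.reshape(-1, 1), times, events)
    except ValueError:
        # fall back to a rate ratio if the Cox fit degenerates
        hi = grp == "high"
        num = events[hi].sum() / max(times[hi].sum(), 1e-12)
        den = events[~hi].sum() / max(times[~hi].sum(), 1e-12)
        return num / den if den > 0 else np.inf
    return fit.fits[0].hr
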
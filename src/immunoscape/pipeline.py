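"""End-to-end orchestration with one config, one seed and provenance.

Stages run in a fixed order (simulate/load -> preprocess -> screen ->
cluster -> validate -> score -> modules -> landscape -> prognosis); each
stage writes TSV outputs into the output directory, and a provenance record
(canonical config hash, seed, stages run and skipped, SHA-256 of every
output file) is written as ``provenance.json``.  Outputs carry no
timestamps, so identical config + seed reproduces byte-identical files;
wall-clock timing goes to the log only.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_core
from .antigen_screen import (ScreenThresholds, differential_expression,
                             mutation_summary, screen_antigens)
from .coexpression import (CoexpressionParams, adjacency_matrix, detect_modules,
                           module_eigengenes, module_prognosis,
                           soft_threshold_scan, tom_matrix)
from .consensus_cluster import run_consensus
from .io_core import preprocess_expression
from .landscape import (branch_subsets, component_correlations, ddrtree_embed,
                        extreme_location_groups)
from .ssgsea import group_differential, ssgsea_scores
from .subtype_validation import in_group_proportion, subtype_centroids
from .survival_stats import cox_ph, multigroup_logrank
from .synthetic_data import (GeneratorConfig, generate_paired_cohorts,
                             generate_signature_sets)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "preprocess", "screen", "cluster", "validate",
              "score", "modules", "landscape", "prognosis")

STAGE_REQUIRES = {
    "preprocess": ("simulate",),
    "screen": ("preprocess",),
    "cluster": ("preprocess",),
    "validate": ("cluster",),
    "score": ("cluster",),
    "modules": ("cluster",),
    "landscape": ("score",),
    "prognosis": ("cluster",),
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage, partial outputs remain."""


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "immunoscape_out"
    stages: tuple[str, ...] = ALL_STAGES
    generator: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)     # optional file paths
    de: dict = field(default_factory=lambda: {"log2fc_min": 1.0, "q_max": 0.01})
    consensus: dict = field(default_factory=lambda: {
        "k_range": [2, 8], "B": 100, "frac": 0.8, "delta_threshold": 0.05,
        "k_override": None, "final_method": "pam"})
    ssgsea: dict = field(default_factory=lambda: {
        "alpha": 0.25, "n_null": 5, "set_size": 30})
    coexpression: dict = field(default_factory=dict)
    landscape: dict = field(default_factory=lambda: {
        "q": 2, "K": None, "lam": 1.0, "gamma": 10.0})

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        for st in self.stages:
            missing = [r for r in STAGE_REQUIRES.get(st, ())
                       if r not in self.stages]
            if missing:
                raise ValueError(f"stage {st!r} requires {missing}")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        for key, path in self.inputs.items():
            if path is not None and not Path(path).exists():
                raise ValueError(f"input {key!r}: path {path!r} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and return the report index.

    The report maps stage -> in-memory results and lists every file written;
    the same information lands in ``report.json`` / ``provenance.json``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("immunoscape")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    state: dict = {}
    written: list[Path] = []
    ran: list[str] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        _write_tsv(df, path)
        written.append(path)

    def run_stage(name, fn):
        if name not in config.stages:
            return
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as e:  # noqa: BLE001 - stage name must surface
            raise PipelineError(f"stage {name!r} failed: {e}") from e
        ran.append(name)
        logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)

    # ------------------------------------------------------------------ stages
    def simulate():
        if config.inputs.get("expression"):
            expr = io_core.read_expression(config.inputs["expression"])
            state["expr_raw"] = expr
            state["clinical"] = io_core.read_clinical(config.inputs["clinical"])
            state["mutations"] = io_core.read_mutations(config.inputs["mutations"])
            state["infiltration"] = io_core.read_score_table(config.inputs["infiltration"])
            purity = io_core.read_score_table(config.inputs["purity"])
            state["purity"] = purity.iloc[:, 0]
            if config.inputs.get("normal_expression"):
                state["normal_raw"] = io_core.read_expression(
                    config.inputs["normal_expression"])
            state["synthetic"] = False
        else:
            gen_cfg = GeneratorConfig(**config.generator)
            disc, valid = generate_paired_cohorts(gen_cfg, config.seed)
            state.update(
                expr_raw=disc.expression, clinical=disc.clinical,
                mutations=disc.mutations, infiltration=disc.infiltration,
                purity=disc.purity, normal_raw=disc.normal_expression,
                truth=disc.truth, valid_bundle=valid, gen_cfg=gen_cfg,
                synthetic=True,
            )
            io_core.write_clinical(disc.clinical, outdir / "clinical.tsv")
            written.append(outdir / "clinical.tsv")
            with open(outdir / "generator_config.yaml", "w") as fh:
                yaml.safe_dump(asdict(gen_cfg), fh, sort_keys=True)
            written.append(outdir / "generator_config.yaml")
        logger.info("cohort: %d genes x %d samples",
                    *state["expr_raw"].shape)

    def preprocess():
        state["expr"] = preprocess_expression(state["expr_raw"])
        if state.get("normal_raw") is not None:
            state["normal"] = preprocess_expression(state["normal_raw"])
        if state.get("valid_bundle") is not None:
            state["valid_expr"] = preprocess_expression(
                state["valid_bundle"].expression)
        logger.info("preprocessed: %d genes retained", state["expr"].shape[0])

    def screen():
        if state.get("normal") is None:
            raise ValueError("screen stage needs a normal-tissue expression matrix")
        de = differential_expression(state["expr"], state["normal"],
                                     **config.de)
        emit(de, "differential_expression.tsv")
        samples = state["expr"].sample_ids
        mut = mutation_summary(state["mutations"], samples)
        emit(mut["gene_frequency"].to_frame(), "mutation_frequency.tsv")
        emit(mut["sample_counts"].to_frame(), "mutation_counts.tsv")
        res = screen_antigens(de, mut["gene_frequency"], state["clinical"],
                              state["expr"], state["infiltration"],
                              state["purity"], ScreenThresholds())
        emit(res.table, "antigen_screen.tsv")
        state["screen"] = res
        state["mutation_summary"] = mut
        logger.info("antigen funnel %s; candidates %s",
                    res.funnel_counts, res.candidates)

    def cluster():
        cc = dict(config.consensus)
        lo, hi = cc.pop("k_range", [2, 8])
        features = state["expr"].values.T  # samples x genes
        res = run_consensus(features, k_range=range(lo, hi + 1),
                            seed=config.seed, **cc)
        state["consensus"] = res
        emit(res.labels.to_frame(), "subtype_labels.tsv")
        areas = pd.DataFrame({
            "area": res.area, "delta_area": res.delta_area,
        })
        areas.index.name = "k"
        emit(areas, "consensus_areas.tsv")
        logger.info("consensus chose k=%d", res.chosen_k)

    def validate_stage():
        if state.get("valid_expr") is None:
            logger.warning("no validation cohort; validate stage skipped")
            return
        labels = state["consensus"].labels
        disc_features = state["expr"].values.T
        cents = subtype_centroids(disc_features, labels)
        shared = [g for g in state["valid_expr"].gene_ids
                  if g in set(state["expr"].gene_ids)]
        val_features = state["valid_expr"].values.loc[shared].T
        report = in_group_proportion(val_features, cents,
                                     discovery_features=disc_features,
                                     discovery_labels=labels)
        emit(report, "validation_report.tsv")
        state["validation"] = report
        logger.info("validation IGP %s",
                    report["igp"].round(3).to_dict())

    def score():
        if state.get("synthetic"):
            sigs = generate_signature_sets(
                state["gen_cfg"], config.seed,
                n_null=config.ssgsea.get("n_null", 5),
                set_size=config.ssgsea.get("set_size", 30))
        else:
            sigs = io_core.read_gmt(config.inputs["signatures"])
        sm = ssgsea_scores(state["expr"], sigs,
                           alpha=config.ssgsea.get("alpha", 0.25))
        emit(sm.scores, "ssgsea_scores.tsv")
        diff = group_differential(sm.scores, state["consensus"].labels)
        emit(diff, "signature_subtype_association.tsv")
        state["scores"] = sm
        state["signatures"] = sigs

    def modules():
        cparams = CoexpressionParams(**config.coexpression)
        expr = state["expr"]
        scan = soft_threshold_scan(expr)
        emit(scan, "soft_threshold_scan.tsv")
        adj = adjacency_matrix(expr, beta=cparams.beta)
        tom = tom_matrix(adj)
        labels = detect_modules(tom, expr.gene_ids, cparams)
        mset = module_eigengenes(expr, labels,
                                 merge_height=cparams.merge_height)
        emit(mset.assignment.to_frame(), "module_assignment.tsv")
        emit(mset.eigengenes, "module_eigengenes.tsv")
        emit(mset.kme, "module_kme.tsv")
        prog = module_prognosis(mset, expr, state["clinical"],
                                state["consensus"].labels)
        emit(prog, "module_prognosis.tsv")
        state["modules"] = mset
        state["module_prognosis"] = prog

    def landscape_stage():
        lp = dict(config.landscape)
        features = state["expr"].values.T
        emb = ddrtree_embed(features, seed=config.seed, **lp)
        state["landscape"] = emb
        emit(emb.coordinates(), "landscape_coordinates.tsv")
        edges = pd.DataFrame(emb.tree_edges, columns=["center_a", "center_b"])
        emit(edges.set_index("center_a"), "landscape_tree_edges.tsv")
        corr = component_correlations(emb, state["scores"].scores)
        emit(corr.set_index("component"), "landscape_component_correlations.tsv")
        subsets = branch_subsets(emb, state["consensus"].labels)
        emit(subsets.to_frame(), "landscape_subsets.tsv")
        try:
            ext = extreme_location_groups(emb, state["clinical"])
            state["extreme_groups"] = ext
        except ValueError as e:
            logger.warning("extreme-location comparison skipped: %s", e)

    def prognosis():
        labels = state["consensus"].labels
        clin = state["clinical"]
        samples = [s for s in labels.index if s in clin.index]
        chi2, df, p = multigroup_logrank(
            clin.loc[samples, "os_time"], clin.loc[samples, "os_event"],
            labels.loc[samples])
        # subtype indicators + ordinal stage/grade, complete cases only
        dummies = pd.get_dummies(labels.loc[samples], drop_first=True).astype(float)
        covs = pd.concat([dummies, clin.loc[samples, ["stage", "grade"]]], axis=1)
        ok = covs.notna().all(axis=1)
        cox = cox_ph(covs.loc[ok],
                     clin.loc[samples, "os_time"][ok],
                     clin.loc[samples, "os_event"][ok])
        tbl = cox.as_frame().set_index("covariate")
        emit(tbl, "subtype_cox.tsv")
        tmb = state["mutation_summary"]["sample_counts"] if "mutation_summary" in state \
            else None
        summary = {"logrank_chi2": chi2, "logrank_df": df, "logrank_p": p}
        if tmb is not None:
            assoc = group_differential(tmb.loc[samples].to_frame(), labels.loc[samples])
            summary["tmb_anova_p"] = float(assoc["p"].iloc[0])
        state["prognosis"] = summary
        logger.info("subtype log-rank chi2=%.2f (df=%d, p=%.3g)", chi2, df, p)

    try:
        run_stage("simulate", simulate)
        run_stage("preprocess", preprocess)
        run_stage("screen", screen)
        run_stage("cluster", cluster)
        run_stage("validate", validate_stage)
        run_stage("score", score)
        run_stage("modules", modules)
        run_stage("landscape", landscape_stage)
        run_stage("prognosis", prognosis)

        provenance = {
            "config": config.to_dict(),
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "stages_run": ran,
            "stages_skipped": [s for s in ALL_STAGES if s not in ran],
            "outputs": {p.name: _file_hash(p) for p in sorted(written)},
        }
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True)
        report = {
            "provenance": provenance,
            "files": sorted(p.name for p in written),
        }
        if "consensus" in state:
            report["chosen_k"] = state["consensus"].chosen_k
        if "screen" in state:
            report["antigen_candidates"] = state["screen"].candidates
            report["funnel_counts"] = state["screen"].funnel_counts
        if "prognosis" in state:
            report["prognosis"] = {
                k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                for k, v in state["prognosis"].items()}
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=str)
        report["state"] = state
        return report
    finally:
        root.removeHandler(handler)
        handler.close()
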
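"""End-to-end orchestration: simulate -> QC -> EWAS -> meta -> multi-trait ->
significance sets -> overlap/novelty -> enrichment -> diagnostics.

Every stage reads its inputs from, and writes its outputs to, one run
directory as headered TSV files, so the CLI subcommands and :func:`run_all`
share the same file contract.  All randomness flows from the run seed; a
rerun with the same configuration produces byte-identical outputs, and every
file header carries the config hash and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mtewas import io as mio
from mtewas.diagnostics import compare_betas, manhattan_table, qq_coordinates
from mtewas.enrichment import AnnotationMap, gometh_test
from mtewas.ewas import genomic_inflation, run_ewas
from mtewas.meta import SignificanceSet, fisher_combine_frame, meta_single_trait, significant_set
from mtewas.multitrait import MCConfig, overlap_summary, run_multitrait
from mtewas.preprocess import TraitCorr, complete_cases, estimate_trait_correlation, filter_outliers
from mtewas.synthetic import MARKERS, BetaMatrix, SimConfig, generate_cohort, generate_gene_sets

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "ewas", "meta", "multitrait", "enrich", "diagnostics")
PLATFORMS = ("p1", "p2")


@dataclass
class RunConfig:
    """One structured configuration file drives the whole workflow."""

    out_dir: str = "mtewas_run"
    seed: int = 0
    markers: tuple = MARKERS
    covariates: list | str = "auto"
    alpha_family: float = 0.05
    k_sd: float = 3.0
    simulate: dict = field(default_factory=dict)  # SimConfig overrides
    mc: dict = field(default_factory=dict)  # MCConfig overrides
    enrich: dict = field(default_factory=lambda: {"n_terms": 40, "term_size": [5, 40]})
    stages: dict = field(default_factory=lambda: {"enrich": True, "diagnostics": True})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.markers = tuple(cfg.markers)
        if "effect_classes" in cfg.simulate:
            # YAML parses a bare `null` mapping key as None
            cfg.simulate["effect_classes"] = {
                ("null" if k is None else str(k)): v
                for k, v in cfg.simulate["effect_classes"].items()
            }
        return cfg

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "markers": list(self.markers),
            "covariates": self.covariates,
            "alpha_family": self.alpha_family,
            "k_sd": self.k_sd,
            "simulate": self.simulate,
            "mc": self.mc,
            "enrich": self.enrich,
            "stages": self.stages,
        }

    @property
    def hash(self) -> str:
        return mio.config_hash(self.to_dict())

    def meta_header(self, stage: str) -> dict:
        return {"config_hash": self.hash, "seed": self.seed, "stage": stage}

    def sim_config(self) -> SimConfig:
        params = dict(self.simulate)
        if "trait_corr_target" in params:
            params["trait_corr_target"] = np.asarray(params["trait_corr_target"], float)
        params.setdefault("seed", self.seed)
        return SimConfig(**params)

    def mc_config(self) -> MCConfig:
        params = dict(self.mc)
        params.setdefault("seed", self.seed)
        return MCConfig(**params)

    def covariate_list(self, pheno: pd.DataFrame) -> list[str]:
        if self.covariates != "auto":
            return list(self.covariates)
        cols = ["age"]
        cols += [c for c in pheno.columns if c.startswith("covariate_")]
        # cell-type proportions sum to 1: drop the largest fraction as reference
        ct = [c for c in pheno.columns if c.startswith("celltype_")]
        cols += [c for c in ct if c != "celltype_gran"]
        return cols


def _out(config: RunConfig) -> Path:
    path = Path(config.out_dir)
    path.mkdir(parents=True, exist_ok=True)
    return path


def _read_beta(config: RunConfig, platform: str, suffix: str = "") -> BetaMatrix:
    out = _out(config)
    values = mio.read_beta_matrix(out / f"beta_{platform}{suffix}.tsv")
    ann = mio.read_tsv(out / f"annotation_{platform}.tsv")
    return BetaMatrix(values=values, annotation=ann, platform=platform)


def stage_simulate(config: RunConfig) -> None:
    out = _out(config)
    cohort = generate_cohort(config.sim_config())
    meta = config.meta_header("simulate")
    mio.write_tsv(cohort.pheno, out / "pheno.tsv", meta)
    for bm in (cohort.beta_platform1, cohort.beta_platform2):
        mio.write_beta_matrix(bm.values, out / f"beta_{bm.platform}.tsv", meta)
        mio.write_tsv(bm.annotation, out / f"annotation_{bm.platform}.tsv", meta)
    mio.write_tsv(cohort.truth.cpg_effects, out / "truth_cpg_effects.tsv", meta)
    mio.write_tsv(cohort.truth.chip_intercepts, out / "truth_chip_intercepts.tsv", meta)


def stage_qc(config: RunConfig) -> None:
    """3-SD marker outlier filter (applied exactly once), complete cases,
    and per-platform marker correlation estimation."""
    out = _out(config)
    pheno = mio.read_tsv(out / "pheno.tsv")
    filtered, removed = filter_outliers(pheno, k_sd=config.k_sd, markers=config.markers)
    logger.info("outlier filter removed %d of %d samples", len(removed), len(pheno))
    meta = config.meta_header("qc")
    mio.write_tsv(
        pd.DataFrame({"removed_sample_id": removed}),
        out / "qc_removed_samples.tsv",
        {**meta, "n_input": len(pheno), "n_removed": len(removed), "filter_applications": 1},
    )
    for platform in PLATFORMS:
        sub = filtered[filtered["platform"] == platform].reset_index(drop=True)
        bm = _read_beta(config, platform)
        ph_cc, bm_cc = complete_cases(sub, bm)
        corr = estimate_trait_correlation(ph_cc, markers=config.markers)
        mio.write_tsv(ph_cc, out / f"pheno_qc_{platform}.tsv", meta)
        mio.write_beta_matrix(bm_cc.values, out / f"beta_{platform}_qc.tsv", meta)
        corr_df = pd.DataFrame(corr.matrix, columns=list(config.markers))
        corr_df.insert(0, "marker", list(config.markers))
        mio.write_tsv(corr_df, out / f"trait_corr_{platform}.tsv", meta)


def _load_corr(config: RunConfig, platform: str) -> TraitCorr:
    df = mio.read_tsv(_out(config) / f"trait_corr_{platform}.tsv")
    return TraitCorr(matrix=df[list(config.markers)].to_numpy(float), markers=tuple(config.markers))


def stage_ewas(config: RunConfig) -> None:
    out = _out(config)
    meta = config.meta_header("ewas")
    for platform in PLATFORMS:
        pheno = mio.read_tsv(out / f"pheno_qc_{platform}.tsv")
        bm = _read_beta(config, platform, suffix="_qc")
        covs = config.covariate_list(pheno)
        for marker in config.markers:
            res = run_ewas(bm, pheno, marker, covs)
            mio.write_tsv(res, out / f"ewas_{platform}_{marker}.tsv", meta)


def stage_meta(config: RunConfig) -> None:
    out = _out(config)
    meta = config.meta_header("meta")
    for marker in config.markers:
        res1 = mio.read_tsv(out / f"ewas_p1_{marker}.tsv")
        res2 = mio.read_tsv(out / f"ewas_p2_{marker}.tsv")
        combined = meta_single_trait(res1, res2)
        mio.write_tsv(combined, out / f"meta_{marker}.tsv", meta)


def _write_set(config: RunConfig, s: SignificanceSet) -> None:
    meta = {
        **config.meta_header("sets"),
        "analysis": s.label,
        "m_tests": s.m_tests,
        "alpha_family": s.alpha_family,
        "threshold": f"{s.threshold:.6g}",
    }
    mio.write_tsv(s.table, _out(config) / f"set_{s.label}.tsv", meta)


def _read_set(config: RunConfig, label: str) -> SignificanceSet:
    path = _out(config) / f"set_{label}.tsv"
    header = mio.read_tsv_meta(path)
    try:
        table = mio.read_tsv(path)
    except pd.errors.EmptyDataError:
        table = pd.DataFrame(columns=["cpg_id", "p"])
    return SignificanceSet(
        label=label,
        m_tests=int(header["m_tests"]),
        alpha_family=float(header["alpha_family"]),
        threshold=float(header["threshold"]),
        table=table,
    )


def analysis_labels(config: RunConfig) -> tuple[list[str], list[str]]:
    """(single-trait labels, multi-trait labels) across p1/p2/meta."""
    single = [f"{m}_{a}" for m in config.markers for a in ("p1", "p2", "meta")]
    multi = [f"{t}_{a}" for t in ("cpassoc", "omnitest") for a in ("p1", "p2", "meta")]
    return single, multi


def stage_multitrait(config: RunConfig) -> None:
    """Cross-phenotype tests per platform, Fisher meta across platforms, and
    all per-analysis Bonferroni significance sets plus overlap counts."""
    out = _out(config)
    meta = config.meta_header("multitrait")
    mc = config.mc_config()
    per_platform = {}
    for platform in PLATFORMS:
        tables = {
            m: mio.read_tsv(out / f"ewas_{platform}_{m}.tsv") for m in config.markers
        }
        corr = _load_corr(config, platform)
        res = run_multitrait(tables, corr, mc)
        per_platform[platform] = res
        mio.write_tsv(res, out / f"multitrait_{platform}.tsv", meta)
    fisher_shom = fisher_combine_frame(list(per_platform.values()), "shom_p")
    fisher_omni = fisher_combine_frame(list(per_platform.values()), "omnitest_p")
    mt_meta = fisher_shom.rename(
        columns={"fisher_stat": "shom_fisher_stat", "fisher_p": "shom_p", "fisher_df": "shom_fisher_df"}
    ).merge(
        fisher_omni.rename(
            columns={
                "fisher_stat": "omnitest_fisher_stat",
                "fisher_p": "omnitest_p",
                "fisher_df": "omnitest_fisher_df",
            }
        ),
        on="cpg_id",
    )
    mio.write_tsv(mt_meta, out / "multitrait_meta.tsv", meta)

    alpha = config.alpha_family
    for m in config.markers:
        for analysis, fname in (("p1", f"ewas_p1_{m}.tsv"), ("p2", f"ewas_p2_{m}.tsv"), ("meta", f"meta_{m}.tsv")):
            table = mio.read_tsv(out / fname)
            _write_set(config, significant_set(table, "p", alpha, label=f"{m}_{analysis}"))
    for test, col in (("cpassoc", "shom_p"), ("omnitest", "omnitest_p")):
        for analysis in ("p1", "p2"):
            _write_set(
                config,
                significant_set(per_platform[analysis], col, alpha, label=f"{test}_{analysis}"),
            )
        _write_set(config, significant_set(mt_meta, col, alpha, label=f"{test}_meta"))

    single, multi = analysis_labels(config)
    sets = [_read_set(config, lab) for lab in single + multi]
    overlap = overlap_summary(sets, single_trait_labels=single)
    pairwise = overlap["pairwise"].copy()
    pairwise.insert(0, "analysis", pairwise.index)
    mio.write_tsv(pairwise, out / "overlap_pairwise.tsv", meta)
    novel = pd.DataFrame(
        sorted(overlap["novel"].items()), columns=["analysis", "n_novel_vs_single_trait"]
    )
    mio.write_tsv(novel, out / "overlap_novel.tsv", meta)


def stage_enrich(config: RunConfig) -> None:
    """Wallenius gene-set enrichment of the multi-trait meta discovery sets,
    against gene sets generated from the shared-panel annotation."""
    out = _out(config)
    meta = config.meta_header("enrich")
    ann1 = mio.read_tsv(out / "annotation_p1.tsv")
    ann2 = mio.read_tsv(out / "annotation_p2.tsv")
    shared_ids = sorted(set(ann1["cpg_id"]) & set(ann2["cpg_id"]))
    annotation = ann1[ann1["cpg_id"].isin(shared_ids)]
    params = dict(config.enrich)
    gene_sets = generate_gene_sets(
        annotation,
        n_terms=params.get("n_terms", 40),
        term_size=tuple(params.get("term_size", (5, 40))),
        seed=params.get("seed", config.seed),
    )
    mio.write_tsv(gene_sets, out / "gene_sets.tsv", meta)
    # universe: CpGs actually tested in the meta analyses
    universe = mio.read_tsv(out / "multitrait_meta.tsv")["cpg_id"].tolist()
    amap = AnnotationMap.from_tables(annotation, gene_sets, universe)
    for label in ("cpassoc_meta", "omnitest_meta"):
        sig = _read_set(config, label)
        if len(sig) == 0:
            mio.write_tsv(
                pd.DataFrame(
                    columns=["term_id", "n_genes_in_term", "n_selected_in_term", "odds", "wallenius_p", "fdr_q"]
                ),
                out / f"enrichment_{label}.tsv",
                meta,
            )
            continue
        result = gometh_test(sig, amap)
        mio.write_tsv(result, out / f"enrichment_{label}.tsv", meta)


def stage_diagnostics(config: RunConfig) -> None:
    out = _out(config)
    meta = config.meta_header("diagnostics")
    single, multi = analysis_labels(config)
    lambdas = {}
    for label in single + multi:
        table, col = _analysis_table(config, label)
        lambdas[label] = genomic_inflation(table[col].dropna())
    mio.write_tsv(
        pd.DataFrame(sorted(lambdas.items()), columns=["analysis", "lambda"]),
        out / "inflation_factors.tsv",
        meta,
    )
    for label in ("cpassoc_meta", "omnitest_meta"):
        table, col = _analysis_table(config, label)
        mio.write_tsv(qq_coordinates(table[col].dropna()), out / f"qq_{label}.tsv", meta)
    ann = mio.read_tsv(out / "annotation_p1.tsv").rename(columns={"pos_1based": "pos"})
    mt = mio.read_tsv(out / "multitrait_meta.tsv").merge(ann, on="cpg_id")
    for label, col in (("cpassoc_meta", "shom_p"), ("omnitest_meta", "omnitest_p")):
        mio.write_tsv(manhattan_table(mt, col), out / f"manhattan_{label}.tsv", meta)


def _analysis_table(config: RunConfig, label: str) -> tuple[pd.DataFrame, str]:
    out = _out(config)
    name, _, analysis = label.rpartition("_")
    if name in ("cpassoc", "omnitest"):
        col = "shom_p" if name == "cpassoc" else "omnitest_p"
        fname = "multitrait_meta.tsv" if analysis == "meta" else f"multitrait_{analysis}.tsv"
        return mio.read_tsv(out / fname), col
    fname = f"meta_{name}.tsv" if analysis == "meta" else f"ewas_{analysis}_{name}.tsv"
    return mio.read_tsv(out / fname), "p"


def _summarise(config: RunConfig) -> dict:
    out = _out(config)
    single, multi = analysis_labels(config)
    counts: dict[str, dict[str, int]] = {}
    m_tests: dict[str, dict[str, int]] = {}
    for label in single + multi:
        s = _read_set(config, label)
        name, _, analysis = label.rpartition("_")
        counts.setdefault(name, {})[analysis] = len(s)
        m_tests.setdefault(name, {})[analysis] = s.m_tests
    novel = mio.read_tsv(out / "overlap_novel.tsv")
    pairwise = mio.read_tsv(out / "overlap_pairwise.tsv")
    overlap_multi = {
        a: int(
            pairwise.set_index("analysis").loc[f"cpassoc_{a}", f"omnitest_{a}"]
        )
        for a in ("p1", "p2", "meta")
    }
    qc_meta = mio.read_tsv_meta(out / "qc_removed_samples.tsv")
    summary = {
        "config_hash": config.hash,
        "seed": config.seed,
        "n_samples_removed_by_outlier_filter": int(qc_meta.get("n_removed", 0)),
        "outlier_filter_applications": int(qc_meta.get("filter_applications", 1)),
        "counts": counts,
        "m_tests": m_tests,
        "overlap_cpassoc_omnitest": overlap_multi,
        "novel_vs_single_trait": {
            row.analysis: int(row.n_novel_vs_single_trait) for row in novel.itertuples()
        },
    }
    if config.stages.get("diagnostics", True):
        infl = mio.read_tsv(out / "inflation_factors.tsv")
        summary["lambda"] = dict(zip(infl["analysis"], infl["lambda"].astype(float)))
    # cross-platform agreement of single-trait effect estimates (shared CpGs)
    r2 = {}
    for m in config.markers:
        res1 = mio.read_tsv(out / f"ewas_p1_{m}.tsv")
        res2 = mio.read_tsv(out / f"ewas_p2_{m}.tsv")
        try:
            r2[m] = compare_betas(res1, res2)
        except ValueError:
            r2[m] = None
    summary["beta_r2_between_platforms"] = r2
    return summary


def run_all(config: RunConfig) -> dict:
    """Run every enabled stage and write a machine-readable summary.

    Deterministic given the seed; a stage failure aborts with the failing
    stage named, retaining the partial outputs already written.
    """
    enabled = {
        "simulate": True,
        "qc": True,
        "ewas": True,
        "meta": True,
        "multitrait": True,
        "enrich": config.stages.get("enrich", True),
        "diagnostics": config.stages.get("diagnostics", True),
    }
    stage_fns = {
        "simulate": stage_simulate,
        "qc": stage_qc,
        "ewas": stage_ewas,
        "meta": stage_meta,
        "multitrait": stage_multitrait,
        "enrich": stage_enrich,
        "diagnostics": stage_diagnostics,
    }
    for name in STAGES:
        if not enabled[name]:
            continue
        try:
            stage_fns[name](config)
        except Exception as exc:  # noqa: BLE001 - stage name must surface
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
    summary = _summarise(config)
    with open(_out(config) / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
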
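"""Config-driven orchestration of the analysis stages.

A run is described by a YAML/JSON config with a ``simulate`` block (synthetic
cohort) or an ``inputs`` block (paths to the TSV formats in
:mod:`panomix.io`), a ``stages`` list, and optional per-stage ``params``.
``run_pipeline(config, seed, outdir)`` executes the enabled stages, writes
one TSV per result, and logs a ``manifest.json`` with package/library
versions, the seed and the effective parameters.  The same config and seed
reproduce byte-identical outputs.

Stage order and dependencies: de_status needs the expression pair;
multiomics needs de_status (and methylation for the methylation layer);
survival, progression and enrich need the RNA-seq matrix plus the sample
sheet.  Counts are TMM-normalized and log-CPM transformed once, then batch
centered when a batch column exists (normalization first, adjustment second
— recorded in the manifest).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, simulate as sim
from .containers import ExpressionMatrix, TUMOR
from .destatus import array_ttest_de, count_nb_de, status_table
from .enrichment import (
    common_pathways,
    enrichment_universe,
    hypergeom_enrich,
    mirna_consensus,
    mirna_de,
    pearson_screen,
)
from .exceptions import ConfigError
from .methylation import cpg_wilcoxon, filter_impute_cpgs, gene_methylation_status
from .multiomics import alteration_frequencies, consistency_annotation, summarize_panel
from .normalization import batch_adjust, log_cpm, tmm_factors
from .progression import metastasis_de, split_metastasis, stage_anova_tukey
from .survival import cox_fit, logrank, median_dichotomize, mutation_expression_strata

log = logging.getLogger("panomix")

ALL_STAGES = ("de_status", "methylation", "multiomics", "survival", "progression", "enrich")
_TOP_KEYS = {"simulate", "inputs", "stages", "params"}
_PARAM_KEYS = {
    "alpha",
    "min_cnv_freq",
    "min_metastasis_group",
    "anchor_gene",
    "afp_cutoff",
    "hazard_gene_panel",
    "strata_pairs",
    "universe_policy",
    "n_enrich_datasets",
    "mirna_min_support",
}


def _float_fmt(df: pd.DataFrame) -> pd.DataFrame:
    return df


def load_config(config: str | Path | dict) -> dict:
    if isinstance(config, dict):
        cfg = config
    else:
        text = Path(config).read_text()
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    params = cfg.get("params", {})
    bad = set(params) - _PARAM_KEYS
    if bad:
        raise ConfigError(f"unknown params key(s): {sorted(bad)}")
    if "simulate" in cfg:
        known = {f.name for f in dataclasses.fields(sim.CohortConfig)}
        bad = set(cfg["simulate"]) - known
        if bad:
            raise ConfigError(f"unknown simulate key(s): {sorted(bad)}")
    return cfg


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g", **kw)


def run_pipeline(config: str | Path | dict, seed: int, outdir: str | Path) -> Path:
    """Execute the configured stages and write results under ``outdir``."""
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(cfg.get("stages", ALL_STAGES))
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
    params = dict(cfg.get("params", {}))
    alpha = float(params.get("alpha", 0.05))

    if "simulate" in cfg:
        sim_kw = dict(cfg["simulate"])
        sim_kw["seed"] = int(seed)
        ccfg = sim.CohortConfig(**sim_kw)
        cohort = sim.simulate_cohort(ccfg)
        _write_cohort(cohort, outdir / "cohort")
        data = _cohort_data(cohort)
    elif "inputs" in cfg:
        data = _load_inputs(cfg["inputs"])
    else:
        raise ConfigError("config needs a 'simulate' or 'inputs' block")

    notes: dict = {}
    results: dict[str, Path] = {}

    # shared normalization of the count matrix
    logcpm = None
    if data.get("counts") is not None:
        factors = tmm_factors(data["counts"])
        logcpm = log_cpm(data["counts"], factors)
        if data.get("batches") is not None:
            logcpm = batch_adjust(logcpm, data["batches"])
            notes["batch_adjustment"] = "per-gene batch mean centering on log-CPM, after TMM"
        ftab = pd.DataFrame({"factor": factors.factors, "lib_size": factors.lib_sizes})
        _write(ftab, outdir / "norm_factors.tsv", index_label="sample")

    if "de_status" in stages:
        _stage_de_status(data, logcpm, alpha, outdir, notes)
    if "methylation" in stages and data.get("beta") is not None:
        _stage_methylation(data, alpha, outdir)
    if "multiomics" in stages and data.get("mutations") is not None:
        _stage_multiomics(data, params, outdir)
    if "survival" in stages and data.get("samples") is not None and logcpm is not None:
        _stage_survival(data, logcpm, params, outdir)
    if "progression" in stages and data.get("samples") is not None and logcpm is not None:
        _stage_progression(data, logcpm, params, alpha, outdir)
    if "enrich" in stages and logcpm is not None:
        _stage_enrich(data, logcpm, params, alpha, outdir, seed, cfg)

    manifest = {
        "package": "panomix",
        "version": __version__,
        "versions": _lib_versions(),
        "seed": int(seed),
        "stages": stages,
        "params": params,
        "config": _jsonable(cfg),
        "notes": notes,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def _lib_versions() -> dict:
    import lifelines, scipy, statsmodels

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
        "lifelines": lifelines.__version__,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _cohort_data(cohort: sim.Cohort) -> dict:
    return {
        "array": cohort.expression.array,
        "array_groups": cohort.expression.array_groups,
        "counts": cohort.seq_expression,
        "seq_groups": cohort.expression.seq_groups,
        "batches": cohort.expression.batches,
        "beta": cohort.methylation.beta,
        "beta_groups": cohort.methylation.groups,
        "cpg_map": cohort.methylation.cpg_map,
        "samples": cohort.samples,
        "mutations": cohort.mutations,
        "cnv": cohort.cnv,
        "mirna": cohort.mirna,
        "pathways": cohort.pathways,
        "anchor": cohort.config.anchor_gene,
        "sim_config": cohort.config,
    }


def _load_inputs(inputs: dict) -> dict:
    known = {
        "array",
        "counts",
        "beta",
        "cpg_map",
        "samples",
        "mutations",
        "cnv",
        "gmt",
        "mirna",
        "mirna_lists",
    }
    bad = set(inputs) - known
    if bad:
        raise ConfigError(f"unknown inputs key(s): {sorted(bad)}")
    data: dict = {n: None for n in known}
    if "samples" in inputs:
        sheet = io.read_sample_sheet(inputs["samples"])
        data["samples"] = sheet
    sheet = data.get("samples")
    if "array" in inputs:
        data["array"] = io.read_matrix(inputs["array"], kind="array")
    if "counts" in inputs:
        data["counts"] = io.read_matrix(inputs["counts"], kind="counts")
    if sheet is not None:
        grp = sheet["group"]
        if data.get("array") is not None:
            data["array_groups"] = grp.reindex(data["array"].samples)
        if data.get("counts") is not None:
            data["seq_groups"] = grp.reindex(data["counts"].samples)
            if "batch" in sheet.columns:
                data["batches"] = sheet["batch"].reindex(data["counts"].samples)
    if "beta" in inputs:
        data["beta"] = io.read_matrix(inputs["beta"], kind="beta")
        data["cpg_map"] = io.read_cpg_map(inputs["cpg_map"])
        if sheet is not None:
            data["beta_groups"] = sheet["group"].reindex(data["beta"].samples)
    if "mutations" in inputs:
        data["mutations"] = io.read_mutations(inputs["mutations"], nonsyn_only=True)
    if "cnv" in inputs:
        data["cnv"] = io.read_cnv(inputs["cnv"])
    if "gmt" in inputs:
        data["pathways"] = io.read_gmt(inputs["gmt"])
    data.setdefault("batches", None)
    return data


def _stage_de_status(data, logcpm, alpha, outdir: Path, notes: dict) -> None:
    de_a = array_ttest_de(data["array"], data["array_groups"], alpha=alpha)
    # NB test runs on raw counts with TMM factors (not on log-CPM)
    factors = tmm_factors(data["counts"])
    de_s = count_nb_de(data["counts"], factors, data["seq_groups"], alpha=alpha)
    notes["nb_dispersion"] = de_s.attrs.get("dispersion")
    tab = status_table(de_a, de_s, alpha=alpha)
    _write(de_a, outdir / "de_array.tsv", index_label="gene")
    _write(de_s, outdir / "de_seq.tsv", index_label="gene")
    _write(tab, outdir / "status_table.tsv", index_label="gene")


def _stage_methylation(data, alpha, outdir: Path) -> None:
    filt, dropped = filter_impute_cpgs(data["beta"])
    sites = cpg_wilcoxon(filt, data["beta_groups"], alpha=alpha)
    genes = gene_methylation_status(sites, data["cpg_map"])
    _write(sites, outdir / "cpg_tests.tsv", index_label="cpg_id")
    _write(genes, outdir / "gene_methylation.tsv", index_label="gene")


def _stage_multiomics(data, params, outdir: Path) -> None:
    counts = data["counts"]
    tumors = [
        s for s in counts.samples if data["seq_groups"] is not None and data["seq_groups"].get(s) == TUMOR
    ]
    summary = alteration_frequencies(
        data["mutations"], data["cnv"], tumors, genes=list(counts.genes)
    )
    _write(summary, outdir / "alteration_summary.tsv", index_label="gene")
    panel = pd.DataFrame([summarize_panel(summary)])
    _write(panel, outdir / "alteration_panel_means.tsv", index=False)
    status_path = outdir / "status_table.tsv"
    meth_path = outdir / "gene_methylation.tsv"
    if status_path.exists():
        status = pd.read_csv(status_path, sep="\t", index_col="gene")
        gene_meth = (
            pd.read_csv(meth_path, sep="\t", index_col="gene") if meth_path.exists() else None
        )
        flags = consistency_annotation(
            status, summary, gene_meth, min_cnv_freq=float(params.get("min_cnv_freq", 10.0))
        )
        _write(flags, outdir / "consistency.tsv", index=False)


def _stage_survival(data, logcpm: ExpressionMatrix, params, outdir: Path) -> None:
    sheet = data["samples"]
    tumors = [s for s in logcpm.samples if s in sheet.index and sheet.at[s, "group"] == TUMOR]
    sub = sheet.loc[tumors]
    times = pd.to_numeric(sub["os_time"])
    events = pd.to_numeric(sub["os_event"])
    panel = params.get("hazard_gene_panel") or list(logcpm.genes[: min(20, len(logcpm.genes))])
    rows = []
    for g in panel:
        if g not in logcpm.genes:
            continue
        expr = logcpm.values.loc[g, tumors]
        z = (expr - expr.mean()) / (expr.std() if expr.std() > 0 else 1.0)
        row: dict = {"gene": g}
        try:
            df = pd.DataFrame({"time": times, "event": events, "expr": z})
            fit = cox_fit(df, "time", "event", ["expr"])
            row.update(
                hr=fit.summary.at["expr", "hr"],
                hr_lower=fit.summary.at["expr", "hr_lower"],
                hr_upper=fit.summary.at["expr", "hr_upper"],
                cox_p=fit.summary.at["expr", "p"],
            )
        except Exception as exc:  # degenerate gene: report, keep going
            log.warning("univariate Cox failed for %s: %s", g, exc)
        try:
            split = median_dichotomize(expr)
            lr = logrank(times, events, split)
            row.update(logrank_p=lr.pvalue, n_high=(split == "high").sum(), n_low=(split == "low").sum())
        except Exception as exc:
            log.warning("median-split log-rank failed for %s: %s", g, exc)
        # multivariate: adjust for AFP (binary at cutoff), tumor size, TNM ordinal
        try:
            afp_cut = float(params.get("afp_cutoff", 20.0))
            mdf = pd.DataFrame(
                {
                    "time": times,
                    "event": events,
                    "expr": z,
                    "afp_high": (pd.to_numeric(sub["afp"]) > afp_cut).astype(float),
                    "size": pd.to_numeric(sub["tumor_size"]),
                    "tnm": pd.to_numeric(sub["tnm"]),
                }
            )
            mfit = cox_fit(mdf, "time", "event", ["expr", "afp_high", "size", "tnm"])
            row.update(adj_hr=mfit.summary.at["expr", "hr"], adj_p=mfit.summary.at["expr", "p"])
        except Exception as exc:
            log.warning("multivariate Cox failed for %s: %s", g, exc)
        rows.append(row)
    _write(pd.DataFrame(rows), outdir / "survival_report.tsv", index=False)

    # mutation x expression four-subgroup stratification
    for pair in params.get("strata_pairs", []) or []:
        mut_gene, expr_gene = pair
        muts = data.get("mutations")
        if muts is None or expr_gene not in logcpm.genes:
            continue
        mutated = set(muts.loc[muts["gene"] == mut_gene, "sample"])
        mut_status = pd.Series([s in mutated for s in tumors], index=tumors)
        res = mutation_expression_strata(
            mut_status, logcpm.values.loc[expr_gene, tumors], times, events
        )
        out = {
            "mut_gene": mut_gene,
            "expr_gene": expr_gene,
            "group_sizes": res["group_sizes"],
            "overall_p": res["overall"].pvalue if res["overall"] else None,
            "within_mutant_p": res["within_mutant"].pvalue if res["within_mutant"] else None,
            "within_wildtype_p": res["within_wildtype"].pvalue if res["within_wildtype"] else None,
            "expression_ttest_p": res["expression_ttest"]["pvalue"] if res["expression_ttest"] else None,
        }
        path = outdir / f"strata_{mut_gene}_{expr_gene}.json"
        path.write_text(json.dumps(_jsonable(out), indent=2, sort_keys=True))


def _stage_progression(data, logcpm, params, alpha, outdir: Path) -> None:
    sheet = data["samples"]
    groups = split_metastasis(sheet)
    keep = [s for s in groups.metastatic + groups.non_metastatic if s in set(logcpm.samples)]
    groups.metastatic = [s for s in groups.metastatic if s in keep]
    groups.non_metastatic = [s for s in groups.non_metastatic if s in keep]
    de = metastasis_de(
        logcpm, groups, alpha=alpha, min_group_size=int(params.get("min_metastasis_group", 10))
    )
    if de is not None:
        _write(de, outdir / "metastasis_de.tsv", index_label="gene")
    tumors = [s for s in logcpm.samples if s in sheet.index and sheet.at[s, "group"] == TUMOR]
    stages_s = sheet.loc[tumors, "stage"]
    rows = []
    panel = params.get("hazard_gene_panel") or list(logcpm.genes[: min(20, len(logcpm.genes))])
    for g in panel:
        if g not in logcpm.genes:
            continue
        try:
            cmp_ = stage_anova_tukey(logcpm.values.loc[g, tumors], stages_s)
        except Exception as exc:
            log.warning("stage ANOVA failed for %s: %s", g, exc)
            continue
        rows.append(
            {
                "gene": g,
                "F": cmp_.f_statistic,
                "anova_p": cmp_.anova_p,
                "early_late_t": cmp_.early_late_t,
                "early_late_p": cmp_.early_late_p,
            }
        )
    _write(pd.DataFrame(rows), outdir / "stage_tests.tsv", index=False)


def _stage_enrich(data, logcpm, params, alpha, outdir: Path, seed: int, cfg: dict) -> None:
    anchor = params.get("anchor_gene") or data.get("anchor") or str(logcpm.genes[0])
    pathways = data.get("pathways")
    n_sets = int(params.get("n_enrich_datasets", 1))
    matrices = [logcpm]
    if "simulate" in cfg and n_sets > 1:
        # replicate cohorts from derived seeds stand in for independent datasets
        for k in range(1, n_sets):
            sim_kw = dict(cfg["simulate"])
            sim_kw["seed"] = (int(seed) + 100003 * k) % (2**31)
            rep = sim.simulate_expression_pair(sim.CohortConfig(**sim_kw))
            factors = tmm_factors(rep.counts)
            matrices.append(log_cpm(rep.counts, factors))
    pos_lists, neg_lists = [], []
    for i, mat in enumerate(matrices):
        screen = pearson_screen(anchor, mat, alpha=alpha)
        _write(screen.table, outdir / f"correlation_screen_{i + 1}.tsv", index_label="gene")
        if pathways is None:
            continue
        uni = enrichment_universe(mat, pathways, params.get("universe_policy", "annotated"))
        for name, query, bucket in (
            ("pos", screen.positive, pos_lists),
            ("neg", screen.negative, neg_lists),
        ):
            if not query:
                bucket.append([])
                continue
            enr = hypergeom_enrich(query, pathways, uni, alpha=alpha)
            _write(enr, outdir / f"enrichment_{name}_{i + 1}.tsv", index_label="pathway")
            bucket.append(enr.index[enr["significant"]].tolist())
    if pathways is not None and len(matrices) > 1:
        inter = pd.DataFrame(
            [("positive", p) for p in common_pathways(pos_lists)]
            + [("negative", p) for p in common_pathways(neg_lists)],
            columns=["direction", "pathway"],
        )
        _write(inter, outdir / "common_pathways.tsv", index=False)

    mirna = data.get("mirna")
    if mirna is not None:
        consensus = mirna_consensus(mirna.lists, min_support=int(params.get("mirna_min_support", 2)))
        _write(consensus, outdir / "mirna_consensus.tsv", index_label="mirna")
        kept = consensus.index[consensus["consensus"]].tolist()
        de = mirna_de(mirna.mirna, mirna.groups, mirnas=kept)
        _write(de, outdir / "mirna_de.tsv", index_label="mirna")


def _write_cohort(cohort: sim.Cohort, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_matrix(cohort.expression.array, outdir / "array.tsv", index_label="gene")
    io.write_matrix(cohort.seq_expression, outdir / "counts.tsv", index_label="gene")
    io.write_matrix(cohort.methylation.beta, outdir / "beta.tsv", index_label="cpg_id")
    cohort.methylation.cpg_map.rename("gene").to_csv(outdir / "cpg_map.tsv", sep="\t", index_label="cpg_id")
    io.write_sample_sheet(cohort.samples, outdir / "samples.tsv")
    io.write_table(cohort.mutations, outdir / "mutations.tsv")
    io.write_matrix(cohort.cnv, outdir / "cnv.tsv", index_label="gene")
    io.write_matrix(cohort.mirna.mirna, outdir / "mirna.tsv", index_label="mirna")
    for name, lst in cohort.mirna.lists.items():
        io.write_gene_list(lst, outdir / f"targets_{name}.txt")
    io.write_gmt(cohort.pathways, outdir / "pathways_synthetic.gmt")
    io.write_table(cohort.expression.truth, outdir / "truth_expression.tsv", index=True, index_label="gene")
    io.write_table(cohort.methylation.truth, outdir / "truth_methylation.tsv", index=True, index_label="gene")
    io.write_table(cohort.alteration_truth, outdir / "truth_alterations.tsv", index=True, index_label="gene")
    io.write_table(cohort.mirna.truth, outdir / "truth_mirna.tsv", index=True, index_label="mirna")
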
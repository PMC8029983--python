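"""Seeded synthetic multi-omics cohort generator with planted effects.

The generator emulates the input surface of a paired tumor/normal
multi-omics study: log-intensity microarray and raw-count RNA-seq expression
(separate sample sets per platform), multi-CpG beta-value methylation with
missingness, sparse non-synonymous mutations, discrete copy-number calls,
proportional-hazards survival with clinical covariates and stage/metastasis
labels, and miRNA expression with three target-prediction lists.  Every
planted effect is recorded in a truth table so downstream recovery tests
consume truth rather than re-deriving it.  Generation is a pure function of
(config, seed): each operation draws from its own named substream of the
config seed, so the full cohort and any individual piece are reproducible
independently.

Counts use a Gamma-Poisson parameterization with dispersion phi
(variance mu + phi*mu^2), matching the negative-binomial model the DE test
assumes; library sizes are log-uniform so TMM is exercised nontrivially.
By default 5% of planted genes are discordant between platforms, exercising
the S = 0 branch of the status score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import ExpressionMatrix, GeneSetCollection, NORMAL, TUMOR
from .exceptions import ConfigError

# substream ids, one per operation, so ops are independently reproducible
_STREAMS = {
    "expression": 1,
    "methylation": 2,
    "clinical": 3,
    "alterations": 4,
    "mirna": 5,
    "pathways": 6,
}


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort; defaults define the study conditions.

    Effect sizes are log2 (expression) or logit (methylation) shifts between
    tumor and normal means; survival uses a Weibull baseline (shape/scale in
    days) with a linear predictor over standardized expression of the
    ``hazard_genes``.
    """

    seed: int = 0
    # cohort size
    n_tumor: int = 30
    n_normal: int = 30
    n_genes: int = 500
    # expression effects
    de_fraction: float = 0.10
    log2_effect: float = 2.0
    discordant_fraction: float = 0.05
    array_sd: float = 1.0
    array_baseline: tuple[float, float] = (4.0, 12.0)
    nb_dispersion: float = 0.1
    base_abundance: tuple[float, float] = (5.0, 500.0)  # mean counts at 1e6 reads
    libsize_range: tuple[float, float] = (5e5, 1.5e6)
    n_batches: int = 1
    batch_effect_sd: float = 0.5
    # planted anchor-correlation block (drives the enrichment stage)
    anchor_gene: str | None = None
    n_pos_correlated: int = 40
    n_neg_correlated: int = 40
    corr_strength: float = 0.8
    # methylation
    cpgs_per_gene: tuple[int, int] = (2, 6)
    meth_shift: float = 1.5
    meth_sd: float = 0.8
    meth_na_rate: float = 0.05
    meth_de_fraction: float = 0.10
    meth_mixed_fraction: float = 0.05
    meth_baseline_logit: tuple[float, float] = (-2.0, 2.0)
    # genomic alterations
    mutation_rate: float = 0.02
    mutation_rates: dict[str, float] = field(default_factory=dict)
    cnv_del_prob: float = 0.10
    cnv_amp_prob: float = 0.05
    cnv_probs: dict[str, tuple[float, float]] = field(default_factory=dict)  # gene -> (del, amp)
    silent_fraction: float = 0.2  # extra silent rows per mutated sample (tests the filter)
    # survival
    weibull_shape: float = 1.2
    weibull_scale: float = 1000.0
    censoring_rate: float = 0.3
    hazard_genes: dict[str, float] = field(default_factory=dict)  # gene -> log HR per SD
    stage_probs: tuple[float, ...] = (0.30, 0.30, 0.25, 0.15)
    stage_trend_genes: dict[str, float] = field(default_factory=dict)  # gene -> shift per stage
    n_plus_prob: float = 0.35
    m_plus_prob: float = 0.10
    nx_prob: float = 0.05
    # miRNA
    n_mirna: int = 60
    mirna_list_prob: float = 0.5
    n_regulator_mirnas: int = 5
    mirna_anticorr: float = 0.8
    mirna_tumor_shift: float = 1.0
    mirna_sd: float = 1.0
    # pathways
    n_pathways: int = 50
    pathway_size: tuple[int, int] = (10, 60)
    n_planted_pos_pathways: int = 3
    n_planted_neg_pathways: int = 2

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in (
            "de_fraction",
            "discordant_fraction",
            "meth_na_rate",
            "meth_de_fraction",
            "meth_mixed_fraction",
            "mutation_rate",
            "cnv_del_prob",
            "cnv_amp_prob",
            "censoring_rate",
            "mirna_list_prob",
            "mirna_anticorr",
            "n_plus_prob",
            "m_plus_prob",
            "nx_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_tumor", "n_normal", "n_genes"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if abs(sum(self.stage_probs) - 1.0) > 1e-9:
            raise ConfigError("stage_probs must sum to 1")
        if self.cnv_del_prob + self.cnv_amp_prob > 1.0:
            raise ConfigError("cnv_del_prob + cnv_amp_prob exceed 1")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])


def gene_names(config: CohortConfig) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(config.n_genes)]


def _sample_ids(prefix: str, n_tumor: int, n_normal: int) -> tuple[list[str], list[str]]:
    tum = [f"{prefix}T{i + 1:03d}" for i in range(n_tumor)]
    nor = [f"{prefix}N{i + 1:03d}" for i in range(n_normal)]
    return tum, nor


def _groups(tumors: list[str], normals: list[str]) -> pd.Series:
    return pd.Series(
        [TUMOR] * len(tumors) + [NORMAL] * len(normals), index=tumors + normals, name="group"
    )


@dataclass
class ExpressionPair:
    array: ExpressionMatrix
    counts: ExpressionMatrix
    array_groups: pd.Series
    seq_groups: pd.Series
    truth: pd.DataFrame
    batches: pd.Series | None = None


def simulate_expression_pair(config: CohortConfig) -> ExpressionPair:
    """Paired-platform expression with planted, optionally discordant, DE.

    Microarray values are Normal(baseline +/- direction*effect/2, sd) on the
    log2 scale; counts are Gamma-Poisson with mean
    base_abundance * libsize/1e6 * 2^(+/- direction*effect/2) and dispersion
    phi.  The truth table records each gene's planted direction per platform.
    """
    if config.n_tumor < 1 or config.n_normal < 1:
        raise ConfigError("need at least one sample per group")
    rng = config.rng("expression")
    genes = gene_names(config)
    G = config.n_genes

    n_de = int(round(G * config.de_fraction))
    de_idx = rng.choice(G, size=n_de, replace=False)
    direction = np.zeros(G, dtype=int)
    direction[de_idx] = rng.choice([-1, 1], size=n_de)
    n_disc = int(round(n_de * config.discordant_fraction))
    disc_idx = rng.choice(de_idx, size=n_disc, replace=False) if n_de else np.array([], dtype=int)
    dir_seq = direction.copy()
    dir_array = direction.copy()
    dir_array[disc_idx] *= -1

    eff = config.log2_effect

    # --- microarray platform ---
    a_tum, a_nor = _sample_ids("A_", config.n_tumor, config.n_normal)
    base_a = rng.uniform(*config.array_baseline, size=G)
    mean_t = base_a + dir_array * eff / 2
    mean_n = base_a - dir_array * eff / 2
    arr = np.concatenate(
        [
            rng.normal(mean_t[:, None], config.array_sd, size=(G, config.n_tumor)),
            rng.normal(mean_n[:, None], config.array_sd, size=(G, config.n_normal)),
        ],
        axis=1,
    )
    batches = None
    if config.n_batches > 1:
        labels = rng.integers(config.n_batches, size=arr.shape[1])
        offsets = rng.normal(0.0, config.batch_effect_sd, size=(G, config.n_batches))
        arr = arr + offsets[:, labels]
        batches = pd.Series([f"B{b + 1}" for b in labels], index=a_tum + a_nor, name="batch")
    array_em = ExpressionMatrix(
        pd.DataFrame(arr, index=genes, columns=a_tum + a_nor), kind="array"
    )

    # --- RNA-seq platform ---
    s_tum, s_nor = _sample_ids("S_", config.n_tumor, config.n_normal)
    n_samp = config.n_tumor + config.n_normal
    lo, hi = config.libsize_range
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samp))
    base_c = np.exp(rng.uniform(*np.log(config.base_abundance), size=G))
    fc = np.concatenate(
        [
            2.0 ** (dir_seq[:, None] * eff / 2) * np.ones((G, config.n_tumor)),
            2.0 ** (-dir_seq[:, None] * eff / 2) * np.ones((G, config.n_normal)),
        ],
        axis=1,
    )
    mu = base_c[:, None] * (lib[None, :] / 1e6) * fc

    # planted anchor-correlation block: genes share a latent sample factor
    anchor = config.anchor_gene
    pos_idx = neg_idx = np.array([], dtype=int)
    if anchor is not None:
        if anchor not in genes:
            raise ConfigError(f"anchor_gene {anchor!r} not among simulated genes")
        a_idx = genes.index(anchor)
        latent = rng.normal(0.0, 1.0, size=n_samp)
        free = np.setdiff1d(np.arange(G), np.concatenate([de_idx, [a_idx]]))
        picked = rng.choice(
            free, size=min(len(free), config.n_pos_correlated + config.n_neg_correlated), replace=False
        )
        pos_idx = picked[: config.n_pos_correlated]
        neg_idx = picked[config.n_pos_correlated :]
        rho = config.corr_strength
        mu[a_idx] *= 2.0 ** latent
        mu[pos_idx] *= 2.0 ** (rho * latent[None, :])
        mu[neg_idx] *= 2.0 ** (-rho * latent[None, :])

    phi = config.nb_dispersion
    if phi > 0:
        lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    else:
        lam = mu
    counts = rng.poisson(lam)
    counts_em = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=s_tum + s_nor), kind="counts"
    )

    truth = pd.DataFrame(
        {
            "planted": direction != 0,
            "direction_array": dir_array,
            "direction_seq": dir_seq,
            "log2_effect": np.where(direction != 0, eff, 0.0),
            "discordant": np.isin(np.arange(G), disc_idx),
            "correlation_block": np.where(
                np.isin(np.arange(G), pos_idx), "pos", np.where(np.isin(np.arange(G), neg_idx), "neg", "")
            ),
        },
        index=genes,
    )
    return ExpressionPair(
        array=array_em,
        counts=counts_em,
        array_groups=_groups(a_tum, a_nor),
        seq_groups=_groups(s_tum, s_nor),
        truth=truth,
        batches=batches,
    )


@dataclass
class MethylationSim:
    beta: ExpressionMatrix
    cpg_map: pd.Series
    groups: pd.Series
    truth: pd.DataFrame


def simulate_methylation(config: CohortConfig) -> MethylationSim:
    """Multi-CpG beta values with planted gene-level shifts and NA masking.

    Beta values are inverse-logit of Normal variates; a planted gene shifts
    all its CpGs in one direction on the logit scale, a ``mixed`` gene shifts
    half its CpGs up and half down (so the gene-level caller must exclude
    it), and missing entries are masked at the configured rate.
    """
    rng = config.rng("methylation")
    genes = gene_names(config)
    G = config.n_genes
    tum, nor = _sample_ids("M_", config.n_tumor, config.n_normal)
    n_samp = len(tum) + len(nor)

    n_de = int(round(G * config.meth_de_fraction))
    n_mixed = int(round(G * config.meth_mixed_fraction))
    picked = rng.choice(G, size=n_de + n_mixed, replace=False)
    de_idx, mixed_idx = picked[:n_de], picked[n_de:]
    gene_dir = np.zeros(G, dtype=int)
    gene_dir[de_idx] = rng.choice([-1, 1], size=n_de)

    lo, hi = config.cpgs_per_gene
    n_sites = rng.integers(lo, hi + 1, size=G)
    cpg_ids, cpg_gene, site_dir = [], [], []
    for gi, g in enumerate(genes):
        for si in range(n_sites[gi]):
            cpg_ids.append(f"cg_{g}_{si + 1}")
            cpg_gene.append(g)
            if gi in mixed_idx:
                site_dir.append(1 if si % 2 == 0 else -1)
            else:
                site_dir.append(gene_dir[gi])
    site_dir = np.array(site_dir)
    S = len(cpg_ids)

    base = rng.uniform(*config.meth_baseline_logit, size=S)
    shift = config.meth_shift
    mean_t = base + site_dir * shift / 2
    mean_n = base - site_dir * shift / 2
    lg = np.concatenate(
        [
            rng.normal(mean_t[:, None], config.meth_sd, size=(S, len(tum))),
            rng.normal(mean_n[:, None], config.meth_sd, size=(S, len(nor))),
        ],
        axis=1,
    )
    beta = expit(lg)
    if config.meth_na_rate > 0:
        mask = rng.random(size=beta.shape) < config.meth_na_rate
        beta = np.where(mask, np.nan, beta)
    beta_df = pd.DataFrame(beta, index=cpg_ids, columns=tum + nor)

    call = np.where(
        gene_dir > 0, "hyper", np.where(gene_dir < 0, "hypo", "none")
    ).astype(object)
    call[mixed_idx] = "mixed"
    truth = pd.DataFrame({"call": call, "n_sites": n_sites}, index=genes)
    return MethylationSim(
        beta=ExpressionMatrix(beta_df, kind="beta"),
        cpg_map=pd.Series(cpg_gene, index=pd.Index(cpg_ids, name="cpg_id"), name="gene"),
        groups=_groups(tum, nor),
        truth=truth,
    )


def simulate_clinical_survival(
    config: CohortConfig, expression: ExpressionMatrix, groups: pd.Series
) -> tuple[pd.DataFrame, ExpressionMatrix]:
    """Clinical sheet with proportional-hazards survival ground truth.

    Event times are Weibull with linear predictor
    sum_g beta_g * standardized expression of the hazard genes over tumor
    samples; censoring occurs with the configured probability, uniformly on
    (0, T).  Stage and N/M labels are drawn from the configured
    distributions; genes named in ``stage_trend_genes`` additionally receive
    a monotone per-stage expression shift (returned as the adjusted matrix).
    Overall-survival times are reported in integer days as ``os_time`` /
    ``os_event``.
    """
    rng = config.rng("clinical")
    groups = groups.reindex(expression.samples)
    tumors = groups.index[groups == TUMOR].tolist()
    normals = groups.index[groups == NORMAL].tolist()
    if not tumors:
        raise ConfigError("no tumor samples present")
    nt = len(tumors)

    stages = rng.choice(["I", "II", "III", "IV"], size=nt, p=list(config.stage_probs))
    stage_ord = pd.Series(stages).map({"I": 0, "II": 1, "III": 2, "IV": 3}).to_numpy()

    expr = expression.values.astype(float).copy()
    for g, delta in config.stage_trend_genes.items():
        if g in expr.index:
            vals = expr.loc[g, tumors].to_numpy()
            if expression.kind == "counts":
                # multiplicative trend on counts (log2 delta per stage step)
                expr.loc[g, tumors] = np.rint(vals * 2.0 ** (delta * stage_ord))
            else:
                expr.loc[g, tumors] = vals + delta * stage_ord

    lp = np.zeros(nt)
    for g, beta in config.hazard_genes.items():
        if g not in expr.index:
            raise ConfigError(f"hazard gene {g!r} not in expression matrix")
        vals = expr.loc[g, tumors].to_numpy(dtype=float)
        z = (vals - vals.mean()) / (vals.std() if vals.std() > 0 else 1.0)
        lp += beta * z

    shape, scale = config.weibull_shape, config.weibull_scale
    u = rng.uniform(size=nt)
    t_event = scale * (-np.log(u) / np.exp(lp)) ** (1.0 / shape)
    censored = rng.random(size=nt) < config.censoring_rate
    obs_time = np.where(censored, rng.uniform(size=nt) * t_event, t_event)
    events = (~censored).astype(int)
    if config.censoring_rate >= 1.0:
        warnings.warn("censoring rate is 1.0: every subject is censored")
    obs_time = np.maximum(1, np.round(obs_time)).astype(int)

    def _nm(p_plus: float, x_label: str, zero: str, plus: str) -> np.ndarray:
        r = rng.random(size=nt)
        out = np.where(r < config.nx_prob, x_label, np.where(r < config.nx_prob + p_plus, plus, zero))
        return out

    n_status = _nm(config.n_plus_prob, "NX", "N0", "N+")
    m_status = _nm(config.m_plus_prob, "MX", "M0", "M+")

    afp = np.exp(rng.normal(3.0, 1.2, size=nt))
    size = np.maximum(0.5, rng.normal(4.0, 1.5, size=nt))

    sheet = pd.DataFrame(
        {
            "group": [TUMOR] * nt + [NORMAL] * len(normals),
            "stage": list(stages) + [np.nan] * len(normals),
            "n_status": list(n_status) + [np.nan] * len(normals),
            "m_status": list(m_status) + [np.nan] * len(normals),
            "os_time": list(obs_time) + [np.nan] * len(normals),
            "os_event": list(events) + [np.nan] * len(normals),
            "afp": list(np.round(afp, 2)) + [np.nan] * len(normals),
            "tumor_size": list(np.round(size, 2)) + [np.nan] * len(normals),
            "tnm": list(stage_ord + 1) + [np.nan] * len(normals),
        },
        index=pd.Index(tumors + normals, name="sample_id"),
    )
    return sheet, ExpressionMatrix(expr, kind=expression.kind)


def simulate_genomic_alterations(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Sparse mutation rows and discrete CNV calls for the RNA-seq samples.

    Mutations are per-gene-per-sample Bernoulli draws, emitted as
    Missense_Mutation rows (a configurable fraction of extra Silent rows
    exercises the non-synonymous filter).  CNV calls are drawn per gene with
    the configured deletion/amplification probabilities (deep events are a
    fifth of each).  Returns (mutations, cnv, truth).
    """
    rng = config.rng("alterations")
    genes = gene_names(config)
    tum, _ = _sample_ids("S_", config.n_tumor, config.n_normal)
    rows = []
    rates = np.array([config.mutation_rates.get(g, config.mutation_rate) for g in genes])
    hits = rng.random((config.n_genes, len(tum))) < rates[:, None]
    for gi, g in enumerate(genes):
        for sj in np.flatnonzero(hits[gi]):
            rows.append((g, tum[sj], "Missense_Mutation"))
            if rng.random() < config.silent_fraction:
                rows.append((g, tum[sj], "Silent"))
    mutations = pd.DataFrame(rows, columns=["gene", "sample", "classification"])

    calls = np.zeros((config.n_genes, len(tum)), dtype=int)
    for gi, g in enumerate(genes):
        del_p, amp_p = config.cnv_probs.get(g, (config.cnv_del_prob, config.cnv_amp_prob))
        r = rng.random(len(tum))
        deep = rng.random(len(tum)) < 0.2
        calls[gi] = np.where(
            r < del_p, np.where(deep, -2, -1), np.where(r < del_p + amp_p, np.where(deep, 2, 1), 0)
        )
    cnv = pd.DataFrame(calls, index=genes, columns=tum)

    truth = pd.DataFrame(
        {
            "mutation_rate": rates,
            "del_prob": [config.cnv_probs.get(g, (config.cnv_del_prob, config.cnv_amp_prob))[0] for g in genes],
            "amp_prob": [config.cnv_probs.get(g, (config.cnv_del_prob, config.cnv_amp_prob))[1] for g in genes],
        },
        index=genes,
    )
    return mutations, cnv, truth


@dataclass
class MirnaSim:
    mirna: ExpressionMatrix  # log-scale expression
    lists: dict[str, list[str]]
    groups: pd.Series
    truth: pd.DataFrame


def simulate_mirna_targets(
    config: CohortConfig, target_expression: ExpressionMatrix | None = None, target_groups: pd.Series | None = None
) -> MirnaSim:
    """miRNA expression plus three target-prediction lists.

    Consensus-truth miRNAs appear in at least two lists.  Planted regulator
    miRNAs are overexpressed in tumors and anticorrelated (at the configured
    strength) with the anchor target gene's expression across samples.  When
    no target matrix is supplied the cohort's RNA-seq matrix is regenerated
    from the same config so the correlation refers to the same samples.
    """
    rng = config.rng("mirna")
    if target_expression is None:
        pair = simulate_expression_pair(config)
        target_expression, target_groups = pair.counts, pair.seq_groups
    assert target_groups is not None
    samples = list(target_expression.samples)
    n_samp = len(samples)
    is_tumor = (target_groups.reindex(samples) == TUMOR).to_numpy()

    mirnas = [f"miR-{i + 1:03d}" for i in range(config.n_mirna)]
    member = rng.random((config.n_mirna, 3)) < config.mirna_list_prob
    reg_idx = rng.choice(config.n_mirna, size=min(config.n_regulator_mirnas, config.n_mirna), replace=False)
    for ri in reg_idx:  # regulators are forced into >= 2 lists
        while member[ri].sum() < 2:
            member[ri, rng.integers(3)] = True

    target_gene = config.anchor_gene or target_expression.genes[0]
    tvals = np.log2(target_expression.values.loc[target_gene].to_numpy(dtype=float) + 0.5)
    tz = (tvals - tvals.mean()) / (tvals.std() if tvals.std() > 0 else 1.0)

    rho = config.mirna_anticorr
    base = rng.uniform(4.0, 8.0, size=config.n_mirna)
    expr = rng.normal(0.0, config.mirna_sd, size=(config.n_mirna, n_samp)) + base[:, None]
    for ri in reg_idx:
        noise = rng.normal(0.0, config.mirna_sd, size=n_samp)
        expr[ri] = (
            base[ri]
            - rho * tz * config.mirna_sd
            + np.sqrt(max(0.0, 1 - rho**2)) * noise
            + config.mirna_tumor_shift * is_tumor
        )
    mirna_em = ExpressionMatrix(pd.DataFrame(expr, index=mirnas, columns=samples), kind="mirna")

    names = ("mirtarbase_synthetic", "mirdb_synthetic", "targetscan_synthetic")
    lists = {
        names[j]: [mirnas[i] for i in range(config.n_mirna) if member[i, j]] for j in range(3)
    }
    truth = pd.DataFrame(
        {
            "n_lists": member.sum(axis=1),
            "consensus": member.sum(axis=1) >= 2,
            "regulator": np.isin(np.arange(config.n_mirna), reg_idx),
            "target": target_gene,
        },
        index=mirnas,
    )
    return MirnaSim(mirna=mirna_em, lists=lists, groups=target_groups, truth=truth)


def simulate_pathways(config: CohortConfig, truth: pd.DataFrame) -> GeneSetCollection:
    """Synthetic pathway collection with planted enrichment.

    Random gene sets over the cohort's gene universe, plus a few pathways
    drawn mostly from the planted positive/negative anchor-correlation
    blocks so the enrichment stage has recoverable signal.
    """
    rng = config.rng("pathways")
    genes = np.array(truth.index)
    pos = truth.index[truth["correlation_block"] == "pos"].to_numpy()
    neg = truth.index[truth["correlation_block"] == "neg"].to_numpy()
    sets: dict[str, frozenset[str]] = {}
    lo, hi = config.pathway_size
    n_planted = config.n_planted_pos_pathways + config.n_planted_neg_pathways
    for i in range(config.n_pathways - n_planted):
        size = min(len(genes), int(rng.integers(lo, hi + 1)))
        sets[f"PW_{i + 1:03d}"] = frozenset(rng.choice(genes, size=size, replace=False))
    for block, count in (("pos", config.n_planted_pos_pathways), ("neg", config.n_planted_neg_pathways)):
        pool = pos if block == "pos" else neg
        for i in range(count):
            core = (
                rng.choice(pool, size=min(len(pool), 15), replace=False)
                if len(pool)
                else np.array([], dtype=object)
            )
            pad = rng.choice(genes, size=min(len(genes), 10), replace=False)
            sets[f"PW_{block.upper()}_{i + 1}"] = frozenset(core) | frozenset(pad)
    return GeneSetCollection(sets)


@dataclass
class Cohort:
    """A complete synthetic cohort: every layer plus its truth tables."""

    config: CohortConfig
    expression: ExpressionPair
    methylation: MethylationSim
    samples: pd.DataFrame  # clinical sheet for the RNA-seq cohort
    seq_expression: ExpressionMatrix  # counts after stage-trend adjustment
    mutations: pd.DataFrame
    cnv: pd.DataFrame
    alteration_truth: pd.DataFrame
    mirna: MirnaSim
    pathways: GeneSetCollection


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full multi-omics cohort; pure function of (config, seed)."""
    pair = simulate_expression_pair(config)
    meth = simulate_methylation(config)
    sheet, seq_adj = simulate_clinical_survival(config, pair.counts, pair.seq_groups)
    mutations, cnv, alt_truth = simulate_genomic_alterations(config)
    mirna = simulate_mirna_targets(config, pair.counts, pair.seq_groups)
    pathways = simulate_pathways(config, pair.truth)
    return Cohort(
        config=config,
        expression=pair,
        methylation=meth,
        samples=sheet,
        seq_expression=seq_adj,
        mutations=mutations,
        cnv=cnv,
        alteration_truth=alt_truth,
        mirna=mirna,
        pathways=pathways,
    )


def config_to_dict(config: CohortConfig) -> dict:
    return asdict(config)
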
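"""Two-platform differential expression and the integrated status score S.

Each gene receives a platform status s in {-1, -0.5, 0.5, 1}: magnitude 1
when the BH false-discovery rate is below alpha (default 0.05), 0.5
otherwise, signed by the direction of change in tumors relative to normals
(t statistic on microarray, log2 fold change on RNA-seq).  The integrated
status is

    S = s_array + s_seq   if sgn(s_array) == sgn(s_seq)
    S = 0                 otherwise

so S ranges over {-2, -1.5, -1, 0, 1, 1.5, 2}: |S| = 2 means both platforms
call the gene significantly in the same direction; S = 0 means the platforms
disagree in direction and the gene is treated as not reproducibly altered.

Microarray testing is a classic pooled-variance two-sample Student t test;
RNA-seq testing is an exact negative-binomial test on library-equalized
pseudo-counts with a common method-of-moments dispersion (variance
mu + phi*mu^2), conditioning on each gene's total count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, NormFactors, NORMAL, TUMOR
from .exceptions import AnalysisError, FormatError

STATUS_ALPHABET = (-1.0, -0.5, 0.5, 1.0)
S_ALPHABET = (-2.0, -1.5, -1.0, 0.0, 1.0, 1.5, 2.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN passed through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise AnalysisError("p-values must lie in [0, 1]")
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _split_groups(
    matrix: ExpressionMatrix, groups: pd.Series, min_per_group: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    groups = groups.reindex(matrix.samples)
    if groups.isna().any():
        raise AnalysisError("every sample needs a group label")
    t_cols = np.flatnonzero((groups == TUMOR).to_numpy())
    n_cols = np.flatnonzero((groups == NORMAL).to_numpy())
    if len(t_cols) < min_per_group or len(n_cols) < min_per_group:
        raise AnalysisError(f"need at least {min_per_group} sample(s) per group")
    return t_cols, n_cols


def array_ttest_de(logexpr: ExpressionMatrix, groups: pd.Series, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene pooled-variance Student t test, tumor vs normal.

    Returns a DataFrame indexed by gene with columns ``statistic`` (t, tumor
    minus normal), ``pvalue``, ``fdr`` (BH across all genes in the matrix)
    and ``direction`` in {-1, 0, +1}.  Genes whose statistic is undefined
    (zero variance in both groups with equal means) get NaN p and are
    excluded from the adjustment.
    """
    t_cols, n_cols = _split_groups(logexpr, groups)
    mat = logexpr.values.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(mat[:, t_cols], mat[:, n_cols], axis=1, equal_var=True)
    tstat = np.asarray(res.statistic, dtype=float)
    pval = np.asarray(res.pvalue, dtype=float)
    pval[np.isnan(tstat)] = np.nan
    out = pd.DataFrame(
        {
            "statistic": tstat,
            "pvalue": pval,
            "fdr": bh_adjust(pval),
            "direction": np.sign(np.nan_to_num(tstat)).astype(int),
        },
        index=logexpr.genes,
    )
    return out


def estimate_common_dispersion(scaled: np.ndarray, t_cols: np.ndarray, n_cols: np.ndarray) -> float:
    """Method-of-moments common NB dispersion on library-equalized counts.

    Per gene, pools the within-group variance and solves var = mu + phi*mu^2;
    the common value is the median of per-gene estimates (clipped at 0) over
    genes with positive mean.
    """
    phis = []
    for cols in (t_cols, n_cols):
        sub = scaled[:, cols]
        mu = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = mu > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = (v[ok] - mu[ok]) / mu[ok] ** 2
        phis.append(phi)
    allphi = np.concatenate(phis)
    allphi = allphi[np.isfinite(allphi)]
    if allphi.size == 0:
        return 0.0
    return float(max(0.0, np.median(allphi)))


def _nb_exact_pvalue(a: int, s: int, n1: int, n2: int, phi: float) -> float:
    """Exact two-sided NB test of a group-1 sum ``a`` given total ``s``.

    Group sums of n iid NB(mu, phi) variables are NB with mean n*mu and size
    n/phi.  The conditional distribution of the group-1 sum given the total
    is computed by direct convolution over k = 0..s and the two-sided p-value
    sums all outcomes no more probable than the observed one.  In the
    phi -> 0 limit this is the exact binomial split test.
    """
    if s == 0:
        return 1.0
    k = np.arange(s + 1)
    if phi <= 0:
        logp = stats.binom.logpmf(k, s, n1 / (n1 + n2))
    else:
        mu = s / (n1 + n2)
        r1, r2 = n1 / phi, n2 / phi
        lp1 = stats.nbinom.logpmf(k, r1, r1 / (r1 + n1 * mu))
        lp2 = stats.nbinom.logpmf(s - k, r2, r2 / (r2 + n2 * mu))
        logp = lp1 + lp2
        logp -= np.max(logp)
    prob = np.exp(logp)
    prob /= prob.sum()
    return float(min(1.0, prob[prob <= prob[a] * (1 + 1e-10)].sum()))


def count_nb_de(
    counts: ExpressionMatrix,
    factors: NormFactors,
    groups: pd.Series,
    alpha: float = 0.05,
    prior: float = 0.5,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Per-gene exact negative-binomial test on RNA-seq counts.

    Counts are scaled to a common (geometric-mean) effective library size and
    rounded to pseudo-counts; a common dispersion is estimated by the method
    of moments unless supplied.  ``statistic`` is the log2 fold change of
    normalized group means (with pseudocount ``prior``); all-zero genes are
    skipped (``tested`` False) and excluded from the BH adjustment.
    """
    # the exact conditional test is defined even for a single sample per group
    t_cols, n_cols = _split_groups(counts, groups, min_per_group=1)
    mat = counts.values.to_numpy(dtype=float)
    eff = factors.effective_lib_sizes.reindex(counts.samples).to_numpy()
    target = np.exp(np.mean(np.log(eff)))
    scaled = mat * (target / eff)
    pseudo = np.rint(scaled).astype(np.int64)

    if dispersion is None:
        dispersion = estimate_common_dispersion(scaled, t_cols, n_cols)

    n1, n2 = len(t_cols), len(n_cols)
    cpm = mat / eff * 1e6
    mean_t = cpm[:, t_cols].mean(axis=1)
    mean_n = cpm[:, n_cols].mean(axis=1)
    log2fc = np.log2((mean_t + prior) / (mean_n + prior))

    ngenes = mat.shape[0]
    pval = np.full(ngenes, np.nan)
    tested = np.zeros(ngenes, dtype=bool)
    for i in range(ngenes):
        a = int(pseudo[i, t_cols].sum())
        b = int(pseudo[i, n_cols].sum())
        if a + b == 0:
            continue
        tested[i] = True
        pval[i] = _nb_exact_pvalue(a, a + b, n1, n2, dispersion)

    out = pd.DataFrame(
        {
            "statistic": log2fc,
            "pvalue": pval,
            "fdr": bh_adjust(pval),
            "direction": np.sign(log2fc).astype(int),
            "tested": tested,
        },
        index=counts.genes,
    )
    out.attrs["dispersion"] = float(dispersion)
    return out


def assign_platform_status(fdr: float, direction: int, alpha: float = 0.05) -> float:
    """Map one platform's DE result to its status s.

    +/-1 when FDR < alpha, +/-0.5 otherwise, signed by direction.  An
    undefined direction (statistic exactly 0, or untested gene) yields NaN
    and the gene is excluded from integration.
    """
    if direction == 0 or not np.isfinite(fdr):
        return float("nan")
    mag = 1.0 if fdr < alpha else 0.5
    return mag if direction > 0 else -mag


def integrate_status(s_array: float, s_seq: float) -> float:
    """Integrated status S: the sum when platform signs agree, else 0."""
    if np.isnan(s_array) or np.isnan(s_seq):
        return float("nan")
    for s in (s_array, s_seq):
        if s not in STATUS_ALPHABET:
            raise AnalysisError(f"platform status {s} outside {STATUS_ALPHABET}")
    if np.sign(s_array) == np.sign(s_seq):
        return float(s_array + s_seq)
    return 0.0


def status_table(de_array: pd.DataFrame, de_seq: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Join per-platform DE results into the gene-level status table.

    Returns columns ``s_array``, ``s_seq`` and the integrated ``S`` for the
    genes present on both platforms.
    """
    genes = de_array.index.intersection(de_seq.index)
    rows = []
    for g in genes:
        sa = assign_platform_status(de_array.at[g, "fdr"], de_array.at[g, "direction"], alpha)
        ss = assign_platform_status(de_seq.at[g, "fdr"], de_seq.at[g, "direction"], alpha)
        S = integrate_status(sa, ss) if not (np.isnan(sa) or np.isnan(ss)) else float("nan")
        rows.append((g, sa, ss, S))
    return pd.DataFrame(rows, columns=["gene", "s_array", "s_seq", "S"]).set_index("gene")
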
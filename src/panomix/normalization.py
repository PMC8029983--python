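"""Count normalization: TMM factors, log-CPM, and per-batch centering.

TMM (trimmed mean of M-values) computes one scaling factor per sample from
the doubly trimmed, precision-weighted mean of gene-wise log-ratios against a
reference sample.  Genes with a zero count in either sample are excluded;
30% of genes are trimmed on each tail of the M (log-ratio) distribution and
5% on each tail of the A (log-abundance) distribution; factors are rescaled
to geometric mean 1.  The reference is the sample whose 75th count-fraction
percentile is closest to the cohort mean of that percentile.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, NormFactors
from .exceptions import AnalysisError

M_TRIM = 0.30
A_TRIM = 0.05


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float) -> float:
    """Weighted trimmed log2 ratio of one sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    if keep.sum() == 0:
        return 1.0
    p_obs = obs[keep] / n_obs
    p_ref = ref[keep] / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # approximate delta-method variance of M; weights are its inverse
    w = (n_obs - obs[keep]) / (n_obs * obs[keep]) + (n_ref - ref[keep]) / (n_ref * ref[keep])

    n = m.size
    lo_m, hi_m = np.floor(n * M_TRIM), np.ceil(n * (1 - M_TRIM))
    lo_a, hi_a = np.floor(n * A_TRIM), np.ceil(n * (1 - A_TRIM))
    rank_m = pd.Series(m).rank(method="first").to_numpy()
    rank_a = pd.Series(a).rank(method="first").to_numpy()
    keep2 = (rank_m > lo_m) & (rank_m <= hi_m) & (rank_a > lo_a) & (rank_a <= hi_a)
    if keep2.sum() == 0 or w[keep2].sum() == 0:
        return 1.0
    f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    return float(2.0 ** f)


def tmm_factors(counts: ExpressionMatrix, ref: str | None = None) -> NormFactors:
    """TMM scaling factors for a nonnegative-integer count matrix.

    Parameters
    ----------
    counts
        ``kind='counts'`` matrix, at least two samples.
    ref
        Reference sample id, or None to pick it automatically (sample whose
        upper-quartile count fraction is closest to the cohort mean).
    """
    mat = counts.values.to_numpy(dtype=float)
    samples = counts.samples
    if len(samples) < 2:
        raise AnalysisError("TMM requires at least two samples")
    lib = mat.sum(axis=0)
    if (lib == 0).any():
        bad = samples[lib == 0].tolist()
        raise AnalysisError(f"all-zero sample(s): {bad}")
    if ref is None:
        f75 = np.quantile(mat / lib, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        if ref not in samples:
            raise AnalysisError(f"reference sample {ref!r} not in matrix")
        ref_idx = samples.get_loc(ref)
    ref_col = mat[:, ref_idx]
    factors = np.array(
        [
            1.0 if j == ref_idx else _tmm_pair(mat[:, j], ref_col, lib[j], lib[ref_idx])
            for j in range(mat.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return NormFactors(
        factors=pd.Series(factors, index=samples, name="factor"),
        lib_sizes=pd.Series(lib, index=samples, name="lib_size"),
        ref_sample=str(samples[ref_idx]),
    )


def log_cpm(counts: ExpressionMatrix, factors: NormFactors, prior: float = 0.5) -> ExpressionMatrix:
    """log2 counts-per-million on effective library sizes.

    log2((count + prior) / (effective libsize + 2*prior) * 1e6); a positive
    prior keeps zero counts finite.
    """
    if not counts.samples.equals(factors.factors.index):
        if set(counts.samples) != set(factors.factors.index):
            raise AnalysisError("sample sets of counts and factors differ")
    eff = factors.effective_lib_sizes.reindex(counts.samples).to_numpy()
    mat = counts.values.to_numpy(dtype=float)
    out = np.log2((mat + prior) / (eff + 2 * prior) * 1e6)
    return ExpressionMatrix(pd.DataFrame(out, index=counts.genes, columns=counts.samples), kind="array")


def batch_adjust(logexpr: ExpressionMatrix, batches: pd.Series) -> ExpressionMatrix:
    """Remove per-gene batch location effects, preserving the grand mean.

    Per gene, each batch's mean is shifted onto the gene's grand mean;
    within-batch variance is untouched.  A batch with a single sample is
    passed through with a warning (its mean is not estimable separately from
    its residual).
    """
    batches = batches.reindex(logexpr.samples)
    if batches.isna().any():
        raise AnalysisError("every sample needs a batch label")
    mat = logexpr.values.to_numpy(dtype=float).copy()
    grand = mat.mean(axis=1, keepdims=True)
    for b in pd.unique(batches):
        cols = np.flatnonzero((batches == b).to_numpy())
        if len(cols) == 1:
            warnings.warn(f"batch {b!r} has a single sample; passed through unadjusted")
            continue
        bmean = mat[:, cols].mean(axis=1, keepdims=True)
        mat[:, cols] += grand - bmean
    return ExpressionMatrix(
        pd.DataFrame(mat, index=logexpr.genes, columns=logexpr.samples), kind=logexpr.kind
    )
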
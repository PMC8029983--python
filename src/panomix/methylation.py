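"""450K-style beta-value processing and the all-sites-consistent gene call.

Sites missing in at least half of the samples are dropped; remaining missing
betas are imputed with the site's minimum observed value.  Differential
methylation per CpG uses the Wilcoxon rank-sum test (exact for small
tie-free groups, tie-corrected normal approximation otherwise) with BH
adjustment across sites; direction compares group medians.  A gene is called
hypermethylated (+1) or hypomethylated (-1) only when *every* one of its CpG
sites is significant in that one direction; genes with significant sites in
both directions are excluded from downstream analysis; anything else is
"none".
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, NORMAL, TUMOR
from .destatus import bh_adjust
from .exceptions import AnalysisError

HYPER, HYPO, EXCLUDED, NONE = "hyper", "hypo", "excluded", "none"
_CODE = {HYPER: 1.0, HYPO: -1.0, NONE: 0.0, EXCLUDED: float("nan")}


def filter_impute_cpgs(beta: ExpressionMatrix, max_na_fraction: float = 0.5) -> tuple[ExpressionMatrix, list[str]]:
    """Drop high-missingness CpG sites and impute the rest.

    A site missing in >= ``max_na_fraction`` of samples (default one half) is
    removed; each remaining missing beta becomes that site's minimum observed
    value, so imputation never changes a site's minimum nor leaves [0, 1].
    Returns the completed matrix and the list of dropped sites.
    """
    df = beta.values
    na_frac = df.isna().mean(axis=1)
    dropped = df.index[na_frac >= max_na_fraction].tolist()
    all_na = df.index[df.isna().all(axis=1)]
    if len(all_na):
        warnings.warn(f"{len(all_na)} CpG site(s) missing in all samples; dropped")
    kept = df.loc[na_frac < max_na_fraction].copy()
    mins = kept.min(axis=1, skipna=True)
    kept = kept.T.fillna(mins).T
    return ExpressionMatrix(kept, kind="beta"), dropped


def cpg_wilcoxon(beta: ExpressionMatrix, groups: pd.Series, alpha: float = 0.05) -> pd.DataFrame:
    """Per-site Wilcoxon rank-sum test, tumor vs normal.

    Returns per CpG: ``pvalue``, ``fdr`` (BH across sites), ``direction``
    (sign of tumor median minus normal median) and the resulting ``call``
    (hyper/hypo at FDR < alpha, else none).  A site constant across all
    samples gets p = 1 and no direction.
    """
    groups = groups.reindex(beta.samples)
    if groups.isna().any():
        raise AnalysisError("every sample needs a group label")
    t_cols = (groups == TUMOR).to_numpy()
    n_cols = (groups == NORMAL).to_numpy()
    if t_cols.sum() < 2 or n_cols.sum() < 2:
        raise AnalysisError("need at least two samples per group")
    mat = beta.values.to_numpy(dtype=float)
    pvals = np.ones(mat.shape[0])
    direction = np.zeros(mat.shape[0], dtype=int)
    for i in range(mat.shape[0]):
        x, y = mat[i, t_cols], mat[i, n_cols]
        if np.ptp(mat[i]) == 0:
            continue
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        pvals[i] = res.pvalue
        direction[i] = int(np.sign(np.median(x) - np.median(y)))
    fdr = bh_adjust(pvals)
    call = np.where(
        (fdr < alpha) & (direction > 0), HYPER, np.where((fdr < alpha) & (direction < 0), HYPO, NONE)
    )
    return pd.DataFrame(
        {"pvalue": pvals, "fdr": fdr, "direction": direction, "call": call}, index=beta.genes
    )


def gene_methylation_status(
    site_calls: pd.DataFrame, cpg_map: pd.Series, require_all_sites: bool = True
) -> pd.DataFrame:
    """Collapse per-site calls to the per-gene consistency call.

    With the default strict rule: all sites hyper -> hyper (+1); all sites
    hypo -> hypo (-1); significant sites in both directions -> excluded; any
    non-significant site otherwise -> none.  ``require_all_sites=False``
    relaxes the rule to "at least one significant site and no significant
    site in the opposite direction".  Every site must be mapped to a gene.
    """
    unmapped = site_calls.index.difference(cpg_map.index)
    if len(unmapped):
        raise AnalysisError(f"unmapped CpG site(s): {unmapped.tolist()[:5]}")
    calls = site_calls["call"]
    mapped = cpg_map.reindex(site_calls.index)
    rows = []
    for gene, sites in mapped.groupby(mapped):
        site_ids = sites.index
        c = set(calls.loc[site_ids])
        if HYPER in c and HYPO in c:
            call = EXCLUDED
        elif c == {HYPER} or (not require_all_sites and HYPER in c):
            call = HYPER
        elif c == {HYPO} or (not require_all_sites and HYPO in c):
            call = HYPO
        else:
            call = NONE
        rows.append((gene, call, _CODE[call], len(site_ids)))
    return pd.DataFrame(rows, columns=["gene", "call", "code", "n_sites"]).set_index("gene")
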
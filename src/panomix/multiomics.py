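"""Alteration frequency summaries and expression-consistency annotation.

Mutation frequency is the percentage of profiled samples carrying at least
one non-synonymous mutation in the gene (multiplicity ignored).
Amplification/deletion frequencies are the percentages of samples with a
positive/negative thresholded copy-number call; deletions are reported with
a negative sign.  A copy-number alteration is annotated *consistent* with
expression when its dominant direction matches the sign of the integrated
expression status S, the dominant frequency reaches a threshold (default
10%), and S is nonzero.  A methylation call is consistent when it opposes
expression: hypermethylation with S < 0, hypomethylation with S > 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import AnalysisError


def alteration_frequencies(
    mutations: pd.DataFrame,
    cnv: pd.DataFrame | None,
    samples: list[str],
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene mutation and CNV frequencies over a fixed sample universe.

    Parameters
    ----------
    mutations
        Minimal mutation table (gene, sample, classification), already
        filtered to non-synonymous classes.
    cnv
        Gene x sample discrete call table, or None.
    samples
        The profiled sample universe; frequencies are percentages of it.
    genes
        Gene panel to report (default: union of genes seen in either layer).

    Returns a DataFrame indexed by gene with ``mut_pct``, ``amp_pct``
    (signed +) and ``del_pct`` (signed -).
    """
    samples = list(samples)
    n = len(samples)
    if n == 0:
        raise AnalysisError("zero profiled samples")
    if genes is None:
        genes = sorted(set(mutations["gene"]) | (set(cnv.index) if cnv is not None else set()))
    sset = set(samples)
    mut_in = mutations[mutations["sample"].isin(sset)]
    mut_counts = mut_in.groupby("gene")["sample"].nunique()
    rows = []
    for g in genes:
        mut_pct = 100.0 * mut_counts.get(g, 0) / n
        amp_pct = del_pct = 0.0
        if cnv is not None and g in cnv.index:
            calls = cnv.loc[g, [s for s in samples if s in cnv.columns]]
            denom = len(calls)
            if denom:
                amp_pct = 100.0 * (calls > 0).sum() / denom
                del_pct = -100.0 * (calls < 0).sum() / denom
        rows.append((g, mut_pct, amp_pct, del_pct))
    out = pd.DataFrame(rows, columns=["gene", "mut_pct", "amp_pct", "del_pct"]).set_index("gene")
    return out


def summarize_panel(summary: pd.DataFrame) -> dict[str, float]:
    """Panel-level means: mean mutation rate and mean |CNV| frequencies (%)."""
    return {
        "mean_mut_pct": float(summary["mut_pct"].mean()),
        "mean_amp_pct": float(summary["amp_pct"].mean()),
        "mean_del_pct": float(summary["del_pct"].abs().mean()),
    }


def dominant_cnv_direction(amp_pct: float, del_pct: float) -> tuple[int, float]:
    """The more frequent CNV direction and its (unsigned) frequency.

    Returns (+1, amp%) or (-1, |del%|); ties or all-zero yield (0, 0).
    """
    amp, dele = float(amp_pct), abs(float(del_pct))
    if amp > dele:
        return 1, amp
    if dele > amp:
        return -1, dele
    return 0, 0.0


def consistency_annotation(
    status: pd.DataFrame,
    summary: pd.DataFrame,
    gene_meth: pd.DataFrame | None = None,
    min_cnv_freq: float = 10.0,
) -> pd.DataFrame:
    """Flag CNV and methylation alterations consistent with expression.

    ``status`` carries the integrated S per gene; ``summary`` the alteration
    frequencies; ``gene_meth`` the per-gene methylation call codes (+1 hyper,
    -1 hypo).  Rows are emitted only where both an expression status (S != 0)
    and an alteration direction exist.
    """
    rows = []
    for g in status.index:
        S = status.at[g, "S"]
        if not np.isfinite(S) or S == 0:
            continue
        if g in summary.index:
            direction, freq = dominant_cnv_direction(
                summary.at[g, "amp_pct"], summary.at[g, "del_pct"]
            )
            if direction != 0:
                consistent = bool(direction == np.sign(S) and freq >= min_cnv_freq)
                rows.append((g, "cnv", direction, freq, consistent))
        if gene_meth is not None and g in gene_meth.index:
            code = gene_meth.at[g, "code"]
            if np.isfinite(code) and code != 0:
                # methylation opposes expression when consistent
                consistent = bool((code > 0 and S < 0) or (code < 0 and S > 0))
                rows.append((g, "methylation", int(code), np.nan, consistent))
    return pd.DataFrame(
        rows, columns=["gene", "layer", "direction", "frequency", "consistent"]
    )
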
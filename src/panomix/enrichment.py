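"""Anchor-gene correlation screening, hypergeometric pathway enrichment,
cross-dataset intersection, and miRNA target consensus.

The correlation screen selects genes whose Pearson correlation with an
anchor gene is significant at raw p < 0.05 (the selection is deliberately
unadjusted; only the enrichment step controls the FDR), split into positive
and negative sets.  Pathway enrichment is the upper-tail hypergeometric test
P(X >= k) over a fixed universe with BH adjustment across pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GeneSetCollection
from .destatus import array_ttest_de, bh_adjust
from .exceptions import AnalysisError


@dataclass
class CorrelationScreen:
    anchor: str
    table: pd.DataFrame  # per gene: r, pvalue
    positive: list[str] = field(default_factory=list)
    negative: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)  # zero-variance genes


def pearson_screen(anchor: str, expression: ExpressionMatrix, alpha: float = 0.05) -> CorrelationScreen:
    """Correlate every gene with the anchor gene across samples.

    p-values come from the t transform t = r * sqrt((n-2) / (1-r^2)) with
    n-2 degrees of freedom, two-sided.  Zero-variance genes are excluded and
    reported; the anchor itself belongs to neither set.
    """
    if anchor not in expression.genes:
        raise AnalysisError(f"anchor gene {anchor!r} not in matrix")
    mat = expression.values
    n = mat.shape[1]
    if n < 3:
        raise AnalysisError("need at least three samples for correlation")
    a = mat.loc[anchor].to_numpy(dtype=float)
    if np.std(a) == 0:
        raise AnalysisError("anchor gene has zero variance")
    x = mat.to_numpy(dtype=float)
    sd = x.std(axis=1)
    ok = sd > 0
    dropped = mat.index[~ok].tolist()
    xc = x[ok] - x[ok].mean(axis=1, keepdims=True)
    ac = a - a.mean()
    r = (xc @ ac) / (np.sqrt((xc**2).sum(axis=1)) * np.sqrt((ac**2).sum()))
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    table = pd.DataFrame({"r": r, "pvalue": p}, index=mat.index[ok])
    sig = table[(table["pvalue"] < alpha) & (table.index != anchor)]
    return CorrelationScreen(
        anchor=anchor,
        table=table,
        positive=sig.index[sig["r"] > 0].tolist(),
        negative=sig.index[sig["r"] < 0].tolist(),
        dropped=dropped,
    )


def hypergeom_enrich(
    query: list[str],
    sets: GeneSetCollection,
    universe: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a query gene list.

    For each pathway intersected with the universe: p = P(X >= k) with
    X ~ Hypergeometric(N=|universe|, K=|set|, n=|query|); BH across pathways;
    ``significant`` flags FDR < alpha.
    """
    uni = set(universe)
    if not uni:
        raise AnalysisError("empty universe")
    q = set(query) & uni
    if not set(query):
        raise AnalysisError("empty query")
    n = len(q)
    N = len(uni)
    rows = []
    for name, genes in sets.sets.items():
        K = len(genes & uni)
        if K == 0:
            continue
        k = len(genes & q)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, p))
    out = pd.DataFrame(rows, columns=["pathway", "overlap", "set_size", "query_size", "universe", "pvalue"])
    out["fdr"] = bh_adjust(out["pvalue"].to_numpy()) if len(out) else []
    out["significant"] = out["fdr"] < alpha
    return out.set_index("pathway")


def enrichment_universe(expression: ExpressionMatrix, sets: GeneSetCollection, policy: str = "annotated") -> list[str]:
    """Build the enrichment universe from the matrix and the collection.

    ``annotated``: matrix genes belonging to >= 1 pathway (default);
    ``matrix``: all matrix genes.
    """
    if policy == "annotated":
        return sorted(set(expression.genes) & sets.all_genes())
    if policy == "matrix":
        return sorted(expression.genes)
    raise AnalysisError(f"unknown universe policy {policy!r}")


def common_pathways(per_dataset: list[list[str]]) -> list[str]:
    """Pathways significant in every dataset (order-independent)."""
    if len(per_dataset) < 2:
        raise AnalysisError("need at least two datasets to intersect")
    common = set(per_dataset[0])
    for lst in per_dataset[1:]:
        common &= set(lst)
    return sorted(common)


def mirna_consensus(lists: dict[str, list[str]], min_support: int = 2) -> pd.DataFrame:
    """miRNAs supported by at least ``min_support`` of the target databases.

    Returns per-miRNA membership columns plus ``support`` and ``consensus``;
    duplicates within one list count once.
    """
    if min_support > len(lists):
        raise AnalysisError("min_support exceeds the number of lists")
    names = list(lists)
    all_mirnas = sorted(set().union(*(set(v) for v in lists.values())))
    out = pd.DataFrame(index=pd.Index(all_mirnas, name="mirna"))
    for name in names:
        out[name] = out.index.isin(set(lists[name]))
    out["support"] = out[names].sum(axis=1)
    out["consensus"] = out["support"] >= min_support
    return out


def mirna_de(mirna_log: ExpressionMatrix, groups: pd.Series, mirnas: list[str] | None = None, alpha: float = 0.05) -> pd.DataFrame:
    """Student t DE of (consensus) miRNAs between tumor and normal samples.

    Operates on a log-scale miRNA matrix; BH across the tested miRNAs; adds a
    ``call`` column (+1 overexpressed in tumor / -1 under / 0) at FDR < alpha.
    """
    if mirnas is not None:
        present = [m for m in mirnas if m in mirna_log.genes]
        mirna_log = ExpressionMatrix(mirna_log.values.loc[present], kind=mirna_log.kind)
    de = array_ttest_de(mirna_log, groups, alpha=alpha)
    de["call"] = np.where(de["fdr"] < alpha, de["direction"], 0)
    return de
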
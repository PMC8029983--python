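"""Cancer-progression comparisons: metastasis DE and stage-wise testing.

Tumor samples are partitioned into metastatic (N+ or M+), non-metastatic
(N0 and M0) and excluded (NX/MX/missing).  Metastatic-vs-non-metastatic
differential expression reuses the pooled-variance Student t machinery with
BH adjustment and a +/-1 encoding at FDR < 0.05; groups below a minimum size
(default 10) are skipped with a warning.  Stage-wise testing runs a one-way
fixed-effects ANOVA with Tukey-Kramer post-hoc pairwise comparisons plus a
pooled early (I-II) vs late (III-IV) Student t contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, MetastasisGroups, TUMOR
from .destatus import array_ttest_de
from .exceptions import AnalysisError

EARLY_STAGES = ("I", "II")
LATE_STAGES = ("III", "IV")


def split_metastasis(samples: pd.DataFrame) -> MetastasisGroups:
    """Partition tumor samples by nodal/distant metastasis status.

    Metastatic: N+ or M+.  Non-metastatic: N0 and M0.  Everything else
    (NX, MX, missing) is excluded.  Deterministic and order-independent.
    """
    if "n_status" not in samples.columns and "m_status" not in samples.columns:
        raise AnalysisError("sample sheet has neither n_status nor m_status")
    tumors = samples[samples["group"] == TUMOR]
    n = tumors.get("n_status", pd.Series(index=tumors.index, dtype=object))
    m = tumors.get("m_status", pd.Series(index=tumors.index, dtype=object))
    groups = MetastasisGroups()
    for sid in tumors.index:
        ns, ms = n.get(sid), m.get(sid)
        if ns == "N+" or ms == "M+":
            groups.metastatic.append(sid)
        elif ns == "N0" and ms == "M0":
            groups.non_metastatic.append(sid)
        else:
            groups.excluded.append(sid)
    return groups


def metastasis_de(
    logexpr: ExpressionMatrix,
    groups: MetastasisGroups,
    alpha: float = 0.05,
    min_group_size: int = 10,
) -> pd.DataFrame | None:
    """Metastatic vs non-metastatic Student t DE on tumor expression.

    Returns the DE table with an extra ``call`` column (+1/-1 at FDR < alpha,
    else 0), or None when either group is below ``min_group_size`` (skipped
    with a warning, mirroring small-cohort exclusions).
    """
    n_met, n_non = len(groups.metastatic), len(groups.non_metastatic)
    if min(n_met, n_non) < min_group_size:
        warnings.warn(
            f"metastasis DE skipped: group sizes {n_met}/{n_non} below minimum {min_group_size}"
        )
        return None
    cols = groups.metastatic + groups.non_metastatic
    labels = pd.Series(
        ["tumor"] * n_met + ["normal"] * n_non, index=cols
    )  # reuse tumor/normal slots: 'tumor'=metastatic
    sub = ExpressionMatrix(logexpr.values[cols], kind=logexpr.kind)
    de = array_ttest_de(sub, labels, alpha=alpha)
    de["call"] = np.where(de["fdr"] < alpha, de["direction"], 0)
    return de


@dataclass
class StageComparison:
    """One gene's stage-wise comparison results."""

    f_statistic: float
    anova_p: float
    pairwise: pd.DataFrame  # stage_a, stage_b, p_adj (Tukey-Kramer)
    early_late_t: float = float("nan")
    early_late_p: float = float("nan")
    stages_used: list[str] = field(default_factory=list)


def stage_anova_tukey(values: pd.Series, stages: pd.Series) -> StageComparison:
    """One-way ANOVA over stages with Tukey-Kramer post-hoc pairs.

    Stages with fewer than two samples are dropped with a warning; at least
    two usable stages are required.  Also reports the pooled early (I-II) vs
    late (III-IV) Student t contrast when both pools have two or more
    samples.
    """
    df = pd.DataFrame({"value": values, "stage": stages}).dropna()
    sizes = df.groupby("stage")["value"].size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"stage(s) {small} dropped: fewer than 2 samples")
        df = df[~df["stage"].isin(small)]
    order = [s for s in ("I", "II", "III", "IV") if s in set(df["stage"])]
    if len(order) < 2:
        raise AnalysisError("need at least two stages with two or more samples")
    groups = [df.loc[df["stage"] == s, "value"].to_numpy() for s in order]
    f, p = stats.f_oneway(*groups)
    tk = stats.tukey_hsd(*groups)
    rows = [
        (order[i], order[j], float(tk.pvalue[i, j]))
        for i in range(len(order))
        for j in range(i + 1, len(order))
    ]
    pairwise = pd.DataFrame(rows, columns=["stage_a", "stage_b", "p_adj"])

    early = df.loc[df["stage"].isin(EARLY_STAGES), "value"].to_numpy()
    late = df.loc[df["stage"].isin(LATE_STAGES), "value"].to_numpy()
    el_t = el_p = float("nan")
    if len(early) >= 2 and len(late) >= 2:
        res = stats.ttest_ind(late, early, equal_var=True)
        el_t, el_p = float(res.statistic), float(res.pvalue)
    return StageComparison(
        f_statistic=float(f),
        anova_p=float(p),
        pairwise=pairwise,
        early_late_t=el_t,
        early_late_p=el_p,
        stages_used=order,
    )
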
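"""In-memory containers shared across the pipeline.

The workhorse container is a pandas DataFrame; the thin dataclasses here
attach the metadata the analyses need (platform kind, normalization factors,
pathway membership) and enforce the format invariants once, at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import FormatError

#: allowed matrix kinds
MATRIX_KINDS = ("array", "counts", "beta", "mirna")

#: group labels used throughout
TUMOR = "tumor"
NORMAL = "normal"

#: discrete copy-number alphabet (GISTIC thresholded calls)
CNV_ALPHABET = (-2, -1, 0, 1, 2)


@dataclass
class ExpressionMatrix:
    """A gene (or CpG, or miRNA) x sample numeric matrix tagged with its kind.

    Parameters
    ----------
    values
        DataFrame with feature identifiers as the index and sample ids as
        columns.
    kind
        One of ``array`` (log-intensity), ``counts`` (raw RNA-seq counts),
        ``beta`` (methylation fractions in [0, 1], NaN allowed), ``mirna``
        (miRNA expression, log scale).
    """

    values: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in MATRIX_KINDS:
            raise FormatError(f"unknown matrix kind {self.kind!r}")
        vals = self.values
        if vals.index.duplicated().any():
            dups = vals.index[vals.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature identifiers: {dups[:5]}")
        if vals.columns.duplicated().any():
            raise FormatError("duplicate sample identifiers")
        arr = vals.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("matrix contains non-numeric cells")
        if self.kind == "counts":
            if np.isnan(arr).any():
                raise FormatError("counts matrix contains missing values")
            if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
                raise FormatError("counts must be nonnegative integers")
        elif self.kind == "beta":
            finite = arr[~np.isnan(arr)]
            if ((finite < 0) | (finite > 1)).any():
                raise FormatError("beta values must lie in [0, 1]")
        elif self.kind in ("array", "mirna"):
            if np.isnan(arr).any():
                raise FormatError(f"{self.kind} matrix contains missing values")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class NormFactors:
    """Per-sample TMM scaling factors.

    ``factors`` are rescaled so their geometric mean is 1; the effective
    library size of a sample is its raw library size times its factor.
    """

    factors: pd.Series
    lib_sizes: pd.Series
    ref_sample: str

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise FormatError("normalization factors must be strictly positive")
        self.factors = self.factors.astype(float)
        self.lib_sizes = self.lib_sizes.astype(float)

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.factors


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways) with a tag describing the universe policy.

    ``universe_policy`` records how the enrichment universe is formed:
    ``annotated`` (genes in the expression matrix that belong to at least one
    set — the default) or ``matrix`` (all matrix genes).
    """

    sets: dict[str, frozenset[str]]
    universe_policy: str = "annotated"

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)


@dataclass
class MetastasisGroups:
    """Partition of tumor samples by nodal/distant metastasis status.

    metastatic: N+ or M+; non_metastatic: N0 and M0; excluded: NX/MX/missing.
    """

    metastatic: list[str] = field(default_factory=list)
    non_metastatic: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)
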
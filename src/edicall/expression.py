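"""Expression statistics for editing-defined gene classes.

Count tables are prefiltered (>= 10 reads in total, coefficient of
variation < 1 across samples); classes of genes (e.g. 3'UTR-edited genes,
edited lncRNAs) are compared against all other expressed genes with a
two-sided Welch t-test on per-gene log2 expression ratios; differential
expression supplied by an upstream engine is flagged at the printed
thresholds (|log2FC| > 1 at embryo, > 2 at L4, Padj < 0.05); and overlaps
between gene sets are scored with the upper-tail hypergeometric test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .structure import WelchResult, welch_test

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionConfig:
    min_reads: int = 10  # minimum total reads per gene
    cv_max: float = 1.0  # coefficient of variation bound (exclusive)
    lfc_threshold: Mapping[str, float] = None  # stage -> |log2FC| bound
    padj_max: float = 0.05

    def __post_init__(self):
        if self.lfc_threshold is None:
            object.__setattr__(self, "lfc_threshold", {"embryo": 1.0, "L4": 2.0})
        if self.min_reads < 0 or self.cv_max <= 0 or self.padj_max <= 0:
            raise ValueError("thresholds must be positive")


def filter_counts(
    table: pd.DataFrame, config: ExpressionConfig = ExpressionConfig()
) -> pd.DataFrame:
    """Keep genes with >= min_reads total and CV (sd/mean, ddof=1) < cv_max.

    Genes with zero mean (CV undefined) are dropped and logged.  Idempotent.
    """
    values = table.to_numpy(dtype=float)
    total = values.sum(axis=1)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    defined = mean > 0
    if (~defined).any():
        logger.info("%d genes with zero mean dropped (CV undefined)", int((~defined).sum()))
    cv = np.full(len(table), np.inf)
    cv[defined] = sd[defined] / mean[defined]
    keep = (total >= config.min_reads) & (cv < config.cv_max) & defined
    return table.loc[keep]


def normalized_log2_ratio(
    table: pd.DataFrame,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    pseudo: float = 0.5,
) -> pd.Series:
    """Per-gene log2 of (mean normalized expression in A) / (in B).

    Counts are library-size scaled (counts-per-million over the filtered
    universe); a half-count offset keeps zero-expression genes finite.
    """
    cpm = table / table.sum(axis=0) * 1e6
    mean_a = cpm[list(samples_a)].mean(axis=1)
    mean_b = cpm[list(samples_b)].mean(axis=1)
    return np.log2(mean_a + pseudo) - np.log2(mean_b + pseudo)


def class_shift_test(
    values: pd.Series, class_genes: Sequence[str], two_sided: bool = True
) -> WelchResult:
    """Welch test of a gene class against the complement of the universe.

    ``values`` is a per-gene statistic (default usage: the mutant/wild-type
    log2 expression ratio); the class mean minus the complement mean is the
    reported direction (negative = class down-regulated).
    """
    class_genes = [g for g in class_genes if g in values.index]
    if len(class_genes) < 2:
        raise ValueError("class must contain at least 2 genes in the universe")
    in_class = values.index.isin(class_genes)
    a = values[in_class].to_numpy(dtype=float)
    b = values[~in_class].to_numpy(dtype=float)
    res = welch_test(a, b)
    if not two_sided:
        p_one = stats.t.sf(res.t, res.df) if res.t > 0 else stats.t.cdf(res.t, res.df)
        res = WelchResult(res.t, res.df, float(p_one), res.mean_a, res.mean_b, res.n_a, res.n_b)
    return res


def flag_de(
    de_stats: pd.DataFrame,
    stage: str,
    config: ExpressionConfig = ExpressionConfig(),
) -> set[str]:
    """Genes with |log2FC| strictly above the stage threshold and padj < 0.05.

    ``de_stats`` must have columns log2fc and padj indexed by gene; rows
    with missing padj are skipped (logged), matching how DE engines report
    independently-filtered genes.
    """
    if stage not in config.lfc_threshold:
        raise ValueError(f"no |log2FC| threshold for stage {stage!r}")
    bound = config.lfc_threshold[stage]
    missing = de_stats["padj"].isna()
    if missing.any():
        logger.info("%d genes skipped (missing padj)", int(missing.sum()))
    ok = (
        (~missing)
        & (de_stats["log2fc"].abs() > bound)
        & (de_stats["padj"] < config.padj_max)
    )
    return set(de_stats.index[ok])


@dataclass(frozen=True)
class OverlapResult:
    n_a: int
    n_b: int
    overlap: int
    universe: int
    p: float


def overlap_significance(
    set_a: set, set_b: set, universe: int | Sequence
) -> OverlapResult:
    """Upper-tail hypergeometric p-value of an observed set overlap.

    p = P(X >= k) with X ~ Hypergeometric(N, |A|, |B|) and k the observed
    overlap (the enrichment convention phyper(k-1, ..., lower=FALSE)).
    """
    if not isinstance(universe, int):
        set_a = set_a & set(universe)
        set_b = set_b & set(universe)
        universe = len(set(universe))
    n_a, n_b = len(set_a), len(set_b)
    if n_a > universe or n_b > universe:
        raise ValueError("set larger than the universe")
    k = len(set_a & set_b)
    if k > min(n_a, n_b):
        raise ValueError("overlap exceeds the smaller set")
    p = float(stats.hypergeom.sf(k - 1, universe, n_a, n_b))
    return OverlapResult(n_a, n_b, k, universe, min(p, 1.0))
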
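"""Fold-change-binned feature association statistic.

Genes with a positive log2 fold change are grouped into consecutive
0.1-wide bins; each bin contributes its midpoint and the mean feature value
of its genes (AREP).  The association score is a Pearson-style product of
standardized series where the fold-change side uses fixed constants
(mean 6.4, sd 3.7) rather than the empirical bin moments; significance is a
two-sided Student t-test on the correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

__all__ = [
    "BinSeries",
    "AssociationResult",
    "bin_by_lfc",
    "pcc_eq1",
    "pcc_pvalue",
    "associate_all",
    "DEFAULT_M0",
    "DEFAULT_SD0",
]

DEFAULT_M0 = 6.4
DEFAULT_SD0 = 3.7


@dataclass
class BinSeries:
    """Non-empty fold-change bins: midpoints, mean feature values, sizes."""

    bin_mid: list[float]
    arep: list[float]
    n_genes: list[int]
    window: float = 0.1

    def __len__(self) -> int:
        return len(self.bin_mid)


@dataclass
class AssociationResult:
    feature: str
    pcc: float
    t_stat: float
    p: float
    n_bins: int
    m0: float = DEFAULT_M0
    sd0: float = DEFAULT_SD0
    zero_variance: bool = False


def bin_by_lfc(
    lfc: Sequence[float], feature_values: Sequence[float], window: float = 0.1
) -> BinSeries:
    """Bin feature values by positive log2 fold change.

    Bin k covers [k*window, (k+1)*window), genes with lfc <= 0 are
    excluded, and empty bins are dropped.  AREP is the arithmetic mean of
    the feature over the bin's genes.
    """
    lfc = np.asarray(lfc, dtype=float)
    values = np.asarray(feature_values, dtype=float)
    if lfc.shape != values.shape:
        raise ValueError("fold changes and feature values differ in length")
    keep = lfc > 0
    if not keep.any():
        raise ValueError("no genes with positive log2 fold change")
    lfc, values = lfc[keep], values[keep]
    indices = np.floor(lfc / window).astype(int)
    mids, areps, counts = [], [], []
    for k in np.unique(indices):
        members = values[indices == k]
        mids.append((k + 0.5) * window)
        areps.append(float(members.mean()))
        counts.append(int(members.size))
    return BinSeries(bin_mid=mids, arep=areps, n_genes=counts, window=window)


def pcc_eq1(
    bins: BinSeries, m0: float = DEFAULT_M0, sd0: float = DEFAULT_SD0
) -> float:
    """Correlation-style association over the bin series.

    The fold-change side is standardized by the fixed constants (m0, sd0);
    the AREP side by its own sample mean and sample standard deviation
    (n-1 denominator).  Constant AREP makes the statistic undefined (nan).
    Passing ``m0=None`` / ``sd0=None`` substitutes the empirical moments of
    the midpoint series, which reduces the statistic to the textbook
    Pearson correlation.
    """
    mids = np.asarray(bins.bin_mid, dtype=float)
    arep = np.asarray(bins.arep, dtype=float)
    n = mids.size
    if n < 3:
        raise ValueError("at least 3 bins required")
    if m0 is None:
        m0 = mids.mean()
    if sd0 is None:
        sd0 = mids.std(ddof=1)
    mf = arep.mean()
    sdf = arep.std(ddof=1)
    if sdf == 0:
        return float("nan")
    z_lfc = (mids - m0) / sd0
    z_arep = (arep - mf) / sdf
    return float((z_lfc * z_arep).sum() / (n - 1))


def pcc_pvalue(pcc: float, n_bins: int) -> tuple[float, float]:
    """Two-sided Student t-test for a correlation over ``n_bins`` points."""
    if n_bins <= 2:
        raise ValueError("need more than 2 bins")
    if abs(pcc) >= 1:
        return (math.copysign(math.inf, pcc), 0.0)
    t_stat = pcc * math.sqrt((n_bins - 2) / (1 - pcc**2))
    p = 2.0 * float(t_dist.sf(abs(t_stat), n_bins - 2))
    return (t_stat, min(p, 1.0))


def associate_all(
    feature_table: pd.DataFrame,
    lfc: Sequence[float],
    window: float = 0.1,
    m0: float | None = DEFAULT_M0,
    sd0: float | None = DEFAULT_SD0,
    normalize_first: bool = True,
    exclude_cooccurrence: bool = True,
) -> list[AssociationResult]:
    """Association result for every feature column against fold change.

    Features are normalized (5th/95th-percentile clamp-and-scale) before
    binning when ``normalize_first`` is set.  Co-occurrence count features
    (columns starting with ``cooc_``) are excluded by default.
    """
    from .ml_framework import fit_normalizer, apply_normalizer

    results = []
    for name in feature_table.columns:
        if exclude_cooccurrence and name.startswith("cooc_"):
            continue
        values = feature_table[name].to_numpy(dtype=float)
        if normalize_first:
            lb, ub = fit_normalizer(values)
            values = apply_normalizer(values, lb, ub)
        bins = bin_by_lfc(lfc, values, window=window)
        pcc = pcc_eq1(bins, m0=m0, sd0=sd0)
        if math.isnan(pcc):
            results.append(
                AssociationResult(
                    feature=name, pcc=pcc, t_stat=float("nan"), p=float("nan"),
                    n_bins=len(bins), zero_variance=True,
                )
            )
            continue
        t_stat, p = pcc_pvalue(max(min(pcc, 1.0), -1.0), len(bins))
        results.append(
            AssociationResult(feature=name, pcc=pcc, t_stat=t_stat, p=p, n_bins=len(bins))
        )
    return results


def association_table(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Results as a DataFrame (feature, pcc, t, p, n_bins)."""
    return pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "pcc": [r.pcc for r in results],
            "t": [r.t_stat for r in results],
            "p": [r.p for r in results],
            "n_bins": [r.n_bins for r in results],
        }
    )
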
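"""Association of MHC amino-acid polymorphism with bacterial richness.

Per-partition simple linear regressions (percent polymorphic codons on
species richness) with ANOVA F-tests on (1, n-2) degrees of freedom, emitted
as a locus x codon-partition x richness-partition results grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AssociationResult", "fit_assoc", "association_grid"]


@dataclass
class AssociationResult:
    locus: str
    codon_partition: str
    richness_partition: str
    slope: float
    intercept: float
    F: float
    df_num: int
    df_den: int
    P: float
    r2: float


def fit_assoc(
    y,
    x,
    locus: str = "",
    codon_partition: str = "",
    richness_partition: str = "",
) -> AssociationResult:
    """OLS simple regression y ~ x with an ANOVA F-test.

    F = regression MS / residual MS on (1, n-2) df, identical to the square
    of the slope t-statistic; P is two-sided.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("x and y must be paired 1-d arrays")
    if len(y) < 4:
        raise ValueError("need at least 4 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    n = len(y)
    if x.std() == 0:
        raise ValueError("zero variance in predictor")
    if y.std() == 0:
        warnings.warn("zero variance in response; F = 0, P = 1")
        return AssociationResult(
            locus, codon_partition, richness_partition,
            0.0, float(y[0]), 0.0, 1, n - 2, 1.0, 0.0,
        )
    fit = stats.linregress(x, y)
    df_den = n - 2
    if fit.stderr == 0:  # perfect fit: residual MS is zero
        f = np.inf
        p = 0.0
    else:
        t = fit.slope / fit.stderr
        f = t * t
        p = float(stats.f.sf(f, 1, df_den))
    return AssociationResult(
        locus, codon_partition, richness_partition,
        float(fit.slope), float(fit.intercept), float(f), 1, df_den, p,
        float(fit.rvalue**2),
    )


def association_grid(
    polymorphism: pd.DataFrame, richness: pd.DataFrame
) -> pd.DataFrame:
    """Full locus x codon-partition x richness-partition grid of regressions.

    ``polymorphism``: per-population percent polymorphic codons, with columns
    named ``<locus>_<PBR|non-PBR>``.  ``richness``: per-population richness,
    columns named after partitions (all / nonpathogen / pathogen).  Rows of
    both are populations and must align.  A Bonferroni-adjusted P column over
    the emitted cells is included for transparency; the per-cell P values are
    reported unadjusted.
    """
    common = polymorphism.index.intersection(richness.index)
    if len(common) < 4:
        raise ValueError("fewer than 4 shared populations")
    poly = polymorphism.loc[common]
    rich = richness.loc[common]
    rows = []
    for pcol in poly.columns:
        locus, _, part = pcol.rpartition("_")
        for rcol in rich.columns:
            res = fit_assoc(
                poly[pcol].to_numpy(), rich[rcol].to_numpy(),
                locus=locus, codon_partition=part, richness_partition=rcol,
            )
            rows.append(
                {
                    "locus": res.locus,
                    "codon_partition": res.codon_partition,
                    "richness_partition": res.richness_partition,
                    "slope": res.slope,
                    "F": res.F,
                    "df_num": res.df_num,
                    "df_den": res.df_den,
                    "P": res.P,
                    "r2": res.r2,
                }
            )
    out = pd.DataFrame(rows)
    m = len(out)
    out["P_bonferroni"] = np.minimum(out["P"] * m, 1.0)
    out["significant"] = out["P"] < 0.05
    return out
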
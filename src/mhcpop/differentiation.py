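"""Population differentiation, isolation-by-distance and neutral contrasts.

Presence-absence Euclidean distances, the 0/1 range standardisation
(d_x - d_min)/(d_max - d_min), Mantel and first-order partial Mantel
permutation tests (with optional masking of outlier population pairs),
Hardy-Weinberg dominant-marker Fst, and the resampled neutral slope envelope
used to judge whether an MHC isolation-by-distance slope exceeds what random
subsets of neutral markers produce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from itertools import permutations as _permutations

__all__ = [
    "LabeledDistanceMatrix",
    "MantelResult",
    "SlopeEnvelope",
    "euclidean_presence",
    "standardize01",
    "mantel",
    "partial_mantel",
    "drop_pairs",
    "dominant_fst",
    "neutral_slope_envelope",
]


@dataclass
class LabeledDistanceMatrix:
    """Symmetric nonnegative pairwise distance matrix with population labels.

    ``kind`` records provenance: raw | standardized | fst | geographic.
    An optional condensed-form boolean mask marks population pairs excluded
    from downstream statistics (True = usable).
    """

    labels: list[str]
    values: np.ndarray
    kind: str = "raw"
    mask: np.ndarray | None = None  # condensed, True = usable

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (n * (n - 1) // 2,):
                raise ValueError("mask must be in condensed form")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, 1)
        return self.values[iu]

    def effective_mask(self) -> np.ndarray:
        m = self.n * (self.n - 1) // 2
        return np.ones(m, dtype=bool) if self.mask is None else self.mask

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, kind: str = "raw") -> "LabeledDistanceMatrix":
        return cls(list(df.index), df.to_numpy(dtype=float), kind)

    @classmethod
    def from_coords(cls, labels, coords) -> "LabeledDistanceMatrix":
        coords = np.asarray(coords, float)
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        return cls(list(labels), d, "geographic")


def euclidean_presence(presence: pd.DataFrame) -> LabeledDistanceMatrix:
    """Pairwise Euclidean distance between populations over 0/1 variant
    presence vectors (rows = populations)."""
    if presence.shape[0] < 3:
        raise ValueError("need at least 3 populations")
    x = presence.to_numpy(dtype=float)
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=-1))
    return LabeledDistanceMatrix(list(presence.index), d, "raw")


def standardize01(d: LabeledDistanceMatrix) -> LabeledDistanceMatrix:
    """(d_x - d_min) / (d_max - d_min) over off-diagonal cells; the diagonal
    stays zero.  Idempotent; errors on a degenerate (constant) matrix."""
    c = d.condensed()[d.effective_mask()]
    dmin, dmax = c.min(), c.max()
    if dmax == dmin:
        raise ValueError("degenerate matrix: d_max == d_min")
    out = (d.values - dmin) / (dmax - dmin)
    np.fill_diagonal(out, 0.0)
    return LabeledDistanceMatrix(d.labels, out, "standardized", mask=d.mask)


def drop_pairs(
    d: LabeledDistanceMatrix, pairs: list[tuple[str, str]]
) -> LabeledDistanceMatrix:
    """Mask the listed population pairs; downstream Mantel/regression
    statistics use only unmasked cells (permutations keep the mask on fixed
    cell positions)."""
    idx = {lab: i for i, lab in enumerate(d.labels)}
    mask = d.effective_mask().copy()
    n = d.n
    iu = np.triu_indices(n, 1)
    pos = {(int(i), int(j)): k for k, (i, j) in enumerate(zip(*iu))}
    for a, b in pairs:
        if a not in idx or b not in idx:
            raise ValueError(f"unknown population in pair ({a}, {b})")
        i, j = sorted((idx[a], idx[b]))
        mask[pos[(i, j)]] = False
    if mask.sum() < 3:
        raise ValueError("masking leaves fewer than 3 usable pairs")
    return LabeledDistanceMatrix(d.labels, d.values.copy(), d.kind, mask=mask)


# ---------------------------------------------------------------------------
# Mantel machinery


@dataclass
class MantelResult:
    R: float
    P: float
    n_perm: int
    partial: bool = False
    control_used: str | None = None
    slope: float = math.nan
    intercept: float = math.nan
    r2: float = math.nan
    n_pairs: int = 0


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    den = math.sqrt((xc**2).sum() * (yc**2).sum())
    if den == 0:
        raise ValueError("zero variance among off-diagonal distances")
    return float((xc * yc).sum() / den)


def _perm_condensed(values: np.ndarray, perms: np.ndarray, iu) -> np.ndarray:
    """Condensed vectors of ``values`` under simultaneous row/column
    relabelings; ``perms`` has shape (n_perm, n)."""
    return values[perms[:, iu[0]], perms[:, iu[1]]]


def _check_labels(*mats: LabeledDistanceMatrix) -> None:
    labels = mats[0].labels
    for m in mats[1:]:
        if m.labels != labels:
            raise ValueError("distance matrices must share labels and order")


def _combined_mask(*mats: LabeledDistanceMatrix) -> np.ndarray:
    mask = mats[0].effective_mask()
    for m in mats[1:]:
        mask = mask & m.effective_mask()
    return mask


def mantel(
    a: LabeledDistanceMatrix,
    b: LabeledDistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
    exact: bool = False,
) -> MantelResult:
    """Mantel test of matrix correlation.

    R is the Pearson correlation over the n(n-1)/2 off-diagonal pairs
    (restricted to unmasked pairs); the null is built by simultaneous
    row/column permutation of ``a``.  One-tailed P uses the add-one
    convention (count of permuted R >= observed + 1) / (n_perm + 1); with
    ``exact=True`` all n! relabelings are enumerated and P is the exact
    fraction with R >= observed (identity included).

    The least-squares fit of b on a (slope, intercept, R^2) is reported for
    isolation-by-distance summaries.
    """
    _check_labels(a, b)
    n = a.n
    iu = np.triu_indices(n, 1)
    mask = _combined_mask(a, b)
    av, bv = a.condensed()[mask], b.condensed()[mask]
    if mask.sum() < 3:
        raise ValueError("fewer than 3 usable pairs")
    r_obs = _pearson(av, bv)

    # least-squares IBD fit b ~ a over usable pairs
    xc = av - av.mean()
    slope = float((xc * (bv - bv.mean())).sum() / (xc**2).sum())
    intercept = float(bv.mean() - slope * av.mean())
    r2 = r_obs**2

    if exact:
        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8")
        perms = np.array(list(_permutations(range(n))))
        perm_vecs = _perm_condensed(a.values, perms, iu)[:, mask]
        r_perm = _pearson_rows(perm_vecs, bv)
        hits = _tail_hits(r_perm, r_obs, alternative)
        return MantelResult(r_obs, hits / len(perms), len(perms), False, None,
                            slope, intercept, r2, int(mask.sum()))

    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    perm_vecs = _perm_condensed(a.values, perms, iu)[:, mask]
    r_perm = _pearson_rows(perm_vecs, bv)
    hits = _tail_hits(r_perm, r_obs, alternative)
    p = (hits + 1) / (n_perm + 1)
    return MantelResult(r_obs, float(p), n_perm, False, None,
                        slope, intercept, r2, int(mask.sum()))


def _pearson_rows(rows: np.ndarray, y: np.ndarray) -> np.ndarray:
    rc = rows - rows.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    den = np.sqrt((rc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, (rc * yc).sum(axis=1) / den, 0.0)


def _tail_hits(r_perm: np.ndarray, r_obs: float, alternative: str) -> int:
    if alternative == "greater":
        return int((r_perm >= r_obs).sum())
    if alternative == "less":
        return int((r_perm <= r_obs).sum())
    if alternative == "two-sided":
        return int((np.abs(r_perm) >= abs(r_obs)).sum())
    raise ValueError(f"unknown alternative {alternative!r}")


def partial_mantel(
    a: LabeledDistanceMatrix,
    b: LabeledDistanceMatrix,
    control: LabeledDistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """First-order partial Mantel test of a ~ b given ``control``.

    The partial correlation r_ab.c = (r_ab - r_ac r_bc) /
    sqrt((1-r_ac^2)(1-r_bc^2)) is recomputed under simultaneous row/column
    permutations of ``a`` (b and control fixed)."""
    _check_labels(a, b, control)
    n = a.n
    iu = np.triu_indices(n, 1)
    mask = _combined_mask(a, b, control)
    av = a.condensed()[mask]
    bv = b.condensed()[mask]
    cv = control.condensed()[mask]

    def partial_r(x: np.ndarray) -> float:
        r_ab = _pearson(x, bv)
        r_ac = _pearson(x, cv)
        r_bc = _pearson(bv, cv)
        den = math.sqrt((1 - r_ac**2) * (1 - r_bc**2))
        if den == 0:
            raise ValueError("undefined partial correlation (|r| = 1)")
        return (r_ab - r_ac * r_bc) / den

    r_obs = partial_r(av)
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    perm_vecs = _perm_condensed(a.values, perms, iu)[:, mask]
    r_bc = _pearson(bv, cv)
    r_ab = _pearson_rows(perm_vecs, bv)
    r_ac = _pearson_rows(perm_vecs, cv)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_perm = (r_ab - r_ac * r_bc) / np.sqrt((1 - r_ac**2) * (1 - r_bc**2))
    hits = _tail_hits(r_perm[np.isfinite(r_perm)], r_obs, alternative)
    p = (hits + 1) / (n_perm + 1)
    return MantelResult(float(r_obs), float(p), n_perm, True, control.kind,
                        n_pairs=int(mask.sum()))


# ---------------------------------------------------------------------------
# dominant-marker Fst


@lru_cache(maxsize=None)
def _debiased_sqrt_table(n: int) -> np.ndarray:
    """One-step debiased estimator of q = sqrt(1 - f) from k bands out of n.

    For each observed k the exact binomial expectation of sqrt(1 - k'/n)
    under Bin(n, k/n) yields the plug-in bias, which is subtracted from the
    naive estimate; the table has n+1 entries, with u(0) = 1 and u(n) = 0
    exact at fixation."""
    from scipy.stats import binom as _binom

    ks = np.arange(n + 1)
    naive = np.sqrt(1.0 - ks / n)
    table = np.empty(n + 1)
    for k in ks:
        pmf = _binom.pmf(ks, n, k / n)
        bias = float((pmf * naive).sum()) - naive[k]
        table[k] = naive[k] - bias
    return table


def dominant_fst(
    genotypes: pd.DataFrame,
    pop_assign: pd.Series,
    loci_subset: list[str] | np.ndarray | None = None,
) -> LabeledDistanceMatrix:
    """Pairwise multilocus Fst from dominant (band presence/absence)
    genotypes under Hardy-Weinberg equilibrium.

    Per locus the null-allele frequency is q = sqrt(1 - band frequency); the
    per-locus pairwise Fst is the between-population variance of q,
    (q1 - q2)^2 / 4, over q_bar(1 - q_bar), and the multilocus value is the
    ratio of sums across loci.

    The naive plug-in sqrt(1 - f_hat) is badly biased at small sample sizes,
    which would tilt isolation-by-distance slopes; the implementation
    therefore expands the variance as (q1^2 - 2 q1 q2 + q2^2)/4 and estimates
    q_i^2 by the exactly unbiased 1 - f_hat_i, and the cross term by the
    product of per-population debiased sqrt estimators (exact binomial bias
    tables, computable because f_hat takes only n+1 values; the estimators
    are independent across populations, so the product is unbiased up to the
    residual per-population bias).  Negative per-pair estimates are truncated
    at 0; loci with zero denominator are dropped."""
    if loci_subset is not None:
        genotypes = genotypes[list(loci_subset)]
    pops = sorted(pop_assign.unique())
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    counts = genotypes.groupby(pop_assign).size()
    if (counts < 2).any():
        raise ValueError("each population needs at least 2 individuals")
    band_counts = genotypes.groupby(pop_assign).sum().loc[pops].to_numpy()
    n_ind = counts.loc[pops].to_numpy()

    q2u = np.empty(band_counts.shape)  # unbiased estimate of q^2
    uq = np.empty(band_counts.shape)  # debiased estimate of q
    for i, m in enumerate(n_ind):
        u = _debiased_sqrt_table(int(m))
        k = band_counts[i].astype(int)
        q2u[i] = 1.0 - k / m
        uq[i] = u[k]

    n = len(pops)
    fst = np.zeros((n, n))
    informative = False
    for i in range(n):
        for j in range(i + 1, n):
            num = (q2u[i] + q2u[j] - 2.0 * uq[i] * uq[j]) / 4.0
            qbar2 = (q2u[i] + q2u[j] + 2.0 * uq[i] * uq[j]) / 4.0
            den = (uq[i] + uq[j]) / 2.0 - qbar2
            ok = den > 1e-12
            if ok.any():
                informative = True
                fst[i, j] = fst[j, i] = max(0.0, num[ok].sum() / den[ok].sum())
    if not informative:
        raise ValueError("no informative loci (all band frequencies fixed)")
    return LabeledDistanceMatrix(pops, fst, "fst")


@dataclass
class SlopeEnvelope:
    """Distribution of neutral isolation-by-distance regression slopes from
    random marker subsets."""

    subset_size: int
    slopes: list[float] = field(default_factory=list)
    r2s: list[float] = field(default_factory=list)
    n_redrawn: int = 0

    @property
    def n_subsets(self) -> int:
        return len(self.slopes)

    @property
    def min_r2(self) -> float:
        return min(self.r2s)

    @property
    def max_r2(self) -> float:
        return max(self.r2s)

    @property
    def min_slope(self) -> float:
        return min(self.slopes)

    @property
    def max_slope(self) -> float:
        return max(self.slopes)

    def contains_slope(self, x: float) -> bool:
        return self.min_slope <= x <= self.max_slope

    def contains_r2(self, x: float) -> bool:
        return self.min_r2 <= x <= self.max_r2


def neutral_slope_envelope(
    genotypes: pd.DataFrame,
    pop_assign: pd.Series,
    geo: LabeledDistanceMatrix,
    subset_size: int,
    n_subsets: int = 100,
    seed: int | None = None,
) -> SlopeEnvelope:
    """Neutral slope envelope: for each seeded random subset of loci, compute
    dominant-marker Fst and the least-squares slope and R^2 of Fst on
    geographic distance; degenerate draws are discarded and redrawn."""
    if n_subsets < 10:
        raise ValueError("n_subsets must be >= 10")
    loci = np.array(genotypes.columns)
    if subset_size > len(loci):
        raise ValueError("subset_size exceeds locus count")
    rng = np.random.default_rng(seed)
    env = SlopeEnvelope(subset_size=subset_size)
    iu = np.triu_indices(geo.n, 1)
    gv = geo.values[iu]
    budget = n_subsets * 10
    while env.n_subsets < n_subsets and budget > 0:
        budget -= 1
        pick = rng.choice(len(loci), size=subset_size, replace=False)
        try:
            fst = dominant_fst(genotypes, pop_assign, loci[pick])
        except ValueError:
            env.n_redrawn += 1
            continue
        if fst.labels != geo.labels:
            fst = LabeledDistanceMatrix(
                geo.labels,
                fst.to_dataframe().loc[geo.labels, geo.labels].to_numpy(),
                "fst",
            )
        fv = fst.values[iu]
        if fv.std() == 0 or gv.std() == 0:
            env.n_redrawn += 1
            continue
        xc = gv - gv.mean()
        slope = float((xc * (fv - fv.mean())).sum() / (xc**2).sum())
        r = _pearson(gv, fv)
        env.slopes.append(slope)
        env.r2s.append(r * r)
    if env.n_subsets < n_subsets:
        raise RuntimeError("too many degenerate subsets; check the genotypes")
    return env
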
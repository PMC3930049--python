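"""Codon-level diversity and selection statistics on retained variants.

Implements per-codon amino-acid diversity (the inverse participation ratio of
residue frequencies scaled by 20, i.e. DIVAA: 0.05 = fully conserved, 1 =
all twenty residues equally frequent), percent polymorphic codons by
peptide-binding-region (PBR) partition, Welch's unequal-variance t-test, the
Nei-Gojobori pathway-counting estimator of synonymous and nonsynonymous
substitution rates with Jukes-Cantor correction, and a codon-bootstrap Z-test
of positive selection (null: dN = dS).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from ._codon import CODON_TABLE, STOP_CODONS
from .amplicon import CodonAlignment

__all__ = [
    "PbrMask",
    "DEFAULT_MASKS",
    "NeiGojoboriPair",
    "DnDsResult",
    "PolymorphismSummary",
    "site_diversity",
    "percent_polymorphic",
    "welch_t_test",
    "nei_gojobori_pair",
    "pairwise_ng_components",
    "z_test_selection",
    "locus_summary",
]


@dataclass(frozen=True)
class PbrMask:
    """Peptide-binding-region codon mask for one locus (1-based indices)."""

    locus: str
    pbr_codons: tuple[int, ...]
    n_codons: int

    def __post_init__(self):
        idx = sorted(set(self.pbr_codons))
        if len(idx) != len(self.pbr_codons):
            raise ValueError("pbr codon indices must be unique")
        if idx and (idx[0] < 1 or idx[-1] > self.n_codons):
            raise ValueError("pbr codon indices must lie in [1, n_codons]")
        object.__setattr__(self, "pbr_codons", tuple(idx))

    @property
    def non_pbr_codons(self) -> tuple[int, ...]:
        pbr = set(self.pbr_codons)
        return tuple(i for i in range(1, self.n_codons + 1) if i not in pbr)

    def partition(self, name: str) -> tuple[int, ...]:
        if name == "PBR":
            return self.pbr_codons
        if name == "non-PBR":
            return self.non_pbr_codons
        if name == "all":
            return tuple(range(1, self.n_codons + 1))
        raise ValueError(f"unknown partition {name!r}")


# Default masks for the two-locus design (10 of 55 and 11 of 58 codons).
# Synthetic stand-ins: the positions are plausible class-II peptide-contact
# sites by homology, not an empirically determined mask.
DEFAULT_MASKS = {
    "DAB1": PbrMask("DAB1", (6, 8, 10, 14, 22, 24, 25, 35, 36, 44), 55),
    "DAB3": PbrMask("DAB3", (8, 10, 24, 26, 28, 35, 37, 45, 47, 52, 56), 58),
}


# ---------------------------------------------------------------------------
# per-site amino-acid diversity


def site_diversity(aln: CodonAlignment, mask: PbrMask) -> pd.DataFrame:
    """Per-codon DIVAA diversity D = 1 / (20 * sum_i p_i^2) over observed
    amino-acid frequencies (gap codons excluded), the rescaled value
    (D - 1/20) / (1 - 1/20), polymorphism flag and partition label.
    """
    if len(aln) < 2:
        raise ValueError("need at least 2 sequences")
    if aln.n_codons != mask.n_codons:
        raise ValueError("mask and alignment codon counts differ")
    aas = aln.amino_acids()
    pbr = set(mask.pbr_codons)
    rows = []
    for c in range(aln.n_codons):
        col = [row[c] for row in aas if row[c] is not None]
        if not col:
            d = math.nan
            poly = False
        else:
            freqs = np.array(list(pd.Series(col).value_counts())) / len(col)
            d = 1.0 / (20.0 * float((freqs**2).sum()))
            poly = len(set(col)) > 1
        rows.append(
            {
                "codon": c + 1,
                "D": d,
                "D_rescaled": (d - 0.05) / 0.95 if not math.isnan(d) else math.nan,
                "polymorphic": poly,
                "partition": "PBR" if c + 1 in pbr else "non-PBR",
                "n_obs": len(col),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PolymorphismSummary:
    locus: str
    pct_polymorphic_pbr: float
    pct_polymorphic_nonpbr: float
    pct_polymorphic_all: float


def percent_polymorphic(
    aln: CodonAlignment,
    mask: PbrMask,
    subset_ids: list[str] | None = None,
    locus: str = "",
) -> PolymorphismSummary:
    """Percent of codons with >= 2 distinct amino acids, for PBR, non-PBR and
    all codons; optionally restricted to the variants present in one
    population via ``subset_ids``."""
    if subset_ids is not None:
        aln = aln.subset(subset_ids)
    if len(aln) < 2:
        warnings.warn("fewer than 2 sequences in subset; polymorphism is zero")
        return PolymorphismSummary(locus, 0.0, 0.0, 0.0)
    aas = aln.amino_acids()
    poly = []
    for c in range(aln.n_codons):
        col = {row[c] for row in aas if row[c] is not None}
        poly.append(len(col) > 1)
    poly = np.array(poly)
    pbr0 = np.array([i - 1 for i in mask.pbr_codons], dtype=int)
    non0 = np.array([i - 1 for i in mask.non_pbr_codons], dtype=int)
    return PolymorphismSummary(
        locus,
        100.0 * poly[pbr0].mean() if len(pbr0) else 0.0,
        100.0 * poly[non0].mean() if len(non0) else 0.0,
        100.0 * poly.mean(),
    )


def welch_t_test(
    x, y, alternative: str = "two-sided"
) -> tuple[float, float, float]:
    """Welch unequal-variance t-test with Satterthwaite (non-integer) df.
    Returns (t, df, P)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least two observations per sample")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if np.array_equal(np.sort(x), np.sort(y)) or x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.df), float(res.pvalue)


# ---------------------------------------------------------------------------
# Nei-Gojobori


def _syn_fraction(codon: str, pos: int) -> float:
    """Fraction of one-step changes at ``pos`` that are synonymous, among
    changes not creating a stop codon."""
    aa = CODON_TABLE[codon]
    syn = tot = 0
    for b in "TCAG":
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if alt in STOP_CODONS:
            continue
        tot += 1
        if CODON_TABLE[alt] == aa:
            syn += 1
    return syn / tot if tot else 0.0


@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) potential site counts for one codon."""
    s = sum(_syn_fraction(codon, p) for p in range(3))
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _pathway_counts(a: str, b: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) difference counts over all minimal
    mutational pathways between two codons; pathways passing through stop
    codons are excluded (unless all are blocked)."""
    diffs = [p for p in range(3) if a[p] != b[p]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in permutations(diffs):
        cur = a
        syn = non = 0
        blocked = False
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            if CODON_TABLE.get(cur, "*") == CODON_TABLE.get(nxt, "*") and nxt not in STOP_CODONS and cur not in STOP_CODONS:
                syn += 1
            else:
                non += 1
            cur = nxt
        paths.append((syn, non, blocked))
    usable = [p for p in paths if not p[2]]
    if not usable:
        usable = paths
    sd = sum(p[0] for p in usable) / len(usable)
    nd = sum(p[1] for p in usable) / len(usable)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.nan  # saturated
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class NeiGojoboriPair:
    Nd: float
    Sd: float
    n_sites: float
    s_sites: float
    pN: float
    pS: float
    dN: float
    dS: float

    @property
    def saturated(self) -> bool:
        return math.isnan(self.dN) or math.isnan(self.dS)


def nei_gojobori_pair(seq_a: str, seq_b: str) -> NeiGojoboriPair:
    """Nei-Gojobori proportions and Jukes-Cantor-corrected rates for one pair
    of equal-length in-frame coding sequences.

    Potential synonymous sites per codon are averaged between the two
    sequences; observed differences are resolved by averaging over all
    minimal mutational pathways; gap codons in either sequence are skipped
    pairwise-complete.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    if len(seq_a) % 3:
        raise ValueError("sequences must be in frame")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    Sd = Nd = s_sites = 0.0
    n_codons_used = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if "-" in ca or "-" in cb:
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError("stop codon in coding sequence")
        sa, _ = _codon_sites(ca)
        sb, _ = _codon_sites(cb)
        s_sites += (sa + sb) / 2.0
        sd, nd = _pathway_counts(ca, cb)
        Sd += sd
        Nd += nd
        n_codons_used += 1
    n_sites = 3.0 * n_codons_used - s_sites
    pN = Nd / n_sites if n_sites > 0 else 0.0
    pS = Sd / s_sites if s_sites > 0 else 0.0
    return NeiGojoboriPair(
        Nd, Sd, n_sites, s_sites, pN, pS, _jukes_cantor(pN), _jukes_cantor(pS)
    )


def pairwise_ng_components(
    aln: CodonAlignment, codon_indices: tuple[int, ...]
) -> dict[str, np.ndarray]:
    """Per-pair, per-codon Nei-Gojobori components restricted to
    ``codon_indices`` (1-based): arrays of shape (n_pairs, n_codons_in_set)
    for Sd, Nd, s sites and n sites.  Codons with a gap in either member of a
    pair contribute zeros (pairwise-complete deletion)."""
    k = len(aln)
    cols = [i - 1 for i in codon_indices]
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    shape = (len(pairs), len(cols))
    out = {key: np.zeros(shape) for key in ("sd", "nd", "s", "n")}
    for pi, (i, j) in enumerate(pairs):
        a, b = aln.seqs[i], aln.seqs[j]
        for cc, c in enumerate(cols):
            ca, cb = a[3 * c : 3 * c + 3], b[3 * c : 3 * c + 3]
            if "-" in ca or "-" in cb:
                continue
            sa, _ = _codon_sites(ca)
            sb, _ = _codon_sites(cb)
            sd, nd = _pathway_counts(ca, cb)
            out["sd"][pi, cc] = sd
            out["nd"][pi, cc] = nd
            out["s"][pi, cc] = (sa + sb) / 2.0
            out["n"][pi, cc] = 3.0 - (sa + sb) / 2.0
    return out


def _mean_rates(comp: dict[str, np.ndarray], weights: np.ndarray) -> tuple[float, float]:
    """Mean pairwise (dN, dS) for a codon-resampling weight vector."""
    s = comp["s"] @ weights
    n = comp["n"] @ weights
    sd = comp["sd"] @ weights
    nd = comp["nd"] @ weights
    with np.errstate(divide="ignore", invalid="ignore"):
        pN = np.where(n > 0, nd / n, 0.0)
        pS = np.where(s > 0, sd / s, 0.0)
        dN = np.where(pN < 0.75, -0.75 * np.log1p(-4.0 * pN / 3.0), np.nan)
        dS = np.where(pS < 0.75, -0.75 * np.log1p(-4.0 * pS / 3.0), np.nan)
    return float(np.nanmean(dN)), float(np.nanmean(dS))


@dataclass
class DnDsResult:
    partition: str
    n_codons: int
    d_N: float
    d_S: float
    ratio: float  # nan when dS == 0
    Z: float
    P: float
    n_boot: int


def z_test_selection(
    aln: CodonAlignment,
    mask: PbrMask,
    partition: str = "PBR",
    n_boot: int = 1000,
    seed: int | None = None,
) -> DnDsResult:
    """Codon-bootstrap Z-test of positive selection on a codon partition.

    d_N and d_S are means over all unordered sequence pairs restricted to the
    partition's codons; the standard error of d_N - d_S comes from ``n_boot``
    seeded bootstrap resamples of the partition codons; the one-tailed P
    tests for positive selection (d_N > d_S).
    """
    codons = mask.partition(partition)
    if len(codons) < 3:
        raise ValueError("partition has fewer than 3 codons; bootstrap degenerate")
    if len(aln) < 2:
        raise ValueError("need at least 2 sequences")
    comp = pairwise_ng_components(aln, codons)
    ones = np.ones(len(codons))
    d_N, d_S = _mean_rates(comp, ones)
    delta = d_N - d_S

    rng = np.random.default_rng(seed)
    m = len(codons)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        w = np.bincount(rng.integers(0, m, size=m), minlength=m).astype(float)
        bn, bs = _mean_rates(comp, w)
        boots[b] = bn - bs
    se = float(np.nanstd(boots, ddof=1))
    if se == 0.0:
        z = 0.0 if delta == 0.0 else math.copysign(math.inf, delta)
    else:
        z = delta / se
    p = 1.0 if z == 0.0 else float(stats.norm.sf(z))
    ratio = d_N / d_S if d_S > 0 else math.nan
    return DnDsResult(partition, m, d_N, d_S, ratio, z, p, n_boot)


def locus_summary(
    aln: CodonAlignment,
    mask: PbrMask,
    n_boot: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """dN/dS table over the non-PBR, PBR and all-codon partitions."""
    rows = []
    for part in ("non-PBR", "PBR", "all"):
        r = z_test_selection(aln, mask, part, n_boot=n_boot, seed=seed)
        rows.append(
            {
                "locus": mask.locus,
                "partition": part,
                "n_codons": r.n_codons,
                "dN": r.d_N,
                "dS": r.d_S,
                "dN_dS": r.ratio,
                "Z": r.Z,
                "P": r.P,
            }
        )
    return pd.DataFrame(rows)
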
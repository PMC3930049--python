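"""Bacterial community tables: QC filtering, pathogen flagging, richness and
permutational multivariate ANOVA (PERMANOVA) on a dissimilarity matrix.

The input is a classified 16S record table (taxon, population, count,
assignment bootstrap, read length).  Records failing the read-length or
classifier-bootstrap thresholds are discarded, survivors are aggregated to a
taxon x population count matrix, taxa on a configurable pathogen list are
flagged, and per-population species richness is computed for the pathogen,
non-pathogen and all partitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .differentiation import LabeledDistanceMatrix

__all__ = [
    "DEFAULT_PATHOGENS",
    "CommunityTable",
    "PermanovaResult",
    "filter_records",
    "flag_pathogens",
    "richness",
    "community_dissimilarity",
    "permanova",
]

# Freshwater-fish pathogen taxa screened for by default (genus/lowest-rank
# names as emitted by a naive-Bayes 16S classifier).
DEFAULT_PATHOGENS = (
    "Carnobacterium sp.",
    "Lactobacillus sp.",
    "Staphylococcus sp.",
    "Flavobacterium sp.",
    "unclassified Clostridiales",
    "unclassified Enterobacteriaceae",
    "unclassified Pseudomonadaceae",
    "unclassified Oxalobacteraceae",
)


@dataclass
class CommunityTable:
    """Taxa x populations count matrix with per-taxon pathogen flags."""

    counts: pd.DataFrame  # index = taxon, columns = population
    pathogen_flag: pd.Series  # bool per taxon
    qc: dict[str, int]

    def partition(self, which: str = "all") -> pd.DataFrame:
        if which == "all":
            return self.counts
        if which == "pathogen":
            return self.counts.loc[self.pathogen_flag]
        if which == "nonpathogen":
            return self.counts.loc[~self.pathogen_flag]
        raise ValueError(f"unknown partition {which!r}")


def filter_records(
    records: pd.DataFrame, min_len: int = 200, min_bootstrap: float = 0.5
) -> CommunityTable:
    """Drop records with read length < ``min_len`` or assignment bootstrap
    < ``min_bootstrap`` (per-rule counters kept), then aggregate survivors to
    taxon x population counts."""
    df = records.copy()
    if "count" not in df.columns:
        df["count"] = 1
    short = df["length"] < min_len
    lowboot = df["bootstrap"] < min_bootstrap
    keep = ~(short | lowboot)
    qc = {
        "n_input": len(df),
        "n_removed_short": int(short.sum()),
        "n_removed_low_bootstrap": int(lowboot.sum()),
        "n_removed": int((~keep).sum()),
        "n_retained": int(keep.sum()),
    }
    kept = df[keep]
    if kept.empty:
        warnings.warn("all records removed by QC thresholds")
        counts = pd.DataFrame()
    else:
        counts = (
            kept.pivot_table(
                index="taxon", columns="population", values="count",
                aggfunc="sum", fill_value=0,
            )
            .sort_index()
        )
    flags = pd.Series(False, index=counts.index, name="pathogen")
    return CommunityTable(counts, flags, qc)


def flag_pathogens(
    table: CommunityTable, pathogen_list: tuple[str, ...] | list[str] | None = None
) -> CommunityTable:
    """Case-insensitive exact name match against the pathogen list."""
    if pathogen_list is None:
        pathogen_list = DEFAULT_PATHOGENS
    if not pathogen_list:
        warnings.warn("empty pathogen list: no taxa flagged")
    names = {p.strip().lower() for p in pathogen_list}
    flags = pd.Series(
        [t.strip().lower() in names for t in table.counts.index],
        index=table.counts.index,
        name="pathogen",
    )
    return CommunityTable(table.counts, flags, table.qc)


def richness(table: CommunityTable, partition: str = "all") -> pd.Series:
    """Species richness S per population: count of taxa with count > 0
    within the requested partition."""
    sub = table.partition(partition)
    if sub.empty:
        pops = table.counts.columns if not table.counts.empty else []
        return pd.Series(0, index=pops, name=f"richness_{partition}")
    s = (sub > 0).sum(axis=0)
    s.name = f"richness_{partition}"
    return s


def community_dissimilarity(
    table: CommunityTable, partition: str = "all", metric: str = "braycurtis"
) -> LabeledDistanceMatrix:
    """Between-population dissimilarity on the abundance matrix
    (Bray-Curtis by default; ``euclidean`` and ``jaccard`` selectable)."""
    sub = table.partition(partition)
    x = sub.T.to_numpy(dtype=float)  # populations x taxa
    if metric == "jaccard":
        x = (x > 0).astype(float)
    d = squareform(pdist(x, metric=metric))
    d = np.nan_to_num(d, nan=0.0)
    np.fill_diagonal(d, 0.0)
    return LabeledDistanceMatrix(list(sub.columns), d, "raw")


@dataclass
class PermanovaResult:
    pseudo_F: float
    P: float
    n_perm: int
    df_between: int
    df_within: int


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, k: int) -> float:
    """Pseudo-F from squared dissimilarities and integer group codes."""
    n = len(codes)
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(k):
        members = np.nonzero(codes == g)[0]
        if len(members) > 1:
            sub = d2[np.ix_(members, members)]
            ss_within += sub[np.triu_indices(len(members), 1)].sum() / len(members)
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def permanova(
    dissim: LabeledDistanceMatrix,
    groups: pd.Series | dict | list,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-factor PERMANOVA: pseudo-F from between/within sums of squared
    dissimilarities, significance by permuting sample group labels, add-one
    P convention."""
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    elif isinstance(groups, list):
        groups = pd.Series(groups, index=dissim.labels)
    groups = groups.loc[dissim.labels]
    codes, uniq = pd.factorize(groups)
    k = len(uniq)
    n = dissim.n
    if k < 2:
        raise ValueError("need at least 2 groups")
    if k >= n:
        raise ValueError("within-group degrees of freedom are zero")
    d2 = dissim.values**2
    f_obs = _pseudo_f(d2, codes, k)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _pseudo_f(d2, codes[perm], k) >= f_obs:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return PermanovaResult(float(f_obs), float(p), n_perm, k - 1, n - k)
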
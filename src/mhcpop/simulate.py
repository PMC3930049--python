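"""Synthetic-data generator for the pooled-amplicon MHC study design.

Everything the downstream pipeline consumes can be generated here with a
known ground truth: population-tagged pyrosequencing-style reads of pooled
MHC class IIB exon-2 amplicons (with substitution, homopolymer-indel and
chimera artifacts), dominant neutral-marker genotypes structured by
isolation-by-distance, and classified 16S community tables whose pathogen
richness is optionally coupled to a per-population covariate.

All randomness flows from a single seed; each operation draws from its own
deterministically derived sub-stream, so stages can be regenerated in
isolation and full runs are byte-identical for a fixed config.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from ._codon import SENSE_CODONS, codons_of, has_stop, translate_codon

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "ReadTruth",
    "simulate_allele_pool",
    "assign_pool_alleles",
    "simulate_pool_reads",
    "simulate_aflp",
    "simulate_communities",
    "assoc_effect_for_r2",
    "default_tag_map",
    "write_fasta",
]

#: Nine study populations (alpine lake/stream sites).
DEFAULT_POPS = ("Br", "Ic", "Il", "Le", "Lo", "Lu", "Or", "Ta", "Va")

# Default peptide-binding-region codon mask (1-based) for a 55-codon exon.
# Synthetic stand-in chosen to reproduce the 10-of-55 bookkeeping of the
# two-locus design; see selection.DEFAULT_MASKS.
DEFAULT_PBR_MASK = (6, 8, 10, 14, 22, 24, 25, 35, 36, 44)

_FWD_PRIMER = "TGTCTGACCTGGAGTTCACT"
_REV_PRIMER = "GATCGTAGTTGGACGGACCT"


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class GenerationError(RuntimeError):
    """The generator could not satisfy its own invariants (retry budget hit)."""


@dataclass
class SimConfig:
    """Study conditions for a synthetic run.

    Defaults mirror the sampling design being emulated: 9 populations of
    18-20 pooled individuals, two-digit read depth per true allele, mild
    per-base substitution noise, rare homopolymer indels and ~1% chimeras,
    and a peptide-binding region with elevated nonsynonymous acceptance.
    """

    seed: int = 0
    n_pops: int = 9
    pool_size: int = 19
    pop_labels: tuple[str, ...] = DEFAULT_POPS
    pop_coords: np.ndarray | None = None  # (n_pops, 2), km
    coord_range_km: float = 50.0

    # allele pool
    n_alleles_global: int = 24
    n_codons: int = 55
    pbr_mask: tuple[int, ...] = DEFAULT_PBR_MASK  # 1-based codon indices
    omega_pbr: float = 5.0
    omega_nonpbr: float = 0.2
    syn_accept: float = 0.25
    n_mut_proposals: int = 25
    regime: str = "diversifying"  # neutral | diversifying | diversity_coupled
    alleles_per_individual: int = 2
    # per-pool Dirichlet concentration drawn log-uniformly from this range,
    # so pools span near-monoclonal to diverse compositions and population
    # level MHC polymorphism genuinely varies
    pool_alpha_range: tuple[float, float] = (0.05, 0.5)

    # reads
    depth_per_pool: int = 1200
    err_sub: float = 0.002
    err_homopolymer: float = 0.01
    chimera_rate: float = 0.01
    flank5_len: int = 30
    flank3_len: int = 60

    # dominant neutral markers
    n_aflp_loci: int = 500
    ibd_slope_target: float = 0.003  # Fst increase per km
    aflp_noise_sd: float = 0.5
    # band-allele frequency range: dominant markers outside the informative
    # mid-frequency band are unscorable in practice and are pre-filtered in
    # AFLP panels, so the generator never emits them
    aflp_freq_range: tuple[float, float] = (0.1, 0.6)

    # bacterial communities
    n_pathogen_taxa: int = 7
    n_nonpathogen_taxa: int = 40
    nonpathogen_prevalence: float = 0.35
    base_richness: float = 1.5
    assoc_effect: float = 0.0
    assoc_noise_sd: float = 0.9
    junk_record_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.n_pops < 1:
            raise ConfigError("n_pops must be positive")
        if len(self.pop_labels) < self.n_pops:
            raise ConfigError("not enough population labels for n_pops")
        self.pop_labels = tuple(self.pop_labels[: self.n_pops])
        if not (18 <= self.pool_size <= 20):
            # the design pools 18-20 individuals; other sizes are allowed but
            # flagged early when clearly invalid
            if self.pool_size < 1:
                raise ConfigError("pool_size must be positive")
        if self.regime not in {"neutral", "diversifying", "diversity_coupled"}:
            raise ConfigError(f"unknown regime {self.regime!r}")
        if self.regime == "neutral":
            # equal per-proposal acceptance for synonymous and nonsynonymous
            # changes, so dN/dS is 1 in expectation
            self.omega_pbr = 1.0
            self.omega_nonpbr = 1.0
            self.syn_accept = 0.5
        if self.omega_pbr < 0 or self.omega_nonpbr < 0:
            raise ConfigError("omega values must be >= 0")
        for name in ("err_sub", "err_homopolymer", "chimera_rate", "syn_accept",
                     "nonpathogen_prevalence", "junk_record_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        mask = tuple(sorted(set(int(i) for i in self.pbr_mask)))
        if len(mask) != len(self.pbr_mask):
            raise ConfigError("pbr_mask indices must be unique")
        if mask and (mask[0] < 1 or mask[-1] > self.n_codons):
            raise ConfigError("pbr_mask indices must lie in [1, n_codons]")
        self.pbr_mask = mask
        if self.n_pathogen_taxa < 0 or self.n_nonpathogen_taxa < 0:
            raise ConfigError("taxon counts must be >= 0")
        if self.pop_coords is not None:
            self.pop_coords = np.asarray(self.pop_coords, dtype=float)
            if self.pop_coords.shape != (self.n_pops, 2):
                raise ConfigError("pop_coords must have shape (n_pops, 2)")

    # deterministic sub-stream per operation
    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))

    def coords(self) -> np.ndarray:
        if self.pop_coords is None:
            rng = self.rng(10)
            self.pop_coords = rng.uniform(0.0, self.coord_range_km, size=(self.n_pops, 2))
        return self.pop_coords


@dataclass
class ReadTruth:
    """Provenance of one simulated read."""

    pop: str
    kind: str  # "allele" or "chimera"
    allele_id: str | None = None
    parents: tuple[str, str] | None = None
    breakpoint: int | None = None
    n_sub: int = 0
    n_indel: int = 0
    net_indel: int = 0  # summed signed indel lengths over the whole insert
    # ... restricted to the alignable core of the exon: an indel within a few
    # bases of an exon end is observationally indistinguishable from a
    # terminal substitution in a truncated read, so only interior indels are
    # counted as frameshifting ground truth
    exon_net_indel: int = 0

    @property
    def is_artifact_free(self) -> bool:
        return self.kind == "allele" and self.n_sub == 0 and self.n_indel == 0


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside each synthetic dataset."""

    allele_seqs: dict[str, str] = field(default_factory=dict)  # exon only
    pool_alleles: dict[str, Counter] = field(default_factory=dict)  # pop -> copies
    reads: dict[str, ReadTruth] = field(default_factory=dict)
    insert_prefix: str = ""  # 5' flank prepended to the exon in each read
    insert_suffix: str = ""
    realized_ibd_slope: float | None = None
    programmed_assoc_beta: float | None = None

    def true_insert(self, allele_id: str) -> str:
        return self.insert_prefix + self.allele_seqs[allele_id] + self.insert_suffix

    def to_json(self, path) -> None:
        payload = {
            "allele_seqs": self.allele_seqs,
            "pool_alleles": {p: dict(c) for p, c in self.pool_alleles.items()},
            "insert_prefix": self.insert_prefix,
            "insert_suffix": self.insert_suffix,
            "realized_ibd_slope": self.realized_ibd_slope,
            "programmed_assoc_beta": self.programmed_assoc_beta,
            "reads": {rid: dataclasses.asdict(rt) for rid, rt in self.reads.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


# ---------------------------------------------------------------------------
# allele pool


def _acceptance(omega: float) -> float:
    """Map a relative nonsynonymous acceptance rate to a probability."""
    return omega / (1.0 + omega)


def _random_ancestor(rng: np.random.Generator, n_codons: int) -> str:
    return "".join(rng.choice(SENSE_CODONS) for _ in range(n_codons))


def simulate_allele_pool(cfg: SimConfig, retry_budget: int = 200) -> dict[str, str]:
    """Generate the global allele pool by seeded codon mutation from a common
    ancestor.

    Nonsynonymous changes are accepted with probability omega/(1+omega) using
    the PBR or non-PBR omega depending on the codon hit; synonymous changes
    with probability ``syn_accept``.  When both omegas are zero the locus is
    treated as fully frozen and every allele is an exact copy of the ancestor.
    Stop codons are never accepted, and all alleles are unique (except in the
    frozen case).
    """
    rng = cfg.rng(1)
    ancestor = _random_ancestor(rng, cfg.n_codons)
    frozen = cfg.omega_pbr == 0.0 and cfg.omega_nonpbr == 0.0
    pbr0 = {i - 1 for i in cfg.pbr_mask}  # 0-based

    alleles: dict[str, str] = {}
    seen: set[str] = set()
    for k in range(cfg.n_alleles_global):
        aid = f"A{k + 1:03d}"
        if frozen:
            alleles[aid] = ancestor
            continue
        for _attempt in range(retry_budget):
            codons = codons_of(ancestor)
            for _m in range(cfg.n_mut_proposals):
                ci = int(rng.integers(cfg.n_codons))
                pos = int(rng.integers(3))
                old = codons[ci]
                base = rng.choice([b for b in "ACGT" if b != old[pos]])
                cand = old[:pos] + base + old[pos + 1 :]
                if cand in {"TAA", "TAG", "TGA"}:
                    continue
                if translate_codon(cand) == translate_codon(old):
                    p = cfg.syn_accept
                else:
                    omega = cfg.omega_pbr if ci in pbr0 else cfg.omega_nonpbr
                    p = _acceptance(omega)
                if rng.random() < p:
                    codons[ci] = cand
            seq = "".join(codons)
            if seq not in seen:
                break
        else:
            raise GenerationError(
                f"could not generate a unique, stop-free allele within "
                f"{retry_budget} attempts"
            )
        assert not has_stop(seq)
        seen.add(seq)
        alleles[aid] = seq
    return alleles


def assign_pool_alleles(cfg: SimConfig, alleles: dict[str, str]) -> dict[str, Counter]:
    """Draw each population's pool composition.

    Per population a Dirichlet frequency vector over the global allele pool is
    drawn, then each of ``pool_size`` individuals samples
    ``alleles_per_individual`` allele copies; the pooled copy counts are the
    pool-level truth (only pool-level composition is guaranteed downstream).
    """
    rng = cfg.rng(2)
    ids = list(alleles)
    lo, hi = cfg.pool_alpha_range
    pools: dict[str, Counter] = {}
    for pop in cfg.pop_labels:
        alpha = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        freqs = rng.dirichlet(np.full(len(ids), alpha))
        draws = rng.choice(
            len(ids), size=cfg.pool_size * cfg.alleles_per_individual, p=freqs
        )
        pools[pop] = Counter(ids[i] for i in draws)
    return pools


# ---------------------------------------------------------------------------
# reads


def default_tag_map(cfg: SimConfig) -> dict[str, str]:
    """Unique 5-base population tags, drawn deterministically from the seed."""
    rng = cfg.rng(3)
    tags: dict[str, str] = {}
    used: set[str] = set()
    for pop in cfg.pop_labels:
        while True:
            tag = "".join(rng.choice(list("ACGT")) for _ in range(5))
            if tag not in used:
                used.add(tag)
                tags[pop] = tag
                break
    return tags


def _homopolymer_runs(seq: str) -> list[tuple[int, int]]:
    """(start, length) of maximal single-base runs of length >= 2."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= 2:
            runs.append((i, j - i))
        i = j
    return runs


def _apply_errors(
    seq: str,
    cfg: SimConfig,
    rng: np.random.Generator,
    exon_span: tuple[int, int] | None = None,
) -> tuple[str, int, int, int, int]:
    """Homopolymer indels (one base inserted/deleted per affected run) then
    per-base substitutions.

    Returns (sequence, n_sub, n_indel, net_indel, exon_net_indel), where
    exon_net_indel sums signed indel lengths for runs lying entirely inside
    ``exon_span`` (original coordinates) — the indels that can frameshift the
    coding frame downstream.
    """
    n_indel = 0
    net_indel = 0
    exon_net = 0
    if cfg.err_homopolymer > 0:
        out = []
        last = 0
        for start, length in _homopolymer_runs(seq):
            if rng.random() < cfg.err_homopolymer:
                out.append(seq[last:start])
                run = seq[start : start + length]
                delta = 1 if rng.random() < 0.5 else -1
                out.append(run + run[0] if delta == 1 else run[:-1])
                last = start + length
                n_indel += 1
                net_indel += delta
                if exon_span and exon_span[0] <= start and start + length <= exon_span[1]:
                    exon_net += delta
        out.append(seq[last:])
        seq = "".join(out)
    n_sub = 0
    if cfg.err_sub > 0:
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        hits = np.nonzero(rng.random(len(arr)) < cfg.err_sub)[0]
        for i in hits:
            base = arr[i].decode()
            arr[i] = rng.choice([b for b in "ACGT" if b != base]).encode()
        n_sub = len(hits)
        seq = arr.tobytes().decode()
    return seq, n_sub, n_indel, net_indel, exon_net


def simulate_pool_reads(
    cfg: SimConfig,
    pool_alleles: dict[str, Counter],
    alleles: dict[str, str],
    tag_map: dict[str, str] | None = None,
) -> tuple[list[tuple[str, str]], SyntheticTruth]:
    """Emit multiplexed reads (id, sequence) plus their ground truth.

    Each read is ``tag + forward primer + insert`` where the insert is a
    5' flank, the allele exon and a 3' flank (amplicon-style, longer than the
    downstream truncation length).  A ``chimera_rate`` fraction of reads join
    the 5' part of one allele's insert to the 3' part of another at a uniform
    breakpoint; homopolymer indels and substitutions are layered on top.
    """
    if tag_map is None:
        tag_map = default_tag_map(cfg)
    if len(set(tag_map.values())) != len(tag_map):
        raise ConfigError("duplicate population tags")
    for pop in pool_alleles:
        if not pool_alleles[pop]:
            raise ConfigError(f"pool {pop} has no alleles")

    rng = cfg.rng(4)
    flank5 = "".join(rng.choice(list("ACGT")) for _ in range(cfg.flank5_len))
    flank3 = "".join(rng.choice(list("ACGT")) for _ in range(cfg.flank3_len))
    # alignable core of the exon (12-base margins): indels here always leave
    # frameshift evidence in a reference-anchored alignment
    exon_span = (cfg.flank5_len + 12, cfg.flank5_len + 3 * cfg.n_codons - 12)

    truth = SyntheticTruth(
        allele_seqs=dict(alleles),
        pool_alleles={p: Counter(c) for p, c in pool_alleles.items()},
        insert_prefix=flank5,
        insert_suffix=flank3,
    )

    reads: list[tuple[str, str]] = []
    for pop in cfg.pop_labels:
        counts = pool_alleles[pop]
        ids = sorted(counts)
        weights = np.array([counts[a] for a in ids], dtype=float)
        weights /= weights.sum()
        inserts = {a: flank5 + alleles[a] + flank3 for a in ids}
        for r in range(cfg.depth_per_pool):
            rid = f"{pop}_r{r:05d}"
            if len(ids) > 1 and rng.random() < cfg.chimera_rate:
                i, j = rng.choice(len(ids), size=2, replace=False, p=weights)
                a, b = ids[int(i)], ids[int(j)]
                bp = int(rng.integers(1, len(inserts[a])))
                insert = inserts[a][:bp] + inserts[b][bp:]
                rt = ReadTruth(pop=pop, kind="chimera", parents=(a, b), breakpoint=bp)
            else:
                a = ids[int(rng.choice(len(ids), p=weights))]
                insert = inserts[a]
                rt = ReadTruth(pop=pop, kind="allele", allele_id=a)
            (insert, rt.n_sub, rt.n_indel, rt.net_indel,
             rt.exon_net_indel) = _apply_errors(insert, cfg, rng, exon_span)
            reads.append((rid, tag_map[pop] + _FWD_PRIMER + insert))
            truth.reads[rid] = rt
    return reads, truth


def write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


# ---------------------------------------------------------------------------
# dominant neutral markers


def _true_fst_matrix(q_null: np.ndarray) -> np.ndarray:
    """Multilocus pairwise two-population Fst from null-allele frequencies.

    Per locus: numerator (q1-q2)^2/4 (the between-population variance of q),
    denominator q_bar (1 - q_bar); multilocus value is the ratio of sums.
    """
    n_pops = q_null.shape[0]
    fst = np.zeros((n_pops, n_pops))
    for i in range(n_pops):
        for j in range(i + 1, n_pops):
            q1, q2 = q_null[i], q_null[j]
            qbar = (q1 + q2) / 2.0
            num = (q1 - q2) ** 2 / 4.0
            den = qbar * (1.0 - qbar)
            ok = den > 0
            fst[i, j] = fst[j, i] = num[ok].sum() / den[ok].sum() if ok.any() else 0.0
    return fst


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    return float((xc * (y - y.mean())).sum() / (xc**2).sum())


def simulate_aflp(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.Series, np.ndarray, float]:
    """Dominant (band presence/absence) genotypes with isolation by distance.

    Per-locus band-allele frequencies follow a random linear geographic
    gradient whose strength is calibrated so that true pairwise Fst rises with
    distance at roughly ``ibd_slope_target`` per km, plus independent
    per-population noise. Individuals show a band with probability
    1 - (1-p)^2 under Hardy-Weinberg.

    Returns (genotypes, pop_assign, true_band_freqs, realized_ibd_slope); the
    realized slope is the OLS slope of truth-frequency Fst on distance.
    """
    if cfg.n_pops < 3:
        raise ConfigError("need at least 3 populations")
    if cfg.n_aflp_loci < 10:
        raise ConfigError("n_aflp_loci < 10: slope estimation unstable")
    coords = cfg.coords()
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    if np.any(d[~np.eye(cfg.n_pops, dtype=bool)] == 0):
        raise ConfigError("population coordinates must be pairwise distinct")

    rng = cfg.rng(5)
    L = cfg.n_aflp_loci
    d_max = d.max()
    lo, hi = cfg.aflp_freq_range
    if not 0.0 <= lo < hi <= 1.0:
        raise ConfigError("aflp_freq_range must satisfy 0 <= lo < hi <= 1")
    # small-perturbation calculation: a logit difference dl moves the band
    # frequency by ~(hi-lo)/8 * dl near the middle of the range, Fst ~
    # (dq)^2 / (4 qbar(1-qbar)); matching the secant slope over [0, d_max]
    # to the target gives the gradient scale kappa
    c = (hi - lo) / 8.0
    qmid = 1.0 - (lo + hi) / 2.0
    kappa = np.sqrt(
        8.0 * qmid * (1.0 - qmid) * max(cfg.ibd_slope_target, 0.0)
        / (c**2 * d_max)
    )

    alpha = rng.normal(0.0, 0.8, size=L)
    theta = rng.uniform(0, 2 * np.pi, size=L)
    grad = np.stack([np.cos(theta), np.sin(theta)], axis=1)  # (L, 2)
    proj = coords @ grad.T  # (n_pops, L)
    proj = proj - proj.mean(axis=0, keepdims=True)
    noise = rng.normal(0.0, cfg.aflp_noise_sd, size=(cfg.n_pops, L))
    p_band = lo + (hi - lo) * expit(alpha[None, :] + kappa * proj + noise)

    band_prob = 1.0 - (1.0 - p_band) ** 2
    rows = []
    pops = []
    for pi, pop in enumerate(cfg.pop_labels):
        g = (rng.random((cfg.pool_size, L)) < band_prob[pi]).astype(np.int8)
        rows.append(g)
        pops.extend([pop] * cfg.pool_size)
    genotypes = pd.DataFrame(
        np.vstack(rows),
        index=[f"{p}_{i}" for i, p in enumerate(pops)],
        columns=[f"L{j + 1:04d}" for j in range(L)],
    )
    pop_assign = pd.Series(pops, index=genotypes.index, name="population")

    fst_true = _true_fst_matrix(1.0 - p_band)
    iu = np.triu_indices(cfg.n_pops, 1)
    realized = _ols_slope(d[iu], fst_true[iu])
    return genotypes, pop_assign, p_band, realized


# ---------------------------------------------------------------------------
# bacterial communities

PATHOGEN_TAXA = (
    "Carnobacterium sp.",
    "Staphylococcus sp.",
    "Flavobacterium sp.",
    "unclassified Clostridiales",
    "unclassified Enterobacteriaceae",
    "unclassified Pseudomonadaceae",
    "unclassified Oxalobacteraceae",
)


def assoc_effect_for_r2(r2: float, noise_sd: float = 0.9) -> float:
    """Effect size giving an expected population R^2 on a standardised
    covariate with the given residual noise."""
    if not 0.0 <= r2 < 1.0:
        raise ConfigError("r2 must be in [0, 1)")
    return noise_sd * np.sqrt(r2 / (1.0 - r2))


def simulate_communities(
    cfg: SimConfig, pop_covariate: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Classified 16S record table (taxon, population, count, bootstrap,
    length, pathogen_truth).

    Pathogen richness per population is ``base_richness + assoc_effect * z``
    (z = standardised covariate) plus Gaussian noise, rounded and clipped to
    the number of pathogen taxa; that many pathogen taxa are then drawn
    present. Non-pathogen taxa are present independently. A
    ``junk_record_fraction`` of extra records with short length or low
    assignment bootstrap is appended so QC filtering is exercised without
    perturbing the programmed counts.
    """
    z = np.asarray(pop_covariate, dtype=float)
    if z.shape != (cfg.n_pops,):
        raise ConfigError("pop_covariate needs one value per population")
    if z.std() > 0:
        z = (z - z.mean()) / z.std()
    rng = cfg.rng(6)

    path_taxa = list(PATHOGEN_TAXA[: cfg.n_pathogen_taxa])
    if cfg.n_pathogen_taxa > len(PATHOGEN_TAXA):
        path_taxa += [
            f"unclassified Pathogen_{k}"
            for k in range(len(PATHOGEN_TAXA), cfg.n_pathogen_taxa)
        ]
    nonpath_taxa = [f"Aquaticus taxon_{k + 1:02d}" for k in range(cfg.n_nonpathogen_taxa)]

    rows = []
    for pi, pop in enumerate(cfg.pop_labels):
        latent = cfg.base_richness + cfg.assoc_effect * z[pi] + rng.normal(0, cfg.assoc_noise_sd)
        s_path = int(np.clip(round(latent), 0, len(path_taxa)))
        present = rng.choice(len(path_taxa), size=s_path, replace=False) if s_path else []
        for t in present:
            rows.append((path_taxa[int(t)], pop, 1 + rng.poisson(3.0)))
        for t in nonpath_taxa:
            if rng.random() < cfg.nonpathogen_prevalence:
                rows.append((t, pop, 1 + rng.poisson(5.0)))

    n_junk = int(round(len(rows) * cfg.junk_record_fraction))
    records = []
    for taxon, pop, count in rows:
        records.append(
            (taxon, pop, count, 0.5 + 0.5 * rng.beta(2.0, 1.0), 200 + rng.poisson(60.0))
        )
    all_taxa = path_taxa + nonpath_taxa
    for _ in range(n_junk):
        taxon = all_taxa[int(rng.integers(len(all_taxa)))]
        pop = cfg.pop_labels[int(rng.integers(cfg.n_pops))]
        if rng.random() < 0.5:
            boot, length = rng.uniform(0.0, 0.5), 200 + rng.poisson(60.0)
        else:
            boot, length = 0.5 + 0.5 * rng.beta(2.0, 1.0), int(rng.integers(80, 200))
        records.append((taxon, pop, 1, boot, length))

    df = pd.DataFrame(
        records, columns=["taxon", "population", "count", "bootstrap", "length"]
    )
    df["length"] = df["length"].astype(int)
    df["pathogen_truth"] = df["taxon"].isin(path_taxa)
    return df


# ---------------------------------------------------------------------------
# truth evaluation


def classify_variants(
    variants, truth: SyntheticTruth, truncate_length: int = 220
) -> pd.DataFrame:
    """Label each collapsed variant against the ground truth.

    A variant is ``true`` when its sequence equals the truncated insert of a
    simulated allele.  Otherwise it is an artifact, tagged chimeric when any
    contributing read was a chimera, frameshifted when any contributing read
    carried a net non-3k indel inside the exon span, and substitution-only
    otherwise.
    """
    true_seqs = {
        truth.true_insert(a)[:truncate_length]: a for a in truth.allele_seqs
    }
    rows = []
    for v in variants:
        rids = [r for pool in v.read_ids.values() for r in pool]
        rts = [truth.reads[r] for r in rids]
        is_true = v.sequence in true_seqs
        chimeric = any(rt.kind == "chimera" for rt in rts)
        fs_flags = [rt.exon_net_indel % 3 != 0 for rt in rts]
        rows.append(
            {
                "variant_id": v.variant_id,
                "status": v.status,
                "removal_reason": v.removal_reason,
                "is_true": is_true,
                "source_allele": true_seqs.get(v.sequence),
                "is_chimeric": chimeric and not is_true,
                "is_frameshift": any(fs_flags) and not is_true,
                "all_reads_frameshift": bool(fs_flags) and all(fs_flags) and not is_true,
            }
        )
    return pd.DataFrame(rows)


def recovery_rates(
    variants, truth: SyntheticTruth, truncate_length: int = 220
) -> dict[str, float]:
    """Truth-recovery summary for a filtered variant set.

    Reports the fraction of true alleles present in >= 2 pools whose
    truncated sequence was retained, the removal rate of chimeric/frameshift
    artifact variants, and the removal rate of variants composed exclusively
    of frameshifted reads (which the mod-3 screen must always catch).
    """
    cls = classify_variants(variants, truth, truncate_length)
    pools_per_allele = Counter()
    for pop, counts in truth.pool_alleles.items():
        for aid, c in counts.items():
            if c > 0:
                pools_per_allele[aid] += 1
    eligible = {a for a, k in pools_per_allele.items() if k >= 2}
    retained_true = set(
        cls.loc[(cls.status == "retained") & cls.is_true, "source_allele"]
    )
    recovered = eligible & retained_true

    art = cls[cls.is_chimeric | cls.is_frameshift]
    strict = cls[cls.all_reads_frameshift]
    return {
        "n_true_alleles_2pools": len(eligible),
        "n_true_recovered": len(recovered),
        "true_recovery_rate": len(recovered) / len(eligible) if eligible else 1.0,
        "n_artifacts_chimera_or_fs": int(len(art)),
        "artifact_removal_rate": float((art.status == "removed").mean())
        if len(art)
        else 1.0,
        "n_strict_frameshift": int(len(strict)),
        "strict_frameshift_removal_rate": float((strict.status == "removed").mean())
        if len(strict)
        else 1.0,
    }
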
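"""True-variant calling from multiplexed, population-tagged amplicon reads.

The stepwise filter mirrors the pooled-amplicon genotyping protocol for
duplicated MHC class IIB loci: demultiplex by exact 5-bp tag plus primer
match, truncate reads to a fixed length, collapse exact-identity variants,
discard singletons and single-population variants as putative artifacts,
screen out frameshifted variants by reference-anchored alignment, and emit a
population x variant presence-absence matrix of retained true variants (TV).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align, SeqIO

from ._codon import revcomp, translate_codon

__all__ = [
    "PoolSpec",
    "VariantRecord",
    "CodonAlignment",
    "DemuxResult",
    "FilterResult",
    "demultiplex",
    "truncate_reads",
    "collapse_variants",
    "filter_artifacts",
    "screen_frameshift",
    "build_presence_matrix",
    "run_filter",
    "read_pool_specs",
]


class PoolConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PoolSpec:
    """One population pool: 5-base tag plus locus primers."""

    pop_id: str
    tag: str
    fwd_primer: str
    rev_primer: str

    def __post_init__(self):
        if len(self.tag) != 5:
            raise PoolConfigError(f"tag for {self.pop_id} must be 5 bases")


@dataclass
class VariantRecord:
    variant_id: str
    sequence: str
    counts: dict[str, int]
    read_ids: dict[str, list[str]] = field(default_factory=dict)
    status: str = "retained"
    removal_reason: str = "none"

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    @property
    def n_pops(self) -> int:
        return sum(1 for c in self.counts.values() if c > 0)

    @property
    def symbol_role(self) -> str:
        """TV for retained true variants, AV for removed artifacts."""
        return "TV" if self.status == "retained" else "AV"


@dataclass
class CodonAlignment:
    """In-frame gapped alignment of retained variants against a reference
    codon frame (insertions relative to the reference are dropped; deletions
    appear as gap characters, so every row has length 3 * n_codons)."""

    ids: list[str]
    seqs: list[str]
    n_codons: int

    def __post_init__(self):
        for s in self.seqs:
            if len(s) != 3 * self.n_codons:
                raise ValueError("all rows must span the full codon frame")

    def __len__(self) -> int:
        return len(self.seqs)

    def amino_acids(self) -> list[list[str | None]]:
        """Per sequence, per codon: amino acid or None for gap codons."""
        out = []
        for s in self.seqs:
            row = []
            for i in range(0, len(s), 3):
                codon = s[i : i + 3]
                row.append(None if "-" in codon else translate_codon(codon))
            out.append(row)
        return out

    def subset(self, ids: list[str]) -> "CodonAlignment":
        keep = {i: s for i, s in zip(self.ids, self.seqs)}
        return CodonAlignment([i for i in ids], [keep[i] for i in ids], self.n_codons)


@dataclass
class DemuxResult:
    per_pool: dict[str, list[tuple[str, str]]]
    n_assigned: int
    n_unassigned: int


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _iter_reads(reads) -> list[tuple[str, str]]:
    if isinstance(reads, (str,)) or hasattr(reads, "__fspath__"):
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(reads), "fasta")]
    return [(rid, seq.upper()) for rid, seq in reads]


def demultiplex(
    reads, pools: list[PoolSpec], max_primer_mismatch: int = 1
) -> DemuxResult:
    """Assign each read to the pool whose tag matches exactly at the 5' end
    and whose forward or reverse primer matches downstream within
    ``max_primer_mismatch``; tag and primer are stripped.  Reads matching the
    reverse primer are reverse-complemented into forward orientation.
    """
    if not pools:
        raise PoolConfigError("no pools given")
    tags = [p.tag for p in pools]
    if len(set(tags)) != len(tags):
        raise PoolConfigError("duplicate tags across pools")
    by_tag = {p.tag: p for p in pools}

    per_pool: dict[str, list[tuple[str, str]]] = {p.pop_id: [] for p in pools}
    n_assigned = n_unassigned = 0
    for rid, seq in _iter_reads(reads):
        pool = by_tag.get(seq[:5])
        insert = None
        if pool is not None:
            f, r = pool.fwd_primer, pool.rev_primer
            if len(seq) >= 5 + len(f) and _mismatches(seq[5 : 5 + len(f)], f) <= max_primer_mismatch:
                insert = seq[5 + len(f) :]
            elif len(seq) >= 5 + len(r) and _mismatches(seq[5 : 5 + len(r)], r) <= max_primer_mismatch:
                insert = revcomp(seq[5 + len(r) :])
        if insert is None:
            n_unassigned += 1
        else:
            per_pool[pool.pop_id].append((rid, insert))
            n_assigned += 1
    if n_assigned == 0:
        warnings.warn("no reads could be assigned to any pool")
    return DemuxResult(per_pool, n_assigned, n_unassigned)


def truncate_reads(
    reads: list[tuple[str, str]], length: int = 220
) -> tuple[list[tuple[str, str]], int]:
    """Cut reads to their first ``length`` bases; shorter reads are discarded.
    Returns (kept, n_discarded_short)."""
    if length <= 0:
        raise ValueError("truncation length must be positive")
    kept, dropped = [], 0
    for rid, seq in reads:
        if len(seq) < length:
            dropped += 1
        else:
            kept.append((rid, seq[:length]))
    return kept, dropped


def collapse_variants(per_pool: dict[str, list[tuple[str, str]]]) -> list[VariantRecord]:
    """Exact string identity defines a variant (any base or indel difference
    separates variants).  Variant ids are deterministic, ordered by total
    count descending then sequence lexicographic."""
    counts: dict[str, dict[str, int]] = {}
    read_ids: dict[str, dict[str, list[str]]] = {}
    for pop, reads in per_pool.items():
        for rid, seq in reads:
            counts.setdefault(seq, {}).setdefault(pop, 0)
            counts[seq][pop] += 1
            read_ids.setdefault(seq, {}).setdefault(pop, []).append(rid)
    ordered = sorted(counts, key=lambda s: (-sum(counts[s].values()), s))
    width = max(4, len(str(len(ordered))))
    return [
        VariantRecord(
            variant_id=f"V{k + 1:0{width}d}",
            sequence=seq,
            counts=dict(counts[seq]),
            read_ids=read_ids[seq],
        )
        for k, seq in enumerate(ordered)
    ]


def filter_artifacts(
    variants: list[VariantRecord], singleton_scope: str = "global"
) -> list[VariantRecord]:
    """Remove putative artifact variants.

    ``singleton``: total read count <= 1 (``global`` scope, default) or no
    pool with >= 2 reads (``per_pool`` scope).  ``single_population``: present
    in fewer than two pools.  The first matching rule is recorded.
    """
    if singleton_scope not in {"global", "per_pool"}:
        raise ValueError("singleton_scope must be 'global' or 'per_pool'")
    for v in variants:
        if v.status == "removed":
            continue
        if singleton_scope == "global":
            is_singleton = v.total_count <= 1
        else:
            is_singleton = max(v.counts.values(), default=0) <= 1
        if is_singleton:
            v.status, v.removal_reason = "removed", "singleton"
        elif v.n_pops < 2:
            v.status, v.removal_reason = "removed", "single_population"
    return variants


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -1.0
    # variant flanks (non-exonic bases) hang off the reference for free;
    # reference end gaps stay penalized so terminal exon indels are not
    # silently absorbed into the overhang
    try:
        aligner.end_insertion_score = 0.0
    except AttributeError:  # older biopython naming
        aligner.target_end_gap_score = 0.0
    return aligner


def _project_onto_reference(alignment, ref_len: int) -> tuple[str, list[int]]:
    """Gapped variant sequence in reference coordinates plus the lengths of
    internal indel runs (insertions and deletions) within the reference span."""
    tgt_blocks, qry_blocks = alignment.aligned  # target = reference
    qseq = str(alignment.query)

    gapped = ["-"] * ref_len
    runs: list[int] = []
    prev_t_end = prev_q_end = None
    first = True
    for (t0, t1), (q0, q1) in zip(tgt_blocks, qry_blocks):
        if not first:
            t_gap = t0 - prev_t_end  # deletion in variant (ref bases skipped)
            q_gap = q0 - prev_q_end  # insertion in variant
            if t_gap > 0:
                runs.append(t_gap)
            if q_gap > 0:
                runs.append(q_gap)
        first = False
        for off in range(t1 - t0):
            gapped[t0 + off] = qseq[q0 + off]
        prev_t_end, prev_q_end = t1, q1
    return "".join(gapped), runs


def screen_frameshift(
    variants: list[VariantRecord],
    reference: str,
    min_score_frac: float = 0.5,
) -> tuple[list[VariantRecord], CodonAlignment]:
    """Align each retained variant to the in-frame reference exon, trim
    flanking non-exonic bases to reference coordinates, and remove variants
    containing any indel run whose length is not a multiple of three.

    Survivors form an in-frame codon alignment (gap codons allowed for 3k
    deletions; insertions relative to the reference are dropped from the
    projection).  Variants scoring below ``min_score_frac`` of the maximum
    attainable score are removed as unalignable.
    """
    reference = reference.upper()
    if len(reference) % 3:
        raise ValueError("reference must be in frame (length multiple of 3)")
    aligner = _make_aligner()
    ids, rows = [], []
    for v in variants:
        if v.status == "removed":
            continue
        alignment = aligner.align(reference, v.sequence)[0]
        if alignment.score < min_score_frac * len(reference):
            v.status, v.removal_reason = "removed", "unalignable"
            continue
        gapped, runs = _project_onto_reference(alignment, len(reference))
        if any(r % 3 for r in runs):
            v.status, v.removal_reason = "removed", "frameshift"
            continue
        ids.append(v.variant_id)
        rows.append(gapped)
    return variants, CodonAlignment(ids, rows, len(reference) // 3)


def build_presence_matrix(variants: list[VariantRecord]) -> pd.DataFrame:
    """0/1 population x variant matrix over retained variants, with stable
    row (sorted population) and column (variant id) order."""
    retained = [v for v in variants if v.status == "retained"]
    if not retained:
        raise ValueError(
            "no retained variants; review filtering parameters or input depth"
        )
    pops = sorted({p for v in retained for p in v.counts})
    data = {
        v.variant_id: [1 if v.counts.get(p, 0) > 0 else 0 for p in pops]
        for v in retained
    }
    return pd.DataFrame(data, index=pd.Index(pops, name="population"), dtype=np.int8)


@dataclass
class FilterResult:
    variants: list[VariantRecord]
    alignment: CodonAlignment
    presence: pd.DataFrame
    stats: dict[str, int]

    def variant_table(self) -> pd.DataFrame:
        rows = []
        for v in self.variants:
            rows.append(
                {
                    "variant_id": v.variant_id,
                    "status": v.status,
                    "symbol_role": v.symbol_role,
                    "removal_reason": v.removal_reason,
                    "total_count": v.total_count,
                    "n_pops": v.n_pops,
                    "sequence": v.sequence,
                }
            )
        return pd.DataFrame(rows)


def run_filter(
    reads,
    pools: list[PoolSpec],
    reference: str,
    truncate_length: int = 220,
    max_primer_mismatch: int = 1,
    singleton_scope: str = "global",
    min_score_frac: float = 0.5,
) -> FilterResult:
    """Full filtering chain: demultiplex -> truncate -> collapse -> artifact
    filter -> frameshift screen -> presence matrix."""
    demux = demultiplex(reads, pools, max_primer_mismatch)
    per_pool = {}
    n_short = 0
    for pop, rds in demux.per_pool.items():
        kept, dropped = truncate_reads(rds, truncate_length)
        per_pool[pop] = kept
        n_short += dropped
    variants = collapse_variants(per_pool)
    variants = filter_artifacts(variants, singleton_scope)
    variants, alignment = screen_frameshift(variants, reference, min_score_frac)
    presence = build_presence_matrix(variants)
    reasons = {}
    for v in variants:
        if v.status == "removed":
            reasons[v.removal_reason] = reasons.get(v.removal_reason, 0) + 1
    stats = {
        "n_assigned": demux.n_assigned,
        "n_unassigned": demux.n_unassigned,
        "n_discarded_short": n_short,
        "n_variants": len(variants),
        "n_retained": sum(v.status == "retained" for v in variants),
        **{f"removed_{k}": n for k, n in sorted(reasons.items())},
    }
    return FilterResult(variants, alignment, presence, stats)


def read_pool_specs(path) -> list[PoolSpec]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        PoolSpec(r.pop_id, r.tag, r.fwd_primer, r.rev_primer)
        for r in df.itertuples(index=False)
    ]
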
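"""Independent brute-force oracles used by the test suite.

Everything here is written against Biopython's translation engine and plain
enumeration, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

from itertools import permutations

from Bio.Seq import Seq

BASES = "TCAG"


def bio_translate(codon: str) -> str:
    return str(Seq(codon).translate())


def is_stop(codon: str) -> bool:
    return bio_translate(codon) == "*"


def oracle_syn_sites(codon: str) -> float:
    """Potential synonymous sites of one codon: per position, the fraction of
    the non-stop one-step changes that preserve the amino acid."""
    aa = bio_translate(codon)
    total = 0.0
    for pos in range(3):
        syn = cnt = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if is_stop(alt):
                continue
            cnt += 1
            if bio_translate(alt) == aa:
                syn += 1
        total += syn / cnt if cnt else 0.0
    return total


def oracle_pathway_counts(a: str, b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences averaged over all minimal
    mutational pathways; pathways through stop codons dropped unless all are
    blocked."""
    diffs = [p for p in range(3) if a[p] != b[p]]
    if not diffs:
        return 0.0, 0.0
    results = []
    for order in permutations(diffs):
        cur = a
        syn = non = 0
        blocked = False
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1 :]
            if is_stop(nxt):
                blocked = True
            if (
                not is_stop(cur)
                and not is_stop(nxt)
                and bio_translate(cur) == bio_translate(nxt)
            ):
                syn += 1
            else:
                non += 1
            cur = nxt
        results.append((syn, non, blocked))
    usable = [r for r in results if not r[2]] or results
    sd = sum(r[0] for r in usable) / len(usable)
    nd = sum(r[1] for r in usable) / len(usable)
    return sd, nd


def oracle_ng_pair(seq_a: str, seq_b: str):
    """Brute-force Nei-Gojobori components for an in-frame codon pair of
    sequences: (Nd, Sd, n_sites, s_sites)."""
    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    Sd = Nd = s_sites = 0.0
    n_codons = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if "-" in ca or "-" in cb:
            continue
        s_sites += (oracle_syn_sites(ca) + oracle_syn_sites(cb)) / 2.0
        sd, nd = oracle_pathway_counts(ca, cb)
        Sd += sd
        Nd += nd
        n_codons += 1
    return Nd, Sd, 3.0 * n_codons - s_sites, s_sites
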
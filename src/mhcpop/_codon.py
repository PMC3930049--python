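"""Codon-level primitives shared by the simulator and the selection statistics.

The standard genetic code is built here as a plain dict so that the
Nei-Gojobori machinery does not depend on any external translation engine
(tests cross-check translation against Biopython independently).
"""

from __future__ import annotations

from itertools import product

BASES = "TCAG"

# NCBI standard code, codons enumerated with the first base varying slowest.
_AA_ORDER = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)

CODON_TABLE: dict[str, str] = {
    "".join(codon): aa for codon, aa in zip(product(BASES, repeat=3), _AA_ORDER)
}

STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")
SENSE_CODONS = tuple(c for c in CODON_TABLE if c not in STOP_CODONS)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str | None:
    """Amino acid for a codon; ``None`` for gap-containing or ambiguous codons."""
    if "-" in codon:
        return None
    return CODON_TABLE.get(codon.upper())


def translate(seq: str) -> str:
    """Translate an in-frame DNA string; gap/ambiguous codons become ``-``."""
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not a multiple of 3")
    out = []
    for i in range(0, len(seq), 3):
        aa = translate_codon(seq[i : i + 3])
        out.append(aa if aa is not None else "-")
    return "".join(out)


def has_stop(seq: str) -> bool:
    return "*" in translate(seq)


def codons_of(seq: str) -> list[str]:
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not a multiple of 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]
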
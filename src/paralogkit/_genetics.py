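"""Standard-genetic-code lookup tables shared by the divergence machinery.

Everything here is derived programmatically from Biopython's standard codon
table at import time, so the fourfold-degenerate prefix set and the
synonymous-fraction tables cannot drift out of sync with the code itself.
"""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
GAP_CODON = "---"

#: codon -> one-letter amino acid, stop codons mapped to "*"
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(c for c in CODON_TO_AA if CODON_TO_AA[c] != "*"))

#: unique transition partner of each base (purine<->purine, pyrimidine<->pyrimidine)
TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}

_PURINES = frozenset("AG")


def is_transversion(a: str, b: str) -> bool:
    """True iff a->b crosses the purine/pyrimidine divide."""
    return a != b and ((a in _PURINES) != (b in _PURINES))


def _fourfold_prefixes() -> frozenset[str]:
    out = set()
    for p1 in BASES:
        for p2 in BASES:
            aas = {CODON_TO_AA[p1 + p2 + b] for b in BASES}
            if len(aas) == 1 and "*" not in aas:
                out.add(p1 + p2)
    return frozenset(out)


#: dinucleotide prefixes whose third position is fourfold degenerate
FOURFOLD_PREFIXES = _fourfold_prefixes()

assert FOURFOLD_PREFIXES == frozenset(
    {"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"}
)


def translate_cds(seq: str) -> str:
    """Translate an ungapped in-frame CDS; raises on length % 3 != 0."""
    if len(seq) % 3:
        raise ValueError(f"CDS length {len(seq)} is not a multiple of 3")
    return "".join(CODON_TO_AA.get(seq[i : i + 3], "X") for i in range(0, len(seq), 3))
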
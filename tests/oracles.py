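"""Independent brute-force oracles, deliberately written from scratch:
translation goes through Bio.Seq rather than the package's tables, and
every quantity is enumerated rather than precomputed."""

import math
from itertools import permutations

from Bio.Seq import Seq

BASES = "ACGT"


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_syn_sites(codon: str) -> float:
    """Synonymous site count of one codon by enumerating all 9 changes."""
    s = 0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if _aa(mut) == _aa(codon):
                s += 1
    return s / 3.0


def oracle_path_counts(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) by enumerating every permutation of the differing positions,
    dropping pathways that pass through a stop codon (all-blocked fallback)."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    clean, blocked = [], []
    for order in permutations(diffs):
        cur, sd, nd, stop = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            if _aa(nxt) == "*":
                stop = True
            cur = nxt
        (blocked if stop else clean).append((sd, nd))
    paths = clean or blocked
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


def oracle_ng86(seq_a: str, seq_b: str):
    """Full NG86 Ka/Ks by direct enumeration over the codon columns."""
    S = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if "-" in ca or "-" in cb or "N" in ca or "N" in cb:
            continue
        if _aa(ca) == "*" or _aa(cb) == "*":
            continue
        n_codons += 1
        S += (oracle_syn_sites(ca) + oracle_syn_sites(cb)) / 2.0
        sd, nd = oracle_path_counts(ca, cb)
        Sd += sd
        Nd += nd
    N = 3.0 * n_codons - S
    ps, pn = Sd / S, Nd / N
    jc = lambda p: 0.0 if p == 0 else -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    return {"S": S, "N": N, "Sd": Sd, "Nd": Nd, "Ka": jc(pn), "Ks": jc(ps)}


def oracle_pairwise_diversity(allele_matrix) -> float:
    """Mean pairwise difference count across haploid samples by enumerating
    every pair. ``allele_matrix``: samples x sites array of allele codes."""
    n = len(allele_matrix)
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += sum(a != b for a, b in zip(allele_matrix[i], allele_matrix[j]))
    return total / (n * (n - 1) / 2)
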
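"""Pairwise codon-level divergence: 4DTv, NG86 Ka/Ks, identity.

The divergence statistics operate on a :class:`CodonAlignment`, a pair of
in-frame CDS rows whose gaps occur only as whole codons. Alignments are
normally produced by threading a protein alignment back onto the CDS
(:func:`thread_codon_alignment`), the pal2nal-style route that keeps the
nucleotide alignment in frame by construction.

4DTv is the proportion of transversion differences at fourfold-degenerate
third positions — positions where any nucleotide encodes the same amino
acid, so substitutions there are synonymous and roughly clock-like. The
multiple-hit correction is the Kimura two-parameter transversion distance
-1/2 ln(1 - 2Q), pluggable should a different correction be preferred.

Ka/Ks follows Nei & Gojobori (1986): synonymous site counts from per-site
fractions of synonymous single-nucleotide changes, observed differences
partitioned by equal-weight averaging over all minimal substitution
pathways, and a Jukes-Cantor correction of the raw proportions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from ._genetics import (
    BASES,
    CODON_TO_AA,
    FOURFOLD_PREFIXES,
    GAP_CODON,
    STOP_CODONS,
    is_transversion,
    translate_cds,
)
from .io_formats import SequenceRecord


class SaturationError(ValueError):
    """Observed divergence outside the domain of the distance correction."""


@dataclass
class CodonAlignment:
    """Two aligned in-frame CDS rows; gaps only as whole '---' codons."""

    seq_a: str
    seq_b: str
    id_a: str = "a"
    id_b: str = "b"

    def __post_init__(self) -> None:
        self.seq_a = self.seq_a.upper()
        self.seq_b = self.seq_b.upper()
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned rows differ in length")
        if len(self.seq_a) % 3:
            raise ValueError("alignment length not divisible by 3")
        for name, row in ((self.id_a, self.seq_a), (self.id_b, self.seq_b)):
            for i in range(0, len(row), 3):
                codon = row[i : i + 3]
                if "-" in codon and codon != GAP_CODON:
                    raise ValueError(
                        f"row {name!r}: partial gap in codon {i // 3 + 1} ({codon!r})"
                    )
            ungapped = row.replace("-", "")
            aa = translate_cds(ungapped)
            if "*" in aa[:-1]:
                raise ValueError(f"row {name!r}: internal stop codon")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codon_pairs(self) -> Iterable[tuple[str, str]]:
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


@dataclass
class FourDTvResult:
    n_4d_sites: int
    n_4d_transversions: int
    raw: float
    corrected: float | None  # None when saturated
    saturated: bool

    @property
    def Q(self) -> float:
        return self.raw


@dataclass
class KaKsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ka: float
    Ks: float
    omega: float | None  # None when Ks == 0


@dataclass
class DivergenceEstimate:
    """Bundle of all pairwise divergence statistics for one pair."""

    id_a: str
    id_b: str
    fourdtv: FourDTvResult | None
    kaks: KaKsResult | None
    nt_identity_pct: float
    aa_identity_pct: float | None = None


# ---------------------------------------------------------------------------
# Codon threading (protein alignment -> in-frame nucleotide alignment)


def thread_codon_alignment(
    protein_alignment: Sequence[str],
    cds_a: SequenceRecord,
    cds_b: SequenceRecord,
    id_a: str | None = None,
    id_b: str | None = None,
) -> CodonAlignment:
    """Back-translate a 2-row protein alignment onto its source CDSs.

    Each residue becomes its source codon and each gap a '---' codon, so
    the result is 3x the protein alignment length. Terminal stop codons on
    the CDS are trimmed; any residue that disagrees with the CDS
    translation raises, naming the residue position.
    """
    if len(protein_alignment) != 2:
        raise ValueError("protein alignment must have exactly 2 rows")
    rows = []
    for prot_row, cds in zip(protein_alignment, (cds_a, cds_b)):
        cds_seq = cds.ungapped
        if len(cds_seq) % 3:
            raise ValueError(f"{cds.id}: CDS length not divisible by 3")
        aa = translate_cds(cds_seq)
        if aa.endswith("*"):
            aa = aa[:-1]
            cds_seq = cds_seq[:-3]
        ungapped_prot = prot_row.replace("-", "").upper()
        if len(ungapped_prot) != len(aa):
            raise ValueError(
                f"{cds.id}: protein row has {len(ungapped_prot)} residues but "
                f"CDS translates to {len(aa)}"
            )
        out = []
        k = 0
        for res in prot_row.upper():
            if res == "-":
                out.append(GAP_CODON)
                continue
            if res != aa[k] and res != "X" and aa[k] != "X":
                raise ValueError(
                    f"{cds.id}: protein residue {k + 1} is {res!r} but CDS "
                    f"translates to {aa[k]!r}"
                )
            out.append(cds_seq[3 * k : 3 * k + 3])
            k += 1
        rows.append("".join(out))
    return CodonAlignment(
        rows[0], rows[1], id_a=id_a or cds_a.id, id_b=id_b or cds_b.id
    )


def align_proteins(aa_a: str, aa_b: str) -> tuple[str, str]:
    """Global BLOSUM62 protein alignment (convenience for pipeline glue)."""
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aln = aligner.align(aa_a, aa_b)[0]
    return str(aln[0]), str(aln[1])


# ---------------------------------------------------------------------------
# Fourfold-degenerate transversion distance


def identify_4d_sites(aln: CodonAlignment) -> list[int]:
    """Alignment column indices (0-based, nt) of usable fourfold sites.

    A codon column contributes one site iff neither codon is gapped or
    ambiguous, both codons share the same first two nucleotides, and that
    prefix is fourfold degenerate — so a third-position change is
    synonymous in both sequences.
    """
    sites = []
    for idx, (ca, cb) in enumerate(aln.codon_pairs()):
        if "-" in ca or "-" in cb or "N" in ca or "N" in cb:
            continue
        if ca[:2] == cb[:2] and ca[:2] in FOURFOLD_PREFIXES:
            sites.append(3 * idx + 2)
    return sites


def k2p_transversion_correction(q: float) -> float:
    """Kimura 2-parameter transversion distance -1/2 ln(1-2Q); domain Q < 1/2."""
    return -0.5 * math.log(1.0 - 2.0 * q)


def fourDTv(
    aln: CodonAlignment,
    correction: Callable[[float], float] = k2p_transversion_correction,
) -> FourDTvResult:
    """Raw and multiple-hit-corrected 4DTv of a codon alignment.

    Raises on zero fourfold sites; at Q >= 0.5 the correction is undefined
    and the result is flagged saturated with ``corrected=None``.
    """
    sites = identify_4d_sites(aln)
    if not sites:
        raise ValueError("no fourfold degenerate sites")
    tv = sum(1 for i in sites if is_transversion(aln.seq_a[i], aln.seq_b[i]))
    raw = tv / len(sites)
    if raw >= 0.5:
        return FourDTvResult(len(sites), tv, raw, None, True)
    return FourDTvResult(len(sites), tv, raw, correction(raw), False)


# ---------------------------------------------------------------------------
# NG86 Ka/Ks

def _syn_fraction(codon: str) -> float:
    """Synonymous fraction of the three possible changes at each position,
    summed over positions. Changes to stop codons count as nonsynonymous."""
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if CODON_TO_AA[mut] == aa:  # stops map to '*', never equal to aa
                s += 1.0
        # 3 alternatives per position
    return s / 3.0


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) between two codons, averaged with equal weight over all
    minimal substitution pathways; pathways through stop codons are
    excluded unless every pathway is blocked."""
    diff_positions = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_positions:
        return 0.0, 0.0
    pathways: list[tuple[float, float]] = []
    blocked: list[tuple[float, float]] = []
    for order in itertools.permutations(diff_positions):
        cur = c1
        sd = nd = 0.0
        hits_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            if nxt in STOP_CODONS:
                hits_stop = True
            cur = nxt
        (blocked if hits_stop else pathways).append((sd, nd))
    if not pathways:
        pathways = blocked
    sd = sum(p[0] for p in pathways) / len(pathways)
    nd = sum(p[1] for p in pathways) / len(pathways)
    return sd, nd


# precomputed tables keyed by codon (pair); built once at import
_SYN_FRACTION = {c: _syn_fraction(c) for c in CODON_TO_AA if CODON_TO_AA[c] != "*"}
_PATHWAY = {
    (a, b): _pathway_counts(a, b)
    for a in _SYN_FRACTION
    for b in _SYN_FRACTION
}


def jukes_cantor(p: float) -> float:
    """JC69 distance -3/4 ln(1 - 4p/3); domain p < 3/4."""
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_kaks(aln: CodonAlignment) -> KaKsResult:
    """Nei-Gojobori (1986) Ka, Ks and omega for a pairwise codon alignment.

    Codon columns containing a gap or an ambiguous base are excluded from
    both site and difference counts. Raises :class:`SaturationError` when
    ps or pn reaches 3/4 and ValueError when no synonymous sites remain.
    """
    S = 0.0
    Sd = Nd = 0.0
    n_used = 0
    for ca, cb in aln.codon_pairs():
        if "-" in ca or "-" in cb or "N" in ca or "N" in cb:
            continue
        if ca not in _SYN_FRACTION or cb not in _SYN_FRACTION:
            continue  # stop codon in a column (terminal): not countable
        n_used += 1
        S += 0.5 * (_SYN_FRACTION[ca] + _SYN_FRACTION[cb])
        sd, nd = _PATHWAY[(ca, cb)]
        Sd += sd
        Nd += nd
    if S <= 0:
        raise ValueError("no synonymous sites in alignment")
    N = 3.0 * n_used - S
    ps = Sd / S
    pn = Nd / N if N > 0 else 0.0
    if ps >= 0.75 or pn >= 0.75:
        raise SaturationError(f"proportion at or beyond JC69 domain (ps={ps:.3f}, pn={pn:.3f})")
    Ks = jukes_cantor(ps)
    Ka = jukes_cantor(pn)
    omega = Ka / Ks if Ks > 0 else None
    return KaKsResult(S=S, N=N, Sd=Sd, Nd=Nd, ps=ps, pn=pn, Ka=Ka, Ks=Ks, omega=omega)


# ---------------------------------------------------------------------------
# Identity and profiles


def pairwise_identity(row_a: str, row_b: str) -> float:
    """Percent identity over columns where neither row is gapped."""
    if len(row_a) != len(row_b):
        raise ValueError("rows differ in length")
    comparable = matches = 0
    for a, b in zip(row_a.upper(), row_b.upper()):
        if a == "-" or b == "-":
            continue
        comparable += 1
        if a == b:
            matches += 1
    if comparable == 0:
        raise ValueError("no comparable (gap-free) columns")
    return 100.0 * matches / comparable


def classify_age(result: FourDTvResult, recent_lt: float = 0.01, ancient_gt: float = 0.5) -> str:
    """Duplication-age class from corrected 4DTv: recent / intermediate / ancient / saturated."""
    if result.saturated or result.corrected is None:
        return "saturated"
    if result.corrected > ancient_gt:
        return "ancient"
    if result.corrected < recent_lt:
        return "recent"
    return "intermediate"


def divergence_profile(
    alignments: Sequence[CodonAlignment],
    recent_lt: float = 0.01,
    ancient_gt: float = 0.5,
) -> tuple[list[DivergenceEstimate], dict[str, int]]:
    """Per-pair divergence estimates plus age-class counts for a cohort."""
    if not alignments:
        raise ValueError("empty cohort")
    counts = {"recent": 0, "intermediate": 0, "ancient": 0, "saturated": 0}
    estimates = []
    for aln in alignments:
        ft = fourDTv(aln)
        counts[classify_age(ft, recent_lt, ancient_gt)] += 1
        try:
            kaks = ng86_kaks(aln)
        except (SaturationError, ValueError):
            kaks = None
        estimates.append(
            DivergenceEstimate(
                id_a=aln.id_a,
                id_b=aln.id_b,
                fourdtv=ft,
                kaks=kaks,
                nt_identity_pct=pairwise_identity(aln.seq_a, aln.seq_b),
            )
        )
    return estimates, counts
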
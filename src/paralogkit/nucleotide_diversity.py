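"""Per-gene nucleotide diversity, impact filtering, and co-occurrence tests.

Nucleotide diversity pi is computed VariScan-style: per segregating site
the unbiased heterozygosity h = (n/(n-1)) (1 - sum p_i^2) with per-site
complete-case sample size n, then summed and normalized either per
interval base (per_site) or per segregating site (per_segregating_site).
The normalization is a mandatory argument — the two conventions differ by
orders of magnitude and published values do not always say which was used
— and reports carry both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import VariantSite

log = logging.getLogger(__name__)

NORMALIZATIONS = ("per_site", "per_segregating_site")


@dataclass
class DiversityResult:
    gene_id: str
    n_snps: int
    pi: float | None
    normalization: str
    L: int
    n_min: int | None = None
    n_max: int | None = None
    n_low_n_excluded: int = 0


@dataclass
class ImpactSummary:
    gene_id: str
    impact_counts: dict[str, int]
    n_nonsynonymous: int
    n_nonsense_or_frameshift: int
    n_deleterious: int


@dataclass
class AccessionGenotypeMatrix:
    """Accessions x variants presence/absence of the ALT allele."""

    gene_id: str
    accessions: list[str]
    variant_keys: list[tuple[str, int, str]]  # (chrom, pos, alt)
    matrix: np.ndarray  # shape (n_accessions, n_variants), dtype int8

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.accessions), len(self.variant_keys)):
            raise ValueError("matrix dimensions inconsistent with labels")

    def carriers(self) -> set[str]:
        """Accessions carrying at least one of the variants."""
        if self.matrix.size == 0:
            return set()
        mask = self.matrix.any(axis=1)
        return {a for a, m in zip(self.accessions, mask) if m}


def site_heterozygosity(site: VariantSite) -> float:
    """Unbiased per-site heterozygosity (n/(n-1)) (1 - sum p_i^2)."""
    if site.n < 2:
        raise ValueError(f"{site.chrom}:{site.pos}: n={site.n} < 2")
    p = np.array(list(site.allele_counts.values()), dtype=float) / site.n
    return site.n / (site.n - 1) * (1.0 - float(np.sum(p * p)))


def _unique_sites(sites: list[VariantSite]) -> list[VariantSite]:
    """One record per physical site (decomposed multiallelics collapse)."""
    seen: dict[tuple[str, int], VariantSite] = {}
    for s in sites:
        seen.setdefault((s.chrom, s.pos), s)
    return list(seen.values())


def pi_gene(
    sites: list[VariantSite],
    L: int,
    normalization: str,
    gene_id: str = "",
) -> DiversityResult:
    """Nucleotide diversity of one gene interval.

    ``sites`` are the segregating sites inside the interval of length L bp;
    monomorphic positions contribute h = 0 implicitly. Sites with n < 2
    after missing-genotype removal are excluded and counted.
    """
    if L <= 0:
        raise ValueError(f"interval length L={L} must be positive")
    if normalization not in NORMALIZATIONS:
        raise ValueError(f"normalization must be one of {NORMALIZATIONS}")
    unique = _unique_sites(sites)
    usable = [s for s in unique if s.n >= 2]
    n_excluded = len(unique) - len(usable)
    if n_excluded:
        log.info("pi_gene %s: excluded %d site(s) with n < 2", gene_id, n_excluded)
    h_sum = sum(site_heterozygosity(s) for s in usable)
    n_snps = len(usable)
    if normalization == "per_site":
        pi = h_sum / L
    else:
        pi = h_sum / n_snps if n_snps else None
    return DiversityResult(
        gene_id=gene_id,
        n_snps=n_snps,
        pi=pi,
        normalization=normalization,
        L=L,
        n_min=min((s.n for s in usable), default=None),
        n_max=max((s.n for s in usable), default=None),
        n_low_n_excluded=n_excluded,
    )


def filter_by_impact(
    sites: list[VariantSite], keep: set[str] = frozenset({"MODERATE", "HIGH"})
) -> list[VariantSite]:
    """Keep sites whose annotation impact is in ``keep``; order preserved.

    Sites with impact 'unknown' are dropped (and counted in the log)
    unless 'unknown' is explicitly in the keep-set.
    """
    kept = [s for s in sites if s.impact in keep]
    n_unknown = sum(1 for s in sites if s.impact == "unknown")
    if n_unknown and "unknown" not in keep:
        log.info("filter_by_impact: dropped %d site(s) with unknown impact", n_unknown)
    return kept


_NONSYN_EFFECTS = ("missense_variant",)
_NONSENSE_EFFECTS = ("stop_gained", "stop_lost", "frameshift_variant")


def effect_summary(sites: list[VariantSite], gene_id: str = "") -> ImpactSummary:
    """Count annotation impact classes, nonsynonymous (missense) changes,
    nonsense/frameshift changes, and deleterious flags."""
    impact_counts: dict[str, int] = {}
    n_nonsyn = n_nonsense = n_del = 0
    for s in sites:
        impact_counts[s.impact] = impact_counts.get(s.impact, 0) + 1
        effects = s.effect.split("&") if s.effect else []
        if any(e in _NONSYN_EFFECTS for e in effects):
            n_nonsyn += 1
        if any(e in _NONSENSE_EFFECTS for e in effects):
            n_nonsense += 1
        if s.deleterious:
            n_del += 1
    return ImpactSummary(
        gene_id=gene_id,
        impact_counts=impact_counts,
        n_nonsynonymous=n_nonsyn,
        n_nonsense_or_frameshift=n_nonsense,
        n_deleterious=n_del,
    )


def shared_deleterious(
    matrix_a: AccessionGenotypeMatrix, matrix_b: AccessionGenotypeMatrix
) -> tuple[bool, list[str]]:
    """Do any accessions carry a deleterious variant in BOTH genes?

    The matrices must be restricted to deleterious variants and share the
    same accession index; returns the offending accessions, sorted.
    """
    if matrix_a.accessions != matrix_b.accessions:
        raise ValueError("accession sets differ between the two matrices")
    both = sorted(matrix_a.carriers() & matrix_b.carriers())
    return bool(both), both


def read_genotype_matrix(
    vcf_path,
    chrom: str,
    start: int,
    end: int,
    gene_id: str = "",
    variant_subset: set[tuple[str, int, str]] | None = None,
) -> AccessionGenotypeMatrix:
    """Presence/absence of ALT alleles per accession over an interval.

    An accession is a carrier when homozygous for the ALT (haploid-accession
    convention: heterozygous or missing genotypes do not count). Restrict
    to ``variant_subset`` keys (chrom, pos, alt) when given, e.g. the
    deleterious variants of a gene.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    accessions = list(vcf.samples)
    keys: list[tuple[str, int, str]] = []
    columns: list[np.ndarray] = []
    for v in vcf:
        if v.CHROM != chrom or not (start <= v.POS <= end):
            continue
        alts = [a for a in v.ALT if a]
        if len(v.REF) != 1 or any(len(a) != 1 or a not in "ACGT" for a in alts):
            continue
        alleles = [v.REF] + alts
        gt_allele = np.full(len(accessions), -1, dtype=int)
        for i, gt in enumerate(v.genotypes):
            a = gt[:-1]
            if a and a[0] >= 0 and len(set(a)) == 1:
                gt_allele[i] = a[0]
        for k, alt in enumerate(alts, start=1):
            key = (v.CHROM, v.POS, alt)
            if variant_subset is not None and key not in variant_subset:
                continue
            keys.append(key)
            columns.append((gt_allele == k).astype(np.int8))
    matrix = (
        np.column_stack(columns)
        if columns
        else np.zeros((len(accessions), 0), dtype=np.int8)
    )
    return AccessionGenotypeMatrix(
        gene_id=gene_id, accessions=accessions, variant_keys=keys, matrix=matrix
    )
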
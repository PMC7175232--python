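"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions are 1-based inclusive everywhere on the public
surface (GFF3 and VCF native convention); no half-open coordinates leak
out of this module.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

_NT_ALPHABET = frozenset("ACGTN-")
_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZJUO*-")


@dataclass
class SequenceRecord:
    """A named nucleotide or amino-acid sequence.

    ``is_cds`` asserts that the gap-stripped sequence is an in-frame
    coding sequence (length divisible by 3).
    """

    id: str
    seq: str
    moltype: str = "nt"  # {"nt", "aa"}
    is_cds: bool = False

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.moltype not in ("nt", "aa"):
            raise ValueError(f"record {self.id!r}: unknown moltype {self.moltype!r}")
        self.seq = self.seq.upper()
        alphabet = _NT_ALPHABET if self.moltype == "nt" else _AA_ALPHABET
        bad = set(self.seq) - alphabet
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal {self.moltype} character(s) "
                f"{''.join(sorted(bad))!r}"
            )
        if self.is_cds:
            if self.moltype != "nt":
                raise ValueError(f"record {self.id!r}: is_cds requires moltype='nt'")
            ungapped = self.seq.replace("-", "")
            if len(ungapped) % 3:
                raise ValueError(
                    f"record {self.id!r}: CDS length {len(ungapped)} not divisible by 3"
                )

    @property
    def ungapped(self) -> str:
        return self.seq.replace("-", "")


@dataclass(frozen=True)
class GeneModel:
    """A gene locus in GFF3 convention: 1-based, inclusive on both ends."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError(f"gene {self.gene_id!r}: empty chromosome")
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class VariantSite:
    """One biallelic SNP record (multiallelic sites are decomposed per ALT).

    ``allele_counts`` maps every allele observed at the site (REF and all
    ALTs) to its haploid count, so decomposed records of one multiallelic
    site share identical counts and the site contributes once to diversity.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    allele_counts: dict[str, int]
    n: int
    impact: str = "unknown"  # {HIGH, MODERATE, LOW, MODIFIER, unknown}
    effect: str = ""
    deleterious: bool | None = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"{self.chrom}:{self.pos}: n must be positive")
        if sum(self.allele_counts.values()) != self.n:
            raise ValueError(
                f"{self.chrom}:{self.pos}: allele counts "
                f"{self.allele_counts} do not sum to n={self.n}"
            )


RELATION_COLUMNS = ["species", "gene_a", "gene_b", "relation", "ka", "ks"]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, moltype: str = "nt", is_cds: bool = False) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into SequenceRecords, order preserved."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            records.append(
                SequenceRecord(id=rec.id, seq=str(rec.seq), moltype=moltype, is_cds=is_cds)
            )
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: list[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 60):
                fh.write(rec.seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# GFF3

_GFF_COLS = ("seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes")


def read_gff3(path, feature_type: str = "gene") -> list[GeneModel]:
    """Read gene models from a GFF3 file (1-based inclusive coordinates).

    Only rows of ``feature_type`` are returned; the ID attribute becomes
    ``gene_id``. A row of the requested type without an ID, or with
    start > end, raises with the offending line number.
    """
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated fields")
            row = dict(zip(_GFF_COLS, fields))
            if row["type"] != feature_type:
                continue
            m = re.search(r"(?:^|;)\s*ID=([^;]+)", row["attributes"])
            if not m:
                raise ValueError(f"{path}:{lineno}: {feature_type} feature lacks ID attribute")
            try:
                model = GeneModel(
                    gene_id=m.group(1).strip(),
                    chrom=row["seqid"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"] if row["strand"] in ("+", "-") else ".",
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            models.append(model)
    return models


def write_gff3(models: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write(
                f"{m.chrom}\t.\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\tID={m.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# VCF

ANN_FIELDS = (
    "allele", "effect", "impact", "gene_name", "gene_id", "feature_type",
    "feature_id", "biotype",
)
_IMPACTS = frozenset({"HIGH", "MODERATE", "LOW", "MODIFIER"})


def _parse_ann(ann_value: str, alt: str, gene_id: str | None) -> tuple[str, str]:
    """Pick (effect, impact) from a SnpEff ANN string.

    The first annotation whose gene field matches ``gene_id``
    (case-insensitive) wins; with no gene constraint, the first annotation
    for the ALT allele wins, else the first annotation overall. No match
    at all -> ("", "unknown").
    """
    annotations = []
    for chunk in ann_value.split(","):
        parts = chunk.split("|")
        entry = dict(zip(ANN_FIELDS, parts))
        annotations.append(entry)
    if gene_id is not None:
        want = gene_id.lower()
        for entry in annotations:
            if entry.get("gene_name", "").lower() == want or entry.get("gene_id", "").lower() == want:
                return _effect_impact(entry)
        return "", "unknown"
    for entry in annotations:
        if entry.get("allele") == alt:
            return _effect_impact(entry)
    if annotations:
        return _effect_impact(annotations[0])
    return "", "unknown"


def _effect_impact(entry: dict[str, str]) -> tuple[str, str]:
    impact = entry.get("impact", "")
    return entry.get("effect", ""), impact if impact in _IMPACTS else "unknown"


@dataclass
class VcfScanStats:
    """Records dropped while scanning an interval, for the run log."""

    n_snps: int = 0
    n_indels_skipped: int = 0
    n_other_skipped: int = 0
    n_all_missing_skipped: int = 0
    n_multiallelic: int = 0


def read_vcf_interval(
    path,
    chrom: str,
    start: int,
    end: int,
    ann_field: bool = True,
    gene_id: str | None = None,
    stats: VcfScanStats | None = None,
) -> list[VariantSite]:
    """Read SNPs from ``chrom:start-end`` (1-based, inclusive both ends).

    Each inbred accession contributes one haploid allele: homozygous
    genotypes count their allele once, heterozygous and missing genotypes
    are dropped from that site's n. Indels and other non-SNP records are
    skipped and counted in ``stats`` (also logged). Multiallelic SNPs are
    decomposed into one record per ALT sharing the full allele-count map.
    """
    from cyvcf2 import VCF

    if end < start:
        raise ValueError(f"interval end {end} < start {start}")
    if stats is None:
        stats = VcfScanStats()
    sites: list[VariantSite] = []
    vcf = VCF(str(path))
    for v in vcf:
        if v.CHROM != chrom or not (start <= v.POS <= end):
            continue
        alts = [a for a in v.ALT if a]
        if not alts:
            stats.n_other_skipped += 1
            continue
        if len(v.REF) != 1 or any(len(a) != 1 or a not in "ACGT" for a in alts):
            stats.n_indels_skipped += 1
            continue
        alleles = [v.REF] + alts
        counts = {a: 0 for a in alleles}
        for gt in v.genotypes:
            a = gt[:-1]  # drop phasing flag
            if not a or a[0] < 0 or len(set(a)) != 1:
                continue  # missing or heterozygous: not one haploid allele
            counts[alleles[a[0]]] += 1
        n = sum(counts.values())
        if n == 0:
            stats.n_all_missing_skipped += 1
            continue
        if len(alts) > 1:
            stats.n_multiallelic += 1
        ann_value = v.INFO.get("ANN") if ann_field else None
        for alt in alts:
            effect, impact = ("", "unknown")
            if ann_value:
                effect, impact = _parse_ann(str(ann_value), alt, gene_id)
            sites.append(
                VariantSite(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=alt,
                    allele_counts=dict(counts),
                    n=n,
                    impact=impact,
                    effect=effect,
                )
            )
        stats.n_snps += 1
    log.info(
        "VCF scan %s:%d-%d: %d SNP sites kept; skipped %d indel, %d other, "
        "%d all-missing records (%d multiallelic)",
        chrom, start, end, stats.n_snps, stats.n_indels_skipped,
        stats.n_other_skipped, stats.n_all_missing_skipped, stats.n_multiallelic,
    )
    return sites


# ---------------------------------------------------------------------------
# Relation tables and TSV reports


def read_relation_table(path) -> pd.DataFrame:
    """Read a paralog/ortholog relation TSV (species, gene_a, gene_b, relation[, ka, ks])."""
    df = pd.read_csv(path, sep="\t", dtype={"species": str, "gene_a": str, "gene_b": str})
    missing = {"species", "gene_a", "gene_b", "relation"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: relation table missing columns {sorted(missing)}")
    bad = set(df["relation"].unique()) - {"paralog", "ortholog"}
    if bad:
        raise ValueError(f"{path}: unknown relation values {sorted(bad)}")
    for col in ("ka", "ks"):
        if col not in df.columns:
            df[col] = pd.NA
    return df[RELATION_COLUMNS]


def write_report(rows, path, columns: list[str] | None = None) -> None:
    """Write homogeneous rows (dicts or dataclass-likes) as a TSV report.

    Zero rows with ``columns`` given yields a header-only file.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(list(rows), columns=columns)
    if columns is not None:
        df = df.reindex(columns=columns)
    df.to_csv(path, sep="\t", index=False)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Deleteriousness calls (external predictor output consumed as a table)


def read_deleterious_table(path) -> dict[tuple[str, int, str], bool]:
    """Read (chrom, pos, alt, deleterious in {0,1}) TSV into a lookup map."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "alt": str})
    missing = {"chrom", "pos", "alt", "deleterious"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: deleterious table missing columns {sorted(missing)}")
    return {
        (r.chrom, int(r.pos), r.alt): bool(int(r.deleterious))
        for r in df.itertuples()
    }


def annotate_deleterious(
    sites: list[VariantSite], table: dict[tuple[str, int, str], bool]
) -> list[VariantSite]:
    """Attach deleteriousness flags in place; unknown variants stay None."""
    for s in sites:
        key = (s.chrom, s.pos, s.alt)
        if key in table:
            s.deleterious = table[key]
    return sites
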
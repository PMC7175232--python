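"""Pipeline orchestration: wire the stages into reproducible file-to-file runs.

Two entry points mirror the two halves of the analysis:

* :func:`run_divergence_report` — gene models + paralog relations + CDS
  (and optional protein) FASTA -> tandem classification, 4DTv, Ka/Ks and
  identity reports.
* :func:`run_diversity_report` — annotated VCF + gene intervals
  (+ optional deleteriousness table) -> per-gene nucleotide diversity
  under both normalizations, impact summaries and the cross-gene
  deleterious co-occurrence verdict.

Every run writes a ``manifest.json`` recording inputs, parameters, seed
and package version; report files contain no timestamps, so re-running
with the same config and seed reproduces them byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .codon_divergence import (
    SaturationError,
    align_proteins,
    fourDTv,
    ng86_kaks,
    pairwise_identity,
    thread_codon_alignment,
)
from .io_formats import (
    VcfScanStats,
    annotate_deleterious,
    read_deleterious_table,
    read_fasta,
    read_gff3,
    read_relation_table,
    read_vcf_interval,
    write_report,
)
from .nucleotide_diversity import (
    effect_summary,
    filter_by_impact,
    pi_gene,
    read_genotype_matrix,
    shared_deleterious,
)
from .paralog_architecture import TANDEM_THRESHOLD_BP, build_pairs

log = logging.getLogger(__name__)


@dataclass
class GeneInterval:
    gene_id: str
    chrom: str
    start: int
    end: int

    @classmethod
    def parse(cls, gene_id: str, spec: str) -> "GeneInterval":
        """Parse 'chrom:start-end' (1-based inclusive)."""
        chrom, _, span = spec.partition(":")
        start_s, _, end_s = span.partition("-")
        start, end = int(start_s), int(end_s)
        if not chrom or end < start:
            raise ValueError(f"bad interval spec {spec!r}")
        return cls(gene_id, chrom, start, end)


@dataclass
class PipelineConfig:
    gff: str | None = None
    cds: str | None = None
    protein: str | None = None
    vcf: str | None = None
    relations: str | None = None
    deleterious: str | None = None
    intervals: list[GeneInterval] = field(default_factory=list)
    threshold_bp: int = TANDEM_THRESHOLD_BP
    distance_metric: str = "gap"
    pi_normalization: str | None = None  # reports always carry both
    impact_keep: tuple[str, ...] = ("MODERATE", "HIGH")
    seed: int = 0
    out_dir: str = "paralogkit_out"

    def __post_init__(self) -> None:
        if self.threshold_bp <= 0:
            raise ValueError("threshold_bp must be positive")


def load_config(path=None, **overrides) -> PipelineConfig:
    """Build a config with precedence overrides > file > defaults."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    intervals = [
        iv if isinstance(iv, GeneInterval) else GeneInterval(**iv)
        for iv in data.get("intervals", [])
    ]
    data["intervals"] = intervals
    return PipelineConfig(**data)


def _write_manifest(cfg: PipelineConfig, out_dir: Path, stage: str, extra: dict) -> None:
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in dataclasses.asdict(cfg).items()
        },
        **extra,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def _require(path: str | None, what: str) -> str:
    if path is None:
        raise ValueError(f"config is missing required input: {what}")
    if not Path(path).exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    return path


def run_divergence_report(cfg: PipelineConfig) -> dict[str, Path]:
    """Tandem architecture + pairwise divergence; returns written paths."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    relations = read_relation_table(_require(cfg.relations, "relation table"))
    paths: dict[str, Path] = {}

    if cfg.gff:
        models = read_gff3(_require(cfg.gff, "GFF3"))
        pairs = build_pairs(relations, models, cfg.threshold_bp, cfg.distance_metric)
        rows = [
            {
                "gene_a": p.gene_a.gene_id,
                "gene_b": p.gene_b.gene_id,
                "same_chrom": p.same_chrom,
                "gap_bp": p.gap_bp,
                "start_to_start_bp": p.start_to_start_bp,
                "is_tandem": p.is_tandem,
            }
            for p in pairs
        ]
        paths["tandem"] = out_dir / "tandem_pairs.tsv"
        write_report(
            rows, paths["tandem"],
            columns=["gene_a", "gene_b", "same_chrom", "gap_bp", "start_to_start_bp", "is_tandem"],
        )

    if cfg.cds:
        cds = {r.id: r for r in read_fasta(_require(cfg.cds, "CDS FASTA"), "nt", is_cds=True)}
        prot = (
            {r.id: r for r in read_fasta(cfg.protein, "aa")} if cfg.protein else {}
        )
        div_rows = []
        for row in relations.itertuples():
            try:
                a, b = cds[row.gene_a], cds[row.gene_b]
            except KeyError as exc:
                raise KeyError(
                    f"divergence stage: CDS missing for gene {exc} "
                    f"(pair {row.gene_a}/{row.gene_b})"
                ) from exc
            if row.gene_a in prot and row.gene_b in prot:
                pa, pb = prot[row.gene_a].seq, prot[row.gene_b].seq
                aln_a, aln_b = align_proteins(pa, pb)
            else:
                from ._genetics import translate_cds

                pa = translate_cds(a.ungapped).rstrip("*")
                pb = translate_cds(b.ungapped).rstrip("*")
                aln_a, aln_b = align_proteins(pa, pb)
            aln = thread_codon_alignment([aln_a, aln_b], a, b)
            ft = fourDTv(aln)
            try:
                kk = ng86_kaks(aln)
                ka, ks, omega = kk.Ka, kk.Ks, kk.omega
            except (SaturationError, ValueError) as exc:
                log.warning("kaks %s/%s: %s", row.gene_a, row.gene_b, exc)
                ka = ks = omega = None
            div_rows.append(
                {
                    "gene_a": row.gene_a,
                    "gene_b": row.gene_b,
                    "n_4d_sites": ft.n_4d_sites,
                    "fourdtv_raw": round(ft.raw, 6),
                    "fourdtv_corrected": None if ft.corrected is None else round(ft.corrected, 6),
                    "saturated": ft.saturated,
                    "ka": None if ka is None else round(ka, 6),
                    "ks": None if ks is None else round(ks, 6),
                    "omega": None if omega is None else round(omega, 6),
                    "nt_identity_pct": round(pairwise_identity(aln.seq_a, aln.seq_b), 2),
                    "aa_identity_pct": round(pairwise_identity(aln_a, aln_b), 2),
                }
            )
        paths["divergence"] = out_dir / "divergence.tsv"
        write_report(
            div_rows, paths["divergence"],
            columns=["gene_a", "gene_b", "n_4d_sites", "fourdtv_raw", "fourdtv_corrected",
                     "saturated", "ka", "ks", "omega", "nt_identity_pct", "aa_identity_pct"],
        )

    _write_manifest(cfg, out_dir, "divergence", {"outputs": {k: str(v) for k, v in paths.items()}})
    paths["manifest"] = out_dir / "manifest.json"
    return paths


def run_diversity_report(cfg: PipelineConfig) -> dict[str, Path]:
    """Per-gene diversity + impact summary + co-occurrence verdict."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vcf_path = _require(cfg.vcf, "VCF")
    del_table = (
        read_deleterious_table(_require(cfg.deleterious, "deleterious table"))
        if cfg.deleterious
        else {}
    )
    rows = []
    matrices = {}
    for iv in cfg.intervals:
        stats = VcfScanStats()
        sites = read_vcf_interval(
            vcf_path, iv.chrom, iv.start, iv.end, gene_id=iv.gene_id, stats=stats
        )
        annotate_deleterious(sites, del_table)
        L = iv.end - iv.start + 1
        per_site = pi_gene(sites, L, "per_site", iv.gene_id)
        per_seg = pi_gene(sites, L, "per_segregating_site", iv.gene_id)
        impactful = filter_by_impact(sites, set(cfg.impact_keep))
        summary = effect_summary(sites, iv.gene_id)
        rows.append(
            {
                "gene": iv.gene_id,
                "n_snps": per_site.n_snps,
                "pi_per_site": None if per_site.pi is None else round(per_site.pi, 6),
                "pi_per_segregating_site": None if per_seg.pi is None else round(per_seg.pi, 6),
                "n_impact_filtered": len(impactful),
                "n_nonsynonymous": summary.n_nonsynonymous,
                "n_nonsense_or_frameshift": summary.n_nonsense_or_frameshift,
                "n_deleterious": summary.n_deleterious,
                "n_indels_skipped": stats.n_indels_skipped,
            }
        )
        del_keys = {
            (s.chrom, s.pos, s.alt) for s in sites if s.deleterious
        }
        matrices[iv.gene_id] = read_genotype_matrix(
            vcf_path, iv.chrom, iv.start, iv.end, iv.gene_id, variant_subset=del_keys
        )
    paths = {"diversity": out_dir / "diversity.tsv"}
    write_report(
        rows, paths["diversity"],
        columns=["gene", "n_snps", "pi_per_site", "pi_per_segregating_site",
                 "n_impact_filtered", "n_nonsynonymous", "n_nonsense_or_frameshift",
                 "n_deleterious", "n_indels_skipped"],
    )
    co_rows = []
    gene_ids = list(matrices)
    for i in range(len(gene_ids)):
        for j in range(i + 1, len(gene_ids)):
            any_shared, offenders = shared_deleterious(
                matrices[gene_ids[i]], matrices[gene_ids[j]]
            )
            co_rows.append(
                {
                    "gene_a": gene_ids[i],
                    "gene_b": gene_ids[j],
                    "any_shared_deleterious": any_shared,
                    "offending_accessions": ",".join(offenders),
                }
            )
    paths["cooccurrence"] = out_dir / "cooccurrence.tsv"
    write_report(
        co_rows, paths["cooccurrence"],
        columns=["gene_a", "gene_b", "any_shared_deleterious", "offending_accessions"],
    )
    _write_manifest(cfg, out_dir, "diversity", {"outputs": {k: str(v) for k, v in paths.items()}})
    paths["manifest"] = out_dir / "manifest.json"
    return paths
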
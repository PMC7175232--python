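"""Ground-truth generators for every downstream stage.

Three simulators, matched to what the analysis assumes:

* :func:`evolve_codon_pair` — two coding sequences diverged from a random
  stop-free ancestor along two branches of length d/2 each. Substitution
  events arrive as a Poisson process per nucleotide site; each event is a
  transition with probability kappa/(kappa+2) (one transition vs two
  transversion alternatives per base, rate ratio kappa), amino-acid
  changing events are accepted with probability min(1, omega_true), and
  stop codons are never created. Truth records the realized (counted)
  substitutions, so estimator tests separate estimation error from
  Monte-Carlo noise.

* :func:`simulate_snp_panel` — haploid accession panel with a neutral-like
  site frequency spectrum: segregating-site count Poisson(theta L a_n)
  with a_n the harmonic number, derived-allele count i proportional to
  1/i. truth_pi is the exact average pairwise difference per site of the
  emitted panel.

* :func:`plant_paralog_layout` — chromosomes with planted paralog pairs at
  chosen intergenic gaps, plus the tandem answer key under the strict
  gap < 2500 bp rule.

Identical seeds yield byte-identical outputs everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._genetics import (
    BASES,
    CODON_TO_AA,
    FOURFOLD_PREFIXES,
    SENSE_CODONS,
    TRANSITION_PARTNER,
)
from .io_formats import (
    GeneModel,
    RELATION_COLUMNS,
    SequenceRecord,
    VariantSite,
    write_gff3,
    write_report,
)
from .paralog_architecture import TANDEM_THRESHOLD_BP

_TRANSVERSION_PARTNERS = {
    b: tuple(x for x in BASES if x != b and x != TRANSITION_PARTNER[b]) for b in BASES
}


# ---------------------------------------------------------------------------
# Codon-pair evolution


@dataclass
class PairEvolutionConfig:
    n_codons: int
    d: float  # expected substitution attempts per nucleotide site, both branches
    kappa: float  # transition/transversion rate ratio
    omega_true: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.d < 0:
            raise ValueError("branch length d must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.omega_true < 0:
            raise ValueError("omega_true must be >= 0")


@dataclass
class DivergenceTruth:
    """Realized event counts of one simulated pair, plus the expectation
    parameters they were drawn under."""

    d: float
    kappa: float
    omega_true: float
    n_codons: int
    syn_substitutions: int = 0
    nonsyn_substitutions: int = 0
    transitions: int = 0
    transversions: int = 0
    events_at_4d_sites: int = 0
    transversions_at_4d_sites: int = 0

    @property
    def expected_tv_distance(self) -> float:
        return expected_4d_transversion_distance(self.d, self.kappa)


def expected_4d_transversion_distance(d: float, kappa: float) -> float:
    """Expected transversion substitutions per fourfold-degenerate site.

    At a fourfold third position every event is synonymous and accepted,
    so the realized rate is the full attempt rate d and each event is a
    transversion with probability 2/(kappa+2).
    """
    return d * 2.0 / (kappa + 2.0)


def evolve_codon_pair(
    cfg: PairEvolutionConfig,
) -> tuple[SequenceRecord, SequenceRecord, DivergenceTruth]:
    """Evolve two descendant CDSs from a random ancestor; see module docs."""
    rng = np.random.default_rng(cfg.seed)
    ancestor = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=cfg.n_codons)]
    truth = DivergenceTruth(
        d=cfg.d, kappa=cfg.kappa, omega_true=cfg.omega_true, n_codons=cfg.n_codons
    )
    p_tv = 2.0 / (cfg.kappa + 2.0)
    descendants = []
    for _branch in range(2):
        seq = list(ancestor)
        n_sites = 3 * cfg.n_codons
        n_events = int(rng.poisson(n_sites * cfg.d / 2.0))
        codon_idx = rng.integers(cfg.n_codons, size=n_events)
        pos_idx = rng.integers(3, size=n_events)
        u_type = rng.random(n_events)
        u_which = rng.integers(2, size=n_events)
        u_accept = rng.random(n_events)
        for i, pos, ut, uw, ua in zip(codon_idx, pos_idx, u_type, u_which, u_accept):
            cur = seq[i]
            base = cur[pos]
            is_tv = bool(ut < p_tv)
            new_base = (
                _TRANSVERSION_PARTNERS[base][uw] if is_tv else TRANSITION_PARTNER[base]
            )
            new_codon = cur[:pos] + new_base + cur[pos + 1 :]
            at_4d = pos == 2 and cur[:2] in FOURFOLD_PREFIXES
            if CODON_TO_AA[new_codon] == "*":
                continue  # stop codons are never emitted
            synonymous = CODON_TO_AA[new_codon] == CODON_TO_AA[cur]
            if not synonymous and ua >= min(1.0, cfg.omega_true):
                continue  # amino-acid change rejected by selection
            seq[i] = new_codon
            truth.syn_substitutions += synonymous
            truth.nonsyn_substitutions += not synonymous
            truth.transversions += is_tv
            truth.transitions += not is_tv
            if at_4d:
                truth.events_at_4d_sites += 1
                truth.transversions_at_4d_sites += is_tv
        descendants.append("".join(seq))
    rec_a = SequenceRecord(id="sim_a", seq=descendants[0], moltype="nt", is_cds=True)
    rec_b = SequenceRecord(id="sim_b", seq=descendants[1], moltype="nt", is_cds=True)
    return rec_a, rec_b, truth


# ---------------------------------------------------------------------------
# SNP panel simulation


@dataclass
class PanelConfig:
    n_accessions: int
    L: int  # locus length, bp
    theta: float  # expected per-site diversity
    sfs_model: str = "neutral_1_over_i"  # or "fixed_frequency"
    fixed_freq: float = 0.5
    chrom: str = "1"
    start: int = 1  # 1-based position of the first locus base
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_accessions < 2:
            raise ValueError("n_accessions must be >= 2")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.sfs_model not in ("neutral_1_over_i", "fixed_frequency"):
            raise ValueError(f"unknown sfs_model {self.sfs_model!r}")
        if self.sfs_model == "fixed_frequency" and not 0.0 < self.fixed_freq < 1.0:
            raise ValueError("fixed_freq must lie in (0, 1)")


def simulate_snp_panel(cfg: PanelConfig) -> tuple[list[VariantSite], float]:
    """Draw a panel of segregating sites; returns (sites, truth_pi).

    truth_pi is the exact mean pairwise difference per site of the emitted
    panel: sum_sites i(n-i) / (n(n-1)/2) / L, computed from the emitted
    derived-allele counts, not from theta.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_accessions
    a_n = float(np.sum(1.0 / np.arange(1, n)))
    n_sites = min(int(rng.poisson(cfg.theta * cfg.L * a_n)), cfg.L)
    positions = np.sort(rng.choice(cfg.L, size=n_sites, replace=False)) + cfg.start
    if cfg.sfs_model == "neutral_1_over_i":
        i_values = np.arange(1, n)
        weights = (1.0 / i_values) / np.sum(1.0 / i_values)
        derived = rng.choice(i_values, size=n_sites, p=weights)
    else:
        derived = np.full(n_sites, int(np.clip(round(cfg.fixed_freq * n), 1, n - 1)))
    sites = []
    pair_diffs = 0
    for pos, i in zip(positions, derived):
        i = int(i)
        ref_i, alt_i = rng.choice(4, size=2, replace=False)
        ref, alt = BASES[ref_i], BASES[alt_i]
        sites.append(
            VariantSite(
                chrom=cfg.chrom,
                pos=int(pos),
                ref=ref,
                alt=alt,
                allele_counts={ref: n - i, alt: i},
                n=n,
            )
        )
        pair_diffs += i * (n - i)
    truth_pi = pair_diffs / (n * (n - 1) / 2) / cfg.L
    return sites, truth_pi


_EFFECT_CLASSES = {
    "synonymous": ("synonymous_variant", "LOW"),
    "missense": ("missense_variant", "MODERATE"),
    "nonsense": ("stop_gained", "HIGH"),
    "noncoding": ("intron_variant", "MODIFIER"),
}


def assign_effects(
    sites: list[VariantSite],
    gene_id: str,
    class_probs: dict[str, float] | None = None,
    seed: int = 0,
) -> dict[str, int]:
    """Plant SnpEff-style effect/impact annotations on panel sites.

    Returns the answer key: planted count per effect class. Default class
    mix is mostly synonymous/noncoding with a missense minority and no
    nonsense, echoing a strongly conserved gene.
    """
    if class_probs is None:
        class_probs = {"synonymous": 0.45, "missense": 0.15, "nonsense": 0.0, "noncoding": 0.4}
    names = list(_EFFECT_CLASSES)
    probs = np.array([class_probs.get(k, 0.0) for k in names], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("class probabilities sum to zero")
    probs /= probs.sum()
    rng = np.random.default_rng(seed)
    counts = dict.fromkeys(names, 0)
    for s in sites:
        cls = names[rng.choice(len(names), p=probs)]
        s.effect, s.impact = _EFFECT_CLASSES[cls]
        counts[cls] += 1
    return counts


def assign_deleterious(
    sites: list[VariantSite], fraction: float = 0.25, seed: int = 0
) -> list[tuple[str, int, str]]:
    """Flag a random fraction of missense sites as deleterious (standing in
    for an external predictor); returns the flagged variant keys."""
    rng = np.random.default_rng(seed)
    flagged = []
    for s in sites:
        if s.effect == "missense_variant":
            s.deleterious = bool(rng.random() < fraction)
            if s.deleterious:
                flagged.append((s.chrom, s.pos, s.alt))
        elif s.effect:
            s.deleterious = False
    return flagged


def write_panel_vcf(
    sites: list[VariantSite],
    path,
    gene_id: str = "",
    contig_length: int | None = None,
    seed: int = 0,
) -> dict[str, list[tuple[str, int, str]]]:
    """Write a panel as an uncompressed VCF with inbred-style homozygous
    genotypes and SnpEff-dialect ANN strings for annotated sites.

    Derived-allele carriers are drawn uniformly per site; returns the
    carrier map accession -> [(chrom, pos, alt), ...] as the answer key
    for co-occurrence analyses.
    """
    import pysam

    if not sites:
        raise ValueError("no sites to write")
    rng = np.random.default_rng(seed)
    n = sites[0].n
    samples = [f"acc{i:04d}" for i in range(1, n + 1)]
    header = pysam.VariantHeader()
    contigs = sorted({s.chrom for s in sites})
    length = contig_length or max(s.pos for s in sites) + 1000
    for chrom in contigs:
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    header.add_line(
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in samples:
        header.add_sample(s)
    carriers_of: dict[str, list[tuple[str, int, str]]] = {s: [] for s in samples}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for site in sorted(sites, key=lambda s: (s.chrom, s.pos)):
            if site.n != n:
                raise ValueError("all sites must share the same accession count")
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                alleles=(site.ref, site.alt),
            )
            if site.effect:
                rec.info["ANN"] = (
                    f"{site.alt}|{site.effect}|{site.impact}|{gene_id}|{gene_id}"
                    f"|transcript|{gene_id}.1|protein_coding"
                )
            i = site.allele_counts[site.alt]
            carrier_idx = rng.choice(n, size=i, replace=False)
            carrier_set = set(int(c) for c in carrier_idx)
            for j, sample in enumerate(samples):
                rec.samples[sample]["GT"] = (1, 1) if j in carrier_set else (0, 0)
            for j in carrier_set:
                carriers_of[samples[j]].append((site.chrom, site.pos, site.alt))
            out.write(rec)
    return carriers_of


def write_deleterious_table(
    keys: list[tuple[str, int, str]], all_sites: list[VariantSite], path
) -> None:
    """Write the (chrom, pos, alt, deleterious) TSV consumed downstream."""
    flagged = set(keys)
    rows = [
        {
            "chrom": s.chrom,
            "pos": s.pos,
            "alt": s.alt,
            "deleterious": int((s.chrom, s.pos, s.alt) in flagged),
        }
        for s in all_sites
    ]
    write_report(rows, path, columns=["chrom", "pos", "alt", "deleterious"])


# ---------------------------------------------------------------------------
# Planted paralog genomes


@dataclass
class PlantedPair:
    chrom: str
    gap_bp: int | None  # None -> the two genes go on different chromosomes
    chrom_b: str | None = None


@dataclass
class GenomeLayoutConfig:
    pairs: list[PlantedPair]
    gene_length: int = 3000
    pair_spacing: int = 50_000  # distance between consecutive planted pairs
    species: str = "synthetica"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("no pairs to plant")
        if self.gene_length < 1:
            raise ValueError("gene_length must be >= 1")
        for p in self.pairs:
            if p.gap_bp is not None and p.gap_bp < 0:
                raise ValueError("planted genes would overlap (negative gap)")


def plant_paralog_layout(
    cfg: GenomeLayoutConfig,
) -> tuple[list[GeneModel], pd.DataFrame, pd.DataFrame]:
    """Lay planted pairs onto chromosomes; returns (models, relations, key).

    The answer key marks a pair tandem iff both genes share a chromosome
    and the intergenic gap is strictly below 2500 bp.
    """
    cursor: dict[str, int] = {}
    models: list[GeneModel] = []
    rel_rows = []
    key_rows = []
    for k, p in enumerate(cfg.pairs, start=1):
        ga_id, gb_id = f"{cfg.species}_g{2 * k - 1:04d}", f"{cfg.species}_g{2 * k:04d}"
        start_a = cursor.get(p.chrom, 1)
        a = GeneModel(ga_id, p.chrom, start_a, start_a + cfg.gene_length - 1)
        cursor[p.chrom] = a.end + cfg.pair_spacing
        if p.gap_bp is None:
            chrom_b = p.chrom_b or f"{p.chrom}_alt"
            start_b = cursor.get(chrom_b, 1)
            b = GeneModel(gb_id, chrom_b, start_b, start_b + cfg.gene_length - 1)
            cursor[chrom_b] = b.end + cfg.pair_spacing
            is_tandem = False
            gap = None
        else:
            start_b = a.end + p.gap_bp + 1
            b = GeneModel(gb_id, p.chrom, start_b, start_b + cfg.gene_length - 1)
            cursor[p.chrom] = b.end + cfg.pair_spacing
            is_tandem = p.gap_bp < TANDEM_THRESHOLD_BP
            gap = p.gap_bp
        models.extend([a, b])
        rel_rows.append(
            {"species": cfg.species, "gene_a": ga_id, "gene_b": gb_id,
             "relation": "paralog", "ka": pd.NA, "ks": pd.NA}
        )
        key_rows.append(
            {"gene_a": ga_id, "gene_b": gb_id, "gap_bp": gap, "is_tandem": is_tandem}
        )
    relations = pd.DataFrame(rel_rows, columns=RELATION_COLUMNS)
    answer_key = pd.DataFrame(key_rows)
    return models, relations, answer_key


def plant_paralog_genome(cfg: GenomeLayoutConfig, out_dir) -> dict[str, Path]:
    """File-writing wrapper around :func:`plant_paralog_layout`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    models, relations, answer_key = plant_paralog_layout(cfg)
    paths = {
        "gff3": out_dir / "planted_genes.gff3",
        "relations": out_dir / "planted_relations.tsv",
        "answer_key": out_dir / "planted_answer_key.tsv",
    }
    write_gff3(models, paths["gff3"])
    write_report(relations, paths["relations"])
    write_report(answer_key, paths["answer_key"])
    return paths
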
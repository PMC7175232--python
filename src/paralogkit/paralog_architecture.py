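"""Paralog copy-number tabulation and tandem-duplication classification.

Two paralogs are called a tandem duplication when they lie on the same
chromosome within a small physical distance (default: strictly less than
2500 bp). "Physical distance" is ambiguous between the intergenic gap and
the start-to-start span, so both are computed and the classification
metric is selectable; the gap is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import GeneModel

TANDEM_THRESHOLD_BP = 2500


@dataclass
class PairDistance:
    gap_bp: int | None  # None when on different chromosomes
    start_to_start_bp: int | None
    same_chrom: bool


@dataclass
class ParalogPair:
    gene_a: GeneModel
    gene_b: GeneModel
    gap_bp: int | None
    start_to_start_bp: int | None
    same_chrom: bool
    is_tandem: bool


def pair_distance(a: GeneModel, b: GeneModel) -> PairDistance:
    """Distances between two gene models.

    The intergenic gap counts the bases strictly between the two genes
    (0 if they touch or overlap); start_to_start is |a.start - b.start|.
    Different chromosomes: distances are undefined (None).
    """
    if a.chrom != b.chrom:
        return PairDistance(None, None, False)
    gap = max(0, max(a.start, b.start) - min(a.end, b.end) - 1)
    return PairDistance(gap, abs(a.start - b.start), True)


def classify_tandem(
    a: GeneModel,
    b: GeneModel,
    threshold_bp: int = TANDEM_THRESHOLD_BP,
    metric: str = "gap",
) -> bool:
    """True iff same chromosome and the chosen distance is strictly below
    the threshold. Strand is ignored."""
    d = pair_distance(a, b)
    if not d.same_chrom:
        return False
    value = d.gap_bp if metric == "gap" else d.start_to_start_bp
    if metric not in ("gap", "start_to_start"):
        raise ValueError(f"unknown distance metric {metric!r}")
    return value < threshold_bp


def build_pairs(
    relations: pd.DataFrame,
    models: dict[str, GeneModel] | list[GeneModel],
    threshold_bp: int = TANDEM_THRESHOLD_BP,
    metric: str = "gap",
) -> list[ParalogPair]:
    """Resolve paralog rows of a relation table against gene models and
    classify each pair."""
    if not isinstance(models, dict):
        models = {m.gene_id: m for m in models}
    pairs = []
    for row in relations.itertuples():
        if row.relation != "paralog":
            continue
        try:
            a, b = models[row.gene_a], models[row.gene_b]
        except KeyError as exc:
            raise KeyError(f"relation table gene {exc} not found in gene models") from exc
        d = pair_distance(a, b)
        pairs.append(
            ParalogPair(
                gene_a=a,
                gene_b=b,
                gap_bp=d.gap_bp,
                start_to_start_bp=d.start_to_start_bp,
                same_chrom=d.same_chrom,
                is_tandem=classify_tandem(a, b, threshold_bp, metric),
            )
        )
    return pairs


def copy_number_table(relations: pd.DataFrame, singletons: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-species paralog copy number from a relation table.

    n_copies = number of distinct genes of the species appearing in its
    paralog rows; species listed in ``singletons`` (columns species, gene)
    with no paralog relation get n_copies = 1. A gene claimed by two
    species is an inconsistency and raises.
    """
    gene_species: dict[str, str] = {}
    species_genes: dict[str, set[str]] = {}

    def _claim(species: str, gene: str) -> None:
        prev = gene_species.get(gene)
        if prev is not None and prev != species:
            raise ValueError(f"gene {gene!r} assigned to both {prev!r} and {species!r}")
        gene_species[gene] = species
        species_genes.setdefault(species, set()).add(gene)

    for row in relations.itertuples():
        if row.relation != "paralog":
            continue
        _claim(row.species, row.gene_a)
        _claim(row.species, row.gene_b)
    if singletons is not None:
        for row in singletons.itertuples():
            if row.gene not in gene_species:
                _claim(row.species, row.gene)
    rows = [
        {"species": sp, "n_copies": len(genes)}
        for sp, genes in sorted(species_genes.items())
    ]
    return pd.DataFrame(rows, columns=["species", "n_copies"])


def copy_number_histogram(table: pd.DataFrame) -> dict[int, int]:
    """How many species carry 1, 2, ... paralog copies."""
    return table["n_copies"].value_counts().sort_index().to_dict()


def tandem_distance_stats(
    pairs: list[ParalogPair], metric: str = "gap"
) -> tuple[float, int, int]:
    """(mean, min, max) of the chosen distance over tandem-classified pairs."""
    values = [
        (p.gap_bp if metric == "gap" else p.start_to_start_bp)
        for p in pairs
        if p.is_tandem
    ]
    if not values:
        raise ValueError("no tandem pairs")
    return sum(values) / len(values), min(values), max(values)
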
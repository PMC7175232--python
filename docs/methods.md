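# Methods

## Tandem-duplication classification

A paralog pair is called a tandem duplication when both genes share a
chromosome and their physical distance is strictly below a threshold
(default 2500 bp). "Physical distance" is genuinely ambiguous in the
literature — published tandem cohorts sometimes report distance ranges
extending beyond their own cutoff, which is only consistent if the
cutoff and the reported range use different metrics. The package
therefore computes both candidates and makes the classification metric
explicit:

* **intergenic gap** (default): bases strictly between the two gene
  bodies, `max(0, max(start) − min(end) − 1)`; 0 for touching or
  overlapping genes;
* **start-to-start**: `|start_a − start_b|`.

Strand is ignored; the rule is distance-only. Classification is
symmetric in the pair and monotone in the threshold (both are
property-tested). Pairs on different chromosomes are never tandem and
their distances are reported as undefined rather than as a sentinel
number.

## Codon threading

Divergence statistics need an in-frame nucleotide alignment. Rather than
re-implementing a codon-aware aligner, the package threads a given
protein alignment back onto the source CDSs: each residue becomes its
codon, each residue gap a `---` codon. The protein alignment can come
from any aligner (a global BLOSUM62 pairwise alignment is provided as a
convenience; for near-identical paralogs the choice is immaterial).
Threading validates that each CDS translates exactly to its ungapped
protein row (terminal stop codons are trimmed first) and fails loudly,
naming the residue, on any disagreement — silent frame damage is the
classic failure mode of this step. Within an alignment, gaps may occur
only as whole codons and internal stops are rejected.

## 4DTv

A codon column contributes a fourfold-degenerate (4D) site iff neither
codon is gapped or ambiguous, both codons agree at positions 1–2, and
the shared prefix is fourfold degenerate in the standard code (CT, GT,
TC, CC, AC, GC, CG, GG). Requiring prefix *agreement* guarantees a
third-position change is synonymous in both sequence backgrounds; the
degeneracy table is derived from the genetic code at import rather than
hard-coded. Because the site definition already excludes any gapped
codon column, computing on "all 4D sites" and on "gap-free columns
only" coincide, and no separate option exists for it.

Raw 4DTv is the transversion fraction Q at these sites. The multiple-hit
correction is the Kimura two-parameter transversion distance
−½ ln(1 − 2Q): under a K2P-like process the transversion probability
saturates at ½, and this inverse maps Q back to the expected number of
transversions per site. The correction is a plain function argument, so
an alternative correction can be swapped in without touching the
counting. At Q ≥ ½ the estimate is flagged saturated and the corrected
value is undefined (None), never extrapolated. Corrected 4DTv is 0 at
Q = 0, strictly increasing, and ≥ Q on its domain (tested numerically).

Age classes for duplication cohorts: recent < 0.01, ancient > 0.5 on
the corrected scale, saturated kept separate.

## Ka/Ks (Nei–Gojobori 1986, Jukes–Cantor corrected)

Synonymous site count per codon = Σ over its three positions of
(synonymous single-nucleotide changes at that position)/3, with changes
that create a stop codon counted as nonsynonymous; S averages the two
sequences, N = 3·(codons used) − S. Observed differences in a codon
column are partitioned into synonymous/nonsynonymous by averaging with
equal weight over all minimal substitution pathways (1, 2 or 6 orders);
pathways passing through a stop-codon intermediate are excluded, with a
fallback to all pathways if every order is blocked. Proportions
ps = Sd/S and pn = Nd/N are corrected with Jukes–Cantor
d = −¾ ln(1 − 4p/3); ω = Ka/Ks is undefined when Ks = 0, and p ≥ ¾
raises a saturation error rather than returning a number.

Codon columns containing a gap or an N are excluded from all counts —
conservative and deterministic. The per-codon site fractions and
per-pair pathway partitions are precomputed into lookup tables at import;
the test suite checks them against an independently written brute-force
enumerator (Biopython translation, `itertools.permutations`),
exhaustively for all sense-codon pairs with ≤ 2 differences and on
random 50-codon alignments.

NG86 assumes no transition/transversion bias. On simulated cohorts with
a transition bias (κ = 2) it under-estimates ω by ~15–20% — a known
property of the estimator, visible in the examples; the neutral
ω-recovery check therefore runs at κ = 1, where the assumption holds
and mean ω lands within [0.9, 1.1].

## Nucleotide diversity

Per segregating site, the unbiased haploid heterozygosity
h = (n/(n−1))(1 − Σ pᵢ²), which equals the mean pairwise difference at
that site, i(n−i)/C(n,2) for a biallelic site with derived count i
(tested against an all-pairs enumeration oracle). Per-gene π is Σh
normalized either by the interval length in bp (**per_site**) or by the
number of segregating sites (**per_segregating_site**). The
normalization argument is mandatory and reports always carry both
values: the two conventions differ by orders of magnitude, and published
per-gene diversity numbers do not always state which was used — forcing
the choice surfaces the ambiguity instead of hiding it.

Accession handling follows the inbred-line convention: each accession
contributes one haploid allele; a homozygous genotype counts its allele
once, and missing genotypes are dropped from that site's n (complete
cases per site). Heterozygous calls are also treated as missing — inbred
accessions should be homozygous, so residual hets are most likely
genotyping errors; counting either allele would be arbitrary.
Multiallelic SNPs are decomposed into per-ALT records that share the
full allele-count map, and π deduplicates by position so a multiallelic
site contributes once. Sites with n < 2 after removal are excluded and
counted in the result. Indels and other non-SNP records are skipped at
VCF parsing with logged counts.

Impact filtering keeps MODERATE and HIGH SnpEff classes by default
(missense and worse); records whose ANN annotation does not match the
queried gene get impact `unknown` and are dropped by the filter with a
logged count. Deleteriousness is consumed from an external per-variant
table (chrom, pos, alt → 0/1), standing in for a structure-aware
predictor; no prediction is computed here. The co-occurrence test asks
whether any accession carries ≥ 1 deleterious variant in each of two
genes, using homozygous-ALT presence per accession.

## Synthetic-data generators

The generators produce data with exactly the statistical structure the
estimators assume, plus ground truth *realized on the emitted data* (not
the expectation), so estimator tests separate estimation error from
Monte-Carlo noise.

**Codon-pair evolver.** A random stop-free ancestor of `n_codons`
codons; each of two branches of length d/2 receives Poisson(d/2)
substitution events per nucleotide site. Each event is a transition with
probability κ/(κ+2) (each base has one transition and two transversion
alternatives, rate ratio κ), amino-acid-changing events are accepted
with probability min(1, ω_true), and events creating stops are always
rejected. This is an accept/reject scheme, not a full codon rate matrix
— sufficient to generate known Ts/Tv and syn/nonsyn structure at desk
scale, and simple enough that its expectations are available in closed
form: at a fourfold third position every event is synonymous, so the
expected transversion distance there is d·2/(κ+2), which is what
corrected 4DTv estimates. Defaults used in the recovery checks:
n_codons = 3000, d = 0.3, κ = 2 (200 replicates), giving an expected
transversion distance of 0.15. What the evolver does *not* emulate:
codon-usage bias, rate heterogeneity among sites, indels — so passing
recovery tests shows estimator correctness under the model's own
assumptions, not robustness to real-alignment pathologies.

**SNP panel.** Segregating-site count ~ Poisson(θ·L·aₙ) with
aₙ = Σ 1/i, derived-allele counts ∝ 1/i (the neutral SFS shape), or a
fixed-frequency mode; positions uniform without replacement. truth_pi is
the exact mean pairwise difference per site of the emitted counts. There
is no linkage or recombination structure — π is insensitive to linkage,
so the simulator stays minimal; linkage-sensitive statistics should not
be tested against it. Default panel for the exactness checks: n = 100
accessions, L = 10 kb, θ ∈ {0, 0.005, 0.02} — θ = 0.005 is of the order
of genome-wide diversity in a selfing plant, 0.02 a high-diversity
locus. VCF export writes inbred-style homozygous genotypes with
uniformly drawn carriers and returns the carrier map as the answer key.

**Planted genomes.** Pairs are laid down sequentially with chosen
intergenic gaps (50 kb between pairs), optionally split across
chromosomes; the answer key applies the strict < 2500 bp rule to the
planted gaps. Overlapping plants are rejected at configuration time.

## Assay formulas

EL = (S₁−S₀)/(S₂−S₀) × 100 requires S₂ > S₀ (total lysis above
baseline); non-monotone triples are flagged, not rejected, and values
outside [0, 100] are returned as-is — truncating would hide instrument
problems. The formula is invariant under affine rescaling of all three
readings. Comparative Ct uses efficiency exactly 2 (no efficiency
correction — the method as cited assumes perfect doubling); technical
replicates are aggregated by mean Ct before ΔΔCt, biological replicates
summarized as mean ± s.e.m. Greening rate is a plain percentage.

## Numerical and interface choices

* Coordinates are 1-based inclusive (GFF3/VCF convention) on every
  public surface; interval queries are inclusive on both ends and
  disjoint covers concatenate exactly (tested).
* Saturation (Q ≥ ½, p ≥ ¾, Ks = 0) always yields an explicit flag,
  None, or a typed error — never a silently clipped number.
* GFF3 parsing is a strict line-based reader so that a feature of the
  requested type lacking an ID attribute, or with start > end, raises
  with the offending line number; library readers that auto-assign IDs
  would mask exactly the input errors this pipeline needs surfaced.
* All randomness flows through `numpy.random.default_rng(seed)`; the
  same seed reproduces sequences, panels and reports byte for byte
  (timestamps live only in the run manifest).
* Pipeline report sizes: the recovery cohorts (200×3000 codons; 100-
  accession panels) run in a few seconds on one CPU; they were chosen as
  the smallest sizes at which Monte-Carlo error is clearly below the
  recovery tolerances.

## Known limitations

* NG86 with JC correction, not a maximum-likelihood codon model; ω
  values on strongly biased or highly diverged pairs differ from
  codeml-style estimates, and ω comparisons against database-derived
  values should be read to ~two decimals.
* The K2P transversion correction is one standard choice among several;
  it is pluggable precisely because the "right" correction is a
  modelling decision.
* Haploid-accession genotype handling is tailored to inbred panels;
  outcrossing diploid panels would need real diploid counting.
* The copy-number tabulation assumes one gene family per relation
  table (one paralog group per species).
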
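"""Simulate a diverged paralog pair and recover its divergence.

Evolves two CDSs from a common ancestor (d = 0.3 substitution attempts
per site, transition/transversion ratio kappa = 2, neutral amino-acid
changes), then estimates 4DTv, NG86 Ka/Ks and identity from the pair
alone and compares against the generator's ground truth.
"""

from paralogkit import (
    CodonAlignment,
    PairEvolutionConfig,
    evolve_codon_pair,
    expected_4d_transversion_distance,
    fourDTv,
    ng86_kaks,
    pairwise_identity,
)

cfg = PairEvolutionConfig(n_codons=3000, d=0.3, kappa=2.0, omega_true=1.0, seed=42)
a, b, truth = evolve_codon_pair(cfg)
aln = CodonAlignment(a.seq, b.seq)

ft = fourDTv(aln)
kk = ng86_kaks(aln)

print(f"simulated pair: {cfg.n_codons} codons, d={cfg.d}, kappa={cfg.kappa}")
print(f"realized substitutions: {truth.syn_substitutions} syn, {truth.nonsyn_substitutions} nonsyn")
print(f"4DTv raw       = {ft.raw:.4f}  ({ft.n_4d_transversions}/{ft.n_4d_sites} fourfold sites)")
print(f"4DTv corrected = {ft.corrected:.4f}  "
      f"(analytic expectation {expected_4d_transversion_distance(cfg.d, cfg.kappa):.4f})")
print(f"Ka = {kk.Ka:.4f}  Ks = {kk.Ks:.4f}  omega = {kk.omega:.3f}")
print(f"nt identity = {pairwise_identity(aln.seq_a, aln.seq_b):.1f}%")
print()
print("corrected 4DTv near the expectation means the transversion clock at")
print("fourfold-degenerate sites recovers the simulated divergence. omega is")
print("close to 1 (neutral regime) but biased slightly downward: NG86 assumes")
print("no transition/transversion bias, and this cohort was built with kappa=2.")
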
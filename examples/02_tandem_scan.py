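"""Plant paralog pairs on a synthetic chromosome and detect tandems.

Pairs with an intergenic gap strictly below 2500 bp are tandem
duplications; the planted answer key verifies every call.
"""

from paralogkit import GenomeLayoutConfig, PlantedPair, plant_paralog_layout, tandem_distance_stats
from paralogkit.paralog_architecture import build_pairs

gaps = [71, 1500, 2499, 2500, 4963, 9000]
cfg = GenomeLayoutConfig(pairs=[PlantedPair("chr1", g) for g in gaps])
models, relations, key = plant_paralog_layout(cfg)

pairs = build_pairs(relations, models)
for p, planted in zip(pairs, key.itertuples()):
    ok = "ok" if p.is_tandem == planted.is_tandem else "MISMATCH"
    print(f"{p.gene_a.gene_id} - {p.gene_b.gene_id}: gap {p.gap_bp:>5} bp  "
          f"tandem={p.is_tandem}  [{ok}]")

mean, lo, hi = tandem_distance_stats(pairs)
print(f"\ntandem pairs: mean gap {mean:.0f} bp, range {lo}-{hi} bp")
print("the 2500 bp pair is NOT tandem: the rule is a strict '<'.")
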
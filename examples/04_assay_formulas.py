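"""The printed wet-lab assay formulas on worked inputs.

Electrolyte leakage quantifies membrane damage from three conductivity
readings of the same sample; the comparative-Ct method converts qPCR
cycle thresholds into fold changes assuming perfect doubling per cycle.
"""

from paralogkit import (
    ELMeasurement,
    GreeningCount,
    QPCRMeasurement,
    ddct_fold_change,
    electrolyte_leakage,
    greening_rate,
)

el = electrolyte_leakage(ELMeasurement(S0=1.0, S1=3.0, S2=5.0))
print(f"electrolyte leakage (S0=1, S1=3, S2=5): {el:.1f}%")
print("  -> the sample leaked half of its total electrolyte content")

fold = ddct_fold_change(QPCRMeasurement(
    Ct_target_sample=20, Ct_ref_sample=15,
    Ct_target_calibrator=21, Ct_ref_calibrator=15,
))
print(f"ddCt fold change (ddCt = -1): {fold:.1f}x")
print("  -> the target crosses threshold one cycle earlier than in the")
print("     calibrator relative to the reference gene: twice the mRNA")

rate = greening_rate(GreeningCount(n_green=80, n_total=100))
print(f"cotyledon greening: {rate:.0f}%")
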
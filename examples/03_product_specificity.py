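"""Free-energy triplets and product-specificity calls for GLP enzymes.

Feeds the per-step methyl-transfer barriers of wild-type GLP and its
F1209Y / Y1124F mutants through the triplet calculus and the mono/di/tri
classifier.
"""

from methylspec import BarrierSet, classify_specificity, compute_triplet, threshold_consistency_band

wt = BarrierSet(enzyme="WT", barriers=(13.4, 15.8, 22.1))
f1209y = BarrierSet(enzyme="F1209Y", barriers=(13.8, 17.4, None))  # 3rd step not characterized
y1124f = BarrierSet(enzyme="Y1124F", barriers=(13.9, 15.9, 13.3))

for enzyme in (wt, f1209y, y1124f):
    triplet = compute_triplet(wt, enzyme)
    call = classify_specificity(enzyme, threshold=3.0)
    blocked = f"blocked at step {call.blocking_step}" if call.blocking_step else "no block"
    print(f"{enzyme.enzyme:8s} triplet {triplet.formatted():18s} → {call.call:4s} ({blocked})")

lo, hi = threshold_consistency_band(
    {"WT": wt, "F1209Y": f1209y, "Y1124F": y1124f},
    {"WT": "di", "F1209Y": "mono", "Y1124F": "tri"},
)
print(f"\nall three calls hold for blocking thresholds in ({lo:.1f}, {hi:.1f}] kcal/mol;")
print("the 3.0 kcal/mol default is the midpoint of that band")
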
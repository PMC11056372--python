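"""Invert printed percentage metrics back to integer confusion matrices.

Given a classifier row reported only as precision/sensitivity/specificity
percentages, exhaustive search finds the smallest integer confusion matrix
whose percentages print the same way (accepting round-half-up or truncation),
and the remaining metrics follow from the recovered counts.
"""

import math

from dermoscan import compute_metrics, jaccard_from_f1, reconstruct_confusion_from_metrics

rows = {
    "high-performance row": ("96", "92.30", "95.83"),
    "moderate row": ("76", "73.07", "75"),
}
for name, (prec, sens, spec) in rows.items():
    cm = reconstruct_confusion_from_metrics(prec, sens, spec, max_total=60)
    m = compute_metrics(cm)
    print(f"{name}: precision={prec}% sensitivity={sens}% specificity={spec}%")
    print(f"  minimal matrix: TP={cm.tp} FP={cm.fp} FN={cm.fn} TN={cm.tn} (n={cm.total})")
    print(
        f"  derived: accuracy {100 * m.accuracy:.2f}%, F1 {m.f1:.4f}, "
        f"Jaccard {jaccard_from_f1(math.floor(m.f1 * 100) / 100):.4f}, MCC {100 * m.mcc:.2f}%"
    )
# The derived Jaccard applies F1/(2-F1) to the 2-decimal (truncated) F1, the
# convention used in published summary tables.
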
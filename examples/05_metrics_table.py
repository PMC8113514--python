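"""Confusion-matrix metrics: the five derivations used to score step 2.

Feeding any confusion counts through `metrics` yields accuracy, positive
precision, sensitivity, F1 and negative precision; zero-denominator
metrics come back as None rather than a fabricated 0 or 1.
"""

from microflow.evaluation import ConfusionMatrix, metrics

cm = ConfusionMatrix(tp=3179, tn=787, fp=255, fn=183)
m = metrics(cm)
print(f"counts: TP={cm.tp} TN={cm.tn} FP={cm.fp} FN={cm.fn} (n={cm.total})")
for name, value in m.rounded().items():
    print(f"  {name:20s} {value}")

degenerate = metrics(ConfusionMatrix(tp=0, tn=10, fp=0, fn=0))
print("\nall-negative ground truth:")
print(f"  accuracy    {degenerate.accuracy}")
print(f"  sensitivity {degenerate.sensitivity}   (undefined: no positives exist)")
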
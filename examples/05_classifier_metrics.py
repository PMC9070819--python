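"""The confusion-matrix metric suite, including the single-point AUC.

Given TP/FN/TN/FP counts the suite computes accuracy, sensitivity,
specificity, precision, F1, TPR, FPR, the one-operating-point AUC
((TPR - FPR + 1) / 2, i.e. balanced accuracy) and the Matthews correlation
coefficient.  The example uses the test-set counts of a 60-vs-80 cm
classifier with 224 held-out trials.
"""

from felanding import ConfusionMatrix, compute_metrics

cm = ConfusionMatrix(tp=102, fn=9, tn=100, fp=13)
bundle = compute_metrics(cm)

print(f"confusion matrix: TP={cm.tp} FN={cm.fn} TN={cm.tn} FP={cm.fp} "
      f"(n={cm.total})")
for name, value in bundle.as_report().items():
    print(f"  {name:>12}: {value}")
print("\n(the AUC here is the single-operating-point formula, the mean of")
print(" sensitivity and specificity - not a swept ROC area; MCC is the")
print(" balanced 2x2 association in [-1, 1])")
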
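"""The six evaluation metrics from a confusion table.

Evaluates sensitivity, specificity, accuracy, precision, F1 and the Matthews
correlation coefficient on a worked confusion table and on a degenerate one.
"""
import subloc as sl

rep = sl.compute_metrics(sl.ConfusionCounts(tp=70, tn=80, fp=20, fn=30))
print("confusion counts tp=70 tn=80 fp=20 fn=30:")
for k, v in rep.as_dict().items():
    print(f"  {k:>12} = {v:.4f}")

degenerate = sl.compute_metrics(sl.ConfusionCounts(tp=8, tn=0, fp=0, fn=0))
print("\nall-positive edge case (tp=8, everything else 0):")
print(f"  sensitivity = {degenerate.sensitivity}, "
      f"mcc = {degenerate.mcc}, degenerate = {degenerate.degenerate}")
print("Zero-denominator metrics report 0 and are flagged rather than")
print("raised, so batch reports stay machine-readable.")
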
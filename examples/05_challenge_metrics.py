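"""Challenge metrics from a confusion matrix, and stratified splitting.

Feeds the published cross-validation confusion matrix of the optimized
three-layer net through the metrics module and prints the per-class and
total scores; then shows the deterministic stratified 5-fold split on
the database class supports.
"""

import numpy as np

from densecg.evaluate import (ConfusionMatrix4, per_class_metrics,
                              stratified_kfold)

cm = ConfusionMatrix4([[4603, 14, 433, 26],
                       [16, 615, 111, 16],
                       [657, 101, 1627, 30],
                       [67, 10, 49, 153]])
rep = per_class_metrics(cm)
print(f"{'class':<6}{'F1':>8}{'Prec%':>8}{'Recall%':>9}{'Acc%':>7}")
for c in ("N", "AF", "O", "X"):
    print(f"{c:<6}{rep.f1[c]:>8.3f}{rep.precision_pct[c]:>8.1f}"
          f"{rep.recall_pct[c]:>9.1f}{rep.accuracy_pct[c]:>7.1f}")
print(f"F1(Total) = {rep.f1_total:.3f}   Acc(Total) = {rep.acc_total_pct:.2f}%")
print("(F1(Total) averages the N/AF/O class F1; Noise is excluded)\n")

supports = {"N": 5076, "AF": 758, "O": 2415, "X": 279}
labels = np.concatenate([np.array([c] * n, dtype=object)
                         for c, n in supports.items()])
split = stratified_kfold(labels, 5, seed=0)
print("per-class fold sizes of the stratified 5-fold split:")
for c in supports:
    print(f"  {c:>3}: {np.bincount(split.fold[labels == c], minlength=5)}")
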
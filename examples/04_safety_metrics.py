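"""Accuracy and safety statistics straight from a confusion matrix.

Evaluates a 101-case triage confusion matrix (rows = consensus, columns =
prediction, Ok < Plan < Doc < ER) with 12 off-diagonal entries of which 4
sit below the diagonal, then collapses it to the binary medical-attention
outcome (category >= 3).
"""

import numpy as np

from copdtriage.metrics import (
    ConfusionMatrix, binary_metrics, build_confusion, collapse_to_attention,
    safety_summary, triage_metrics,
)

cm = ConfusionMatrix(np.array([
    [6, 0, 0, 0],
    [0, 8, 7, 0],
    [0, 0, 49, 1],
    [0, 0, 4, 26],
]), (1, 2, 3, 4))

m = triage_metrics(cm)
print(f"n = {m.n} cases, {m.TC} matching consensus")
print(f"ACC {m.ACC:.1f}%   ER one-vs-rest: TPR {m.TPR:.1f}%  TNR {m.TNR:.1f}%  "
      f"PPV {m.PPV:.1f}%  NPV {m.NPV:.1f}%")
print(f"UTP {m.UTP:.1f}%   EG1 {m.EG1:.1f}%")

s = safety_summary(cm)
print(f"under-triage: {s.under_triage_rate:.1f}% of cases, "
      f"{s.under_triage_share:.1f}% of misclassifications")

pred = [j + 1 for i in range(4) for j in range(4) for _ in range(cm.counts[i, j])]
cons = [i + 1 for i in range(4) for j in range(4) for _ in range(cm.counts[i, j])]
am = binary_metrics(build_confusion(
    collapse_to_attention(pred), collapse_to_attention(cons), K=2))
print(f"medical attention: ACC {am.ACC:.1f}%  TPR {am.TPR:.1f}%  TNR {am.TNR:.1f}%")
# A TPR of 100% on the attention collapse means no case needing a doctor
# or the ER was ever sent home.
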
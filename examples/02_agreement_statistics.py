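"""Bland–Altman agreement and threshold metrics between two AHI readings.

Builds a mock 12-exam comparison (a reference AHI list and a perturbed
estimate), then prints the bias, its 95 % limits of agreement, and the
15 /h-threshold classification metrics — the statistics by which
single-channel apnea screeners are judged against polysomnography.
"""

import numpy as np

from apneagram.agreement import (bias_and_loa, classification_metrics,
                                 confusion_at_threshold)

rng = np.random.default_rng(3)
ref = np.array([4.0, 7.5, 11.0, 14.0, 16.5, 19.0, 23.0, 27.0, 31.0, 36.0, 42.0, 48.0])
est = ref + rng.normal(0.0, 3.0, ref.size)

ba = bias_and_loa(ref, est)
print(f"bias b = {ba.b:+.2f} /h, sigma = {ba.sigma:.2f} /h")
print(f"95% limits of agreement: [{ba.ll:+.2f}, {ba.lh:+.2f}] /h")
print("  (the interval expected to contain 95% of reference-minus-estimate differences)")

cm = confusion_at_threshold(ref, est, thr=15.0)
print(f"\nconfusion at 15 /h: TP={cm.tp} FP={cm.fp} TN={cm.tn} FN={cm.fn}")
for name, value in classification_metrics(cm).items():
    shown = "undefined" if value is None else f"{100 * value:.1f}%"
    print(f"  {name:3s} = {shown}")
print("Se/Sp describe how reliably moderate-or-worse apnea (AHI >= 15) is recognized.")
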
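"""Method-agreement statistics on paired per-patient measurements.

The statistics mirror a method-comparison study: OLS/Pearson R for
correlation, ICC(2,1) for absolute-agreement reliability, Bland-Altman for
systematic bias, and the Wilcoxon signed-rank test for paired scores.
"""

import numpy as np

from vne.evaluate import PairedMeasurements, agreement_report, wilcoxon_paired

rng = np.random.default_rng(0)
lge = rng.uniform(0.0, 0.4, size=25)              # per-patient burdens
vne = 0.93 * lge + rng.normal(0, 0.03, size=25)   # slightly lower, noisy

pm = PairedMeasurements(list(range(25)), vne, lge, label="burden@50")
rep = agreement_report(pm)
print(f"n={rep.n}  R={rep.r:.3f}  slope={rep.slope:.3f}")
print(f"ICC(2,1)={rep.icc:.3f}  95% CI=({rep.icc_ci95[0]:.3f}, "
      f"{rep.icc_ci95[1]:.3f})")
print(f"Bland-Altman bias={rep.bias:+.4f} "
      f"(negative: first method reads lower)")
print(f"  parametric limits ({rep.loa_parametric[0]:+.4f}, "
      f"{rep.loa_parametric[1]:+.4f}); percentile limits "
      f"({rep.loa_percentile[0]:+.4f}, {rep.loa_percentile[1]:+.4f})")

stat, p = wilcoxon_paired(pm)
print(f"Wilcoxon signed-rank: statistic={stat:.1f}, p={p:.4g}")
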
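"""The two-stage testing cascade on hand-made NQT profiles.

Shows each branch: a clean monotone profile caught by the linear F-test,
a step-like shift caught by Welch's ANOVA at 6 time points, and a
two-time-point decrease caught by the one-sided normal-CDF test.
"""

import numpy as np

from mirtempo import (
    AnalysisConfig,
    assign_anova_groups,
    cdf_test,
    fit_linear,
    welch_anova,
)

# 1) linear stage: monotone NQT profile over 6 time points
y_trend = np.array([-1.2, -0.7, -0.1, 0.4, 0.8, 1.3])
fit = fit_linear(y_trend, np.arange(1, 7.0))
print(f"linear trend:  slope={fit.slope:+.3f}  F={fit.f_statistic:8.1f}  "
      f"p={fit.p_value:.2e}")

# 2) ANOVA stage (>3 time points): early/late step, no straight-line fit
y_step = np.array([-0.9, -1.1, -1.0, 0.9, 1.1, 1.0])
groups = assign_anova_groups(6)
print(f"step profile:  groups {groups[0]} vs {groups[1]}  "
      f"Welch p={welch_anova(y_step, groups):.4f}")

# 3) CDF stage (<=3 time points): one-sided shift between tp1 and tp2
p_down = cdf_test(tp1=0.8, tpn=-1.2)
p_up = cdf_test(tp1=-0.5, tpn=1.0)
print(f"two-point drop  (0.8 -> -1.2): p={p_down:.4f}")
print(f"two-point rise (-0.5 -> 1.0): p={p_up:.4f} "
      f"(one-sided: increases give large p; "
      f"two-sided p={cdf_test(-0.5, 1.0, two_sided=True):.4f})")
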
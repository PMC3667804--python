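"""Y-maze behavioral arm: trials-to-criterion ANOVA across sessions.

Simulates 18 rats at the published session means/SDs (27+/-5 preop,
77+/-18 day 1, 70+/-14 day 3, ~29+/-6 day 9), runs the one-way ANOVA and
the preop-vs-day pairwise t contrasts.  Days 1 and 3 show a large spatial-
memory deficit (p << 0.01); day 9 is typically statistically
indistinguishable from the preoperative baseline (its true deficit is ~2
trials, so individual draws occasionally cross p = 0.05).
"""

import numpy as np

from lffconn import ymaze_anova
from lffconn.synthetic import simulate_ymaze

table = simulate_ymaze(18, rng=np.random.default_rng(11))
means = table.groupby("condition", sort=False)["trials_to_criterion"].agg(["mean", "std"])
print("trials to criterion (mean +/- SD):")
for cond, row in means.iterrows():
    print(f"  {cond:>5}: {row['mean']:5.1f} +/- {row['std']:.1f}")

res = ymaze_anova(table)
print(f"\none-way ANOVA: F = {res.f_statistic:.1f}, p = {res.p_value:.3g}")
for cond, (t, p) in res.pairwise.items():
    flag = "**" if p < 0.01 else ("n.s." if p > 0.05 else "*")
    print(f"  {cond} vs preop: t = {t:+.2f}, p = {p:.3g}  {flag}")
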
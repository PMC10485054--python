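"""Ethospace ordination and per-metric linear models.

The z-scored 16-metric matrix is ordinated by PCA; each video is one point
in the resulting behavioural space.  Group separation (swimmer present vs
absent) is judged by whether each group's mean lies inside the other
group's 95% ellipse, and each metric is additionally regressed on the
human-presence indicator.
"""

import numpy as np

import sharkmove as sm
from sharkmove.ethospace import ethospace, fit_linear_models, zscore
from sharkmove.metrics import METRIC_NAMES, MetricConfig

tracks = sm.simulate_tracks(sm.whale_shark_preset(seed=42))
table = sm.metric_table(tracks, MetricConfig())
finite = table[METRIC_NAMES].replace([np.inf, -np.inf], np.nan).dropna(axis=1)
human = table["human_present"].to_numpy()

res = ethospace(zscore(finite), human)
pct = 100 * res.variance_fraction
print(f"PC1 {pct[0]:.1f}%, PC2 {pct[1]:.1f}%, PC3 {pct[2]:.1f}% of behavioural variance")
top = res.contributions["PC1"].idxmax()
print(f"largest PC1 contributor: {top} ({res.contributions.loc[top, 'PC1']:.1f}%)")
print("group means inside the other group's 95% ellipse:",
      dict(res.overlap_verdict))

lm = fit_linear_models(finite, human)
print()
print(lm[["coefficient", "t_value", "p_value", "df_den"]].round(4).to_string())
# mutual ellipse overlap means the mean behaviours of the two groups are not
# separable in this ordination; the regressions test each metric marginally
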
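"""Generate one synthetic trial under the default study conditions.

Draws ~1100 participants in two arms with four questionnaire waves, heavy-
tailed behaviour counts, wave-wise dropout and the reward scheme, then prints
the structural summary a trial statistician would glance at first.
"""

import numpy as np

from lgcmtrial import GeneratorConfig, generate

cfg = GeneratorConfig()
ds = generate(cfg, seed=1)

print(f"participants: {len(ds)} ({ds.n_exp} experimental / {ds.n_wait} waitlist)")
print(f"female fraction: {ds.wide['female'].mean():.3f}")
print(f"mean age: {ds.wide['age'].mean():.1f}")

y = ds.outcome_matrix("qids")
observed = (~np.isnan(y)).mean(axis=0)
print("observed fraction per wave:", np.round(observed, 3))

for arm in ("exp", "wait"):
    sub = y[(ds.wide["arm"] == arm).to_numpy()]
    means = np.nanmean(sub, axis=0)
    print(f"depression means, {arm:>4}: " + "  ".join(f"{m:.2f}" for m in means))

print(f"max compensation observed: JPY {ds.wide['compensation_jpy'].max()}")

# Interpretation: the experimental arm's depression trajectory declines faster
# than the waitlist arm's (the generating slope arm effect is -0.319 per unit
# of log2 time); dropout rises to ~20% by wave 4, as configured.
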
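"""The study's statistical toolkit on small worked examples."""

import numpy as np

from osteofabric.stats import (
    dunn_multiple_comparison,
    mann_whitney,
    pearson_correlation,
    percent_increase,
    wilcoxon_signed_rank,
)

# Mann-Whitney on completely separated groups of 3: the exact two-sided p
# is 2 * (3! * 3!)/6! = 0.1 — significance is unreachable at these sizes.
res = mann_whitney([1, 2, 3], [4, 5, 6])
print(f"Mann-Whitney {res.statistic=:.0f} p={res.p_two_sided} ({res.method})")

# Wilcoxon signed-rank on 6 paired differences, all positive
res = wilcoxon_signed_rank([0.4, 1.1, 0.7, 0.2, 0.9, 0.5])
print(f"Wilcoxon W={res.statistic:.0f} p={res.p_two_sided:.4f} ({res.method})")

# Dunn's adjusted pairwise comparisons across three time points
rng = np.random.default_rng(0)
groups = [rng.normal(m, 1.0, 8) for m in (0.0, 0.5, 4.0)]
p = dunn_multiple_comparison(groups)
print("Dunn adjusted p matrix:\n", np.round(p, 4))

# Pearson correlation of an imaging metric against a reference measurement
r, p_r = pearson_correlation([1, 2, 3, 4], [1, 3, 2, 4])
print(f"Pearson r={r:.2f} p={p_r:.3f}")

# Radiographic tumor burden: percent increase of the injected side over the
# paired contralateral limb
print(f"percent increase (3.3 vs 3.0 mm^2): {percent_increase(3.3, 3.0):.1f}%")
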
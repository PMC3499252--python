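"""The study-standard statistical comparisons on small metric tables.

Categorical outcomes -> Fisher's exact test; a non-Gaussian metric ->
Mann-Whitney; a Gaussian metric across three groups -> one-way ANOVA with
Tukey's post-test.
"""

import numpy as np

from wormmate import (
    ContingencyTable2x2,
    anova_tukey,
    fisher_exact,
    mann_whitney,
    potency_fraction,
)

# potency: 22/30 wild-type vs 11/30 mutant males sired cross-progeny
wt = ["potent"] * 22 + ["not_potent"] * 8
mut = ["potent"] * 11 + ["not_potent"] * 19
frac_wt, n_wt = potency_fraction(wt)
frac_mut, n_mut = potency_fraction(mut)
table = ContingencyTable2x2(22, 8, 11, 19)
res = fisher_exact(table)
print(f"potency {100*frac_wt:.0f}% (n={n_wt}) vs {100*frac_mut:.0f}% "
      f"(n={n_mut}): Fisher p = {res.p_value:.4f}")

# vulva-contact durations (s), skewed -> rank test
rng = np.random.default_rng(0)
ctrl = rng.exponential(12.0, size=14)
mutant = rng.exponential(25.0, size=14)
mw = mann_whitney(ctrl, mutant)
print(f"contact duration: U = {mw.u_statistic:.0f}, "
      f"p = {mw.p_value:.4f} ({mw.method})")

# thrust frequency (Hz) across three genotypes, Gaussian-like
groups = {
    "wild type": rng.normal(9.0, 0.5, 12),
    "mutant A": rng.normal(9.1, 0.5, 12),
    "mutant B": rng.normal(7.8, 0.5, 12),
}
res = anova_tukey(groups)
print(f"thrust frequency ANOVA: F = {res.f_statistic:.2f}, p = {res.p_value:.2e}")
for _, row in res.pairwise.iterrows():
    print(f"  {row.group_1} vs {row.group_2}: "
          f"dmean = {row.mean_diff:+.2f} Hz, p_adj = {row.p_adj:.4f}"
          + ("  *" if row.reject else ""))

# Small p-values flag the comparisons where the groups genuinely differ.
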
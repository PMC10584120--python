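"""The univariate testing framework on an embryo-development response.

Simulates a monthly embryo response (e.g. percent area yolk declining as
yolk is consumed) for females nested within pH treatment, crossed with
month, then runs the nested ANOVA (treatment tested over the
female-within-treatment mean square), checks normality (Anderson-Darling)
and homogeneity of variance (Levene), and applies the gatekeeping rule:
if variances are heterogeneous the treatment effect must beat the Levene
p-value, not just alpha = 0.05.
"""

import numpy as np
import pandas as pd

from opilio.univariate import (anderson_darling, heteroscedastic_gate,
                               levene_test, nested_anova, tukey_hsd)

rng = np.random.default_rng(3)
rows = []
for treatment in ("Ambient", "pH 7.8", "pH 7.5"):
    for f in range(8):  # 8 females per treatment
        female_effect = rng.normal(scale=2.0)
        for m, month in enumerate(["Aug", "Oct", "Dec", "Feb", "Apr"]):
            pay = 90 - 15 * m + female_effect + rng.normal(scale=2.5)
            rows.append({"treatment": treatment, "female": f"{treatment}-{f}",
                         "month": month, "pay": pay})
df = pd.DataFrame(rows)

res = nested_anova(df.pay, df.treatment, df.female, df.month)
print(res.table.round(3).to_string(index=False))

p_lev = levene_test(df.pay, df.treatment)
# additive female + month residuals (one observation per cell, so the
# two-way fit leaves honest residual noise to check for normality)
resid = (df.pay - df.groupby("female").pay.transform("mean")
         - df.groupby("month").pay.transform("mean") + df.pay.mean())
p_ad = anderson_darling(resid)
gate = heteroscedastic_gate(res.term("treatment").p, p_lev)
print(f"\nLevene p = {p_lev:.3f}, Anderson-Darling (residuals) p = {p_ad:.3f}")
print(f"treatment significant: {gate.significant} at alpha = {gate.alpha_used:.3g} "
      f"(heteroscedastic: {gate.heteroscedastic})")

hsd = tukey_hsd(df.pay, df.treatment.to_numpy())
print("\nTukey letters (groups sharing a letter do not differ):", hsd.letters)
print("With no built-in treatment effect the month term should dominate and "
      "all treatments should share one letter.")
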
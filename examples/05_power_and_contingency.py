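"""The statistics behind the design: sample size and independence tests.

First: how strong must a correlation be for a 3-replicate design to detect
it?  The Fisher-z calculation shows that at alpha = 0.01 (one-sided) and
80% power, rho = 0.9998 needs ~3.5 samples — the rationale for the
r >= 0.9998 edge threshold with n = 3.

Second: chi-square tests on the published summary tables — seed-mapping
quality vs arm (strong association: exact mapping favors the 5p arm) and
regulation direction vs arm (no detectable association).
"""

from coexmir import pearson_chisq, sample_size_for_correlation
from coexmir.reference import arm_by_direction_table, arm_by_quality_table

for rho in (0.9, 0.99, 0.9998):
    res = sample_size_for_correlation(rho, alpha=0.01, power=0.8, sided="one")
    print(f"rho = {rho}: formula n = {res['raw']:.2f} (ceil {res['n']})")

print("\narm x mapping quality (network nodes, both conditions pooled):")
print(arm_by_quality_table())
q = pearson_chisq(arm_by_quality_table())
print(f"chi2 = {q.chi2:.4f}, df = {q.df}, p = {q.p:.4f}  -> mapping quality depends on arm")

print("\narm x regulation direction (seed-mapped DE genes):")
print(arm_by_direction_table())
d = pearson_chisq(arm_by_direction_table())
print(f"chi2 = {d.chi2:.4f}, df = {d.df}, p = {d.p:.4f}  -> no arm preference detectable")
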
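"""Clinical contrasts between the Ch4 groups, plus the power arithmetic.

Median (IQR) with Kruskal-Wallis for continuous scores, presence rates with
uncorrected Pearson chi-square for binarized part-1 items (score >= 1), and
the two-sample t-test power at the study's group sizes for a standardized
mean difference of 0.56.
"""

from ch4subtype import (
    ContingencyTable2x2,
    SimulationConfig,
    fit_norming_model,
    generate_hc_cohort,
    generate_pdmci_cohort,
    kruskal_wallis,
    median_iqr,
    pearson_chi2,
    score_table,
    two_sample_power,
)

cfg = SimulationConfig(seed=1)
model = fit_norming_model(generate_hc_cohort(cfg))
cohort, _, _ = generate_pdmci_cohort(cfg)
scored = score_table(cohort, model)
low = scored[scored["ch4_group"] == "low"]
normal = scored[scored["ch4_group"] == "normal"]

print(f"{'score':<12}{'normal Ch4':<22}{'low Ch4':<22}p")
for col in ("updrs2", "updrs3", "scopa_aut", "upsit", "moca"):
    mn, q1n, q3n = median_iqr(normal[col])
    ml, q1l, q3l = median_iqr(low[col])
    p = kruskal_wallis(normal[col], low[col]).p_value
    print(f"{col:<12}{f'{mn:.1f} ({q1n:.1f}-{q3n:.1f})':<22}"
          f"{f'{ml:.1f} ({q1l:.1f}-{q3l:.1f})':<22}{p:.3f}")

print("\npart-1 item presence (score >= 1):")
for item in ("updrs_1_2", "updrs_1_5"):
    a = int((normal[item] >= 1).sum())
    c = int((low[item] >= 1).sum())
    tab = ContingencyTable2x2(a, len(normal) - a, c, len(low) - c)
    print(f"  {item}: {a}/{len(normal)} vs {c}/{len(low)}, "
          f"chi2 p={pearson_chi2(tab).p_value:.3f}")

power = two_sample_power(116, 32, d=0.56, alpha=0.05)
print(f"\npower at n=116 vs 32 for d=0.56: {100 * power:.0f}%")
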
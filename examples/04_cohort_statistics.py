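"""Cohort-level inference on switching rates.

Simulates a two-arm cohort (dependent vs control) scanned before and after
an exposure that raises the planted switching rate, then runs the study
battery: ANCOVA on pre-exposure rates with age/education/motion covariates,
whole-sample and per-group paired t-tests, and score correlations.
"""

from netswitch import PlantedDesign, SlidingWindowConfig, generate_cohort, run_study_stats
from netswitch.stats import bh_fdr, two_sample_t_summary

design = PlantedDesign.static(n_nodes=12, n_modules=2, n_volumes=240)
cohort = generate_cohort(
    (24, 26),                       # the two arm sizes
    {"dependent": design, "control": design},
    effect=0.01,                    # post-exposure planted-rate increase
    seed=11,
    window=SlidingWindowConfig(),
    events_mean=6, events_sd=2,
    outcome_noise_sd=0.004,
)

table = run_study_stats(cohort, level="global")
for _, row in table.iterrows():
    print(f"{row['test']:>22}: {row['statistic_kind']} = {row['statistic']:7.3f}, p = {row['p']:.4f}")
print("-> the paired tests catch the planted post > pre effect; the")
print("   pre-exposure ANCOVA group contrast is null by construction")

t = two_sample_t_summary(24, 10.58, 6.68, 26, 4.04, 4.65, "pooled")
print(f"\ndemographics check from summary stats alone: t = {t.statistic:.3f}, df = {t.df}")
adj = bh_fdr([0.01, 0.02, 0.04, 0.05])
print(f"step-up FDR of [0.01 0.02 0.04 0.05]: {[round(float(q), 3) for q in adj]}")
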
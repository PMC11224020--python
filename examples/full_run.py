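"""A complete synthetic confinement study: simulate -> measure -> compare.

Two conditions mimic the qualitative contrast between cells confined at a
permissive height (unfolded nuclei, faster migration, nuclear reporter
enrichment) and a control height (folded nuclei, slower, no enrichment).
Every cell is generated, measured and summarized; the comparison reports
differences of medians with seeded bootstrap intervals.
"""

from dcmorph import ConditionSpec, RunConfig, condition_compare, run_pipeline

config = RunConfig(
    seed=1,
    conditions=(
        ConditionSpec(name="h4_control", n_cells=6, fold_amplitude=0.10,
                      width_mean_um=4.5, speed_um_min=2.0, intensity_ratio=1.0),
        ConditionSpec(name="h3_confined", n_cells=6, fold_amplitude=0.03,
                      width_mean_um=3.0, speed_um_min=4.0, intensity_ratio=2.0),
    ),
)
per_cell, summary = run_pipeline(config)

cols = ["condition", "n_cells", "eop_median", "efc_ratio_median",
        "avg_min_um_median", "median_speed_um_min_median", "ratio_nuc_cyt_median"]
print(summary[cols].to_string(index=False, float_format=lambda x: f"{x:8.3f}"))

for metric in ("eop", "efc_ratio", "median_speed_um_min"):
    row = condition_compare(per_cell, metric, seed=0).iloc[0]
    print(
        f"{metric:22s} control->confined difference of medians "
        f"{row['diff_median']:+8.3f}  [{row['ci_low']:+.3f}, {row['ci_high']:+.3f}]"
    )

print(
    "\nThe confined condition shows lower EOP (smoother envelope), higher EFC,"
    "\nthinner cells, faster migration and a doubled nuclear reporter ratio —"
    "\neach recovered from images, not read from the generator."
)
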
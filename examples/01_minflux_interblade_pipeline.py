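"""Interblade distances from a synthetic 3D-MINFLUX/DNA-PAINT dataset.

Generates two conditions — a curved-state population (mean interblade
distance 21.7 nm) and a partially flattened one (23.9 nm) — runs the full
localization-filter -> trace-center -> DBSCAN -> trimer-rules pipeline on
each, and compares them with the normality-gated two-group test.
"""

from piezoflux.cohort_stats import compare_conditions, summarize
from piezoflux.pipeline import run_minflux_pipeline
from piezoflux.synthgen import SynthMinfluxConfig, generate_minflux_dataset

for label, mean_nm, seed in [("CTL", 21.7, 0), ("Yoda1", 23.9, 1)]:
    cfg = SynthMinfluxConfig(n_trimers=150, interblade_mean=mean_nm, seed=seed)
    table, truth = generate_minflux_dataset(cfg)
    result = run_minflux_pipeline(table)
    s = summarize(result.interblade_distances)
    print(
        f"{label}: {len(table)} localizations -> {result.report['n_centers']} "
        f"trace centers -> {result.report['n_sites']} protomer sites -> "
        f"{s.n} trimers; interblade {s.mean:.2f} +- {s.sem:.2f} nm (SD {s.sd:.2f})"
    )
    if label == "CTL":
        ctl = result.interblade_distances
    else:
        yoda = result.interblade_distances

cmp_ = compare_conditions(ctl, yoda)
print(
    f"\n{cmp_.test}: p = {cmp_.p_value:.2e}, mean shift = {-cmp_.effect_nm:.2f} nm"
)
print(
    "A positive shift means the flattened condition has larger blade-tip\n"
    "separations, i.e. the channel population moved toward the flat state."
)
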
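"""Compare the four accession groups with the MATS multivariate test.

The modified ANOVA-type statistic tolerates heteroscedastic and even
singular covariances; its p-value comes from a 10,000-iteration parametric
bootstrap, followed by pairwise post-hoc contrasts with Holm adjustment.
"""

from phenoprop import group_comparison as gc
from phenoprop.synthetic_data import generate_study_panel

panel = generate_study_panel(seed=13, n_parent=60, n_hybrid=60,
                             components=("yield",))
table = panel.frames["yield"]
groups = {
    cls: table[table.class_label == cls].drop(columns=["unit_id", "class_label"]).to_numpy()
    for cls in sorted(table.class_label.unique())
}

res = gc.param_bootstrap_p(list(groups.values()), iterations=10_000, seed=1)
print(f"global MATS = {res.statistic:.1f}, bootstrap p = {res.p_boot:.4f}")

posthoc = gc.posthoc_pairwise(groups, iterations=10_000, seed=2)
print("\npairwise contrasts:")
print(posthoc.round(4).to_string(index=False))
print(
    "\nA small global p rejects equality of the four accessions' mean\n"
    "descriptor vectors; the pairwise rows show which accessions differ,\n"
    "with Holm-adjusted p-values guarding the multiple comparisons."
)
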
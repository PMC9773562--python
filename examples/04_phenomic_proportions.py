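"""Estimate the hybrid's phenomic proportions and compare with the truth.

The proportions are the shares of held-out hybrid observations a 4-class
random forest assigns to each parental class, averaged over 25 replicated
70/30 splits. Because the panel is synthetic, the estimates can be read
against the mixture weights that generated the hybrid.
"""

from phenoprop import pipeline
from phenoprop.proportions import proportion_report
from phenoprop.synthetic_data import DEFAULT_WEIGHTS, generate_study_panel

panel = generate_study_panel(seed=5, n_parent=300, n_hybrid=300,
                             components=("seed_morph", "physiology"))
results = pipeline.analyze_panel(panel, seed=6, replicates=25,
                                 mats_iterations=1000, run_posthoc=False)

report = proportion_report({c: r.estimate for c, r in results.items()})
print(report.round(2).to_string(index=False))

truth = {**{k: 100 * v for k, v in DEFAULT_WEIGHTS.items() if k != "self"},
         "hybrid": 100 * DEFAULT_WEIGHTS["self"]}
print("\ntrue proportions (%):", truth)
print(
    "\nEach row is the percentage of held-out hybrid units predicted as that\n"
    "class; 'hybrid' is the hybrid-unique share. With well-separated classes\n"
    "the estimates recover the generating weights to within a few points."
)
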
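"""Classify the three parental accessions with a random forest.

Standardizes the parents' seed-morphometry descriptors to [0, 1], fits a
PCA to derive per-descriptor weights from PC contributions, then trains a
100-tree forest on a stratified 70% split and reports the OOB error, both
importance measures and the held-out confusion matrix.
"""

from phenoprop import parent_classification as pc
from phenoprop import preprocess as pp
from phenoprop.synthetic_data import generate_study_panel

panel = generate_study_panel(seed=11, n_parent=150, n_hybrid=150,
                             components=("seed_morph",))
table = panel.frames["seed_morph"]
parents = table[table.class_label != "hybrid"]

scaled = pp.minmax_standardize(parents)
pca = pc.fit_pca(scaled.values)
weights = pc.descriptor_weights(pca)
print("retained PCs (>= 80% cumulative variance):", pc.retained_pcs(pca))
print("descriptor weights:\n", weights.round(3).to_string())

report = pc.train_forest(
    pc.apply_weights(scaled.values, weights)[list(weights.index)],
    parents.class_label, n_trees=100, train_fraction=0.7, seed=1,
)
print(f"\nOOB error: {report.oob_error:.2f}%  (low = parents well separated)")
print("top descriptors by mean decrease in accuracy:")
print(report.importance_mda.sort_values(ascending=False).head(5).round(4).to_string())
print("\nheld-out confusion matrix (rows = truth):")
print(report.confusion.to_string())
print("\nselected descriptors:", pc.select_features(report, gini_min=0.0, mda_min=0.0)[:5])
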
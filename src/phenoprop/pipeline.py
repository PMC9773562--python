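"""End-to-end phenomic-proportions pipeline for one or more components.

Chains the analysis stages in the study order: outlier screening, PCA on
the parental units with PC-contribution descriptor weighting, 0-1
standardization of parents + hybrid, replicated random-forest proportion
estimation, and the MATS group comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import group_comparison, parent_classification, preprocess, proportions
from .synthetic_data import HYBRID_LABEL, PhenotypePanel

__all__ = ["ComponentResult", "analyze_component", "analyze_panel"]


@dataclass
class ComponentResult:
    """All per-component outputs of the pipeline."""

    component: str
    pca: parent_classification.PcaSummary
    weights: pd.Series
    parent_report: parent_classification.ForestReport
    estimate: proportions.ProportionEstimate
    mats: group_comparison.MatsResult
    posthoc: pd.DataFrame | None
    n_outliers: int


def analyze_component(
    table: pd.DataFrame,
    component: str = "component",
    replicates: int = 25,
    n_trees: int = 100,
    train_fraction: float = 0.7,
    mats_iterations: int = 10_000,
    run_posthoc: bool = True,
    seed: int | None = None,
) -> ComponentResult:
    """Run the full analysis for one component's wide table.

    ``table`` needs ``unit_id``/``class_label`` columns plus descriptors;
    classes are three parents and the hybrid. Returns per-stage results
    bundled in a ComponentResult.
    """
    ss = np.random.SeedSequence(seed)
    s_parent, s_prop, s_mats, s_post = (
        int(s) for s in ss.generate_state(4) % (2**31 - 1)
    )

    flags = preprocess.flag_outliers(preprocess.outlier_scores(table))
    kept = table.loc[~flags.to_numpy()]

    is_parent = kept["class_label"] != HYBRID_LABEL
    scaled = preprocess.minmax_standardize(kept)
    pca = parent_classification.fit_pca(scaled.values.loc[is_parent.to_numpy()])
    weights = parent_classification.descriptor_weights(pca)
    weighted = parent_classification.apply_weights(scaled.values, weights)
    feats = weighted[[c for c in weighted.columns if c in weights.index]]
    labels = kept["class_label"]

    parent_report = parent_classification.train_forest(
        feats.loc[is_parent.to_numpy()],
        labels[is_parent],
        n_trees=n_trees,
        train_fraction=train_fraction,
        seed=s_parent,
    )
    estimate = proportions.phenomic_proportions(
        feats,
        labels,
        n_trees=n_trees,
        train_fraction=train_fraction,
        replicates=replicates,
        seed=s_prop,
        component=component,
    )
    group_arrays = {
        cls: feats.loc[(labels == cls).to_numpy()].to_numpy()
        for cls in sorted(labels.unique())
    }
    mats = group_comparison.param_bootstrap_p(
        list(group_arrays.values()), iterations=mats_iterations, seed=s_mats
    )
    posthoc = (
        group_comparison.posthoc_pairwise(
            group_arrays, iterations=mats_iterations, seed=s_post
        )
        if run_posthoc
        else None
    )
    return ComponentResult(
        component=component,
        pca=pca,
        weights=weights,
        parent_report=parent_report,
        estimate=estimate,
        mats=mats,
        posthoc=posthoc,
        n_outliers=int(flags.sum()),
    )


def analyze_panel(panel: PhenotypePanel, seed: int | None = None, **kwargs):
    """Run :func:`analyze_component` for every component of a panel.

    Returns a dict component -> ComponentResult; per-component seeds are
    spawned from ``seed``.
    """
    seeds = np.random.SeedSequence(seed).generate_state(len(panel.frames)) % (
        2**31 - 1
    )
    return {
        comp: analyze_component(df, component=comp, seed=int(s), **kwargs)
        for s, (comp, df) in zip(seeds, panel.frames.items())
    }
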
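"""Phenomic proportions: the hybrid row of the 4-class confusion matrix.

For each characterization component a random forest is trained to separate
the three parents and the hybrid on PC-contribution-weighted, 0-1
standardized descriptors. The proportion of held-out hybrid units predicted
as each parental class is that parent's phenomic proportion — the share of
the hybrid's measurable phenotype still expressed from that parent; the
share predicted as "hybrid" is the hybrid's own (self) component.

Because a single 70/30 split of a small panel makes these percentages
high-variance, the estimator replicates the split/train/predict cycle
(default 25 replicates with per-replicate seeds) and reports the mean and
dispersion over replicates; ``replicates=1`` reproduces the single-split
protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parent_classification import train_forest

__all__ = ["ProportionEstimate", "phenomic_proportions", "proportion_report"]


@dataclass
class ProportionEstimate:
    """Per-component phenomic proportions of the hybrid.

    ``proportions`` maps each class (three parents + the hybrid itself) to
    the mean percentage of held-out hybrid units predicted as that class;
    it sums to 100. ``dispersion`` is the per-class standard deviation over
    replicates (0 for a single replicate).
    """

    component: str
    proportions: pd.Series  # class -> percent, sums to 100
    dispersion: pd.Series  # class -> sd over replicates
    n_hybrid_validated: int
    replicates: int

    def __post_init__(self) -> None:
        total = float(self.proportions.sum())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"proportions sum to {total}, not 100")
        if (self.proportions < -1e-12).any():
            raise ValueError("proportions must be nonnegative")


def phenomic_proportions(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    hybrid_label: str = "hybrid",
    n_trees: int = 100,
    train_fraction: float = 0.7,
    replicates: int = 25,
    seed: int | None = None,
    component: str = "component",
) -> ProportionEstimate:
    """Estimate the hybrid's phenomic proportions for one component.

    ``features`` are the (weighted, standardized) descriptor columns and
    ``labels`` the 4 accession classes including ``hybrid_label``. For each
    replicate a forest is trained on a stratified 70% partition and the
    held-out hybrid units are tabulated by predicted class; percentages are
    averaged over replicates.
    """
    y = np.asarray(labels).astype(str)
    classes = sorted(np.unique(y))
    if hybrid_label not in classes:
        raise ValueError(f"no {hybrid_label!r} units in the panel")
    if len(classes) != 4:
        raise ValueError(f"expected 4 classes (3 parents + hybrid), got {classes}")
    if replicates < 1:
        raise ValueError("need at least 1 replicate")

    child_seeds = np.random.SeedSequence(seed).generate_state(replicates) % (2**31 - 1)
    per_rep = np.zeros((replicates, len(classes)))
    n_valid = None
    for r, s in enumerate(child_seeds):
        report = train_forest(
            features,
            y,
            n_trees=n_trees,
            train_fraction=train_fraction,
            seed=int(s),
            compute_importance=False,
        )
        is_hybrid = y[report.valid_index] == hybrid_label
        n_h = int(is_hybrid.sum())
        if n_h == 0:
            raise ValueError("no hybrid units in the validation split")
        n_valid = n_h
        pred = pd.Categorical(report.valid_pred[is_hybrid], categories=classes)
        per_rep[r] = pd.Series(pred).value_counts(sort=False).to_numpy() / n_h * 100.0

    props = pd.Series(per_rep.mean(axis=0), index=classes)
    props = props * (100.0 / props.sum())  # guard float accumulation
    disp = pd.Series(per_rep.std(axis=0, ddof=0), index=classes)
    return ProportionEstimate(
        component=component,
        proportions=props,
        dispersion=disp,
        n_hybrid_validated=n_valid,
        replicates=replicates,
    )


def proportion_report(estimates: dict[str, ProportionEstimate]) -> pd.DataFrame:
    """Summary table: one row per (component, class) with the mean
    proportion, its dispersion over replicates and the replicate count."""
    if not estimates:
        raise ValueError("need at least one component estimate")
    rows = []
    for comp, est in estimates.items():
        for cls in est.proportions.index:
            rows.append(
                {
                    "component": comp,
                    "class": cls,
                    "proportion_pct": float(est.proportions[cls]),
                    "dispersion_pct": float(est.dispersion[cls]),
                    "replicates": est.replicates,
                    "n_hybrid_validated": est.n_hybrid_validated,
                }
            )
    return pd.DataFrame(rows)
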
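"""Synthetic phenotype panels and seed/pod images with known ground truth.

The generative model mirrors a hybrid-characterization study: three parental
accessions, each with its own multivariate-normal descriptor distribution,
and one interspecific hybrid whose observations are a finite mixture over
the parent distributions plus a hybrid-unique ("self") component. Under this
model the mixture weights ARE the phenomic proportions, which makes the
downstream confusion-matrix estimator testable against ground truth.

Four characterization components are emulated, with the descriptor sets of
the bean study design: seed morphometry (12 shape descriptors), pod
morphometry (12), physiology (14 MultispeQ-style fluorescence/leaf
descriptors) and yield (PSW, PW, VW, SN, PHI with PW = PSW + VW and
PHI = 100 PSW / PW by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "ClassModel",
    "HybridMixture",
    "PhenotypePanel",
    "COMPONENTS",
    "DESCRIPTORS",
    "PARENT_LABELS",
    "HYBRID_LABEL",
    "DEFAULT_WEIGHTS",
    "compute_phi",
    "generate_component_table",
    "generate_panel",
    "default_class_models",
    "generate_study_panel",
    "generate_seed_image",
    "generate_pod_image",
]


class ConfigurationError(ValueError):
    """Raised for invalid generator configurations (non-PSD covariance,
    object exceeding its canvas, weights not summing to one, ...)."""


PARENT_LABELS = ("acutifolius", "parvifolius", "vulgaris")
HYBRID_LABEL = "hybrid"

#: Default hybrid mixture weights: the hybrid mostly expresses its own
#: descriptor distribution, with minority contributions from two parents.
DEFAULT_WEIGHTS = {
    "acutifolius": 0.20,
    "parvifolius": 0.10,
    "vulgaris": 0.00,
    "self": 0.70,
}

_SHAPE_DESCRIPTORS = (
    "area",
    "perimeter",
    "width",
    "height",
    "major",
    "minor",
    "feret",
    "min_feret",
    "ar",
    "circularity",
    "roundness",
    "solidity",
)

DESCRIPTORS: dict[str, tuple[str, ...]] = {
    "seed_morph": _SHAPE_DESCRIPTORS,
    "pod_morph": _SHAPE_DESCRIPTORS,
    "physiology": (
        "Phi2",
        "PhiNPQ",
        "PhiNO",
        "Chl",
        "LEF",
        "LTD",
        "Fm_prime",
        "Fo_prime",
        "Fs_prime",
        "FvFm_prime",
        "qL",
        "qP",
        "RFd",
        "leaf_thickness",
    ),
    "yield": ("PSW", "PW", "VW", "SN", "PHI"),
}

COMPONENTS = tuple(DESCRIPTORS)


@dataclass(frozen=True)
class ClassModel:
    """Multivariate-normal descriptor model of one accession class."""

    label: str
    mean: np.ndarray
    cov: np.ndarray
    n: int = 0

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        if cov.shape != (mean.size, mean.size):
            raise ConfigurationError(
                f"{self.label}: cov shape {cov.shape} does not match "
                f"mean dimension {mean.size}"
            )
        if not np.allclose(cov, cov.T):
            raise ConfigurationError(f"{self.label}: covariance not symmetric")
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() < -1e-8 * max(eigvals.max(), 1.0):
            raise ConfigurationError(f"{self.label}: covariance not PSD")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)

    @property
    def dim(self) -> int:
        return self.mean.size


@dataclass(frozen=True)
class HybridMixture:
    """Finite-mixture model of the hybrid: parent components plus 'self'."""

    weights: dict[str, float]
    self_model: ClassModel
    n: int = 0

    def __post_init__(self) -> None:
        w = np.array(list(self.weights.values()), dtype=float)
        if (w < 0).any():
            raise ConfigurationError("mixture weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ConfigurationError(f"mixture weights sum to {w.sum()}, not 1")


@dataclass
class PhenotypePanel:
    """Wide descriptor tables, one per characterization component.

    ``frames`` maps component name -> DataFrame with columns
    ``unit_id``, ``class_label`` followed by the component's descriptors.
    ``truth`` records the latent mixture component of every hybrid unit
    (columns ``unit_id``, ``component``, ``latent``), enabling
    parameter-recovery tests.
    """

    frames: dict[str, pd.DataFrame]
    truth: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["unit_id", "component", "latent"]
        )
    )

    @property
    def components(self) -> tuple[str, ...]:
        return tuple(self.frames)

    def descriptors(self, component: str) -> list[str]:
        return [
            c
            for c in self.frames[component].columns
            if c not in ("unit_id", "class_label")
        ]

    def to_long(self) -> pd.DataFrame:
        """Tidy long view: unit_id, class_label, component, descriptor, value."""
        parts = []
        for comp, df in self.frames.items():
            melted = df.melt(
                id_vars=["unit_id", "class_label"],
                var_name="descriptor",
                value_name="value",
            )
            melted.insert(2, "component", comp)
            parts.append(melted)
        return pd.concat(parts, ignore_index=True)

    def write_csv(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for comp, df in self.frames.items():
            df.to_csv(outdir / f"panel_{comp}.csv", index=False)
        self.truth.to_csv(outdir / "truth_latent.csv", index=False)


def compute_phi(seed_dry_weight: float, pod_whole_weight: float) -> float:
    """Pod harvest index: seed dry weight as a percentage of whole-pod dry
    weight at harvest, PHI = 100 * PSW / PW."""
    if not pod_whole_weight > 0:
        raise ValueError("pod whole weight must be positive")
    if seed_dry_weight < 0 or seed_dry_weight > pod_whole_weight:
        raise ValueError("seed dry weight must lie in [0, pod whole weight]")
    return 100.0 * seed_dry_weight / pod_whole_weight


def _draw(model: ClassModel, n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.multivariate_normal(model.mean, model.cov, size=n, method="svd")


def generate_component_table(
    parents: list[ClassModel],
    hybrid: HybridMixture,
    descriptor_names,
    seed: int | np.random.Generator,
    component: str = "component",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one component's wide table for 3 parents + hybrid.

    Parent units are sampled from their own multivariate normals; each hybrid
    unit first draws a latent component (a parent label or ``"self"``) from
    the mixture weights and then samples from that component's distribution.

    Returns
    -------
    table, truth
        ``table`` has columns unit_id, class_label, descriptors...;
        ``truth`` has one row per hybrid unit with its latent component.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    descriptor_names = list(descriptor_names)
    dims = {p.label: p.dim for p in parents}
    dims[HYBRID_LABEL] = hybrid.self_model.dim
    if len(set(dims.values())) != 1 or parents[0].dim != len(descriptor_names):
        raise ConfigurationError(f"descriptor dimensions disagree: {dims}")
    models = {p.label: p for p in parents}
    models["self"] = hybrid.self_model

    rows, labels, unit_ids = [], [], []
    for p in parents:
        rows.append(_draw(p, p.n, rng))
        labels += [p.label] * p.n
        unit_ids += [f"{p.label}_{i:04d}" for i in range(p.n)]

    comp_names = list(hybrid.weights)
    probs = np.array([hybrid.weights[c] for c in comp_names])
    latent = rng.choice(comp_names, size=hybrid.n, p=probs)
    hyb = np.empty((hybrid.n, len(descriptor_names)))
    for c in comp_names:
        idx = np.flatnonzero(latent == c)
        if idx.size:
            hyb[idx] = _draw(models[c], idx.size, rng)
    rows.append(hyb)
    labels += [HYBRID_LABEL] * hybrid.n
    hybrid_ids = [f"{HYBRID_LABEL}_{i:04d}" for i in range(hybrid.n)]
    unit_ids += hybrid_ids

    table = pd.DataFrame(np.vstack(rows), columns=descriptor_names)
    table.insert(0, "class_label", labels)
    table.insert(0, "unit_id", unit_ids)
    truth = pd.DataFrame(
        {"unit_id": hybrid_ids, "component": component, "latent": latent}
    )
    return table, truth


def generate_panel(
    parents_by_component: dict[str, list[ClassModel]],
    hybrid_by_component: dict[str, HybridMixture],
    seed: int,
) -> PhenotypePanel:
    """Assemble a multi-component PhenotypePanel (one mixture draw per
    component, all driven by a single seed)."""
    rng = np.random.default_rng(seed)
    frames, truths = {}, []
    for comp, parents in parents_by_component.items():
        names = DESCRIPTORS.get(comp) or tuple(
            f"d{i}" for i in range(parents[0].dim)
        )
        table, truth = generate_component_table(
            parents, hybrid_by_component[comp], names, rng, component=comp
        )
        if comp == "yield":
            table = _enforce_yield_constraints(table)
        frames[comp] = table
        truths.append(truth)
    return PhenotypePanel(frames=frames, truth=pd.concat(truths, ignore_index=True))


def _enforce_yield_constraints(table: pd.DataFrame) -> pd.DataFrame:
    """Impose the accounting identities of the yield component: weights are
    positive, PW = PSW + VW, SN is a positive integer count and PHI is
    recomputed from PSW/PW."""
    table = table.copy()
    table["PSW"] = table["PSW"].clip(lower=0.01)
    table["VW"] = table["VW"].clip(lower=0.01)
    table["PW"] = table["PSW"] + table["VW"]
    table["SN"] = table["SN"].round().clip(lower=1)
    table["PHI"] = [
        compute_phi(psw, pw) for psw, pw in zip(table["PSW"], table["PW"])
    ]
    return table


# ---------------------------------------------------------------------------
# Default study conditions: three contrasting parents plus a hybrid whose
# "self" distribution is distinct from all parents. Mean separations between
# classes are 5-7 within-class standard deviations on the discriminating
# descriptors, emulating the contrast between a wild small-seeded accession,
# a domesticated tepary-like parent and a large-seeded commercial bean.
# ---------------------------------------------------------------------------

_BASE_MEANS = {
    "seed_morph": np.array(
        [0.55, 2.9, 1.05, 0.72, 1.08, 0.70, 1.10, 0.70, 1.55, 0.82, 0.62, 0.97]
    ),
    "pod_morph": np.array(
        [6.0, 16.0, 7.5, 1.6, 8.2, 1.15, 8.3, 1.15, 7.2, 0.30, 0.12, 0.88]
    ),
    "physiology": np.array(
        # Phi2 PhiNPQ PhiNO  Chl   LEF  LTD  Fm'   Fo'   Fs'  Fv'/Fm' qL  qP  RFd  thick
        [0.55, 0.28, 0.17, 32.0, 180.0, 1.5, 1400, 520, 700, 0.63, 0.55, 0.78, 1.8, 0.22]
    ),
    "yield": np.array([0.55, 0.90, 0.35, 5.0, 60.0]),  # PSW PW VW SN PHI
}

_CV = {  # within-class sd as a fraction of a typical scale per descriptor
    "seed_morph": 0.06,
    "pod_morph": 0.07,
    "physiology": 0.08,
    "yield": 0.09,
}

# Per-class offsets in units of the within-class sd, on two contrast axes:
# a size axis separating the parents and a shape/self axis separating the
# hybrid's own distribution from every parent.
_CLASS_SHIFTS = {
    "acutifolius": (0.0, 0.0),
    "parvifolius": (-6.0, 0.0),
    "vulgaris": (6.0, 0.0),
    "self": (2.5, 6.0),
}

_AXIS_MASKS = {
    # which descriptors load on the size axis / the self axis, per component
    "seed_morph": (np.array([1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0]),
                   np.array([0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1])),
    "pod_morph": (np.array([1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0]),
                  np.array([0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1])),
    "physiology": (np.array([1, 1, 0, 1, 1, 0, 1, 1, 1, 0, 0, 0, 0, 1]),
                   np.array([0, 0, 1, 0, 0, 1, 0, 0, 0, 1, 1, 1, 1, 0])),
    "yield": (np.array([1, 1, 1, 0, 0]), np.array([0, 0, 0, 1, 1])),
}


def default_class_models(
    component: str,
    n_parent: int = 250,
    n_hybrid: int = 250,
    weights: dict[str, float] | None = None,
    rho: float = 0.2,
) -> tuple[list[ClassModel], HybridMixture]:
    """Default parent/hybrid models for one characterization component.

    Classes are equicorrelated multivariate normals (correlation ``rho``)
    whose means differ along a size axis (separating the three parents) and
    a self axis (separating the hybrid-unique distribution), each by 5-7
    within-class standard deviations — strong but realistic contrasts for
    accessions spanning wild and domesticated material.
    """
    if component not in DESCRIPTORS:
        raise ConfigurationError(f"unknown component {component!r}")
    weights = dict(DEFAULT_WEIGHTS if weights is None else weights)
    base = _BASE_MEANS[component]
    sd = _CV[component] * np.abs(base)
    d = base.size
    corr = np.full((d, d), rho) + (1 - rho) * np.eye(d)
    cov = corr * np.outer(sd, sd)
    size_axis, self_axis = _AXIS_MASKS[component]

    def mean_for(cls: str) -> np.ndarray:
        a, b = _CLASS_SHIFTS[cls]
        return base + a * sd * size_axis + b * sd * self_axis

    parents = [
        ClassModel(lbl, mean_for(lbl), cov, n=n_parent) for lbl in PARENT_LABELS
    ]
    self_model = ClassModel("self", mean_for("self"), cov)
    return parents, HybridMixture(weights=weights, self_model=self_model, n=n_hybrid)


def generate_study_panel(
    seed: int,
    n_parent: int = 250,
    n_hybrid: int = 250,
    weights: dict[str, float] | None = None,
    components=COMPONENTS,
) -> PhenotypePanel:
    """Generate the default four-component study panel with ground truth."""
    parents_by, hybrid_by = {}, {}
    for comp in components:
        parents_by[comp], hybrid_by[comp] = default_class_models(
            comp, n_parent=n_parent, n_hybrid=n_hybrid, weights=weights
        )
    return generate_panel(parents_by, hybrid_by, seed)


# ---------------------------------------------------------------------------
# Image fixtures
# ---------------------------------------------------------------------------

_BACKGROUND = 215.0
_OBJECT = 40.0


def _render(mask: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    img = np.where(mask, _OBJECT, _BACKGROUND)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0, 255)


def generate_seed_image(
    axes_px: tuple[float, float],
    noise_sd: float = 4.0,
    seed: int = 0,
    angle_deg: float = 0.0,
    canvas_shape: tuple[int, int] | None = None,
) -> tuple[np.ndarray, dict]:
    """Render a dark elliptical 'seed' on a light noisy background.

    ``axes_px = (a, b)`` are the full major/minor axes in pixels (a >= b).
    Returns the image and a metadata dict with the analytic ground truth
    (area, axes, orientation).
    """
    a, b = float(axes_px[0]), float(axes_px[1])
    if not (a >= b > 0):
        raise ConfigurationError("need major >= minor > 0")
    pad = int(0.25 * a) + 5
    shape = canvas_shape or (int(a) + 2 * pad, int(a) + 2 * pad)
    if min(shape) < a + 2:
        raise ConfigurationError("object exceeds canvas")
    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    th = np.deg2rad(angle_deg)
    u = (cc - cx) * np.cos(th) + (rr - cy) * np.sin(th)
    v = -(cc - cx) * np.sin(th) + (rr - cy) * np.cos(th)
    mask = (u / (a / 2.0)) ** 2 + (v / (b / 2.0)) ** 2 <= 1.0
    meta = {
        "kind": "seed",
        "area_px": np.pi * a * b / 4.0,
        "major_px": a,
        "minor_px": b,
        "angle_deg": angle_deg,
    }
    return _render(mask, noise_sd, rng), meta


def generate_pod_image(
    length_px: float,
    width_px: float,
    curvature: float = 0.0,
    noise_sd: float = 4.0,
    seed: int = 0,
    canvas_shape: tuple[int, int] | None = None,
) -> tuple[np.ndarray, dict]:
    """Render a dark capsule-shaped 'pod' of given centerline length, width
    and curvature (1/px; 0 = straight) on a light noisy background.

    The pod is the set of pixels within width/2 of a circular-arc
    centerline, so higher curvature lowers solidity (curved pods have
    concave hulls).
    """
    if length_px <= 0 or width_px <= 0 or curvature < 0:
        raise ConfigurationError("length, width must be > 0 and curvature >= 0")
    if curvature * length_px >= np.pi:
        raise ConfigurationError("curvature too high: arc exceeds a half circle")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, max(int(2 * length_px), 32))
    if curvature == 0.0:
        xs = (t - 0.5) * length_px
        ys = np.zeros_like(xs)
    else:
        radius = 1.0 / curvature
        span = length_px / radius
        ang = (t - 0.5) * span
        xs = radius * np.sin(ang)
        ys = radius * (1.0 - np.cos(ang))  # sagitta bulge
    half = width_px / 2.0
    x_extent = xs.max() - xs.min() + width_px
    y_extent = ys.max() - ys.min() + width_px
    pad = 8
    shape = canvas_shape or (
        int(np.ceil(y_extent)) + 2 * pad,
        int(np.ceil(x_extent)) + 2 * pad,
    )
    if shape[0] < y_extent or shape[1] < x_extent:
        raise ConfigurationError("object exceeds canvas")
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    cx = (shape[1] - 1) / 2.0
    cy = pad + half + (ys.max() - ys.min())  # arc bulges upward (smaller row)
    px = xs - (xs.max() + xs.min()) / 2.0 + cx
    py = cy - (ys - ys.min())
    d2 = np.full(shape, np.inf)
    pts = np.stack([py, px], axis=1)
    for chunk in np.array_split(pts, max(1, len(pts) // 64)):
        dr = rr[..., None] - chunk[:, 0]
        dc = cc[..., None] - chunk[:, 1]
        d2 = np.minimum(d2, (dr**2 + dc**2).min(axis=-1))
    mask = d2 <= half**2
    meta = {
        "kind": "pod",
        "length_px": length_px,
        "width_px": width_px,
        "curvature": curvature,
    }
    return _render(mask, noise_sd, rng), meta
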
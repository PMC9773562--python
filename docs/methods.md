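# Methods

## Problem and model

An interspecific hybrid line descends from three parental accessions. Its
phenotype is characterized in four components — seed morphometry (12 shape
descriptors), pod morphometry (12), physiology (14 fluorescence/leaf
descriptors of the MultispeQ family: Phi2, PhiNPQ, PhiNO, Chl, LEF, LTD,
Fm′, Fo′, Fs′, Fv′/Fm′, qL, qP, RFd, leaf thickness) and yield (PSW, PW,
VW, SN and the pod harvest index PHI = 100·PSW/PW). The *phenomic
proportion* of parent *p* is defined operationally: the percentage of
held-out hybrid observations that a random-forest classifier, trained to
separate the three parents and the hybrid, predicts as class *p*. It
measures how much of the hybrid's measurable phenotype still lies inside
parent *p*'s descriptor distribution.

For validation the package carries its own generative model
(`synthetic_data`): each parent is a multivariate normal over its
component's descriptors; each hybrid observation first draws a latent
origin (a parent, or a hybrid-unique "self" component) from mixture
weights and then samples from that origin's distribution. Under this model
the mixture weights are the ground-truth phenomic proportions, so the
estimator can be judged by parameter recovery rather than by eyeballing.

## Morphometry conventions

* Intensities live in [0, 255]; RGB reduces to luminance
  0.299R + 0.587G + 0.114B. Coordinates are row-major, origin top-left,
  0-based.
* **Thresholds.** Kapur maximum entropy maximizes the summed Shannon
  entropies of the two histogram classes; Huang minimizes the Shannon
  entropy of fuzzy memberships u(g) = 1/(1+|g−μ_class|/C). Both scan all
  256 candidate levels, guarantee two non-empty classes and reject
  constant images. Max entropy is the default for seeds and Huang for
  pods; the assignment is overridable per run since either method suits
  either organ.
* **ROIs** are 8-connected components (the ImageJ particle-analysis
  default), area-filtered and ordered by centroid reading order.
* **Ellipse fit** uses the normalized second central moments of pixel
  centers; axes are 4√eigenvalue (so a disk of radius r gets major ≈ 2r).
  A 1-pixel-thin region has its minor axis clamped to the one-pixel
  equivalent 4√(1/12) and is flagged degenerate.
* **Feret diameters** use pixel-center coordinates throughout: the maximum
  Feret is the exact largest pairwise distance between convex-hull pixel
  centers, the minimum Feret the smallest hull projection width over a
  0.1° caliper sweep. A filled 200×50 px rectangle therefore measures
  Feret = √(199²+49²) ≈ 204.9 px and MinFeret = 49 px — one pixel short of
  the nominal 50 because centers, not pixel boundaries, are measured. The
  center convention is kept for both diameters because mixing conventions
  (centers for Feret, boundaries for MinFeret) breaks the invariant
  MinFeret ≤ Feret on near-circular regions.
* **Perimeter** is the 4-direction Crofton crack-count estimate, chosen so
  that a rasterized disk has circularity ≈ 1 (measured 0.997 at r = 100);
  the popular weighted 3-configuration crack estimator biases the disk to
  0.90, which distorts circularity-based comparisons.
* **Convex hull area** is the exact lattice-point count of the hull
  polygon via the shoelace formula and Pick's theorem, so convex regions
  have solidity exactly 1. Polygon-rasterization hull images overcount
  boundary pixels by several percent on small objects.

## Preprocessing

Outlier screening is a k-nearest-neighbour score (mean distance to the
k = min(10, n−1) nearest neighbours on per-descriptor z-scaled data) with
a Tukey upper fence (Q3 + 1.5·IQR) as the default flagging rule; flagged
units are excluded downstream but always reported. The score is a
deliberately simple, pluggable stand-in for fancier outlier bases: the
screening step is a filter, and the kNN score is affine-invariant by
construction. Min–max standardization maps each descriptor to [0, 1]; when
fitted on a subset (e.g. parents only), out-of-range values are clipped
and counted. By default the scaling is fitted on parents and hybrid
jointly.

## Classification and weighting

PCA runs on centered, unit-scaled descriptors. The contribution of
descriptor j to PC k is 100·loading²_{jk}/Σ_j loading²_{jk}. Descriptor
weights sum contributions over the retained PCs — the smallest leading set
reaching 80% cumulative explained variance, a declared rule since "the PCs
with the highest contribution" admits many readings — multiplied by each
PC's explained-variance ratio and renormalized to Σw = 1.

The forest deliberately mirrors R's randomForest rather than sklearn's
aggregate wrapper: 100 trees on bootstrap samples of a stratified 70%
partition, mtry = ⌊√p⌋, unlimited depth; OOB error from out-of-bag votes;
MDA as the per-tree OOB accuracy drop under single-descriptor permutation
(raw, unscaled); Gini decrease on the raw sample-count scale (sklearn
normalizes it away, which breaks absolute thresholds such as "Gini > 40");
vote ties resolve to the alphabetically lowest class. Both the OOB error
(on bagging) and a held-out 30% confusion matrix are reported — they are
different quantities and are never conflated. Feature selection keeps
descriptors passing both a Gini and an MDA threshold, ordered by MDA, with
a logged top-5-by-MDA fallback.

## Proportion estimation

Proportions are read from held-out (30%) hybrid predictions, not OOB
votes, matching the confusion-matrix framing of the estimate. A single
70/30 split of a small panel makes the percentages high-variance, so the
estimator replicates the whole split/train/predict cycle (default 25
replicates, seeds spawned from one parent seed) and reports mean and
per-class dispersion; `replicates=1` reproduces the single-split protocol.
When a parent's distribution coincides with the hybrid's own, the split
between those two classes is not identifiable — only their sum is — and
the tests assert exactly that.

## Group comparison (MATS / paramBS)

Q_N = N(Tȳ)ᵀ(T D̂_N Tᵀ)⁺(Tȳ), with ȳ the stacked group means, D̂_N the
diagonal of the stacked empirical covariances scaled by N/n_i, and T the
one-way all-groups-equal contrast (P_a ⊗ I_d) by default. Using only the
covariance diagonal makes Q_N invariant to per-descriptor rescaling, and
the Moore–Penrose inverse tolerates singular covariances. The bootstrap
draws every group from a mean-zero normal with its empirical covariance
(null construction), 10,000 iterations by default;
p = #{Q* ≥ Q_obs}/iterations. Singular covariances get an
eigenvalue-clipped factor silently (they are legitimately PSD); a warning
is reserved for numerically indefinite input. The post-hoc table runs the
two-group bootstrap for every pair and reports unadjusted and
Holm-adjusted p-values side by side, since the multiplicity treatment of
pairwise contrasts is a user decision; the two-group one-descriptor case
reduces exactly to the squared Welch t statistic, which anchors the
large-sample agreement test.

## Synthetic study conditions

Default parents are equicorrelated normals (ρ = 0.2) with coefficients of
variation 6–9% per component; class means differ along two axes (a size
axis separating the parents, a self axis separating the hybrid-unique
distribution) by 5–7 within-class standard deviations — the magnitude of
contrast expected between wild, semi-domesticated and commercial material,
and large enough that proportion recovery is limited by estimator
variance, not class overlap. Default mixture weights are 0.20 / 0.10 /
0.00 / 0.70 (two minority parents, one absent, dominant self share). Yield
tables enforce PW = PSW + VW and recompute PHI from the generated weights.
The generator emulates distributional structure only: no photosynthesis
mechanism, no genotype×environment interaction, no pixel-level seed-image
realism beyond noisy ellipses/capsules. Passing tests therefore
demonstrate correctness of the estimators under their stated model, not
field performance on real accessions.

## Problem sizes and numerics

The validation suite uses sizes chosen to keep estimator noise well inside
the asserted bands: 1,000 random blobs for the geometry oracles, 1,000
hybrid + 3×1,000 parent units with 25 replicated splits for proportion
recovery (±7-point band), 500 replications × 500 bootstrap iterations for
the MATS type-I calibration, and n = 200 per group for the Welch
agreement (±0.02). All randomness flows through explicit seeds
(`numpy.random.default_rng` / `SeedSequence.spawn`); fixed seeds give
bit-identical panels, images and forest reports. Degenerate inputs fail
loudly: constant images, constant descriptors, classes with fewer than two
units and empty hybrid validation splits raise errors rather than
propagate NaNs.

## Known limitations

* Phenomic proportions are classifier shares, not genetic ancestry
  fractions; they depend on descriptor choice, weighting and class
  separability.
* Touching objects are not watershed-split; each ROI must be a single
  particle.
* The kNN outlier score replaces dedicated outlier-basis methods; with
  strongly clustered contamination it can mask groups of outliers.
* The MATS bootstrap assumes finite fourth moments for its calibration to
  hold at small n; heavy-tailed descriptors may need larger groups.
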
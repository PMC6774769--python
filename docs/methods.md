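# Methods

This note records the models implemented in `skinmesh`, the defaults and
numerical choices that matter, what the synthetic generators do and do not
emulate, and the known limitations.

## Chrominance representations

All models operate on two-channel chrominance observations (d = 2), on the
premise that skin pixels cluster far more tightly once intensity is removed.
Four planes are supported; 8-bit RGB is divided by 255 before any
conversion, so all channels are unit-range.

- **nRGB** — (r, g) = (R, G)/(R+G+B). Pixels with zero channel sum map to
  the neutral point (1/3, 1/3): they carry no chromatic information and
  should not perturb a fitted model, and the fallback avoids a division
  error on genuinely black pixels.
- **HSV** — hexcone (H, S), both scaled to [0, 1] (H = degrees/360 so all
  channels are on comparable scales for covariance fitting). Achromatic
  pixels take H = 0 by the standard convention; S = 0 already flags them.
  Delegated to `skimage.color.rgb2hsv`.
- **XYZ** — tristimulus from a fixed linear 3×3 matrix applied directly to
  the normalised RGB values (its rows sum to ≈ 1, confirming unit-range
  input; no gamma linearisation is assumed or applied). The two model
  channels are the chromaticities x = X/(X+Y+Z), y = Y/(X+Y+Z) —
  intensity-removed, consistent with the other planes — with the same
  neutral-point fallback at zero sum. Raw (X, Y, Z) stays available via
  `rgb_to_xyz_raw`.
- **L\*a\*b\*** — the nonlinear transform of XYZ relative to a white point,
  with compression function f(r) = r^(1/3) for r > 0.008856 and
  7.7867·r + 16/116 below (the two branches agree at the knee to < 1e-4;
  f is continuous and strictly increasing on [0, 1]). The model channels
  are (a\*, b\*). The white point defaults to D65
  (0.95047, 1.0, 1.08883) — the standard daylight reference — and is
  configurable.

## Skin-colour models

**Single Gaussian (SGM).** Maximum-likelihood mean and biased (1/T)
covariance, in closed form. A covariance whose smallest eigenvalue falls
below 1e-10 (constant or collinear training data) receives an additive
ridge of 1e-6·trace(Σ)/d with a logged warning.

**Gaussian mixture (GMM).** Full-covariance mixture fitted by EM.

- *Initialisation.* A 64×64 histogram over the observed chrominance range
  is smoothed with a Gaussian kernel (σ = bins/16) and component means are
  seeded at the strongest local maxima at least 2 bins apart, falling back
  to the strongest occupied bins when the histogram has fewer maxima than
  components. Light smoothing alone leaves spurious in-cluster maxima that
  can seed two components inside one cluster and strand EM on a symmetric
  saddle; σ = bins/16 collapses them while keeping genuinely separated
  modes distinct. Priors start equal; every component covariance is the
  global scatter divided by J. The initialisation is deterministic.
- *E-step.* Posteriors are computed in the log domain with log-sum-exp, so
  pixels far from every component underflow to a well-defined posterior
  instead of dividing by zero.
- *M-step and degeneracy.* Component covariances are the **constrained**
  maximisers with eigenvalues clipped at a fixed per-fit floor
  1e-6·trace(global scatter)/d. Clipping is exactly the Q-maximiser over
  {Σ : λ_min ≥ floor}, so the generalized-EM ascent property survives;
  a conditional after-the-fact ridge does not (a collapsing component's
  density spike is first admitted and then ridged away, producing
  likelihood drops of several nats). The floor also makes the classical
  EM covariance-collapse singularity impossible. A component whose total
  responsibility falls below 1e-6·T is re-seeded at the observation with
  the lowest current likelihood (logged); this rescue is the one step that
  can, in principle, lower the likelihood, and it essentially never fires
  once covariances cannot collapse.
- *Convergence.* Relative log-likelihood change below 1e-6 or 100
  iterations, both configurable (a 5-iteration preset mirrors the common
  quick-look setting).
- *Component count.* J = 3 by default for both skin and background:
  chrominance histograms of skin are mildly multi-modal (a few lobes), and
  larger J only subdivides lobes. Configurable.

**Probability maps.** With only a skin model, the map is the skin density
divided by the model's peak density — estimated as the maximum density over
the training observations and the component means, frozen into the
serialised model — so maps land in [0, 1] and the fixed decision threshold
τ = 0.55 is meaningful. With a background model the map is the class
posterior p_skin/(p_skin + p_bg) under equal class priors. The posterior is
the right object whenever both classes can be modelled: a peak-normalised
single-class Gaussian at τ = 0.55 keeps only the pixels inside Mahalanobis
radius √(−2 ln 0.55), i.e. ~45% of the skin class in 2-D, whereas the
posterior thresholds on the class boundary. Both variants are exposed;
likelihood-only is the default when no background model is supplied.

**Training data.** Model fitting from masked images pools all pixels under
the mask, capped at 500,000 with seeded subsampling (the scale at which
these models are customarily trained).

## Growing neural gas

Standard GNG with constant-in-time learning parameters. Per signal: find
winner and runner-up (Euclidean metric, ties broken by lowest neuron
index for determinism); add the squared winner distance to the winner's
accumulated error; move winner by eps_b and its topological neighbours by
eps_n; create or age-reset the winner–runner-up edge while the winner's
other edges age; delete edges older than age_max and any neuron thereby
stranded without edges (checked per signal). Every λ-th *signal* a neuron
is inserted halfway between the highest-error neuron q and its
highest-error neighbour f, replacing edge q–f with q–r and f–r; q's and
f's errors decay by α and r inherits q's decayed error. (The insertion
trigger is deliberately tied to the signal count; a trigger on the *node*
count cannot schedule growth, since the node count only changes at
insertion.) If q has no neighbours, the globally second-highest-error
neuron stands in as f so learning cannot abort. After every signal all
errors decay by (1 − β).

Defaults are Fritzke's published values — λ = 100, eps_b = 0.1,
eps_n = 0.005, α = 0.5, β = 0.0005, age_max = 50 — with capacity 200 (2D)
or per-call (3D); all exposed in `GNGConfig`. Signals are uniform
with-replacement draws from the input set under a seeded generator;
learning is bit-reproducible for a fixed seed and stops at capacity or at
an explicit signal budget.

**2D masks.** The input distribution is uniform over foreground pixel
centres normalised to [0, 1]² as (col/(W−1), row/(H−1)). Distinct blobs
further apart than the typical edge length come out as distinct connected
components of the learned graph.

**3D clouds.** Neurons carry an RGB attribute updated as an exponential
running average (rate eps_b) of the colours of signals they win; a new
neuron starts at the mean of its two parents' colours. The exported mesh
has the neurons as vertices, the graph edges, and one triangle per
3-clique of the edge graph — no hole filling, so the mesh may be open
(partial views stay partial).

**Depth utilities.** Raw structured-light disparity kd is normalised as
d = (d_off − kd)/8; d_off is a device calibration offset with no universal
value, defaulting to 1090 and configurable. Depth images back-project
through an ideal pinhole (fx, fy, cx, cy); zero-depth pixels are dropped.

## Evaluation layer

TPR = TP/S and FPR = FP/NS over ground-truth skin (S) and non-skin (NS)
pixel totals; an empty class raises an error naming it rather than
returning a silent NaN. ROC curves sweep a probability map over K
thresholds (101 evenly spaced in [0, 1] by default, K unconstrained),
ordered by descending threshold so both coordinates are non-decreasing.
IoU = |∩|/|∪| and Dice = 2|∩|/(|A|+|B|) satisfy Dice = 2·IoU/(1+IoU)
whenever the union is non-empty; two empty masks score 1 (perfect
agreement, logged) so blank frames do not crash batch runs. The fixed
comparison threshold 0.55 is the evaluation default. AUC summarisation and
bootstrap intervals are deliberately out of scope.

## Synthetic fixtures

The generators provide exact ground truth by construction — analytic
shapes, analytic surfaces, retained mixture labels — and are all
seed-deterministic.

- **Chrominance mixtures** are specified directly in the model space and
  lifted to RGB by inverting the relevant transform with the intensity
  degree of freedom fixed (L\* = 62 for L\*a\*b\*), so tests control the
  exact distribution a model must recover.
- **Scenes** rasterise an elliptical "face" and a five-fingered "hand"
  (palm disc plus finger quadrilaterals — chosen for its elongated,
  branched topology, with no claim of biological realism) over a
  background drawn from a three-lobe background mixture (foliage green,
  sky blue, neutral grey), with a clutter knob adding solid elliptical
  distractors coloured from single background components, and i.i.d.
  Gaussian RGB noise (σ = 0.01 default). The default skin mixture
  (two lobes near a\* ≈ 15–22, b\* ≈ 19–27) and background are well
  separated in (a\*, b\*), emulating the simple-to-cluttered regime
  progression of real test scenes.
- **3D shapes** — sphere, axis-aligned ellipsoid, and a cylinder-union
  "hand" (palm cylinder plus finger stubs) — are sampled on the analytic
  surface, displaced along the outward normal by Gaussian noise, and
  contaminated by per-point Bernoulli outliers drawn uniformly from the
  surface bounding box scaled ×2. The returned surface object provides
  exact (sphere, cylinder union) or first-order implicit (ellipsoid)
  distances for adherence oracles.

What passing tests on these fixtures do **not** show: robustness to
illumination change, shadows, camera colour response, skin-tone diversity
beyond the assumed mixture, motion blur, or sensor noise statistics of
real depth cameras. The fixtures validate the algorithms, not the
ecological claim.

## Problem sizes

The test and reproduction runs use sizes at which every statistical claim
is already stable: mixture recovery at T = 5000 over 20 seeds, GNG
structure over 10⁵ signals at capacity 200, sphere reconstruction with
5000 points and 500 neurons, scenes of 160×200 pixels. All are parameters,
not limits.

## Known limitations

- **Far outliers attract capacity.** Error-driven insertion allocates
  neurons wherever accumulated squared error is high, and scattered far
  outliers generate exactly that. On a unit sphere with 5% uniform-box
  outliers, roughly half of a 500-neuron network settles in the outlier
  volume rather than on the surface, across wide ranges of λ, β, age_max
  and step sizes — consistent with quantisation theory (node density
  scales like p^(d/(d+2)), giving even small probability mass spread over
  a large volume a sizeable node share). The averaging argument for
  outlier tolerance holds for zero-mean *surface noise*, which GNG indeed
  smooths well, not for sparse distant clutter; utility-based pruning
  (GNG-U-style) would be the remedy and is not implemented here.
- The EM fit finds local optima; the histogram-mode initialisation makes
  multi-start unnecessary for separated mixtures but cannot rescue truly
  overlapping components.
- The ellipsoid distance oracle is first-order; it degrades at high
  eccentricity.
- No temporal adaptation, illumination correction, ICC handling, or GPU
  path; meshes are left open by design.
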
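# Methods

This note documents the models, numerical choices and calibration behind
`burndyn`, and the limits of what its synthetic experiments demonstrate.

## The layered forward model

Skin/wound tissue is modelled as six plane layers. Layer *j* carries a
hemoglobin volume index `vHb_j ∈ [0,1]` and an oxygen saturation
`xHbO₂_j ∈ [0,1]`; its absorption spectrum is

```
μ_a,j(λ) = (vHb_j / s_j) · [ x_j·ε_HbO₂(λ) + (1 − x_j)·ε_Hb(λ) ] + μ_base,j(λ)
```

with globally fixed scale factors `s_j` (defaults 1) and baseline
absorbers: melanin (volume fraction 0.02, layer 1 only), water (0.65) and
fat (0.10) in every layer. Remission is a two-pass modified Beer–Lambert
sum: light backscattered from layer *k* traverses layers 1..k twice,

```
R(λ) = Σ_k b_k · exp( −2 Σ_{j≤k} μ_a,j(λ) · w_j · d(λ) )
```

* widths `w = (0.10, 0.20, 0.30, 0.45, 0.70, 1.00)` mm-equivalent;
* backscatter fractions `b = (0.10, 0.12, 0.15, 0.18, 0.20, 0.17)` —
  weighted toward depth, consistent with the longer mean scattering paths
  of NIR light, and chosen to keep the deep layers identifiable in the
  inverse problem;
* `d(λ) = μ_s'(λ)/⟨μ_s'⟩`, a path-length factor from the reduced
  scattering curve.

The model is monotone in every absorber, analytically differentiable and
clamped to [0,1]. It is *not* a radiative-transfer solution; specular
reflection, polarization and photon-path statistics are out of scope. Its
purpose is a well-behaved, invertible forward operator that carries the
downstream analysis.

### Chromophore table

`data/chromophores_synthetic.csv` is a synthetic analytic approximation of
the literature spectra (450–1000 nm, 5 nm steps): HbO₂ alpha/beta bands at
542/577 nm, an Hb band at 556 nm with the 758 nm shoulder, Hb > HbO₂
through 620–750 nm, isosbestic crossings inside 500–600 nm (at 525, 540,
570 and 590 nm on this table), power-law melanin and reduced scattering,
and NIR water (970 nm) and fat (930 nm) bands. Units are 1/mm at unit
volume fraction. It is packaged so builds and tests are hermetic; it is
not measured data, and absolute absorption levels are only
order-of-magnitude realistic.

## Inverse solver

Per pixel, the 12 parameters are fit by bounded least squares
(`scipy.optimize.least_squares`, trust-region reflective, analytic
Jacobian) minimising

```
‖R_model(p) − R_obs‖² + λ_s² ( ‖D₂ vHb‖² + ‖D₂ x‖² )
```

where `D₂` takes second differences across layers. The smoothness penalty
addresses the intrinsic depth ambiguity: the spectrum constrains composed
rather than per-layer quantities, so unregularised fits scatter blood
arbitrarily between adjacent layers. A single penalty weight trades bias
in the composed volumes against bias in the composed saturations, so the
solver uses a two-stage continuation: a strong solve at `λ_s = 0.05` finds
the basin, a weak polish at `λ_s = 0.007` releases the smoothing bias.
Five restarts (one heuristic flat start plus four seed-derived uniform
draws) guard against local minima; the returned result is the restart with
the lowest RMS spectral misfit, ties broken by restart index. All settings
are exposed in `InverseConfig`.

Measured on 100 uniform-random ground-truth profiles at spectral noise SD
0.005, the median absolute errors of the composed parameters are ≈ 0.04
(v₁), 0.04–0.05 (v₂), 0.06–0.08 (x₁) and 0.07–0.13 (x₂), shrinking
monotonically as the noise goes to zero (`scripts/acceptance.py`
recomputes these). Saturations of nearly bloodless layers are intrinsically
ill-determined; by convention a layer with `vHb = 0` reports `xHbO₂ = 0`.

## Secondary parameters

Layer groups: upper = 1–2, middle = 3–4, deeper = 5–6 (equal weights 0.5
within a group). Composed volumes are weighted sums clamped to [0,1];
composed saturations are vHb-weighted means (a bloodless group has
saturation 0 — plain means would let empty layers vote). Derived indices:

```
flow₁ = v₁·x₁/(xₐ−x₁)    flow₂ = v₂·(x₂−x₁)/(xₐ−x₂)    xRate = v₃·(xₐ−x₁)
```

clamped to [0,1]; a non-positive numerator gives 0, a saturated
denominator (x ≥ xₐ with positive numerator) gives 1. The arterial
saturation defaults to `xₐ = 0.98` (physiologic resting value;
config-exposed). `flow₂` reads as oxygen delivered to depth relative to
the remaining arterio-venous reserve; it is the single most
class-discriminating index. The parameter spaces are PS₁ = (v₁, xRate)
and PS₂ = (v₂, flow₂), both unit squares.

## Segmentation

Greedy agglomerative merging starting from single masked pixels: always
merge the 4-adjacent pair whose merged region has the smallest spread (max
over channels of the within-region SD), stop when the smallest candidate
exceeds the homogeneity threshold τ; regions under `min_area` are absorbed
into the adjacent region with the nearest channel mean. Merge order is
fully deterministic (score, then pixel index), and the merge sequence at a
smaller τ is a prefix of the sequence at a larger τ, so the segment count
is non-increasing in τ. Starting from single pixels (rather than a
SLIC-style over-segmentation) guarantees exact boundary recovery on
noise-free fixtures and removes the only potential source of
non-determinism.

τ has no canonical value; the module default 0.05 suits noise-free
parameter maps. The end-to-end pipeline judges homogeneity on the
channels that are robust per pixel — v₁, v₂, v₃, xRate — because the
saturation/flow channels carry pole-amplified inversion noise (per-pixel
SD 0.1–0.27) that no single τ separates from class contrast; with
τ = 0.07 the pipeline recovers the generated partition (purity ≈ 0.97 on
development runs). Both the channel set and τ are config-exposed.

## Reference classification

Closure by day 14 (inclusive) → 2a; day 15–21 (inclusive) → 2b1; later
closure or surgical treatment → 2b2. The boundary-day readings
("by day 14", "between 14 and 21") are ambiguous at exactly 14/21; both
boundaries are config-exposed, with the inclusive reading as default.
Full thickness (class 3) cannot arise from healing times — deep wounds are
treated surgically and would read 2b2 — so class 3 enters only through the
explicit `clinical_grade3` annotation. The class assigned at day 3/4 is
propagated unchanged to the segment's day 0–3 observations (retrospective
labeling); conflicting labels for one segment are a hard error.

## Kernel class regions and overlap

Per class and day, points in a parameter space are smoothed with an
isotropic Gaussian KDE (bandwidth: 2-D Silverman rule per cloud, floored
at 0.02 so tiny clouds do not collapse; grid 200×200; density renormalised
on the unit square after boundary truncation). The *kernel class region*
is the smallest set of highest-density cells capturing 68 % of the mass
(ties broken in row-major order); its convex hull (CCW, starting at the
lowest-then-leftmost vertex) is the abstracted class area. None of these
constants is canonical; all are config-exposed. Overlap is directional —
`area(a ∩ b)/area(a)`, how much of a's area b covers — because class
coverage is an asymmetric notion (a small class can be fully covered by a
large one); a symmetric IoU variant is provided. The per-day
discrimination summary is the mean off-diagonal overlap of the 4×4 class
matrix.

## Classification

A segment-day point is classified by hull membership in PS₂ (deep
perfusion carries the class information); PS₁ membership narrows ties.
Inside several hulls, the most severe candidate wins — deliberately
conservative, since missing a deep burn costs more than over-grading — and
the bias direction is explicit and configurable. Outside all hulls the
nearest hull centroid decides at confidence 0. Confidence is
1 − Σ (overlaps of the chosen region with the others), divided by the
ambiguity count, floored at 0. Evaluation builds regions from training
wounds only (leave-one-wound-out) so a segment never classifies against
regions built from itself.

## Synthetic cohorts: what they emulate, and what they do not

The generator draws, per segment, a class and a coherent day-0..3 profile
series: class/day mean profiles (the `CLASS_DAY_MEANS` table of composed
targets mapped onto the six layers), a per-segment latent offset shared
across days (80 % of the spread) plus fresh per-day jitter (60 %),
truncated to [0,1]. Saturation offsets are scaled by 0.4 relative to
volume offsets. The encoded qualitative dynamics: compact lower-left
day-0 distributions with strong overlap; hyperemic up-right drift with
day-1 widening for 2a/2b1 (2b1 staying under 2a); limited drift, smallest
spread and an upper-layer-2 vHb congestion peak for 2b2; a stationary,
declining, slowly widening class 3. Day-3 class means order as
flow₂(2a) > flow₂(2b1) > flow₂(2b2) > flow₂(3).

Defaults mirror the modelled cohort shape: 59 wounds, mean 4.6 segments
per wound (shifted Poisson), balanced class mixture, days 0–3, 0.5 mm
pixel pitch, spectral noise SD 0.005. Healing records are drawn
consistently with each class (2a: closure day 8–14; 2b1: 15–21; 2b2:
surgery with probability 0.5 or closure 22–35; class 3: surgical +
grade-3 annotation), so the healing-time rule round-trips by construction.
All generative means/spreads are *synthetic calibration constants*, chosen
once so these qualitative signatures hold; they are not fitted to any
measured distribution. Wound geometries are recursive rectangle splits of
a square box — connected, disjoint, mask-covering, but not wound-shaped.

Consequently, passing tests establish that the *pipeline* reproduces the
qualitative class-dynamics structure it assumes, with correct mechanics at
every stage; they do not validate the model against real burn wounds, real
between-patient variance, body-site effects, dressing or infection
influences, or the true magnitude of day-0 ambiguity.

## Problem sizes and numerical choices

* Cube rendering is off for the default 59-wound cohort (the distribution
  analysis runs on composed parameters); the end-to-end pixel pipeline
  runs on small simulated wounds (default 6 wounds of 12×12 px, 111
  bands), chosen as the package's desk-scale configuration.
* The inverse solver is deterministic given (spectrum, seed); the pipeline
  derives one substream seed per stage from the master seed, so whole runs
  are byte-identical and the manifest hashes every data artifact (figures
  are excluded from hashing — raster output is not part of the data
  contract).
* Degenerate inputs: all-zero spectra are rejected; all-collinear point
  sets raise a degenerate-hull error; under-populated class/days (< 5
  points) are omitted from region building; empty masks and empty id
  intersections are hard errors.
* ENVI I/O supports BSQ/BIL/BIP at float32/float64 with strict
  header/payload size checking; the `.npz` dialect is the test-friendly
  archive. Writer/reader pairs round-trip bit-exact.

## Known limitations

* The forward model is phenomenological; recovered profiles are relative
  values under globally fixed scale factors, not absolute volume
  fractions, and layer thicknesses are not recoverable.
* Composed saturations of low-volume groups are weakly identified; x₂
  error is the round-trip's weakest number.
* The severity-first tie-break deliberately over-grades inside ambiguous
  regions; day-0 accuracy is dominated by this choice.
* Hull-based regions ignore density structure inside the hull; two
  interleaved but differently dense classes can show high overlap yet be
  separable by a density-ratio classifier.
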
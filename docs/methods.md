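# Methods

## Problem setting

Percutaneous abscess drainage leaves a fluid-filled cavity that can be
sterilized by methylene-blue (MB) mediated photodynamic therapy: the cavity
is filled with photosensitizer, flushed, filled with diluted Intralipid, and
illuminated at 665 nm through an optical fiber. The biological target is the
abscess *wall* — a thin, bacteria-laden, MB-stained layer — and the planning
quantity is the fluence rate φ (mW cm⁻²) reached there. `pdtplan` models the
full chain: cavity geometry → per-region optical properties → Monte Carlo
light transport → wall dose-volume histogram (DVH) → optimization of
delivered power and Intralipid concentration.

Only fluence *rate* is simulated, not time-integrated fluence: a threshold
fluence rate is required to overcome repair of sublethal damage, and
fluence scales linearly with illumination time once the rate is fixed.

## Geometry

A binary cavity mask is labeled into four regions on an isotropic voxel
grid (pitch default 0.5 mm, configurable):

| region   | meaning                              | optics source            |
|----------|--------------------------------------|--------------------------|
| INTERIOR | cavity fluid (Intralipid suspension) | concentration model      |
| WALL     | 200 µm MB-stained shell              | post-MB spectroscopy     |
| TISSUE   | everything beyond the wall           | pre-MB spectroscopy      |
| BOUNDARY | outermost one-voxel shell            | photon-terminating       |

The wall is the Euclidean dilation of the cavity by
`ceil(200 µm / pitch)` voxels minus the cavity. At pitches above 0.2 mm
the wall is one whole voxel and hence geometrically thicker than 200 µm;
this is inherent to the cuboid-voxel representation and a warning records
it. Tests that depend on wall thinness run at 0.2 mm pitch.

A three-region variant merges WALL into TISSUE so that post-MB optics can
be assigned to both ("post-MB everywhere"); the 200 µm shell is retained
separately so DVH endpoints stay comparable across the two representations.

The BOUNDARY layer absorbs: any packet reaching it is terminated and its
weight booked as escaped. Coordinates are voxel-center based
(position = origin + (index + 0.5)·pitch); the fiber is placed at the
unweighted centroid of INTERIOR voxel centers, snapped to the nearest
interior voxel if the cavity is non-convex.

Cavity surface area uses the voxel-face estimator (count of interior faces
adjacent to non-interior voxels × pitch²). It is exact for axis-aligned
boxes and overestimates smooth surfaces by up to ~1.5×; it is used only as
a correlate in the statistics, where a monotone bias is unproblematic.

## Optical properties

* Intralipid: µs′ = 11.4 cm⁻¹ per 1% volume concentration at 665 nm,
  linear over the swept 0–1% range; anisotropy g = 0.7.
* Wall and tissue: g = 0.9; spectroscopy yields (µa, µs′), converted by the
  similarity relation µs = µs′/(1−g).
* Assumed (non-patient-specific) wall/tissue optics: µa = 0.2 cm⁻¹,
  µs = 100 cm⁻¹ — representative peritoneal-tissue values.
* Cavity interior absorption is not measurable in this setting and is set
  to µa = 0.004 cm⁻¹ (≈ water/dilute saline at 665 nm); config-exposed.
* A single refractive index n = 1.37 everywhere and no Fresnel
  reflection/refraction at internal interfaces: the 0%-Intralipid case is
  interpreted as an index-matching, non-scattering fluid. A mismatched
  boundary model is a possible future extension.

## Monte Carlo transport

Single-threaded voxel Monte Carlo with photon packets:

* Free path sampled in optical depth, τ = −ln ξ, consumed across voxels by
  exact 3D DDA stepping with µt re-read per voxel.
* Fluence scored with the track-length estimator
  φ_v = Σ w·ℓ_v / (N·V_v), chosen over absorption-weighted scoring so the
  non-absorbing interior scores fluence.
* Implicit capture: at each interaction the weight is multiplied by the
  albedo µs/µt; the absorbed fraction accumulates in an energy ledger.
* Henyey–Greenstein deflection with the local voxel's g.
* Russian roulette below weight 10⁻⁴ with survival probability 0.1
  (standard variance/runtime tradeoff); roulette gains and losses are
  booked against the absorbed tally, so
  absorbed + escaped = launched weight to ~10⁻¹² relative per run — this
  is asserted, not assumed.
* RNG: xorshift64\*, one state per run, seeded from the user seed; the
  seed and packet count are recorded in the `FluenceMap`. Identical seeds
  give bit-identical maps.

Sources (all positioned at the cavity centroid):

* `flat_cleaved` — the clinical bare fiber. Emission uniform over the core
  disk, direction uniform in solid angle within the acceptance cone
  θmax = arcsin(NA/n). The fiber's parameters are not standardized in the
  clinical protocol; defaults of 400 µm core and NA 0.22 are typical for
  bare PDT delivery fibers and are config-exposed.
* `spherical_diffuser` — 2 mm bulb, position uniform on the bulb surface,
  cosine-weighted (Lambertian) emission about the outward normal.
* `isotropic_point` — validation source for the closed-form oracles
  (inverse-square in vacuum; φ = e^(−µa r)/(4πr²) in a pure absorber;
  diffusion-limit decay ∝ e^(−µeff r)/r with µeff = √(3µa(µa+µs′))).

Maps are normalized to 1 mW delivered; higher powers are exact linear
scalings capped at 10 000 mW. Default desk-scale packet count is 10⁶ on a
single CPU; the planning sweeps in the test suite use 10⁴–10⁵ packets,
which resolves the lower 5% tail of wall DVHs with hundreds to thousands
of wall voxels.

## DVH endpoints and treatment planning

The wall DVH collects per-mW fluence values over the 200 µm shell.
Coverage uses the inclusive convention (φ·P ≥ T counts as covered); this
matters only in knife-edge cases. The threshold power for target T and
required coverage 95% is P = T/q, where q is the lower-tail order
statistic with f = N − ceil(0.95·N) failures allowed (the (f+1)-th
smallest value). An order statistic rather than an interpolated quantile
keeps the guarantee exact on voxel counts, and this index makes P the true
minimum — it is verified against a brute-force power scan in the tests. A
few-ulp upward guard protects the inclusive comparison against division
roundoff at the binding voxel.

A candidate concentration is feasible iff P ≤ 10 000 mW **and** the
fraction of wall at ≥400 mW cm⁻² at power P is below 5%. When the two
constraints cannot be met simultaneously the plan is reported infeasible
rather than relaxing coverage. The optimum is the feasible candidate with
minimal threshold power, ties broken toward lower concentration. The
default sweep is 0% plus 20 log-spaced points on [0.01%, 1%] with one
refinement pass at halved log-spacing around the incumbent — per-subject
optima typically sit well below 0.1%, so sub-0.1% resolution is needed.
Each concentration uses a seed deterministically derived from the master
seed, recorded in the manifest.

The three retrospective conditions are:

1. **Assumed treatment** — assumed wall/tissue optics, 1% Intralipid,
   clinically delivered power;
2. **Delivered treatment** — measured optics, 1%, clinical power;
3. **Treatment planning** — measured optics, concentration and power
   optimized.

The clinically delivered power itself follows a published rule only
loosely ("a desired fluence rate of 20 mW cm⁻² at the shortest axis");
the package adopts the lossless-sphere reading
P = 20 · 4π(d/2)² mW with d the shortest axis, capped at 10 000 mW, and
isolates it in one function (`clinical_power_rule`) so an alternative rule
can be swapped in.

## Synthetic phantoms and subjects

No patient CTs or spectroscopy values are distributed, so the cohort runs
on synthetic stand-ins:

* **Cavities**: spheres, ellipsoids, and lobulated shapes (radius
  perturbed by seeded low-order real spherical harmonics, degree 2–3,
  peak relative amplitude ≤ 0.5 so the surface stays star-shaped).
  Semi-axes default to 5–40 mm, covering the clinical 1–8 cm span.
* **Optics draws**: post-MB wall µa log-uniform on [0.2, 50] cm⁻¹ and
  pre-MB µa log-uniform on [0.02, 2] cm⁻¹ (measured values span more than
  two decades across subjects, so a log-uniform emulates that heavy
  spread); µs′ uniform on [1, 15] cm⁻¹. The representative measured case
  (pre: µa = 0.08, µs′ = 4.8; post: µa = 49.4, µs′ = 3.0 cm⁻¹) lies inside
  all default ranges.

What the phantoms do *not* emulate: the enhancing rim's CT appearance,
drainage-catheter geometry, anisotropic CT voxels, partial-volume wall
membership, and any correlation between cavity size and optical
properties. Passing tests therefore demonstrate the correctness of the
dosimetry and planning machinery and the direction of the optical effects,
not patient-level numerical endpoints, which depend on the unreleased
geometries.

## Numerical choices

* 6-connectivity for component analysis and face counting; Euclidean-ball
  structuring element for wall dilation.
* Packet-grid traversal keeps integer voxel indices authoritative and
  advances positions by exact boundary distances; accumulated float drift
  is bounded to sub-voxel scale and cannot desynchronize the index.
* Degenerate inputs fail loudly: empty or disconnected masks, masks
  touching the grid edge, sources outside the cavity, non-finite optics,
  inverted sampling ranges, concentration or power outside the allowed
  range.
* The Wilcoxon test drops zero differences and uses an exact null for
  small tie-free samples (normal approximation with tie correction
  otherwise); Fisher's two-sided p uses minimum-likelihood summation;
  Spearman p is an exact permutation for n ≤ 8 and the t-approximation
  beyond, which matches common statistical software at cohort scale
  (n = 13).

## Known limitations

* CPU-only, single-threaded transport; packet counts are chosen for a
  desk-scale machine, and MC noise at 10⁴–10⁵ packets is visible in the
  concentration curves (paired seeds keep comparisons consistent).
* The one-voxel wall at ≥0.5 mm pitch is thicker than the nominal 200 µm
  layer, which dilutes the wall-absorption contrast relative to a
  fine-grid simulation.
* No Fresnel physics; no multi-fiber placement optimization; no
  photochemical dose model (MB consumption, oxygen); no wavelength
  dependence beyond the single 665 nm operating point.
* The voxel-face surface-area estimator has a known upward bias for
  smooth surfaces.
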
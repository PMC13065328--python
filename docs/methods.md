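# Methods

This note documents the models, conventions, parameter defaults, and
numerical choices behind `phasefield`, and what the synthetic test bed does
and does not establish about real recordings.

## Phase representation and wavelet

Phase is a unit complex number `phi = exp(-i*theta)`, `theta in [-pi, pi)`.
Complex-valued phase avoids the error accumulation of spatial unwrapping
and lets the SVD act on circular data directly.

The analysis wavelet is a complex exponential under a Gaussian envelope,
truncated to a total support of `n_cycles` periods (default 2) of the
center frequency, with a partially weighted DC-balancing term:

    w(t) = (exp(2*pi*i*f*t) - beta * kappa) * exp(-t^2 / (2*sigma_t^2)),
    |t| <= n_cycles / (2 f)

where `kappa` is the weight that would make the untruncated kernel exactly
zero-mean. Two dimensionless shape parameters are calibrated **once** and
then fixed for every center frequency:

| parameter | value | meaning |
| --- | --- | --- |
| `sigma_t * f` | 0.26652486 | envelope width per center period |
| `beta` | 0.43299989 | weight on the DC-balancing term |

The calibration (reproducible via `calibrate_morlet_shape`) pins the
realized discrete kernel's half-power passband at 4.5 Hz / 1 kHz sampling
to 2.5–6.8 Hz. A plain symmetric Gaussian kernel cannot produce this
asymmetric band (it gives ≈2.35–6.65 Hz); the partial DC-balance term
supplies the required asymmetry while keeping the kernel near-admissible.
Because both parameters are dimensionless, the band scales proportionally
with `f` and is independent of the sampling rate (verified in tests).
Two-cycle truncation sits at ±3.75 envelope SDs, so truncation ripple is
negligible.

Center temporal frequencies default to 34 log-spaced values, 1.0–97.0 Hz.
Convolution uses reflect padding of one kernel length; samples within half
a kernel of an edge carry a validity mask and are dropped before the SVD by
default. Three variants: `phase_only` (unit modulus), `amplitude`
(`r*exp(-i*theta)`), and `normalized_amplitude` (modulus rescaled per
contact to [0, 1] over the recording via min-max). The kernel is normalized
to unit total absolute weight — irrelevant for phase, recorded for the
amplitude variants.

The per-sample instantaneous frequency of a pure sinusoid carries a small
ripple (±5% at two cycles) from the DC-balance term; the mean rate is exact
to <0.01%.

## Complex SVD and conventions

`Phi_st` is decomposed by economy complex SVD, truncated to `rank`
(default 14, configurable; the spectral conclusions are insensitive over
roughly 10–40 components, and a test verifies the slope sign is stable
between rank 10 and 40). Trials are concatenated along the sample axis
before decomposition. Each component is gauge-fixed by rotating the pair
(u, v) so the largest-magnitude entry of u is real-positive; the product
`u v*` is unchanged, serialization is reproducible, and every downstream
quantity is gauge-invariant anyway (bit-identical under global rotation of
an LSV — tested).

## Standing-wave (DC) removal

Average referencing injects artifactual global synchrony, which appears as
a zero-SF (DC) component of the spatial phase spectrum. Per LSV, the
traveling part is isolated by extending the complex vector over one full
temporal cycle (`n = round(fs/f)` unit phasors), decomposing the real part
by SVD, and recombining the first two components:
`phi_p = exp(-i * angle(u1 + i*u2))`.

Conventions chosen here:

- The quadrature pair is defined up to sign, giving two propagation
  orientations; the orientation maximizing
  `|sum_s phi_p(s) * conj(unit(input_s))|` is returned (preserves the
  input's dominant phase relationship).
- A degenerate input with no rotating part (second singular value below
  1e-8 of the first; e.g. exactly constant phase) has no traveling
  component; it is flagged and **dropped** from spectra, which empties the
  DC bin.
- Removal is applied to every retained LSV (switchable); the cleaned
  phases are combined with the original LSV magnitudes `a_s` in the
  triangle weights.

For mixed standing+traveling inputs the procedure recovers the traveling
part at least as well as simple renormalization, and strictly better as
the standing fraction grows (tested); it is not an exact separation.

## Surface geometry

Contacts are projected to the nearest point of their hemisphere's mesh by
brute force over faces (deterministic lowest-face-index tie-break);
contacts farther than 2 cm are excluded with a warning.

Geodesic distances are shortest paths on a Steiner-refined graph of the
polyhedral surface: 8 evenly spaced extra nodes per mesh edge, all pairs of
boundary nodes joined within each face, Dijkstra via
`scipy.sparse.csgraph`. Off-vertex endpoints are wired to all boundary
nodes of their face, and same-face pairs may take the straight within-face
segment. Against the closed-form great circle on a subdivision-4 icosphere
the worst error is ≈0.3% (0.5% for off-vertex endpoints) — well inside the
1% accuracy contract adopted for any geodesic backend. The graph is cached
per hemisphere. Distances are only defined within a hemisphere;
cross-hemisphere entries are infinite, and disconnected components are
logged.

Triangles: all within-hemisphere contact triplets whose flattened triangle
(law of cosines on geodesic edge lengths) has its most acute angle above
π/4. Curvature-induced angle defect is ignored (triangles of a few cm on
~10 cm-scale curvature). Triplets violating the triangle inequality
(possible with approximate distances) are rejected and counted. The planar
embedding puts A at the origin, B on the +x axis, C above it; re-measuring
the embedded edges recovers the inputs to 1e-10 (tested). Scale
`xi_T = 1/sqrt(area)` is binned into 32 equal-width bins spanning sizes
32 cm down to 1 cm plus an extra bin for sub-centimeter triangles;
`N_T = 1/count(bin)` equalizes the scale distribution. Implants yielding
fewer than ~1500 triangles (≈50 gray contacts) are flagged as noisy but
processed. Oversize (>32 cm) triangles get zero weight and are counted.

## Spectrum assembly

Per LSV r and triangle T: circular phase differences
`d = angle(exp(i*(w2-w1)))` feed the exact three-point plane fit; the
gradient norm over 2π is `xi_rT`; the weight is
`W_rT = s_r * <a>_T * N_T`. Weights accumulate into K = 32 equal-width SF
bins, half-open with the last bin closed; bin width is the real-valued
`(max - min)/K`. The default window is [1/(2 × max triangle size), 50]
cycles/m for plotting and [1/max size, 50] for regressions — estimates
below the reciprocal of the largest measured scale are not interpretable.
Out-of-window weight is excluded and its mass recorded, never clamped.

Pairwise phase differences of magnitude ≥ π alias, exactly as in any
finite-difference scheme: a triangle with sides above half the local
wavelength contributes at whatever SF its wrapped differences imply. No
silent filtering is done. Consequences, both verified on synthetic fields:
small triangles are sensitive to high SFs and large triangles to low SFs
(the triangle-size effect), and the usable SF window of an array runs from
the reciprocal of its largest triangle scale up to roughly the reciprocal
of twice its smallest inter-contact spacing. Validation fixtures therefore
plant their spectra inside the host array's usable window.

Total spectrum power equals the total admitted weight (conservation,
tested at 1e-10). `peak_sf` is the maximum-power bin center (ties to the
lowest SF); `peak_sf_interpolated` refines it by the power-weighted
centroid of the contiguous half-max region around the peak, removing
bin-width quantization (used by the surrogate sweep, where exact rank-order
recovery across a fine SF grid is asserted).

## Surrogate testing

The spherical gradient basis maps each hemisphere to its best-fit sphere by
radial projection (the mesh is a smooth spheroid; the projection's area
distortion is bounded by the shell's relative radius spread) and assigns
`omega = 2*pi*sf*s` with `s` the great-circle arc length from the axis
pole. The rank-1 surrogate time series uses the time-reversed, conjugated,
entry-wise unit-normalized dominant empirical right singular vector, so the
surrogate is itself a time series in phase.

Injection follows `Phi_sur = exp(-i*angle(Phi + w*Phi_xi))` with both
fields unit-modulus, i.e. `w` is the mixing odds against a unit-weight
signal. The sweep's `w_sur` parameter is the surrogate **fraction** of the
mix (7/8 surrogate to 1/8 signal, etc.) and is converted to odds
`w/(1-w)` before injection; with fractions, the sweep's significance
boundary sits where expected — exact rank-order recovery at 7/8,
significant regression at 1/2, no guarantee at 1/3 (all tested).

Further constructions: reversal of the first n singular values (turns a
1/k spatial spectrum into a k spectrum; flips the wavelength–power slope
sign when the planted cascade lies inside the array's usable window),
seeded contact sparsification to ceil(fraction × n) survivors (≥3 per
hemisphere enforced), and average-reference loading (subtracting a
multiple, up to 8, of the across-contact mean).

## Statistics

Regressions are OLS of log power on log wavelength over non-empty bins at
or above the window floor; zero-power bins are dropped and counted; an
exactly flat spectrum returns slope 0 with no test. Significance is a
two-tailed permutation test on the unsigned mean correlation between the
data and the model values, shuffling the model values within each family
member, with add-one correction (`p = (k+1)/(n_perm+1)`, default 10,000
permutations, seeded and bit-reproducible). Type-I error is calibrated
(0.05 ± 0.02 over 500 null simulations, tested). Peak statistics regress
log peak power and log wavelength-at-peak on log TF; an exactly constant
peak series reports a flat, non-significant trend.

## Synthetic data

The generators emulate the structural features the estimator cares about:

- **Mesh**: two closed icosphere-based shells (Euler characteristic 2
  each), radius 7 cm, with a smooth low-order radial distortion (default
  relative amplitude 0.05) standing in for cortical folding at the
  coarsest scale.
- **Electrodes**: straight runs of 12 contacts at exactly 5 mm spacing,
  entering at grazing angles (inward tilt 0.25–0.45) so several contacts
  per run stay superficial. A configurable fraction of electrodes clusters
  within an angular cap around a per-hemisphere target (clinical implants
  concentrate on a suspected focus), the rest spread — giving the
  millimeter-to-array-span distance mix the multi-scale differencing
  needs. Gray/white labels use a distance-to-surface band of 6 mm: thicker
  than anatomical cortex because a smooth spheroid has no folds for a
  trajectory to re-enter; the value is chosen so typical implants yield
  gray-contact counts in the tens, the regime the pipeline targets.
- **Recordings**: sums of plane waves in surface arc-length coordinates
  (geodesic distance from the direction-defining pole — waves travel along
  the sheet, not through space), each with its own TF, SF, direction,
  amplitude, and initial phase, plus white Gaussian noise; white-matter
  contacts carry the waves at 5% relative amplitude (quiet reference
  tissue). Ground-truth sidecars record the exact per-contact spatial
  phases; every generator is bit-reproducible given its seed.

What the synthetic bed does **not** model: realistic folding (sulci/gyri),
volume conduction (sub-centimeter, below the 50 cycles/m ceiling of
interest), non-stationary wave dynamics, 1/f temporal spectra, or
epileptiform artifacts. Passing tests therefore establish estimator
correctness and robustness under known ground truth on realistic array
geometry — not clinical validity on patient data.

Validation fixture scales (chosen to exercise each property at desk scale):
single-wave recovery uses ~70 gray contacts and 3 s at 500 Hz; the
surrogate sweep a ~100-contact wide-coverage implant; the multi-scale
cascade a ~120-contact dense-cluster implant, 8 components at 4–11
cycles/m with 1/xi^1.5 amplitudes over 12 s. The cascade band sits inside
that array's usable SF window (3–12.5 cycles/m), which is also the window
used for its regressions.

## Preprocessing conventions

Per-(trial, sensor) SDs use the unbiased (n−1) denominator. The three
rejection stages run sequentially with recomputation. Stages 1–2 measure a
trial's (sensor's) deviation from the mean in units of the **mean SD
itself** — with a z-score denominator a single gross outlier among ten
trials could never reach 3 SDs and would mask itself; stage 3 uses a
conventional z-score across trial×sensor cells. Replaced cells take the
per-sensor mean across retained trials, computed after excluding all
over-threshold cells (the replacement axis is recorded in the report; with
unequal trial lengths the sensor's scalar mean is used). The white-matter
reference pools the lower floor(n/2) white contacts by signal SD (ties by
contact index) and subtracts their per-sample mean from every gray
contact.

## Known limitations

- Aliasing of large triangles is inherent to finite differencing; spectra
  are only interpretable inside the array's usable SF window, and a
  k-spectrum (high-SF-dominated) field can only be recognized where the
  array resolves it.
- The geodesic backend is an approximation (≤0.5% observed error); exact
  polyhedral algorithms would remove even that.
- The standing/traveling split is exact only for pure cases; mixtures are
  improved, not perfectly separated.
- The spherical inflation used for surrogate gradients is radial
  projection onto the best-fit sphere, adequate for spheroid meshes; real
  cortical inflation pipelines would be needed for patient meshes.
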
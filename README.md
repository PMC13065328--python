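# phasefield

Spatial-frequency spectra of oscillatory phase on sparse, irregular
intracranial arrays.

## The problem

Cortical oscillations organize into traveling waves: smooth spatial
gradients of phase that advance over time, with wavelengths from
millimeters up to the size of a hemisphere. Estimating how phase power is
distributed over spatial frequency (SF, cycles per meter along the cortical
sheet) is straightforward on regular sensor grids, where Fourier analysis
applies, but stereotactic EEG (sEEG) samples the cortex with a few dozen
contacts scattered along depth-electrode runs — far too sparse and
irregular for gridded or non-uniform FFT methods.

`phasefield` implements an estimator built for exactly this regime,
together with the surrogate-testing machinery needed to trust it. It is
aimed at electrophysiologists analyzing sEEG/ECoG/MEG phase dynamics and at
methodologists who want a ground-truth test bed for wave estimators on
irregular arrays.

## The method

1. **Phase extraction.** Band-limited phase `Phi_st = exp(-i*theta_st)`
   (contacts × samples) is computed per center temporal frequency with
   short two-cycle Morlet wavelets (34 log-spaced center frequencies,
   1–97 Hz). The kernel shape is calibrated once so the realized 4.5 Hz
   filter has a 2.5–6.8 Hz half-power passband.
2. **Complex SVD.** `Phi = U S V*`; the leading left singular vectors
   (LSVs) `zeta_s = a_s * exp(i*omega_s)` act as empirical Fourier-like
   spatial components, with singular values `s_r` as their weights. A
   per-LSV standing-wave split removes globally synchronous (zero-SF)
   structure — the DC component that average referencing inflates.
3. **Geodesic triangles.** Contacts are projected to the cortical mesh;
   pairwise geodesic distances (within hemisphere) define approximately
   equilateral contact triangles (most acute angle > π/4) at all available
   scales, each flattened to the plane and assigned scale
   `xi_T = 1/sqrt(area)`. Binning `xi_T` into 32 scale bins with weights
   `N_T = 1/count(bin)` makes the scale distribution effectively uniform.
4. **Local SF and spectrum.** Per LSV and triangle, the exact three-point
   phase-gradient fit (with circular differences) gives
   `xi = |grad omega| / 2pi` cycles/m, weighted by
   `W_rT = s_r * <a>_T * N_T` and accumulated into 32 SF bins.
5. **Statistics.** Log-log regressions of power on wavelength (1/SF), with
   two-tailed permutation tests (10,000 shuffles of the model values) and
   per-TF peak statistics.
6. **Surrogates.** Ground-truth phase gradients (2–16 cycles/m) projected
   on the inflated (best-fit sphere) hemispheres are injected into
   empirical phase at controlled weights; singular-weight reversal,
   contact sparsification, and average-reference loading provide further
   null and robustness constructions.

A first-class synthetic-data module generates distorted-spheroid cortices,
clinically plausible depth-electrode implants (5 mm contact spacing,
clustered + spread), and recordings of plane waves in surface arc-length
coordinates with exact ground-truth sidecars.

## Worked example

Recover a planted traveling wave (8 Hz, 9 cycles/m) on a synthetic
73-gray-contact implant:

```python
import numpy as np

from phasefield import (
    make_spheroid_mesh, make_depth_electrodes, make_wave_recording,
    white_matter_reference, morlet_phase, complex_svd,
    project_to_surface, geodesic_distances, enumerate_triangles, bin_triangles,
    build_spectrum, loglog_regression,
)

mesh = make_spheroid_mesh(radius=0.07, distortion=0.05, seed=11)
contacts = make_depth_electrodes(mesh, n_electrodes=12, contacts_per_electrode=12, seed=3)
rec, truth = make_wave_recording(
    mesh, contacts,
    components=[{"tf": 8.0, "sf": 9.0, "direction": "anterior-posterior", "amplitude": 1.0}],
    noise_sd=0.3, fs=500.0, duration=3.0, seed=7,
)

gray = white_matter_reference(rec)
gray_contacts = contacts[contacts.label == "gray"].reset_index(drop=True)
pts = project_to_surface(gray_contacts[["x", "y", "z"]].to_numpy(),
                         gray_contacts["hemisphere"].to_numpy(), mesh)
D = geodesic_distances(mesh, pts)
triangles = bin_triangles(enumerate_triangles(D, pts.hemisphere))

phase = morlet_phase(gray, rec.fs, 8.0)
svd = complex_svd(phase, rank=14)
spectrum = build_spectrum(svd, triangles, dc_removal=True)
print(f"peak SF: {spectrum.peak_sf_interpolated():.2f} cycles/m (planted: 9.0)")
fit = loglog_regression(spectrum, n_perm=10_000, seed=1)
print(f"log-log wavelength-power slope: {fit.slope:.2f} (r={fit.r:.2f}, p={fit.p:.4f})")
```

Output:

```
peak SF: 9.02 cycles/m (planted: 9.0)
log-log wavelength-power slope: 3.19 (r=0.90, p=0.0001)
```

The peak sits in the bin containing the planted 9 cycles/m, and the
spectrum falls off toward high SF (positive wavelength–power slope, here
dominated by the single planted component), significant under the
permutation test.

A command-line interface exposes each stage and the demos:

```bash
phasefield run --config config.yaml --out-dir out      # end-to-end pipeline
phasefield surrogate-sweep --out-dir sweep             # 2-16 cycles/m recovery
phasefield demo-randomwalk --out-dir demo              # Hankel quadrature pairs
phasefield demo-waveimage --out-dir demo               # SVD wavenumber spectrum
```

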
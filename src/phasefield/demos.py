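"""Self-contained demonstrations that SVD recovers Fourier-like bases.

Two worked examples, independent of any recording:

* ``random_walk_hankel_demo`` — a high-pass-filtered random walk is cut
  into Gaussian-windowed successive segments (a Hankel matrix); its left
  singular vectors come in quadrature pairs approximating one-cycle Morlet
  wavelets of increasing frequency, the first pair completing about one
  cycle across the window.

* ``wave_image_demo`` — a synthetic diagonal plane-wave image (peak SF 15
  cycles per 1000 pixels vertically, about one cycle per 512 pixels
  horizontally) is scanned down at 1 ms/pixel, phase is extracted at 15 Hz
  per column, and the SVD of the horizontal phase vectors yields components
  whose wavenumbers increment by one and whose singular values decrease —
  the singular values read directly as a spatial-frequency spectrum.

The wave image is generated, not a photograph: a dominant one-cycle
horizontal wave plus weaker higher-wavenumber texture at nearby temporal
frequencies, matching the stated spatial/temporal frequency content while
remaining reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decomposition import PhaseSVD, complex_svd
from .spectral_phase import PhaseMatrix, morlet_phase

__all__ = [
    "HankelDemoResult",
    "WaveImageDemoResult",
    "random_walk_hankel_demo",
    "wave_image_demo",
    "lsv_wavenumber",
    "count_cycles",
    "pair_quadrature",
]


@dataclass
class HankelDemoResult:
    lsv: np.ndarray  # (window, n_kept) left singular vectors
    singular_values: np.ndarray
    walk: np.ndarray
    filtered: np.ndarray
    window: int
    meta: dict = field(default_factory=dict)

    def pair(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """The i-th quadrature pair of LSVs (0-based)."""
        return self.lsv[:, 2 * i], self.lsv[:, 2 * i + 1]


def random_walk_hankel_demo(
    n_samples: int = 32768,
    window: int = 1024,
    seed: int = 0,
    n_keep: int = 10,
    gaussian_sigma: float | None = None,
) -> HankelDemoResult:
    """Gaussian-windowed Hankel SVD of a high-pass-filtered random walk.

    The walk is detrended by subtracting a moving average one window long
    (so every surviving component completes at least one cycle per window),
    successive length-``window`` segments are extracted at stride 1 and
    multiplied by a Gaussian window (sigma = window/6 by default), and the
    resulting Hankel matrix is decomposed.  The LSVs are obtained from the
    eigendecomposition of the (window x window) Gram matrix, equivalent to
    the SVD of the Hankel matrix but independent of its huge column count.
    """
    from scipy.ndimage import uniform_filter1d

    if n_samples < 2 * window:
        raise ValueError("need n_samples >= 2*window")
    rng = np.random.default_rng(seed)
    walk = np.cumsum(rng.standard_normal(n_samples))
    filtered = walk - uniform_filter1d(walk, size=window, mode="reflect")
    sigma = window / 6.0 if gaussian_sigma is None else gaussian_sigma
    i = np.arange(window)
    g = np.exp(-((i - (window - 1) / 2.0) ** 2) / (2.0 * sigma**2))
    n_cols = n_samples - window + 1
    idx = i[:, None] + np.arange(n_cols)[None, :]
    A = filtered[idx] * g[:, None]
    eigval, U = np.linalg.eigh(A @ A.T)
    order = np.argsort(eigval)[::-1]
    U = U[:, order]
    s = np.sqrt(np.maximum(eigval[order], 0.0))
    return HankelDemoResult(
        lsv=U[:, :n_keep],
        singular_values=s[:n_keep],
        walk=walk,
        filtered=filtered,
        window=window,
        meta={"sigma": sigma, "n_cols": n_cols, "seed": seed},
    )


def count_cycles(column: np.ndarray) -> float:
    """Cycles completed by a real oscillatory component (zero crossings / 2)."""
    u = np.asarray(column, dtype=float)
    return float(np.sum(np.abs(np.diff(np.sign(u))) > 0)) / 2.0


def pair_quadrature(
    res: HankelDemoResult, i: int, central_sigmas: float = 1.0
) -> tuple[float, float]:
    """Quadrature statistics of the i-th LSV pair: (zero-lag r, quarter-lag |r|).

    The Gaussian window is divided out over the central ``central_sigmas``
    region (where it is well conditioned) so the test probes the underlying
    cosine/sine pair; the second value is the larger |correlation| of the
    two quarter-period shifts, estimated from the pair's zero crossings.
    """
    u1_full, u2_full = res.pair(i)
    sigma = res.meta["sigma"]
    idx = np.arange(res.window)
    central = np.abs(idx - (res.window - 1) / 2.0) < central_sigmas * sigma
    g = np.exp(-((idx - (res.window - 1) / 2.0) ** 2) / (2.0 * sigma**2))
    u1 = u1_full[central] / g[central]
    u2 = u2_full[central] / g[central]
    r0 = float(np.corrcoef(u1, u2)[0, 1])
    cycles = (count_cycles(u1) + count_cycles(u2)) / 2.0
    period = len(u1) / max(cycles, 0.5)
    lag = max(int(round(period / 4.0)), 1)
    r_lag = max(
        abs(float(np.corrcoef(u1[:-lag], u2[lag:])[0, 1])),
        abs(float(np.corrcoef(u1[lag:], u2[:-lag])[0, 1])),
    )
    return r0, r_lag


def lsv_wavenumber(column: np.ndarray) -> int:
    """Integer winding number of a complex spatial component.

    Sums the wrapped angle increments along the array; the total winding
    over 2*pi is the number of cycles the component completes.
    """
    ang = np.angle(np.asarray(column, dtype=complex))
    d = np.angle(np.exp(1j * np.diff(ang)))
    return int(round(abs(d.sum()) / (2.0 * np.pi)))


@dataclass
class WaveImageDemoResult:
    image: np.ndarray
    phase: PhaseMatrix
    svd: PhaseSVD
    wavenumbers: np.ndarray
    variance_explained: np.ndarray
    meta: dict = field(default_factory=dict)


def wave_image_demo(
    width: int = 512,
    height: int = 1000,
    v_sf: float = 15.0,
    scans: int = 3,
    seed: int = 0,
    n_components: int = 6,
    rank: int = 8,
) -> WaveImageDemoResult:
    """Synthetic wave image -> phase at 15 Hz -> SVD of the spatial vectors.

    The image carries ``v_sf`` cycles per 1000 pixels vertically and a
    dominant single cycle per ``width`` pixels horizontally, plus weaker
    texture at wavenumbers 2..``n_components`` (amplitude 1/k) detuned to
    nearby integer temporal frequencies so the components decorrelate over
    the scan.  The vertical axis is treated as time at 1 ms per pixel and
    scanned ``scans`` times.
    """
    fs = 1000.0
    rng = np.random.default_rng(seed)
    rows = np.arange(height) / fs  # seconds (1 ms per pixel)
    cols = np.arange(width) / width  # fraction of the array
    # integer temporal frequencies keep the image continuous across scans
    detunes = np.array([0, 2, -2, 3, -3, 4, -4, 5, -5])
    image = np.zeros((height, width))
    comps = []
    for k in range(1, n_components + 1):
        f_k = v_sf + float(detunes[(k - 1) % len(detunes)])
        amp = 1.0 / k
        phi0 = float(rng.uniform(0, 2 * np.pi)) if k > 1 else 0.0
        image += amp * np.cos(
            2 * np.pi * f_k * rows[:, None] + 2 * np.pi * k * cols[None, :] + phi0
        )
        comps.append({"wavenumber": k, "tf": f_k, "amplitude": amp})
    ts = np.tile(image, (scans, 1)).T  # (width columns, scans*height samples)
    phase = morlet_phase(ts, fs=fs, f=v_sf, variant="phase_only")
    svd = complex_svd(phase, rank=rank)
    wavenumbers = np.array([lsv_wavenumber(svd.lsv[:, r]) for r in range(rank)])
    var = svd.singular_values**2
    var = var / var.sum()
    return WaveImageDemoResult(
        image=image,
        phase=phase,
        svd=svd,
        wavenumbers=wavenumbers,
        variance_explained=var,
        meta={"components": comps, "fs": fs, "scans": scans, "seed": seed},
    )
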
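"""Band-limited phase extraction with short (two-cycle) Morlet wavelets.

Phase at a center temporal frequency (TF) is represented as a unit-length
complex number ``phi = exp(-i*theta)`` with ``theta`` in ``[-pi, pi)``.  A
recording of S contacts by T samples therefore yields, per TF, a complex
matrix ``Phi_st`` of unit-modulus entries (the ``phase_only`` variant).
Amplitude-carrying variants keep ``r*exp(-i*theta)`` either with the raw
wavelet modulus (``amplitude``) or with the modulus rescaled per contact to
span [0, 1] over the recording (``normalized_amplitude``).

The wavelet is a complex exponential under a Gaussian envelope, truncated to
a total support of ``n_cycles`` periods of the center frequency.  Because the
envelope is truncated and carries a partial DC-balancing term, the kernel
shape is pinned by a one-time calibration: the sigma/f ratio and the
DC-balance weight are chosen so that the realized 4.5 Hz kernel at 1 kHz
sampling has a half-power passband of 2.5-6.8 Hz.  The calibrated ratio is
then fixed for every center frequency, so the band scales proportionally
with f and is independent of the sampling rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MORLET_SIGMA_RATIO",
    "MORLET_DC_WEIGHT",
    "PhaseMatrix",
    "center_frequencies",
    "morlet_kernel",
    "morlet_phase",
    "half_power_bandwidth",
    "calibrate_morlet_shape",
]

#: Gaussian envelope width as a fraction of the center period (sigma_t * f).
#: Calibrated once via :func:`calibrate_morlet_shape`; see module docstring.
MORLET_SIGMA_RATIO = 0.26652486

#: Weight on the zero-mean (DC-balancing) correction term, between 0 (plain
#: Gabor kernel) and 1 (fully admissible zero-mean Morlet).  Calibrated
#: jointly with :data:`MORLET_SIGMA_RATIO`.
MORLET_DC_WEIGHT = 0.43299989

VARIANTS = ("phase_only", "amplitude", "normalized_amplitude")


@dataclass
class PhaseMatrix:
    """Complex phase estimates at one center TF.

    ``values`` has shape (contacts, samples).  ``valid`` flags samples more
    than half a kernel length away from either recording edge; edge samples
    are computed with reflect padding and may be dropped downstream.
    """

    values: np.ndarray
    center_freq: float
    fs: float
    variant: str = "phase_only"
    n_cycles: float = 2.0
    valid: np.ndarray | None = None
    zero_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=complex))
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.valid is None:
            self.valid = np.ones(self.values.shape[1], dtype=bool)

    @property
    def n_contacts(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def angles(self) -> np.ndarray:
        """theta_st per Eq-style convention: values = r * exp(-i*theta)."""
        return -np.angle(self.values)


def center_frequencies(fmin: float = 1.0, fmax: float = 97.0, n: int = 34) -> np.ndarray:
    """Logarithmically spaced center TFs (geometric progression), in Hz."""
    if fmin <= 0 or fmax <= 0:
        raise ValueError("frequencies must be positive")
    if not fmin < fmax:
        raise ValueError("fmin must be < fmax")
    if n < 2:
        raise ValueError("need at least two frequencies")
    return np.geomspace(fmin, fmax, n)


def morlet_kernel(
    f: float,
    fs: float,
    n_cycles: float = 2.0,
    sigma_ratio: float = MORLET_SIGMA_RATIO,
    dc_weight: float = MORLET_DC_WEIGHT,
) -> np.ndarray:
    """Complex Morlet kernel truncated to ``n_cycles`` periods of ``f``.

    The kernel is ``(exp(2i*pi*f*t) - dc_weight*kappa) * gauss(t)`` where
    ``kappa`` is the weight that would make the kernel exactly zero-mean in
    the untruncated limit.  Normalized to unit total absolute weight (this is
    irrelevant for phase, recorded for the amplitude variants).
    """
    if f <= 0 or fs <= 0:
        raise ValueError("f and fs must be positive")
    if f >= fs / 2:
        raise ValueError(f"center frequency {f} Hz is at or above Nyquist ({fs / 2} Hz)")
    half = n_cycles / (2.0 * f)
    n = int(np.floor(half * fs))
    if n < 1:
        raise ValueError("kernel support shorter than one sample; fs too low")
    t = np.arange(-n, n + 1) / fs
    sigma_t = sigma_ratio / f
    env = np.exp(-(t**2) / (2.0 * sigma_t**2))
    kappa = np.exp(-2.0 * np.pi**2 * f**2 * sigma_t**2)
    w = (np.exp(2j * np.pi * f * t) - dc_weight * kappa) * env
    return w / np.abs(w).sum()


def half_power_bandwidth(
    f: float,
    fs: float,
    n_cycles: float = 2.0,
    nfft: int = 2**18,
    sigma_ratio: float = MORLET_SIGMA_RATIO,
    dc_weight: float = MORLET_DC_WEIGHT,
) -> tuple[float, float]:
    """Half-power band of the realized discrete kernel, via its DFT.

    Returns the (lower, upper) frequencies in Hz where the power response
    crosses half of its maximum, with linear interpolation between DFT bins.
    """
    w = morlet_kernel(f, fs, n_cycles, sigma_ratio, dc_weight)
    H = np.fft.fft(w, nfft)
    freqs = np.fft.fftfreq(nfft, 1.0 / fs)
    pos = freqs >= 0
    P = np.abs(H[pos]) ** 2
    fr = freqs[pos]
    ipk = int(np.argmax(P))
    half = P[ipk] / 2.0
    lo = hi = None
    for i in range(ipk, 0, -1):
        if P[i - 1] < half <= P[i]:
            lo = float(np.interp(half, [P[i - 1], P[i]], [fr[i - 1], fr[i]]))
            break
    for i in range(ipk, len(P) - 1):
        if P[i + 1] < half <= P[i]:
            hi = float(np.interp(half, [P[i + 1], P[i]], [fr[i + 1], fr[i]]))
            break
    if lo is None or hi is None:
        raise ValueError("power response never drops to half maximum within (0, Nyquist)")
    return lo, hi


def calibrate_morlet_shape(
    target_band: tuple[float, float] = (2.5, 6.8),
    f: float = 4.5,
    fs: float = 1000.0,
    n_cycles: float = 2.0,
) -> tuple[float, float]:
    """Solve for (sigma_ratio, dc_weight) realizing ``target_band`` at ``f``.

    This is the one-time calibration that produced the frozen module
    constants; it is kept so the convention can be re-derived and audited.
    """
    from scipy.optimize import minimize

    lo_t, hi_t = target_band

    def cost(p: np.ndarray) -> float:
        sr, dw = p
        if sr <= 0.05 or not 0.0 <= dw <= 1.5:
            return 1e6
        try:
            lo, hi = half_power_bandwidth(f, fs, n_cycles, sigma_ratio=sr, dc_weight=dw)
        except ValueError:
            return 1e6
        return (lo - lo_t) ** 2 + (hi - hi_t) ** 2

    res = minimize(
        cost,
        x0=np.array([0.265, 0.4]),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-16},
    )
    return float(res.x[0]), float(res.x[1])


def morlet_phase(
    signal: np.ndarray,
    fs: float,
    f: float,
    n_cycles: float = 2.0,
    variant: str = "phase_only",
) -> PhaseMatrix:
    """Extract complex phase at center TF ``f`` from a (contacts, samples) signal.

    Convolution uses reflect padding of one kernel length; samples within
    half a kernel of either edge carry ``valid=False``.  All-zero stretches
    (zero wavelet modulus) are flagged in ``zero_mask`` and, for the
    phase-only variant, set to phase 0.
    """
    from scipy.signal import fftconvolve

    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    k = morlet_kernel(f, fs, n_cycles)
    L = len(k)
    if x.shape[1] < L:
        raise ValueError(f"signal length {x.shape[1]} shorter than wavelet support {L}")
    pad = L
    xp = np.concatenate([x[:, pad:0:-1], x, x[:, -2 : -pad - 2 : -1]], axis=1)
    # correlation with the kernel: c[t] = sum_tau x[t+tau] * conj(k[tau])
    c = fftconvolve(xp, np.conj(k[::-1])[None, :], mode="same", axes=1)
    c = c[:, pad : pad + x.shape[1]]

    r = np.abs(c)
    zero = r < 1e-300
    # Eq-1 convention: phase is exp(-i*theta) with theta the analytic angle.
    ph = np.conj(np.divide(c, r, out=np.ones_like(c), where=~zero))

    if variant == "phase_only":
        values = ph
    elif variant == "amplitude":
        values = r * ph
    else:  # normalized_amplitude
        rmin = r.min(axis=1, keepdims=True)
        rmax = r.max(axis=1, keepdims=True)
        span = np.where(rmax > rmin, rmax - rmin, 1.0)
        values = (r - rmin) / span * ph

    half = L // 2
    valid = np.ones(x.shape[1], dtype=bool)
    valid[:half] = False
    if half > 0:
        valid[-half:] = False
    if zero.any():
        warnings.warn("zero wavelet modulus encountered; phase set to 0 there")
    return PhaseMatrix(
        values=values,
        center_freq=f,
        fs=fs,
        variant=variant,
        n_cycles=n_cycles,
        valid=valid,
        zero_mask=zero if zero.any() else None,
    )


# ---------------------------------------------------------------------------
# serialization

def save_phase(path, phase: PhaseMatrix) -> None:
    """Write a PhaseMatrix to an HDF5 file (complex as paired real datasets)."""
    import h5py

    with h5py.File(path, "w") as h:
        h.create_dataset("real", data=phase.values.real)
        h.create_dataset("imag", data=phase.values.imag)
        h.create_dataset("valid", data=phase.valid.astype(np.uint8))
        h.attrs["center_freq"] = phase.center_freq
        h.attrs["fs"] = phase.fs
        h.attrs["variant"] = phase.variant
        h.attrs["n_cycles"] = phase.n_cycles


def load_phase(path) -> PhaseMatrix:
    import h5py

    with h5py.File(path, "r") as h:
        values = h["real"][...] + 1j * h["imag"][...]
        valid = h["valid"][...].astype(bool)
        return PhaseMatrix(
            values=values,
            center_freq=float(h.attrs["center_freq"]),
            fs=float(h.attrs["fs"]),
            variant=str(h.attrs["variant"]),
            n_cycles=float(h.attrs["n_cycles"]),
            valid=valid,
        )
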
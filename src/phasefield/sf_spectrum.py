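"""Spatial-frequency (SF) spectra from LSV phases on contact triangles.

For each retained LSV and each admitted triangle, the local phase gradient
is fitted exactly through the three vertices of the planar-embedded
triangle using circular (wrapped) phase differences; its norm over 2*pi is
the local SF estimate ``xi_rT`` in cycles/m.  Each estimate carries weight
``W_rT = sigma_r * <a>_T * N_T`` (singular value, mean LSV magnitude at the
three contacts, triangle-bin normalization), and the weights are
accumulated into K equal-width SF bins to form the spectrum ``P_k``.

Pairwise phase differences of magnitude >= pi cannot be detected unaliased;
such triangles contribute at whatever SF the wrapped differences imply,
exactly as in any finite-difference scheme.  No silent filtering is done.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json

import numpy as np
import pandas as pd

from .cortical_geometry import TriangleSet
from .decomposition import PhaseSVD, remove_standing_component

__all__ = [
    "SFSpectrum",
    "sf_to_wavelength",
    "wavelength_to_sf",
    "triangle_phase_gradient",
    "triangle_sf",
    "triangle_weight",
    "build_spectrum",
]


def sf_to_wavelength(sf):
    """Wavelength (m/cycle) from spatial frequency (cycles/m): lambda = 1/xi."""
    return 1.0 / np.asarray(sf, dtype=float)


def wavelength_to_sf(wavelength):
    return 1.0 / np.asarray(wavelength, dtype=float)


@dataclass
class SFSpectrum:
    """Binned SF power spectrum at one center TF.

    ``bin_edges`` has K+1 entries (cycles/m); bins are half-open
    [k*w, (k+1)*w) with the last bin closed.  ``power`` is in arbitrary
    units; the sum over bins equals the total admitted weight.
    """

    bin_edges: np.ndarray
    power: np.ndarray
    center_freq: float | None
    rank: int
    variant: str = "phase_only"
    sf_range: tuple[float, float] | None = None
    dc_removal: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def peak_sf(self) -> float:
        """Bin-center SF of the maximum-power bin (ties: lowest SF)."""
        return float(self.bin_centers[int(np.argmax(self.power))])

    def peak_sf_interpolated(self) -> float:
        """Sub-bin peak location: power-weighted centroid of the peak region.

        The region is the contiguous run of bins around the maximum whose
        power stays at or above half the maximum; the centroid removes the
        bin-width quantization of :attr:`peak_sf`.
        """
        k = int(np.argmax(self.power))
        half = self.power[k] / 2.0
        lo = k
        while lo > 0 and self.power[lo - 1] >= half:
            lo -= 1
        hi = k
        while hi < len(self.power) - 1 and self.power[hi + 1] >= half:
            hi += 1
        sl = slice(lo, hi + 1)
        return float(
            np.average(self.bin_centers[sl], weights=self.power[sl])
        )

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "power": self.power,
            }
        )

    def save(self, path) -> None:
        """Tab-separated table with a JSON header line."""
        header = {
            "center_freq": self.center_freq,
            "rank": self.rank,
            "variant": self.variant,
            "sf_range": list(self.sf_range) if self.sf_range else None,
            "dc_removal": self.dc_removal,
            **{k: v for k, v in self.meta.items() if isinstance(v, (int, float, str, bool))},
        }
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(header) + "\n")
            self.to_table().to_csv(fh, sep="\t", index=False)


def triangle_phase_gradient(planar: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Exact 3-point plane fit of the phase gradient (rad/m).

    ``planar``: (3, 2) or (n, 3, 2) vertex coordinates with A=(0,0) and B
    on the x-axis; ``omega``: matching (3,) or (n, 3) phase angles in rad.
    Differences are circular: ``d = angle(exp(i*(w2 - w1)))``, so a pair
    (3.0, -3.0) differs by 2*pi - 6, not -6.
    """
    p = np.asarray(planar, dtype=float)
    w = np.asarray(omega, dtype=float)
    single = p.ndim == 2
    if single:
        p = p[None]
        w = w[None]
    bx = p[:, 1, 0]
    cx = p[:, 2, 0]
    cy = p[:, 2, 1]
    if np.any(bx == 0) or np.any(cy == 0):
        raise ValueError("degenerate planar coordinates")
    d_ab = np.angle(np.exp(1j * (w[:, 1] - w[:, 0])))
    d_ac = np.angle(np.exp(1j * (w[:, 2] - w[:, 0])))
    gx = d_ab / bx
    gy = (d_ac - cx * gx) / cy
    grad = np.stack([gx, gy], axis=1)
    return grad[0] if single else grad


def triangle_sf(gradient: np.ndarray) -> np.ndarray:
    """SF in cycles/m: Euclidean norm of the gradient over 2*pi."""
    g = np.asarray(gradient, dtype=float)
    return np.linalg.norm(g, axis=-1) / (2.0 * np.pi)


def triangle_weight(singular_value, magnitudes, n_weight):
    """W_rT = sigma_r * <a>_T * N_T with <a>_T the mean vertex magnitude."""
    mags = np.asarray(magnitudes, dtype=float)
    return np.asarray(singular_value, dtype=float) * mags.mean(axis=-1) * np.asarray(
        n_weight, dtype=float
    )


def default_sf_range(
    tset: TriangleSet, max_sf: float = 50.0, for_regression: bool = False
) -> tuple[float, float]:
    """Default SF window given the array's triangle sizes.

    The lower bound is the SF of the maximum triangle size (regressions) or
    of twice the maximum size (plotting); estimates below the reciprocal of
    the largest measurable scale are not interpretable.
    """
    usable = tset.xi if tset.n_weight is None else tset.xi[tset.n_weight > 0]
    if len(usable) == 0:
        raise ValueError("no admitted triangles")
    max_size = 1.0 / usable.min()
    lo = 1.0 / max_size if for_regression else 1.0 / (2.0 * max_size)
    return (lo, max_sf)


def build_spectrum(
    svd: PhaseSVD,
    triangles: TriangleSet,
    K: int = 32,
    sf_range: tuple[float, float] | None = None,
    dc_removal: bool = True,
    for_regression: bool = False,
) -> SFSpectrum:
    """Accumulate the weighted, binned SF spectrum from a phase decomposition.

    Per LSV: optional standing-wave (DC) removal, then per-triangle SF
    estimates and weights.  Weights whose SF falls outside ``sf_range`` are
    excluded and their mass recorded in ``meta['excluded_weight']``; LSVs
    flagged as pure standing under DC removal are dropped and counted.
    Requires a binned triangle set (see :func:`bin_triangles`).
    """
    if len(triangles) == 0:
        raise ValueError("empty triangle set")
    if triangles.n_weight is None:
        raise ValueError("triangle set must be binned first (bin_triangles)")
    if sf_range is None:
        sf_range = default_sf_range(triangles, for_regression=for_regression)
    lo, hi = sf_range
    if not lo < hi:
        raise ValueError("invalid sf_range")
    edges = np.linspace(lo, hi, K + 1)
    width = edges[1] - edges[0]
    power = np.zeros(K)
    excluded = 0.0
    dropped_standing = 0

    admitted = triangles.n_weight > 0
    ids = triangles.ids[admitted]
    planar = triangles.planar[admitted]
    n_w = triangles.n_weight[admitted]

    for r in range(svd.rank):
        zeta = svd.lsv[:, r]
        mags = np.abs(zeta)
        if dc_removal:
            if svd.fs is None or svd.center_freq is None:
                raise ValueError("dc_removal requires fs and center_freq on the PhaseSVD")
            phi_p, pure_standing = remove_standing_component(
                zeta, svd.fs, svd.center_freq
            )
            if pure_standing:
                dropped_standing += 1
                continue
            omega_all = np.angle(phi_p)
        else:
            omega_all = np.angle(zeta)
        omega = omega_all[ids]
        grad = triangle_phase_gradient(planar, omega)
        xi = triangle_sf(grad)
        w = triangle_weight(svd.singular_values[r], mags[ids], n_w)
        inside = (xi >= lo) & (xi < hi) | np.isclose(xi, hi)
        excluded += float(w[~inside].sum())
        k = np.minimum(np.floor((xi[inside] - lo) / width).astype(int), K - 1)
        np.add.at(power, k, w[inside])

    return SFSpectrum(
        bin_edges=edges,
        power=power,
        center_freq=svd.center_freq,
        rank=svd.rank,
        variant=svd.variant,
        sf_range=sf_range,
        dc_removal=dc_removal,
        meta={
            "excluded_weight": excluded,
            "dropped_standing_lsvs": dropped_standing,
            "n_triangles": int(admitted.sum()),
        },
    )
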
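"""Complex SVD of phase matrices and per-component standing-wave removal.

The phase matrix ``Phi_st`` is decomposed as ``U S V*`` with singular values
in descending order; the left singular vectors (LSVs) are spatial covariance
patterns of phase across contacts and are treated downstream as empirical
Fourier-like components.  Each LSV entry ``zeta_s`` carries a magnitude
``a_s = |zeta_s|`` and an angle ``omega_s``.

``remove_standing_component`` splits one LSV into traveling and standing
parts: the vector is extended over one full temporal cycle by an outer
product with a unit-phase ramp, the real part is decomposed by SVD, and the
first two (quadrature) components are recombined into a unit-modulus phase
vector carrying only the traveling gradient.  Globally synchronous
(zero-spatial-frequency) structure — including the artifactual synchrony
introduced by average referencing — is thereby removed, which empties the
DC bin of the downstream spatial-frequency spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral_phase import PhaseMatrix

__all__ = [
    "PhaseSVD",
    "complex_svd",
    "reconstruct",
    "remove_standing_component",
    "save_svd",
    "load_svd",
]


@dataclass
class PhaseSVD:
    """Rank-truncated complex SVD of a phase matrix.

    ``lsv``: (contacts, rank) complex, columns zeta.  ``rsv``: (samples,
    rank) complex, columns of V (so the reconstruction is
    ``sum_i s_i * lsv[:, i] @ rsv[:, i].conj().T``).
    """

    lsv: np.ndarray
    singular_values: np.ndarray
    rsv: np.ndarray
    rank: int
    center_freq: float | None = None
    fs: float | None = None
    variant: str = "phase_only"
    meta: dict = field(default_factory=dict)

    @property
    def magnitudes(self) -> np.ndarray:
        """a_s = |zeta_s| per LSV, shape (contacts, rank)."""
        return np.abs(self.lsv)

    @property
    def angles(self) -> np.ndarray:
        """omega_s = angle(zeta_s) per LSV, shape (contacts, rank)."""
        return np.angle(self.lsv)


def _fix_gauge(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotate each component so its largest-|u| entry is real-positive.

    The SVD is only defined up to a unit complex factor per component; the
    same factor is applied to u and v so the product u v* is unchanged.
    """
    idx = np.argmax(np.abs(U), axis=0)
    rot = np.exp(-1j * np.angle(U[idx, np.arange(U.shape[1])]))
    return U * rot[None, :], V * rot[None, :]


def complex_svd(
    phase: PhaseMatrix | np.ndarray,
    rank: int = 14,
    drop_invalid: bool = True,
) -> PhaseSVD:
    """Economy complex SVD of the phase matrix, truncated to ``rank``.

    When given a :class:`PhaseMatrix`, samples flagged invalid (recording
    edges) are excluded before decomposition unless ``drop_invalid=False``.
    """
    if isinstance(phase, PhaseMatrix):
        values = phase.values
        if drop_invalid and not phase.valid.all():
            values = values[:, phase.valid]
        f, fs, variant = phase.center_freq, phase.fs, phase.variant
    else:
        values = np.atleast_2d(np.asarray(phase, dtype=complex))
        f = fs = None
        variant = "phase_only"
    S, T = values.shape
    if rank > min(S, T):
        raise ValueError(f"rank {rank} exceeds matrix dimensions {S}x{T}")
    U, s, Vh = np.linalg.svd(values, full_matrices=False)
    U, V = _fix_gauge(U[:, :rank], Vh.conj().T[:, :rank])
    return PhaseSVD(
        lsv=U,
        singular_values=s[:rank],
        rsv=V,
        rank=rank,
        center_freq=f,
        fs=fs,
        variant=variant,
        meta={"full_spectrum_sumsq": float(np.sum(s**2)), "gauge": "max-entry real-positive"},
    )


def reconstruct(svd: PhaseSVD, weights: np.ndarray | None = None) -> np.ndarray:
    """Sum of weighted rank-1 terms ``sum_i w_i u_i v_i*``.

    With ``weights=None`` the singular values are used, inverting
    :func:`complex_svd` exactly at full rank.
    """
    w = svd.singular_values if weights is None else np.asarray(weights, dtype=float)
    if len(w) != svd.rank:
        raise ValueError(f"weights length {len(w)} != rank {svd.rank}")
    return (svd.lsv * w[None, :]) @ svd.rsv.conj().T


def remove_standing_component(
    lsv_column: np.ndarray,
    fs: float,
    f: float,
    degenerate_tol: float = 1e-8,
) -> tuple[np.ndarray, bool]:
    """Extract the traveling (positive-SF) part of one LSV of phase.

    The complex vector ``r*phi_s`` is extended to one full cycle by an outer
    product with a unit-phase vector of ``n = round(fs / f)`` samples; the
    real part is decomposed by SVD and the first two components are
    recombined as ``phi_p = exp(-i * angle(u1 + i*u2))``.  The quadrature
    pair is defined only up to sign, giving two propagation orientations;
    the orientation preserving the input's dominant phase relationship
    (maximal |sum phi_p * conj(unit(input))|) is returned.

    Returns ``(phi_p, pure_standing)``.  A degenerate input (constant phase,
    no rotating part: second singular value below ``degenerate_tol`` of the
    first) is flagged ``pure_standing=True`` and returned unit-normalized;
    callers building spectra drop such components, since they carry no
    traveling gradient.
    """
    v = np.asarray(lsv_column, dtype=complex).ravel()
    if v.size < 3:
        raise ValueError("LSV must have at least 3 entries")
    if f > fs:
        raise ValueError("center frequency exceeds sampling rate")
    n = int(round(fs / f))
    if n < 2:
        raise ValueError("fewer than 2 extension samples; fs/f too small")
    phi_c = np.exp(-2j * np.pi * np.arange(n) / n)
    M = np.real(np.outer(v, phi_c))
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    mags = np.abs(v)
    unit_in = np.divide(v, mags, out=np.ones_like(v), where=mags > 0)
    if s[0] == 0 or s[1] < degenerate_tol * s[0]:
        return unit_in, True
    u1, u2 = U[:, 0], U[:, 1]
    cand_a = np.exp(-1j * np.angle(u1 + 1j * u2))
    cand_b = np.exp(-1j * np.angle(u1 - 1j * u2))
    score_a = np.abs(np.sum(cand_a * np.conj(unit_in)))
    score_b = np.abs(np.sum(cand_b * np.conj(unit_in)))
    return (cand_a, False) if score_a >= score_b else (cand_b, False)


# ---------------------------------------------------------------------------
# serialization

def save_svd(path, svd: PhaseSVD) -> None:
    """Write a PhaseSVD to HDF5 (complex as paired real datasets)."""
    import h5py

    with h5py.File(path, "w") as h:
        for name, arr in (("lsv", svd.lsv), ("rsv", svd.rsv)):
            h.create_dataset(f"{name}_real", data=arr.real)
            h.create_dataset(f"{name}_imag", data=arr.imag)
        h.create_dataset("singular_values", data=svd.singular_values)
        h.attrs["rank"] = svd.rank
        h.attrs["variant"] = svd.variant
        h.attrs["gauge"] = svd.meta.get("gauge", "")
        if svd.center_freq is not None:
            h.attrs["center_freq"] = svd.center_freq
        if svd.fs is not None:
            h.attrs["fs"] = svd.fs


def load_svd(path) -> PhaseSVD:
    import h5py

    with h5py.File(path, "r") as h:
        return PhaseSVD(
            lsv=h["lsv_real"][...] + 1j * h["lsv_imag"][...],
            singular_values=h["singular_values"][...],
            rsv=h["rsv_real"][...] + 1j * h["rsv_imag"][...],
            rank=int(h.attrs["rank"]),
            center_freq=float(h.attrs["center_freq"]) if "center_freq" in h.attrs else None,
            fs=float(h.attrs["fs"]) if "fs" in h.attrs else None,
            variant=str(h.attrs["variant"]),
            meta={"gauge": str(h.attrs.get("gauge", ""))},
        )
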
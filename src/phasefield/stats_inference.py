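"""Log-log wavelength-power regressions, peak statistics, permutation tests.

Regressions of SF spectra are ordinary least squares of log power on log
wavelength (1/SF).  Significance is assessed by correlating the empirical
values ``y`` with the model values ``yhat`` and comparing the unsigned mean
correlation over a family of regressions to its permutation distribution
(shuffling ``yhat`` within each member; two-tailed; add-one correction so
the smallest attainable p is 1/(n_perm+1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sf_spectrum import SFSpectrum

__all__ = [
    "RegressionResult",
    "loglog_regression",
    "permutation_pvalue",
    "peak_statistics",
    "PeakStatistics",
]


@dataclass
class RegressionResult:
    """OLS fit summary with optional permutation p-value."""

    slope: float
    offset: float
    r: float
    p: float | None
    n_points: int
    sf_bounds: tuple[float, float]
    meta: dict = field(default_factory=dict)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise ValueError("correlation undefined for constant input")
    return float((a @ b) / denom)


def loglog_regression(
    spectrum: SFSpectrum,
    min_sf: float | None = None,
    n_perm: int = 0,
    seed: int | None = None,
) -> RegressionResult:
    """OLS of log power on log wavelength over admitted SF bins.

    Bins with SF below ``min_sf`` (default: the reciprocal of the maximum
    triangle size, i.e. the spectrum's lower range bound) and zero-power
    bins are dropped (counts recorded).  Requires >= 3 usable bins.
    """
    if min_sf is None:
        min_sf = spectrum.sf_range[0] if spectrum.sf_range else spectrum.bin_edges[0]
    centers = spectrum.bin_centers
    keep = centers >= min_sf
    dropped_zero = int(np.sum(keep & (spectrum.power <= 0)))
    keep &= spectrum.power > 0
    if keep.sum() < 3:
        raise ValueError(f"only {int(keep.sum())} usable bins (need >= 3)")
    x = np.log(1.0 / centers[keep])  # log wavelength
    y = np.log(spectrum.power[keep])
    if np.ptp(y) == 0:
        # exactly flat spectrum: slope 0, nothing to correlate or test
        return RegressionResult(
            slope=0.0,
            offset=float(y[0]),
            r=0.0,
            p=None,
            n_points=int(keep.sum()),
            sf_bounds=(float(min_sf), float(spectrum.bin_edges[-1])),
            meta={"dropped_zero_bins": dropped_zero, "constant": True},
        )
    slope, offset = np.polyfit(x, y, 1)
    yhat = slope * x + offset
    r = _pearson(y, yhat)
    p = None
    if n_perm:
        p = permutation_pvalue(y, yhat, n_perm=n_perm, seed=seed)
    return RegressionResult(
        slope=float(slope),
        offset=float(offset),
        r=r,
        p=p,
        n_points=int(keep.sum()),
        sf_bounds=(float(min_sf), float(spectrum.bin_edges[-1])),
        meta={"dropped_zero_bins": dropped_zero},
    )


def _as_group(y, yhat) -> list[tuple[np.ndarray, np.ndarray]]:
    if isinstance(y, np.ndarray) and y.ndim == 1 and isinstance(yhat, np.ndarray):
        return [(y, yhat)]
    if isinstance(y, (list, tuple)) and isinstance(yhat, (list, tuple)):
        if len(y) != len(yhat):
            raise ValueError("group members must pair up")
        return [(np.asarray(a, float), np.asarray(b, float)) for a, b in zip(y, yhat)]
    return [(np.asarray(y, float), np.asarray(yhat, float))]


def permutation_pvalue(y, yhat, n_perm: int = 10_000, seed: int | None = None) -> float:
    """Two-tailed permutation p for the unsigned mean y-vs-yhat correlation.

    ``y``/``yhat`` may be single vectors or equal-length lists of vectors (a
    family of regressions).  Each permutation shuffles ``yhat`` within each
    member; the statistic is |mean correlation| over members.  Add-one
    corrected: p = (#{perm >= observed} + 1) / (n_perm + 1).
    """
    if n_perm < 1000:
        raise ValueError("use at least 1000 permutations")
    group = _as_group(y, yhat)
    obs = abs(float(np.mean([_pearson(a, b) for a, b in group])))
    rng = np.random.default_rng(seed)
    perm_corr = np.zeros((n_perm, len(group)))
    for m, (a, b) in enumerate(group):
        ac = a - a.mean()
        bc = b - b.mean()
        na = np.sqrt(ac @ ac)
        nb = np.sqrt(bc @ bc)
        if na == 0 or nb == 0:
            raise ValueError("correlation undefined for constant input")
        # vectorized: each row a permutation of bc
        idx = rng.permuted(
            np.tile(np.arange(len(b)), (n_perm, 1)), axis=1
        )
        perm_corr[:, m] = (bc[idx] @ ac) / (na * nb)
    stat = np.abs(perm_corr.mean(axis=1))
    return float((np.sum(stat >= obs) + 1) / (n_perm + 1))


@dataclass
class PeakStatistics:
    """Per-TF spectral peaks and their trends across TF."""

    table: pd.DataFrame
    peak_power_vs_tf: RegressionResult
    peak_sf_vs_tf: RegressionResult


def peak_statistics(
    spectra: list[SFSpectrum],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PeakStatistics:
    """Locate per-TF spectral peaks and regress them on log TF.

    For each spectrum the maximum-power bin gives (peak power, SF at peak);
    ties go to the lowest-SF bin and are flagged.  Peak power and log
    wavelength at peak are each regressed on log TF with permutation
    p-values.  Requires >= 3 TFs.
    """
    if len(spectra) < 3:
        raise ValueError("need at least 3 TFs for peak statistics")
    rows = []
    for sp in spectra:
        imax = int(np.argmax(sp.power))
        ties = int(np.sum(sp.power == sp.power[imax])) > 1
        rows.append(
            {
                "tf": sp.center_freq,
                "peak_power": float(sp.power[imax]),
                "peak_sf": float(sp.bin_centers[imax]),
                "tied_peak": ties,
            }
        )
    table = pd.DataFrame(rows).sort_values("tf").reset_index(drop=True)
    log_tf = np.log(table["tf"].to_numpy(float))

    def _fit(yvals: np.ndarray) -> RegressionResult:
        if np.ptp(yvals) == 0:
            # a perfectly flat trend (e.g. identical peak SF at every TF)
            # has no correlation to test; report it as flat, non-significant
            return RegressionResult(
                slope=0.0,
                offset=float(yvals[0]),
                r=0.0,
                p=1.0,
                n_points=len(yvals),
                sf_bounds=(float(table["tf"].min()), float(table["tf"].max())),
                meta={"constant": True},
            )
        slope, offset = np.polyfit(log_tf, yvals, 1)
        yhat = slope * log_tf + offset
        r = _pearson(yvals, yhat)
        p = permutation_pvalue(yvals, yhat, n_perm=n_perm, seed=seed)
        return RegressionResult(
            slope=float(slope),
            offset=float(offset),
            r=r,
            p=p,
            n_points=len(yvals),
            sf_bounds=(float(table["tf"].min()), float(table["tf"].max())),
        )

    power_fit = _fit(np.log(table["peak_power"].to_numpy(float)))
    sf_fit = _fit(np.log(1.0 / table["peak_sf"].to_numpy(float)))
    return PeakStatistics(table=table, peak_power_vs_tf=power_fit, peak_sf_vs_tf=sf_fit)
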
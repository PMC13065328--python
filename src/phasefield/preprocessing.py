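"""Denoising and white-matter re-referencing of multi-trial sEEG recordings.

The cleaning procedure is a three-stage sequential filter on the per-trial,
per-sensor standard deviation of the signal, with recomputation between
stages: (1) trials whose mean SD deviates by more than ``trial_k`` SDs of the
trial means are dropped; (2) after recomputation, sensors beyond ``sensor_k``
are dropped; (3) after recomputation, over-threshold trial-by-sensor cells
are replaced with the average signal, the average being computed after
excluding every over-threshold cell.

Gray-matter contacts are then re-referenced against the pooled average of
the white-matter contacts whose signal-amplitude SD lies in the bottom 50%
of white contacts ("white-matter low-amplitude contacts").
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RawRecording",
    "RejectionReport",
    "reject_noisy",
    "white_matter_reference",
    "read_electrodes",
    "read_recording",
]


@dataclass
class RawRecording:
    """Multi-trial recording: signal (contacts x samples) plus contact metadata.

    ``trial_bounds`` is a list of half-open ``(start, stop)`` sample
    intervals.  ``labels`` holds ``"gray"``/``"white"`` per contact and
    ``hemisphere`` holds ``"left"``/``"right"``.
    """

    signal: np.ndarray
    fs: float
    trial_bounds: list[tuple[int, int]]
    contact_ids: list[str]
    labels: np.ndarray
    hemisphere: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        self.labels = np.asarray(self.labels)
        self.hemisphere = np.asarray(self.hemisphere)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        S, T = self.signal.shape
        if len(self.contact_ids) != S or len(self.labels) != S or len(self.hemisphere) != S:
            raise ValueError("contact metadata length must match signal rows")
        bad = set(np.unique(self.labels)) - {"gray", "white"}
        if bad:
            raise ValueError(f"unknown contact labels: {bad}")
        prev = 0
        for a, b in self.trial_bounds:
            if not (0 <= a < b <= T):
                raise ValueError(f"trial bounds ({a}, {b}) outside sample range")
            if a < prev:
                raise ValueError("trial intervals must be non-overlapping and sorted")
            prev = b
        if not (self.labels == "gray").any():
            raise ValueError("recording has no gray-matter contacts")

    @property
    def n_contacts(self) -> int:
        return self.signal.shape[0]

    @property
    def n_trials(self) -> int:
        return len(self.trial_bounds)

    def trial(self, i: int) -> np.ndarray:
        a, b = self.trial_bounds[i]
        return self.signal[:, a:b]

    def gray_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels == "gray")

    def white_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels == "white")


@dataclass
class RejectionReport:
    dropped_trials: list[int] = field(default_factory=list)
    dropped_sensors: list[int] = field(default_factory=list)
    replaced_cells: list[tuple[int, int]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)


def _trial_sensor_sd(rec: RawRecording, trials: list[int], sensors: np.ndarray) -> np.ndarray:
    """SD over samples for each retained (trial, sensor), unbiased denominator."""
    return np.stack([rec.trial(i)[sensors].std(axis=1, ddof=1) for i in trials])


def reject_noisy(
    recording: RawRecording,
    trial_k: float = 3.0,
    sensor_k: float = 1.5,
    cell_k: float = 3.0,
) -> tuple[RawRecording, RejectionReport]:
    """Three-stage SD-based rejection with recomputation between stages.

    Returns a new recording containing only retained trials and sensors
    (concatenated in original order, bounds rebuilt) plus a report with
    original indices.  Raises if every trial is rejected.
    """
    if recording.n_trials < 1:
        raise ValueError("recording has no trials")
    if recording.n_contacts < 2:
        raise ValueError("need at least two sensors")

    report = RejectionReport()
    trials = list(range(recording.n_trials))
    sensors = np.arange(recording.n_contacts)

    # stage 1: trials.  The deviation threshold is in units of the mean SD
    # itself (a single gross outlier inflates a z-score denominator enough
    # to hide itself in small trial counts).
    if recording.n_trials == 1:
        warnings.warn("single-trial recording: trial rejection stage skipped")
    else:
        sd = _trial_sensor_sd(recording, trials, sensors)
        trial_mean = sd.mean(axis=1)
        dev = np.abs(trial_mean - trial_mean.mean())
        scale = trial_mean.mean()
        if scale > 0:
            keep = dev <= trial_k * scale
            report.dropped_trials = [t for t, k in zip(trials, keep) if not k]
            trials = [t for t, k in zip(trials, keep) if k]
        if not trials:
            raise ValueError("all trials rejected at stage 1")

    # stage 2: sensors (recomputed on retained trials), same threshold units
    sd = _trial_sensor_sd(recording, trials, sensors)
    sensor_mean = sd.mean(axis=0)
    dev = np.abs(sensor_mean - sensor_mean.mean())
    scale = sensor_mean.mean()
    if scale > 0:
        keep = dev <= sensor_k * scale
        report.dropped_sensors = list(np.flatnonzero(~keep))
        sensors = sensors[keep]
    if len(sensors) < 1:
        raise ValueError("all sensors rejected at stage 2")

    # stage 3: cells (recomputed on retained trials x sensors)
    sd = _trial_sensor_sd(recording, trials, sensors)
    dev = np.abs(sd - sd.mean())
    scale = sd.std(ddof=1)
    over = dev > cell_k * scale if scale > 0 else np.zeros_like(sd, dtype=bool)

    lengths = {recording.trial_bounds[t][1] - recording.trial_bounds[t][0] for t in trials}
    blocks = [recording.trial(t)[sensors].copy() for t in trials]
    if over.any():
        equal_lengths = len(lengths) == 1
        for jj in range(len(sensors)):
            col_over = over[:, jj]
            if not col_over.any():
                continue
            ok = ~col_over
            if not ok.any():
                # every trial over threshold for this sensor: leave as-is, note it
                report.metadata.setdefault("unreplaceable_sensors", []).append(int(sensors[jj]))
                continue
            if equal_lengths:
                avg = np.mean([blocks[i][jj] for i in np.flatnonzero(ok)], axis=0)
            else:
                avg = float(np.mean([blocks[i][jj].mean() for i in np.flatnonzero(ok)]))
            for i in np.flatnonzero(col_over):
                blocks[i][jj] = avg
                report.replaced_cells.append((trials[i], int(sensors[jj])))
        report.metadata["replacement_axis"] = "per-sensor mean across retained trials"

    new_signal = np.concatenate(blocks, axis=1)
    bounds, pos = [], 0
    for b in blocks:
        bounds.append((pos, pos + b.shape[1]))
        pos += b.shape[1]
    cleaned = RawRecording(
        signal=new_signal,
        fs=recording.fs,
        trial_bounds=bounds,
        contact_ids=[recording.contact_ids[i] for i in sensors],
        labels=recording.labels[sensors],
        hemisphere=recording.hemisphere[sensors],
    )
    report.metadata["retained_trials"] = trials
    report.metadata["retained_sensors"] = list(map(int, sensors))
    return cleaned, report


def white_matter_reference(recording: RawRecording) -> np.ndarray:
    """Re-reference gray contacts against the low-amplitude white-matter pool.

    The reference is the per-sample mean of the white contacts whose signal
    SD is in the bottom 50% (the lower floor(n/2) contacts, ties broken by
    contact index).  Returns the referenced gray signal, rows ordered as the
    gray contacts appear in the recording.
    """
    whites = recording.white_indices()
    if len(whites) == 0:
        raise ValueError(
            "no white-matter contacts: pass an explicit reference or skip re-referencing"
        )
    if len(whites) < 2:
        raise ValueError("need at least two white-matter contacts for the 50% pool")
    sds = recording.signal[whites].std(axis=1, ddof=1)
    n_low = max(1, len(whites) // 2)
    order = np.argsort(sds, kind="stable")
    pool = whites[order[:n_low]]
    reference = recording.signal[pool].mean(axis=0)
    grays = recording.gray_indices()
    return recording.signal[grays] - reference[None, :]


# ---------------------------------------------------------------------------
# readers

def read_electrodes(path) -> pd.DataFrame:
    """Contact table: tab-separated with columns id, x, y, z, label, hemisphere.

    Coordinates are in meters (BIDS-iEEG-like electrodes.tsv dialect).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"id", "x", "y", "z", "label", "hemisphere"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"electrodes table missing columns: {sorted(missing)}")
    return df


def read_recording(signal_path, electrodes_path, sidecar_path=None) -> RawRecording:
    """Load a recording from EDF, HDF5, or delimited text plus a JSON sidecar.

    HDF5 files must hold a ``signal`` dataset (contacts x samples); text
    files are parsed as whitespace/comma-delimited numeric matrices.  The
    sidecar supplies ``{"fs": ..., "trial_bounds": [[a, b], ...]}`` for
    non-EDF containers.
    """
    signal_path = Path(signal_path)
    electrodes = read_electrodes(electrodes_path)
    suffix = signal_path.suffix.lower()
    if suffix == ".edf":
        import mne

        raw = mne.io.read_raw_edf(signal_path, preload=True, verbose="error")
        signal = raw.get_data()
        fs = float(raw.info["sfreq"])
        bounds = [(0, signal.shape[1])]
    else:
        if suffix in (".h5", ".hdf5"):
            import h5py

            with h5py.File(signal_path, "r") as h:
                signal = h["signal"][...]
        else:
            signal = np.loadtxt(signal_path, delimiter="," if suffix == ".csv" else None)
        if sidecar_path is None:
            sidecar_path = signal_path.with_suffix(".json")
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
        fs = float(sidecar["fs"])
        bounds = [tuple(b) for b in sidecar["trial_bounds"]]
    return RawRecording(
        signal=signal,
        fs=fs,
        trial_bounds=bounds,
        contact_ids=[str(i) for i in electrodes["id"]],
        labels=electrodes["label"].to_numpy(),
        hemisphere=electrodes["hemisphere"].to_numpy(),
    )
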
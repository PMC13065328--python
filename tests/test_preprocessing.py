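"""Denoising stages and white-matter re-referencing."""

import numpy as np
import pytest

from phasefield.preprocessing import RawRecording, reject_noisy, white_matter_reference


def make_recording(signal, n_trials, labels=None, fs=500.0):
    signal = np.asarray(signal, dtype=float)
    S, T = signal.shape
    per = T // n_trials
    bounds = [(i * per, (i + 1) * per) for i in range(n_trials)]
    if labels is None:
        labels = np.array(["gray"] * S)
    return RawRecording(
        signal=signal,
        fs=fs,
        trial_bounds=bounds,
        contact_ids=[f"c{i}" for i in range(S)],
        labels=np.asarray(labels),
        hemisphere=np.array(["left"] * S),
    )


def oracle_three_stages(blocks, trial_k=3.0, sensor_k=1.5, cell_k=3.0):
    """Independent re-computation of the sequential rejection rules.

    ``blocks`` is (trials, sensors, samples).  Returns (kept trials, kept
    sensors, over-threshold cells) using the same SD conventions.
    """
    blocks = np.asarray(blocks, dtype=float)
    trials = list(range(blocks.shape[0]))
    sensors = list(range(blocks.shape[1]))
    sd = blocks.std(axis=2, ddof=1)
    tm = sd.mean(axis=1)
    # stages 1-2 measure deviation in units of the mean SD; stage 3 in SDs
    if tm.mean() > 0:
        trials = [t for t in trials if abs(tm[t] - tm.mean()) <= trial_k * tm.mean()]
    sd = blocks[trials].std(axis=2, ddof=1)
    sm = sd.mean(axis=0)
    if sm.mean() > 0:
        sensors = [s for s in sensors if abs(sm[s] - sm.mean()) <= sensor_k * sm.mean()]
    sd = blocks[np.ix_(trials, sensors)].std(axis=2, ddof=1)
    scale = sd.std(ddof=1)
    cells = []
    if scale > 0:
        for i, t in enumerate(trials):
            for j, s in enumerate(sensors):
                if abs(sd[i, j] - sd.mean()) > cell_k * scale:
                    cells.append((t, s))
    return trials, sensors, cells


@pytest.fixture
def noise_blocks():
    rng = np.random.default_rng(5)
    return rng.standard_normal((10, 4, 200))


def test_homogeneous_data_passes_untouched():
    blocks = np.tile(np.sin(np.linspace(0, 20, 100))[None, None, :], (10, 4, 1))
    rec = make_recording(blocks.transpose(1, 0, 2).reshape(4, -1), n_trials=10)
    cleaned, report = reject_noisy(rec)
    assert report.dropped_trials == []
    assert report.dropped_sensors == []
    assert report.replaced_cells == []
    np.testing.assert_array_equal(cleaned.signal, rec.signal)


def test_scaled_trial_is_the_only_rejection(noise_blocks):
    blocks = noise_blocks.copy()
    blocks[4] *= 20.0
    kept_trials, kept_sensors, cells = oracle_three_stages(blocks)
    assert kept_trials == [t for t in range(10) if t != 4]
    rec = make_recording(blocks.transpose(1, 0, 2).reshape(4, -1), n_trials=10)
    cleaned, report = reject_noisy(rec)
    assert report.dropped_trials == [4]
    assert report.dropped_sensors == list(set(range(4)) - set(kept_sensors))
    assert cleaned.n_trials == 9


def test_single_hot_cell_replaced_with_excluding_average(noise_blocks):
    blocks = noise_blocks.copy()
    blocks[3, 2] *= 20.0
    kept_trials, kept_sensors, cells = oracle_three_stages(blocks)
    assert kept_trials == list(range(10)) and kept_sensors == list(range(4))
    assert cells == [(3, 2)]
    rec = make_recording(blocks.transpose(1, 0, 2).reshape(4, -1), n_trials=10)
    cleaned, report = reject_noisy(rec)
    assert report.dropped_trials == [] and report.dropped_sensors == []
    assert report.replaced_cells == [(3, 2)]
    expected = np.mean([blocks[t, 2] for t in range(10) if t != 3], axis=0)
    a, b = cleaned.trial_bounds[3]
    np.testing.assert_allclose(cleaned.signal[2, a:b], expected)


def test_stage_order_matches_sequential_oracle(noise_blocks):
    """Permuting the stages changes the outcome; the sequential order rules."""
    blocks = noise_blocks.copy()
    blocks[0] *= 8.0      # bad trial
    blocks[5, 1] *= 25.0  # bad cell elsewhere
    kept_trials, kept_sensors, cells = oracle_three_stages(blocks)
    rec = make_recording(blocks.transpose(1, 0, 2).reshape(4, -1), n_trials=10)
    cleaned, report = reject_noisy(rec)
    assert report.metadata["retained_trials"] == kept_trials
    assert report.metadata["retained_sensors"] == kept_sensors
    assert sorted(report.replaced_cells) == sorted(cells)


def test_single_trial_skips_stage_one_with_warning(noise_blocks):
    rec = make_recording(noise_blocks[0], n_trials=1)
    with pytest.warns(UserWarning, match="single-trial"):
        cleaned, report = reject_noisy(rec)
    assert report.dropped_trials == []


def test_reject_requires_at_least_two_sensors():
    rec = make_recording(np.random.default_rng(0).standard_normal((1, 100)), n_trials=2)
    with pytest.raises(ValueError):
        reject_noisy(rec)


# ---------------------------------------------------------------------------
# white-matter referencing


def test_identical_white_contacts_subtract_exactly():
    rng = np.random.default_rng(1)
    w = rng.standard_normal(300)
    g = rng.standard_normal((3, 300))
    signal = np.vstack([g, w, w])
    labels = ["gray"] * 3 + ["white"] * 2
    rec = make_recording(signal, n_trials=1, labels=labels)
    out = white_matter_reference(rec)
    np.testing.assert_allclose(out, g - w[None, :])


def test_bottom_half_of_white_contacts_forms_the_reference():
    rng = np.random.default_rng(2)
    T = 2000
    whites = np.vstack([sd * rng.standard_normal(T) for sd in (1.0, 2.0, 3.0, 4.0)])
    gray = np.zeros((1, T))
    rec = make_recording(np.vstack([gray, whites]), n_trials=1,
                         labels=["gray"] + ["white"] * 4)
    out = white_matter_reference(rec)
    # reference = mean of the two lowest-SD white contacts
    np.testing.assert_allclose(out[0], -(whites[0] + whites[1]) / 2.0)


def test_gray_equal_to_reference_yields_zero():
    w = np.sin(np.linspace(0, 30, 500))
    signal = np.vstack([w, w, w])
    rec = make_recording(signal, n_trials=1, labels=["gray", "white", "white"])
    out = white_matter_reference(rec)
    np.testing.assert_allclose(out, 0.0, atol=1e-12)


def test_common_mode_signal_cancels():
    # white SDs are well separated so the bottom-50% selection is stable
    # under the added common-mode signal
    rng = np.random.default_rng(3)
    base = rng.standard_normal((5, 400)) * np.array([1.0, 1.0, 1.0, 4.0, 8.0])[:, None]
    labels = ["gray", "gray", "white", "white", "white"]
    rec_a = make_recording(base, n_trials=1, labels=labels)
    common = 2.0 * np.sin(np.linspace(0, 50, 400))
    rec_b = make_recording(base + common[None, :], n_trials=1, labels=labels)
    np.testing.assert_allclose(
        white_matter_reference(rec_a), white_matter_reference(rec_b), atol=1e-10
    )


def test_no_white_contacts_is_an_error():
    rec = make_recording(np.zeros((2, 100)) + np.random.default_rng(0).standard_normal((2, 100)),
                         n_trials=1, labels=["gray", "gray"])
    with pytest.raises(ValueError, match="white"):
        white_matter_reference(rec)
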
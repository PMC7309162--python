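"""Filtering, train/test splitting and sliding-window dataset construction.

The modeling protocol is: 10 s of simultaneously acquired patch and 12-lead
signal, first 5 s for fitting, last 5 s held out; sequence models consume
1-s (250-sample) windows slid one sample (4 ms) at a time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .records import MultiLeadRecord
from .synth import PairedRecording


def bandpass(record: MultiLeadRecord, low: float = 0.05,
             high: float = 100.0, order: int = 4) -> MultiLeadRecord:
    """Zero-phase Butterworth band-pass applied per lead.

    The default passband is 0.05–100 Hz: a diagnostic-bandwidth filter whose
    upper corner fits below the 125 Hz Nyquist at the 250 Hz sampling rate.
    Forward–backward filtering keeps zero phase so the ST segment is not
    skewed.
    """
    nyq = record.fs / 2.0
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high corner {high} Hz ≥ Nyquist {nyq} Hz")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=record.fs,
                     output="sos")
    out = sps.sosfiltfilt(sos, record.data, axis=0)
    return replace(record, data=np.ascontiguousarray(out))


def split_train_test(paired: PairedRecording, train_s: float = 5.0):
    """Split a paired recording into (train, test) at ``train_s`` seconds.

    Ground-truth beats go to the segment containing their R peak; test-side
    fiducial times are re-referenced to the test segment's start.
    """
    if train_s <= 0:
        raise ValueError("train_s must be positive")
    if paired.patch.duration < 2.0 * train_s:
        raise ValueError("recording shorter than twice the training length")
    fs = paired.fs
    cut = int(round(train_s * fs))
    train_beats, test_beats = [], []
    for b in paired.beats:
        if b.r_time < train_s:
            train_beats.append(b)
        else:
            shifted = replace(
                b, r_time=b.r_time - train_s,
                fiducials={k: (None if v is None else v - train_s)
                           for k, v in b.fiducials.items()})
            test_beats.append(shifted)
    train = PairedRecording(patch=paired.patch.slice(0, cut),
                            target=paired.target.slice(0, cut),
                            beats=train_beats)
    test = PairedRecording(patch=paired.patch.slice(cut, paired.n_samples),
                           target=paired.target.slice(cut, paired.n_samples),
                           beats=test_beats)
    return train, test


@dataclass
class WindowDataset:
    """Aligned sliding windows: inputs (n_windows, n_ch, window) and targets
    (n_windows, window), both raw μV unless a normalizer was applied."""

    inputs: np.ndarray
    targets: np.ndarray
    window: int
    step: int

    @property
    def n_windows(self) -> int:
        return self.inputs.shape[0]


def make_windows(patch: np.ndarray, target: np.ndarray, window: int = 250,
                 step: int = 1) -> WindowDataset:
    """Cut aligned sliding windows from a (n_samples, n_ch) patch matrix and
    a (n_samples,) target-lead signal.

    Window k covers samples ``[k·step, k·step + window)``;
    ``n_windows = floor((N − window)/step) + 1``.
    """
    patch = np.asarray(patch, dtype=float)
    target = np.asarray(target, dtype=float)
    if patch.ndim != 2:
        raise ValueError("patch must be (n_samples, n_ch)")
    n = patch.shape[0]
    if target.shape[0] != n:
        raise ValueError("patch and target lengths differ")
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if n < window:
        raise ValueError(f"signal length {n} shorter than window {window}")
    n_windows = (n - window) // step + 1
    starts = np.arange(n_windows) * step
    # (n_windows, n_ch, window)
    idx = starts[:, None] + np.arange(window)[None, :]
    inputs = np.transpose(patch[idx], (0, 2, 1))
    targets = target[idx]
    return WindowDataset(inputs=inputs, targets=targets, window=window,
                         step=step)


class ChannelNormalizer:
    """Per-channel z-normalization with statistics frozen on training data.

    transform/inverse_transform are exact inverses; a constant channel gets
    scale 1 to stay well-defined.
    """

    def __init__(self):
        self.mean_ = None
        self.scale_ = None

    def fit(self, x: np.ndarray) -> "ChannelNormalizer":
        """``x`` is (n_samples, n_ch) or (n_samples,)."""
        x = np.asarray(x, dtype=float)
        axis = 0
        self.mean_ = x.mean(axis=axis)
        scale = x.std(axis=axis)
        self.scale_ = np.where(scale > 0, scale, 1.0)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean_) / self.scale_

    def inverse_transform(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.scale_ + self.mean_
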
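"""Signal conditioning of raw EMG and hand-position recordings.

Pipeline per EMG channel: linear detrend (DC/drift removal) -> median-filter
despiking -> full-wave rectification -> 2 Hz second-order Butterworth
low-pass, giving the linear envelope — the smooth amplitude proxy for muscle
activation that time-domain features are computed on. The 60 Hz position
signal is resampled to 1 kHz to share the EMG time base and low-pass
filtered the same way.

Filtering is zero-phase (forward-backward) by default, appropriate for
offline analysis; a causal mode is available for latency-realistic
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .synthetic import FS_EMG, FS_POS, Recording

__all__ = [
    "ProcessedRecording",
    "remove_dc",
    "despike",
    "rectify",
    "linear_envelope",
    "resample_position",
    "preprocess_recording",
]


@dataclass
class ProcessedRecording:
    """Envelope and 1 kHz position sharing one time base.

    ``envelope`` is (N, 6), non-negative; ``position_1k`` is (N, 3) in cm.
    Trial metadata (task, speed, cycle boundaries in *position* samples at
    the original 60 Hz) is carried over from the source recording.
    """

    envelope: np.ndarray
    position_1k: np.ndarray
    task_id: str
    speed: str
    trial_index: int
    cycle_bounds: list
    seed: int = 0
    fs: float = FS_EMG
    fs_pos_src: float = FS_POS

    def __post_init__(self):
        if self.envelope.shape[0] != self.position_1k.shape[0]:
            raise ValueError("envelope and position_1k lengths differ")
        if np.any(self.envelope < 0):
            raise ValueError("envelope must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.envelope.shape[0]

    def cycle_onsets_ms(self) -> np.ndarray:
        """Cycle onset times in ms on the shared 1 kHz time base."""
        starts = np.asarray([b[0] for b in self.cycle_bounds], dtype=float)
        return starts / self.fs_pos_src * 1000.0


def remove_dc(x: np.ndarray) -> np.ndarray:
    """Subtract the least-squares linear trend (offset plus drift)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to detrend")
    return signal.detrend(x, type="linear")


def despike(x: np.ndarray, kernel: int = 5) -> np.ndarray:
    """Sliding-window median filter; edges handled by reflection.

    The kernel width is in samples (5 samples = 5 ms at 1 kHz) and must be
    odd so the window is centred.
    """
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError("kernel must be odd and >= 3")
    return ndimage.median_filter(
        np.asarray(x, dtype=float), size=kernel, mode="reflect"
    )


def rectify(x: np.ndarray) -> np.ndarray:
    """Full-wave rectification (element-wise absolute value)."""
    return np.abs(np.asarray(x, dtype=float))


def linear_envelope(
    x: np.ndarray, fs: float, cutoff_hz: float = 2.0, causal: bool = False
) -> np.ndarray:
    """Second-order Butterworth low-pass at ``cutoff_hz`` (DC gain 1).

    Zero-phase by default (the filter is applied forward and backward, so
    the effective attenuation is the single-pass magnitude squared);
    ``causal=True`` applies a single forward pass instead.
    """
    if fs <= 2 * cutoff_hz:
        raise ValueError("sampling rate must exceed twice the cutoff")
    b, a = signal.butter(2, cutoff_hz, btype="low", fs=fs)
    if causal:
        return signal.lfilter(b, a, x, axis=0)
    return signal.filtfilt(b, a, x, axis=0)


def resample_position(
    position: np.ndarray, fs_src: float = FS_POS, fs_dst: float = FS_EMG
) -> np.ndarray:
    """Per-axis linear interpolation of (M, 3) position onto the fine grid.

    The output covers the common time span; original samples are reproduced
    exactly at their own time stamps (linear interpolation is interpolating).
    Interpolation corners are removed by the subsequent 2 Hz low-pass.
    """
    position = np.asarray(position, dtype=float)
    if position.ndim != 2 or position.shape[0] < 2:
        raise ValueError("position must have at least 2 samples")
    t_src = np.arange(position.shape[0]) / fs_src
    t_dst = np.arange(int(np.floor(t_src[-1] * fs_dst)) + 1) / fs_dst
    return np.column_stack(
        [np.interp(t_dst, t_src, position[:, ax]) for ax in range(position.shape[1])]
    )


def preprocess_recording(
    rec: Recording, median_kernel: int = 5, causal: bool = False
) -> ProcessedRecording:
    """Condition one recording end to end.

    EMG per channel: ``remove_dc`` -> ``despike`` -> ``rectify`` ->
    ``linear_envelope`` (clipped at zero: zero-phase filtering of a
    rectified signal can leave tiny negative ripple). Position: resampled to
    1 kHz then low-pass filtered per axis. The two streams are truncated to
    the shorter length so they share one time base.
    """
    env = np.empty_like(rec.emg)
    for c in range(rec.emg.shape[1]):
        x = remove_dc(rec.emg[:, c])
        x = despike(x, median_kernel)
        x = rectify(x)
        env[:, c] = linear_envelope(x, rec.fs_emg, causal=causal)
    env = np.clip(env, 0.0, None)

    pos = resample_position(rec.position, rec.fs_pos, rec.fs_emg)
    pos = linear_envelope(pos, rec.fs_emg, causal=causal)

    n = min(env.shape[0], pos.shape[0])
    return ProcessedRecording(
        envelope=env[:n],
        position_1k=pos[:n],
        task_id=rec.task_id,
        speed=rec.speed,
        trial_index=rec.trial_index,
        cycle_bounds=list(rec.cycle_bounds),
        seed=rec.seed,
        fs=rec.fs_emg,
        fs_pos_src=rec.fs_pos,
    )
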
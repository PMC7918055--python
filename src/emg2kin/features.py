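"""Windowed time-domain EMG features.

Seven classic time-domain statistics are provided — mean absolute value
(MAV), variance (VAR), root mean square (RMS), waveform length (WL),
integrated EMG (IEMG), simple square integral (SSI) and slope-sign change
count (SSC) — computed over overlapping windows of the EMG envelope. The
default working set is {RMS, IEMG} on six channels, i.e. a 12-column
feature matrix per recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import ProcessedRecording

ALL_FEATURES = ("mav", "var", "rms", "wl", "iemg", "ssi", "ssc")
WINDOW_CHOICES_MS = (50, 100, 150, 200, 250, 300)

__all__ = [
    "ALL_FEATURES",
    "WINDOW_CHOICES_MS",
    "FeatureSpec",
    "FeatureMatrix",
    "window_feature",
    "sliding_windows",
    "build_feature_matrix",
    "compare_feature_sets",
]


@dataclass(frozen=True)
class FeatureSpec:
    """Which features to extract and on what windowing grid.

    ``window_ms`` is one of 50..300 ms; ``step_ms`` defaults to 50 ms (the
    same granularity as the prediction-horizon sweep). ``ssc_threshold`` is
    the amplitude deadband of the slope-sign-change counter.
    """

    feature_set: tuple = ("rms", "iemg")
    window_ms: int = 100
    step_ms: int = 50
    ssc_threshold: float = 0.0

    def __post_init__(self):
        fs = tuple(f.lower() for f in self.feature_set)
        object.__setattr__(self, "feature_set", fs)
        if not fs:
            raise ValueError("feature_set must be non-empty")
        unknown = set(fs) - set(ALL_FEATURES)
        if unknown:
            raise ValueError(f"unknown features: {sorted(unknown)}")
        if not self.window_ms >= self.step_ms > 0:
            raise ValueError("require window_ms >= step_ms > 0")


@dataclass
class FeatureMatrix:
    """T x F feature values with window-end timestamps and column labels."""

    values: np.ndarray
    window_end_ms: np.ndarray
    columns: list = field(default_factory=list)  # (channel, feature) pairs

    def to_frame(self) -> pd.DataFrame:
        names = [f"ch{c + 1}_{f}" for c, f in self.columns]
        df = pd.DataFrame(self.values, columns=names)
        df.insert(0, "t_ms", self.window_end_ms)
        return df


def window_feature(
    window: np.ndarray, kind: str, ssc_threshold: float = 0.0
) -> float:
    """Evaluate one time-domain feature on one window.

    Definitions (x of length n):
      MAV  = mean |x|            VAR = unbiased sample variance
      RMS  = sqrt(mean x^2)      WL  = sum |x[i+1] - x[i]|
      IEMG = sum |x|             SSI = sum x^2
      SSC  = #{i : (x[i]-x[i-1])(x[i]-x[i+1]) > threshold}
    """
    x = np.asarray(window, dtype=float)
    kind = kind.lower()
    if kind not in ALL_FEATURES:
        raise ValueError(f"unknown feature kind {kind!r}")
    n_min = 3 if kind == "ssc" else 2
    if x.size < n_min:
        raise ValueError(f"{kind} needs at least {n_min} samples")
    if kind == "mav":
        return float(np.mean(np.abs(x)))
    if kind == "var":
        return float(np.var(x, ddof=1))
    if kind == "rms":
        return float(np.sqrt(np.mean(x**2)))
    if kind == "wl":
        return float(np.sum(np.abs(np.diff(x))))
    if kind == "iemg":
        return float(np.sum(np.abs(x)))
    if kind == "ssi":
        return float(np.sum(x**2))
    d1 = x[1:-1] - x[:-2]
    d2 = x[1:-1] - x[2:]
    return float(np.count_nonzero(d1 * d2 > ssc_threshold))


def sliding_windows(
    length_samples: int, window_samples: int, step_samples: int
) -> list[tuple[int, int]]:
    """Half-open index ranges [k*S, k*S + W) covering the series.

    The count is floor((N - W) / S) + 1; a window longer than the series is
    an error rather than an empty schedule.
    """
    if window_samples > length_samples:
        raise ValueError("window longer than the series")
    if step_samples <= 0 or window_samples <= 0:
        raise ValueError("window and step must be positive")
    n = (length_samples - window_samples) // step_samples + 1
    return [(k * step_samples, k * step_samples + window_samples) for k in range(n)]


def build_feature_matrix(
    proc: ProcessedRecording | np.ndarray,
    spec: FeatureSpec | None = None,
    fs: float = 1000.0,
) -> FeatureMatrix:
    """Extract the windowed feature matrix from a multichannel envelope.

    Accepts a :class:`ProcessedRecording` or a raw (N, C) array. Columns are
    channel-major, feature-minor: ch1_rms, ch1_iemg, ch2_rms, ... Window-end
    timestamps are in ms on the envelope's time base.
    """
    spec = spec or FeatureSpec()
    if isinstance(proc, ProcessedRecording):
        env, fs = proc.envelope, proc.fs
    else:
        env = np.asarray(proc, dtype=float)
    w = int(round(spec.window_ms * fs / 1000.0))
    s = int(round(spec.step_ms * fs / 1000.0))
    ranges = sliding_windows(env.shape[0], w, s)

    columns = [(c, f) for c in range(env.shape[1]) for f in spec.feature_set]
    values = np.empty((len(ranges), len(columns)))
    for r, (i0, i1) in enumerate(ranges):
        win = env[i0:i1]
        for j, (c, f) in enumerate(columns):
            values[r, j] = window_feature(win[:, c], f, spec.ssc_threshold)
    end_ms = np.array([i1 for _, i1 in ranges], dtype=float) / fs * 1000.0
    return FeatureMatrix(values=values, window_end_ms=end_ms, columns=columns)


def compare_feature_sets(
    recordings, candidate_sets, eval_fn
) -> pd.DataFrame:
    """Rank candidate feature sets by decoding performance.

    ``eval_fn(recordings, feature_set)`` must return ``(cc, nrmse)`` — in
    practice a cross-validation run from the evaluation module. Mirrors the
    selection procedure of scoring individual features first, then growing
    combinations until no further improvement. Rows sorted by CC descending.
    """
    candidate_sets = list(candidate_sets)
    if not candidate_sets:
        raise ValueError("no candidate feature sets")
    rows = []
    for cand in candidate_sets:
        cc, nrmse = eval_fn(recordings, tuple(cand))
        rows.append({"features": "+".join(cand), "cc": cc, "nrmse": nrmse})
    return (
        pd.DataFrame(rows)
        .sort_values("cc", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
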
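"""Decoding evaluation: horizon alignment, cross-validation and metrics.

The decoder is a strict prediction model: EMG features computed at time t
are mapped to the hand position at t + horizon, where the horizon (50-300
ms) trades on the electromechanical delay — muscle electrical activity
leads mechanical motion by 50-100 ms, so near-future positions are encoded
in the present EMG.

Per-cycle segments (7 s for quick motion, 9 s for slow, covering
preparation, movement and rest) are partitioned into five folds; the model
is trained on four and tested on the fifth, with the recurrent state reset
at every segment boundary. Performance is reported per axis and as the
across-axis mean of the Pearson correlation coefficient (CC) and the
normalized root-mean-square error (NRMSE = RMSE / range of the actual
series). Speed and task conditions are compared with a two-sample t-test
across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureMatrix, FeatureSpec, build_feature_matrix
from .preprocess import ProcessedRecording
from .rfnn import LearningConfig, RecurrentFuzzyRegression, RFNNResults

SEGMENT_S = {"quick": 7.0, "slow": 9.0}
HORIZONS_MS = (50, 100, 150, 200, 250, 300)

__all__ = [
    "SEGMENT_S",
    "HORIZONS_MS",
    "Segment",
    "AlignedDataset",
    "PerformanceReport",
    "segment_cycles",
    "align_for_horizon",
    "nrmse",
    "cc",
    "evaluate_fold",
    "make_cv_plan",
    "cross_validate",
    "compare_conditions",
    "horizon_sweep",
]


class DegenerateSeriesError(ValueError):
    """A metric is undefined because a series has zero variance/range."""


@dataclass
class Segment:
    """One cycle's worth of conditioned data on the 1 kHz time base."""

    envelope: np.ndarray
    position_1k: np.ndarray
    task_id: str
    speed: str
    trial_index: int
    cycle_index: int
    fs: float = 1000.0

    @property
    def cycle_uid(self) -> tuple:
        return (self.task_id, self.speed, self.trial_index, self.cycle_index)


@dataclass
class AlignedDataset:
    """Feature rows paired with future positions at a fixed horizon."""

    X: np.ndarray  # (T, F)
    Y: np.ndarray  # (T, 3) cm at window-end time + horizon
    horizon_ms: float
    window_end_ms: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.X) != len(self.Y):
            raise ValueError("X and Y must be aligned")
        if self.horizon_ms < 0:
            raise ValueError("horizon must be non-negative")


@dataclass
class PerformanceReport:
    """Per-axis and mean CC / NRMSE for one fold or condition."""

    cc_x: float
    cc_y: float
    cc_z: float
    nrmse_x: float
    nrmse_y: float
    nrmse_z: float
    condition: dict = field(default_factory=dict)

    @property
    def cc_mean(self) -> float:
        return (self.cc_x + self.cc_y + self.cc_z) / 3.0

    @property
    def nrmse_mean(self) -> float:
        return (self.nrmse_x + self.nrmse_y + self.nrmse_z) / 3.0

    def to_dict(self) -> dict:
        d = {
            "cc_x": self.cc_x, "cc_y": self.cc_y, "cc_z": self.cc_z,
            "cc_mean": self.cc_mean,
            "nrmse_x": self.nrmse_x, "nrmse_y": self.nrmse_y,
            "nrmse_z": self.nrmse_z, "nrmse_mean": self.nrmse_mean,
        }
        d.update(self.condition)
        return d


def nrmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """RMSE normalized by the range of the actual series.

    Dimensionless and scale-free, so errors are comparable across axes
    with different excursions. Undefined for a constant actual series.
    """
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size < 2 or y.size != y_hat.size:
        raise ValueError("need two aligned series of length >= 2")
    rng = y.max() - y.min()
    if rng <= 0:
        raise DegenerateSeriesError("actual series has zero range")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)) / rng)


def cc(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Pearson correlation coefficient between actual and predicted."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size < 2 or y.size != y_hat.size:
        raise ValueError("need two aligned series of length >= 2")
    dy = y - y.mean()
    dh = y_hat - y_hat.mean()
    denom = np.sqrt(np.sum(dy**2) * np.sum(dh**2))
    if denom <= 0:
        raise DegenerateSeriesError("zero-variance series")
    return float(np.clip(np.sum(dy * dh) / denom, -1.0, 1.0))


def segment_cycles(
    proc: ProcessedRecording, prep_margin_s: float = 0.5
) -> list[Segment]:
    """Cut fixed-length per-cycle segments out of a conditioned recording.

    Each segment starts ``prep_margin_s`` before the cycle onset (the
    preparation period) and lasts 7 s for quick and 9 s for slow motion —
    long enough to contain the whole cycle plus rest before the next one.
    Segments running past the end of the recording are truncated.
    """
    seg_len = int(round(SEGMENT_S[proc.speed] * proc.fs))
    onsets = proc.cycle_onsets_ms() / 1000.0 * proc.fs
    margin = int(round(prep_margin_s * proc.fs))
    out = []
    for k, onset in enumerate(onsets.astype(int)):
        i0 = max(onset - margin, 0)
        i1 = min(i0 + seg_len, proc.n_samples)
        out.append(
            Segment(
                envelope=proc.envelope[i0:i1],
                position_1k=proc.position_1k[i0:i1],
                task_id=proc.task_id,
                speed=proc.speed,
                trial_index=proc.trial_index,
                cycle_index=k,
                fs=proc.fs,
            )
        )
    return out


def align_for_horizon(
    features: FeatureMatrix,
    position_1k: np.ndarray,
    horizon_ms: float,
    fs: float = 1000.0,
    provenance: dict | None = None,
) -> AlignedDataset:
    """Pair each feature row with the position ``horizon_ms`` later.

    The target of the window ending at time t is the position sample at
    t + horizon; rows whose target falls past the end of the recording are
    dropped. All rows invalid is an error.
    """
    if horizon_ms < 0:
        raise ValueError("horizon must be non-negative")
    offs = int(round(horizon_ms * fs / 1000.0))
    # window-end times are 1-based sample counts; index of sample at t is t-1
    idx = np.round(features.window_end_ms * fs / 1000.0).astype(int) - 1 + offs
    valid = idx < position_1k.shape[0]
    if not valid.any():
        raise ValueError("horizon exceeds the recording for every row")
    return AlignedDataset(
        X=features.values[valid],
        Y=position_1k[idx[valid]],
        horizon_ms=horizon_ms,
        window_end_ms=features.window_end_ms[valid],
        provenance=provenance or {},
    )


def _segment_dataset(
    seg: Segment, spec: FeatureSpec, horizon_ms: float
) -> AlignedDataset:
    fm = build_feature_matrix(seg.envelope, spec, fs=seg.fs)
    return align_for_horizon(
        fm, seg.position_1k, horizon_ms, fs=seg.fs,
        provenance={"cycle_uid": seg.cycle_uid},
    )


def evaluate_fold(
    results: RFNNResults, test_sets: list[AlignedDataset], pooled: bool = False,
    condition: dict | None = None,
) -> PerformanceReport:
    """Score a trained model on held-out segments.

    The recurrent state resets at each test segment. By default per-axis
    metrics are computed per segment and then averaged across segments
    (robust to one bad segment); ``pooled=True`` concatenates all segments
    before computing the metrics instead.
    """
    if not test_sets:
        raise ValueError("empty test set")
    preds = results.predict([d.X for d in test_sets])
    if pooled:
        Y = np.vstack([d.Y for d in test_sets])
        P = np.vstack(preds)
        ccs = [cc(Y[:, ax], P[:, ax]) for ax in range(3)]
        errs = [nrmse(Y[:, ax], P[:, ax]) for ax in range(3)]
    else:
        per_seg = np.array(
            [
                [cc(d.Y[:, ax], p[:, ax]) for ax in range(3)]
                + [nrmse(d.Y[:, ax], p[:, ax]) for ax in range(3)]
                for d, p in zip(test_sets, preds)
            ]
        )
        m = per_seg.mean(axis=0)
        ccs, errs = m[:3], m[3:]
    return PerformanceReport(
        cc_x=ccs[0], cc_y=ccs[1], cc_z=ccs[2],
        nrmse_x=errs[0], nrmse_y=errs[1], nrmse_z=errs[2],
        condition=condition or {},
    )


def make_cv_plan(n_items: int, n_folds: int = 5, seed: int = 0) -> np.ndarray:
    """Seeded random partition of items into folds of near-equal size.

    Returns the fold index of each item; with 45 cycles and 5 folds every
    fold holds exactly 9 cycles.
    """
    if n_items < n_folds:
        raise ValueError("fewer items than folds")
    rng = np.random.default_rng(seed)
    folds = np.arange(n_items) % n_folds
    return folds[rng.permutation(n_items)]


def cross_validate(
    segments: list[Segment],
    spec: FeatureSpec | None = None,
    cfg: LearningConfig | None = None,
    horizon_ms: float = 250.0,
    n_folds: int = 5,
    seed: int = 0,
    pooled: bool = False,
) -> list[PerformanceReport]:
    """Segment-level k-fold cross-validation of the full decoder.

    Cycles are randomly partitioned into folds; for each fold the RFNN is
    trained on the remaining segments (each one an independent sequence)
    and scored on the held-out segments. Returns one report per fold;
    aggregate with :func:`summarize_reports` or a DataFrame.
    """
    spec = spec or FeatureSpec()
    cfg = cfg or LearningConfig()
    if len(segments) < n_folds:
        raise ValueError("need at least one segment per fold")
    datasets = [_segment_dataset(s, spec, horizon_ms) for s in segments]
    plan = make_cv_plan(len(segments), n_folds, seed)
    reports = []
    for fold in range(n_folds):
        train = [d for d, f in zip(datasets, plan) if f != fold]
        test = [d for d, f in zip(datasets, plan) if f == fold]
        model = RecurrentFuzzyRegression(
            [d.Y for d in train], [d.X for d in train]
        )
        res = model.fit(replace(cfg, seed=cfg.seed + fold))
        reports.append(
            evaluate_fold(
                res, test, pooled=pooled,
                condition={"fold": fold, "horizon_ms": horizon_ms},
            )
        )
    return reports


def summarize_reports(reports: list[PerformanceReport]) -> pd.DataFrame:
    """One row per report plus a 'mean' row of across-fold averages."""
    df = pd.DataFrame([r.to_dict() for r in reports])
    num = df.select_dtypes("number").mean()
    mean_row = {c: num.get(c, np.nan) for c in df.columns}
    mean_row["fold"] = "mean"
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)


def compare_conditions(
    scores_a, scores_b, welch: bool = False
) -> tuple[float, float]:
    """Two-sample t-test on a per-fold metric between two conditions.

    Pooled-variance (classic) by default; ``welch=True`` drops the
    equal-variance assumption. Returns ``(t, two-sided p)``.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two scores per condition")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0  # identical constant samples: no evidence either way
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    if not (np.isfinite(t) and np.isfinite(p)):
        raise DegenerateSeriesError("degenerate variance in t-test")
    return float(t), float(p)


def horizon_sweep(
    segments: list[Segment],
    spec: FeatureSpec | None = None,
    cfg: LearningConfig | None = None,
    horizons_ms=HORIZONS_MS,
    n_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validate at each prediction horizon; one row per horizon.

    Columns are the across-fold mean CC and NRMSE. Performance typically
    declines once the horizon outruns the electromechanical lead.
    """
    rows = []
    for h in horizons_ms:
        reports = cross_validate(
            segments, spec, cfg, horizon_ms=h, n_folds=n_folds, seed=seed
        )
        rows.append(
            {
                "horizon_ms": h,
                "cc_mean": float(np.mean([r.cc_mean for r in reports])),
                "nrmse_mean": float(np.mean([r.nrmse_mean for r in reports])),
            }
        )
    return pd.DataFrame(rows)
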
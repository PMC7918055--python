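"""Synthetic synchronized surface-EMG and 3-D hand-position recordings.

The generator emulates the statistical structure a myoelectric kinematic
decoder relies on: six EMG channels whose amplitude envelopes *lead* the hand
motion by an electromechanical delay of 50-100 ms, cyclic reach trajectories
confined to a task workspace, two movement speeds, and a trial structure of
repeated cycles separated by rest breaks.

Two task archetypes are provided: a pick-and-pour motion inside a
10 x 45 x 50 cm workspace and an obstacle-avoidance path inside a
20 x 30 x 20 cm workspace. Cycles take ~3 s (quick) or ~5 s (slow), five
cycles per trial with 3 s breaks, nine trials per task x speed by default.

Hand paths are piecewise minimum-jerk polynomials through task waypoints;
EMG is a band-limited Gaussian carrier amplitude-modulated by a linear
mixture of rectified kinematic drivers evaluated *ahead* of the motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

FS_EMG = 1000.0  #: EMG sample rate, Hz
FS_POS = 60.0  #: position sample rate, Hz
N_CHANNELS = 6
SPEEDS = ("quick", "slow")

__all__ = [
    "TaskProfile",
    "SynergyModel",
    "Recording",
    "ExperimentConfig",
    "task_profile",
    "generate_trajectory",
    "generate_emg",
    "generate_recording",
    "generate_experiment",
    "FS_EMG",
    "FS_POS",
    "N_CHANNELS",
    "SPEEDS",
]


class SpeedError(ValueError):
    """Raised for an unknown movement-speed label."""


@dataclass(frozen=True)
class TaskProfile:
    """Geometry and timing of one cyclic manipulation task.

    Parameters
    ----------
    task_id : str
        ``"Task_1"`` (pick/pour) or ``"Task_2"`` (obstacle path), or any
        user-defined label.
    waypoints : ndarray, shape (P, 3)
        Ordered 3-D via-points of one cycle, in cm. A cycle traverses them
        in order; profiles whose last waypoint equals the first produce
        closed loops so rest breaks hold the start position.
    workspace_extent : ndarray, shape (3,)
        Axis-aligned bounding box of the task, in cm.
    cycle_duration_s : dict
        Seconds per cycle for each speed label, e.g. ``{"quick": 3.0,
        "slow": 5.0}``.
    break_s : float
        Rest between consecutive cycles, seconds.
    cycles_per_trial : int
        Number of repetitions per trial.
    """

    task_id: str
    waypoints: np.ndarray
    workspace_extent: np.ndarray
    cycle_duration_s: dict = field(
        default_factory=lambda: {"quick": 3.0, "slow": 5.0}
    )
    break_s: float = 3.0
    cycles_per_trial: int = 5

    def __post_init__(self):
        wp = np.asarray(self.waypoints, dtype=float)
        ext = np.asarray(self.workspace_extent, dtype=float)
        object.__setattr__(self, "waypoints", wp)
        object.__setattr__(self, "workspace_extent", ext)
        if wp.ndim != 2 or wp.shape[1] != 3 or wp.shape[0] < 2:
            raise ValueError("waypoints must be (P>=2, 3)")
        if np.any(wp < 0) or np.any(wp > ext):
            raise ValueError("waypoints must lie inside the workspace box")
        if not self.cycle_duration_s["quick"] < self.cycle_duration_s["slow"]:
            raise ValueError("quick cycles must be shorter than slow cycles")


def task_profile(task_id: str) -> TaskProfile:
    """Return the built-in profile for ``"Task_1"`` or ``"Task_2"``.

    Task_1 mimics picking a bottle from the table and pouring it into a cup
    (workspace 10 x 45 x 50 cm); Task_2 a manipulation path among obstacles
    (20 x 30 x 20 cm). Waypoints form non-self-retracing loops so that the
    kinematic signature of each movement phase is distinct.
    """
    if task_id == "Task_1":
        ext = np.array([10.0, 45.0, 50.0])
        wp = np.array(
            [
                [5.0, 5.0, 5.0],    # rest / reach start
                [8.0, 20.0, 8.0],   # bottle on the table
                [7.0, 25.0, 35.0],  # lift
                [3.0, 38.0, 45.0],  # above the cup
                [2.0, 40.0, 30.0],  # pour (tilt down)
                [6.0, 22.0, 20.0],  # set back
                [5.0, 5.0, 5.0],    # return to start
            ]
        )
    elif task_id == "Task_2":
        ext = np.array([20.0, 30.0, 20.0])
        wp = np.array(
            [
                [3.0, 3.0, 3.0],
                [10.0, 8.0, 15.0],   # over first obstacle
                [17.0, 14.0, 4.0],   # dip between obstacles
                [12.0, 22.0, 16.0],  # over second obstacle
                [5.0, 27.0, 6.0],    # goal
                [2.0, 15.0, 12.0],   # return leg, different corridor
                [3.0, 3.0, 3.0],
            ]
        )
    else:
        raise ValueError(f"unknown task_id {task_id!r}")
    return TaskProfile(task_id=task_id, waypoints=wp, workspace_extent=ext)


@dataclass(frozen=True)
class SynergyModel:
    """Linear synergy mapping kinematic drivers to EMG channel activations.

    Each channel's activation is ``baseline + mapping @ drivers`` where the
    four drivers are the rectified per-axis velocities and the overall speed
    of the hand, evaluated ``electromechanical_lead_ms`` *ahead* of the
    current time — muscle electrical activity precedes mechanical tension by
    50-100 ms, which is the property a prediction-horizon decoder exploits.
    """

    mapping_matrix: np.ndarray  # (6, K) gains, activation units per (cm/s)
    electromechanical_lead_ms: float = 75.0
    carrier_band_hz: tuple = (20.0, 450.0)
    baseline_amplitude: float = 1.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        m = np.atleast_2d(np.asarray(self.mapping_matrix, dtype=float))
        object.__setattr__(self, "mapping_matrix", m)
        if not 50.0 <= self.electromechanical_lead_ms <= 100.0:
            raise ValueError(
                "electromechanical_lead_ms must lie in [50, 100] ms"
            )
        lo, hi = self.carrier_band_hz
        if not 0.0 < lo < hi < FS_EMG / 2:
            raise ValueError("carrier band must lie inside (0, 500) Hz")
        if m.shape[0] != N_CHANNELS or np.any(np.all(m == 0.0, axis=1)):
            raise ValueError("mapping must have a nonzero entry per channel")

    @classmethod
    def default(cls, seed: int = 0) -> "SynergyModel":
        """Seeded 6 x 4 synergy with gains sized for tabletop reach speeds.

        Hand speeds for the built-in tasks peak near 50-100 cm/s. Resting
        surface EMG is largely silent — the tonic baseline is a small
        fraction of a movement burst — so the baseline is set to 0.3 with
        velocity gains of a few hundredths per (cm/s), making bursts several
        times the resting level as in real recordings.
        """
        rng = np.random.default_rng(seed)
        gains = rng.uniform(0.01, 0.06, size=(N_CHANNELS, 4))
        # antagonist-style sign structure is unnecessary: drivers are
        # already rectified, so all-positive gains keep activation >= 0
        return cls(mapping_matrix=gains, baseline_amplitude=0.3, seed=seed)


@dataclass
class Recording:
    """One synchronized trial: raw EMG at 1 kHz plus 3-D position at 60 Hz.

    ``emg`` is (N, 6) in arbitrary amplitude units, ``position`` is (M, 3)
    in cm; both start at ``t0`` and span the same duration to within one
    position sample. ``cycle_bounds`` holds (start, end) position-sample
    indices of each movement cycle.
    """

    emg: np.ndarray
    position: np.ndarray
    task_id: str
    speed: str
    trial_index: int
    cycle_bounds: list
    seed: int = 0
    t0: float = 0.0
    fs_emg: float = FS_EMG
    fs_pos: float = FS_POS

    def __post_init__(self):
        self.emg = np.asarray(self.emg, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if self.emg.ndim != 2 or self.emg.shape[1] != N_CHANNELS:
            raise ValueError("emg must be (N, 6)")
        if self.position.ndim != 2 or self.position.shape[1] != 3:
            raise ValueError("position must be (M, 3)")
        dur_e = self.emg.shape[0] / self.fs_emg
        dur_p = self.position.shape[0] / self.fs_pos
        if abs(dur_e - dur_p) > 1.0 / self.fs_pos:
            raise ValueError("EMG and position durations disagree")
        b = np.asarray(self.cycle_bounds, dtype=int).reshape(-1, 2)
        if np.any(b[:, 0] >= b[:, 1]) or np.any(b < 0) or np.any(
            b > self.position.shape[0]
        ):
            raise ValueError("cycle bounds must be increasing and in range")

    @property
    def duration_s(self) -> float:
        return self.position.shape[0] / self.fs_pos


def _minimum_jerk_profile(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile s(tau) on [0, 1]."""
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _quintic_segment(p0, p1, v0, v1, T, tau):
    """Minimum-jerk (quintic) segment with given end positions/velocities.

    Accelerations are zero at both ends; ``v0``/``v1`` are physical
    velocities (cm/s) and ``tau`` is normalized time in [0, 1]. For
    ``v0 = v1 = 0`` this reduces to the classic rest-to-rest profile.
    """
    # conditions in normalized time: p(0), p'(0)=v0*T, p''(0)=0, and at 1
    d0, d1 = v0 * T, v1 * T
    c0 = p0
    c1 = d0
    c2 = np.zeros_like(p0)
    # solve for c3..c5 from the tau=1 conditions
    rhs1 = p1 - (c0 + c1 + c2)
    rhs2 = d1 - (c1 + 2 * c2)
    rhs3 = -(2 * c2)
    # [[1,1,1],[3,4,5],[6,12,20]] @ [c3,c4,c5] = [rhs1,rhs2,rhs3]
    c3 = 10 * rhs1 - 4 * rhs2 + 0.5 * rhs3
    c4 = -15 * rhs1 + 7 * rhs2 - rhs3
    c5 = 6 * rhs1 - 3 * rhs2 + 0.5 * rhs3
    tau = tau[:, None]
    return (
        c0 + c1 * tau + c2 * tau**2 + c3 * tau**3 + c4 * tau**4 + c5 * tau**5
    )


def _cycle_path(waypoints: np.ndarray, t: np.ndarray, duration: float):
    """Smooth minimum-jerk path through ``waypoints`` over ``duration``.

    Each inter-waypoint leg is a quintic (minimum-jerk) segment; interior
    waypoints carry finite-difference (Catmull-Rom) velocities so the hand
    flows *through* via-points without stopping — natural reaching stops
    only at the cycle's start and end. Segment durations are allotted
    proportionally to inter-waypoint distance (with a small floor so
    coincident waypoints still get time), keeping peak speeds comparable
    across segments.
    """
    seg = np.diff(waypoints, axis=0)
    dist = np.linalg.norm(seg, axis=1)
    weights = dist + 0.05 * max(dist.sum(), 1e-9)
    seg_dur = duration * weights / weights.sum()
    edges = np.concatenate([[0.0], np.cumsum(seg_dur)])
    edges[-1] = duration  # guard rounding

    n_wp = waypoints.shape[0]
    vel = np.zeros_like(waypoints)
    for i in range(1, n_wp - 1):
        vel[i] = (waypoints[i + 1] - waypoints[i - 1]) / (
            seg_dur[i - 1] + seg_dur[i]
        )

    pos = np.empty((t.size, 3))
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(dist) - 1)
    for k in range(len(dist)):
        sel = idx == k
        if not np.any(sel):
            continue
        tau = np.clip((t[sel] - edges[k]) / seg_dur[k], 0.0, 1.0)
        pos[sel] = _quintic_segment(
            waypoints[k], waypoints[k + 1], vel[k], vel[k + 1], seg_dur[k], tau
        )
    return pos


def generate_trajectory(
    profile: TaskProfile,
    speed: str,
    seed: int = 0,
    jitter_frac: float = 0.01,
) -> tuple[np.ndarray, list]:
    """Synthesize one trial's 60 Hz hand path.

    Each cycle is a piecewise minimum-jerk traversal of the profile's
    waypoints taking ``cycle_duration_s[speed]`` seconds; cycles are
    separated by ``break_s`` of rest holding the cycle end position. Every
    cycle's waypoints receive a small seeded Gaussian perturbation
    (``jitter_frac`` of the workspace extent per axis, capped at 2%) so
    repetitions are similar but not identical, as in real motor behaviour.

    Returns
    -------
    position : ndarray, shape (M, 3)
        Hand position in cm at 60 Hz.
    cycle_bounds : list of (int, int)
        Position-sample index range of each movement cycle.
    """
    if speed not in SPEEDS:
        raise SpeedError(f"speed must be one of {SPEEDS}, got {speed!r}")
    if not 0.0 <= jitter_frac <= 0.02:
        raise ValueError("jitter_frac must lie in [0, 0.02]")
    rng = np.random.default_rng(seed)
    cyc_s = profile.cycle_duration_s[speed]
    n_cyc = profile.cycles_per_trial
    total = n_cyc * cyc_s + (n_cyc - 1) * profile.break_s
    t = np.arange(np.ceil(total * FS_POS)) / FS_POS

    pos = np.tile(profile.waypoints[0], (t.size, 1))
    bounds = []
    t_cursor = 0.0
    for _ in range(n_cyc):
        wp = profile.waypoints + jitter_frac * profile.workspace_extent * (
            rng.standard_normal(profile.waypoints.shape)
        )
        wp = np.clip(wp, 0.0, profile.workspace_extent)
        # endpoints stay exact so cycles begin and end at the nominal pose
        wp[0] = profile.waypoints[0]
        wp[-1] = profile.waypoints[-1]
        sel = (t >= t_cursor) & (t < t_cursor + cyc_s)
        i0 = int(np.searchsorted(t, t_cursor))
        i1 = i0 + int(np.count_nonzero(sel))
        pos[sel] = _cycle_path(wp, t[sel] - t_cursor, cyc_s)
        pos[i1:] = wp[-1]  # hold end pose through the break
        bounds.append((i0, i1))
        t_cursor += cyc_s + profile.break_s
    # via-point velocities can overshoot the box by a hair; keep the
    # invariant that the hand stays inside the task workspace
    np.clip(pos, 0.0, profile.workspace_extent, out=pos)
    return pos, bounds


def _bandlimited_carrier(n: int, band: tuple, fs: float, rng) -> np.ndarray:
    """Gaussian noise band-passed to ``band`` and scaled to unit mean |x|.

    Unit mean absolute value makes the 2 Hz linear envelope of
    ``activation * carrier`` an unbiased estimate of the activation itself.
    """
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    return x / np.mean(np.abs(x))


def generate_emg(
    position: np.ndarray,
    synergy: SynergyModel,
    fs_pos: float = FS_POS,
    return_activation: bool = False,
):
    """Synthesize 1 kHz six-channel EMG driven by a 60 Hz hand path.

    The trajectory is upsampled to 1 kHz; the drivers are the rectified
    per-axis velocities plus overall speed (K = 4). Channel activation is
    ``baseline + mapping @ drivers`` evaluated ``electromechanical_lead_ms``
    in the future (activation leads motion), then multiplied by a
    band-limited Gaussian carrier and contaminated with white sensor noise.

    Returns (N, 6) EMG, or ``(emg, activation)`` when ``return_activation``.
    """
    position = np.asarray(position, dtype=float)
    if position.ndim != 2 or position.shape[0] < 2:
        raise ValueError("position must be a non-empty (M, 3) series")
    rng = np.random.default_rng(synergy.seed)

    dur = position.shape[0] / fs_pos
    n = int(round(dur * FS_EMG))
    t_fine = np.arange(n) / FS_EMG
    t_coarse = np.arange(position.shape[0]) / fs_pos
    pos_fine = np.column_stack(
        [np.interp(t_fine, t_coarse, position[:, ax]) for ax in range(3)]
    )
    vel = np.gradient(pos_fine, 1.0 / FS_EMG, axis=0)  # cm/s
    drivers = np.column_stack([np.abs(vel), np.linalg.norm(vel, axis=1)])

    lead = int(round(synergy.electromechanical_lead_ms * FS_EMG / 1000.0))
    led = np.vstack([drivers[lead:], np.repeat(drivers[-1:], lead, axis=0)])
    activation = synergy.baseline_amplitude + led @ synergy.mapping_matrix.T

    emg = np.empty_like(activation)
    for c in range(N_CHANNELS):
        carrier = _bandlimited_carrier(n, synergy.carrier_band_hz, FS_EMG, rng)
        emg[:, c] = activation[:, c] * carrier
    emg += synergy.noise_sd * rng.standard_normal(emg.shape)
    if return_activation:
        return emg, activation
    return emg


def generate_recording(
    profile: TaskProfile,
    speed: str,
    trial_index: int,
    synergy: SynergyModel,
    seed: int = 0,
    jitter_frac: float = 0.01,
) -> Recording:
    """Generate one complete synchronized trial."""
    pos, bounds = generate_trajectory(profile, speed, seed, jitter_frac)
    emg = generate_emg(pos, replace(synergy, seed=seed))
    return Recording(
        emg=emg,
        position=pos,
        task_id=profile.task_id,
        speed=speed,
        trial_index=trial_index,
        cycle_bounds=bounds,
        seed=seed,
    )


@dataclass
class ExperimentConfig:
    """Layout of a full synthetic experiment.

    The default reproduces the study design: 2 tasks x 2 speeds x 9 trials
    = 36 recordings, each with 5 cycles.
    """

    tasks: tuple = ("Task_1", "Task_2")
    speeds: tuple = SPEEDS
    trials_per_condition: int = 9
    master_seed: int = 0
    electromechanical_lead_ms: float = 75.0
    noise_sd: float = 0.05
    jitter_frac: float = 0.01


def generate_experiment(config: ExperimentConfig | None = None) -> list:
    """Generate every recording of an experiment.

    Per-trial seeds are drawn deterministically from the master seed via
    ``numpy.random.SeedSequence`` spawning, so the whole experiment is
    reproducible from a single integer while trials stay independent.
    """
    config = config or ExperimentConfig()
    n = len(config.tasks) * len(config.speeds) * config.trials_per_condition
    children = np.random.SeedSequence(config.master_seed).spawn(n + 1)
    synergy = SynergyModel.default(
        seed=int(children[-1].generate_state(1)[0] % 2**31)
    )
    synergy = replace(
        synergy, electromechanical_lead_ms=config.electromechanical_lead_ms,
        noise_sd=config.noise_sd,
    )
    recordings = []
    k = 0
    for task in config.tasks:
        profile = task_profile(task)
        for speed in config.speeds:
            for trial in range(config.trials_per_condition):
                seed = int(children[k].generate_state(1)[0] % 2**31)
                recordings.append(
                    generate_recording(
                        profile, speed, trial, synergy, seed,
                        config.jitter_frac,
                    )
                )
                k += 1
    return recordings
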
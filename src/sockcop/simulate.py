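"""Synthetic paired sock/platform recordings of squat exercises.

The study data this pipeline targets are paired recordings of two
warm-up/screening movements — a unilateral single-leg squat (10 repetitions
per leg at a 60 bpm metronome) and a bilateral squat with heel raise (30 s
continuous) — captured simultaneously by a six-sensor textile sock and a
force platform.  This module generates such pairs with the statistical
structure the analysis assumes, so every pipeline stage is testable without
real recordings:

* a ground-truth CoP trajectory: a periodic anteroposterior excursion at
  the metronome tempo, slower mediolateral sway, and band-limited noise,
  with amplitudes matching the observed excursion ranges (X within
  +/-20 mm; Y within +/-40 mm unilateral, [-50, +60] mm bilateral), and a
  3 s near-zero-load leg-lift marker at the start of each set;
* a textile-sensor forward model: the true CoP is converted to six
  nonnegative sensor pressures by barycentric weighting over a fan
  triangulation of the sensor hull (exactly consistent with the weighted
  centroid reconstruction), then to conductances with per-application
  sensitivity draws in 0.5-3.0 uS/kPa, placement jitter, baseline,
  saturation and noise;
* a platform model: the truth plus an absolute foot-placement offset,
  Gaussian noise, a clock lag, and optionally an abrupt mid-trial
  baseline-shift ("side-step") event.

Every trial stores the ground truth and all drawn parameters, so recovery
can be asserted, and the whole study is reproducible from one seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.spatial import ConvexHull

from .geometry import (
    N_SENSORS,
    ConductanceSeries,
    CoPSeries,
    SensorGeometry,
    default_geometry,
)
from .preprocess import _phase_grid

__all__ = [
    "TrialSpec",
    "TrajectoryParams",
    "SensorModel",
    "SockApplication",
    "PlatformModel",
    "SideStep",
    "StudyDesign",
    "Trial",
    "Study",
    "simulate_true_cop",
    "distribute_load",
    "draw_application",
    "simulate_sock",
    "simulate_platform",
    "generate_study",
    "sidestep_trial",
]

SINGLE_LEG = "single_leg_squat"
BOTH_LEG = "both_leg_squat_heel_raise"
EXERCISES = (SINGLE_LEG, BOTH_LEG)


@dataclass(frozen=True)
class TrialSpec:
    """Protocol parameters for one exercise set.

    The unilateral squat is specified by a repetition count (default 10,
    one repetition per metronome beat at 60 bpm); the bilateral squat with
    heel raise by a fixed duration (default 30 s).  Each set starts with a
    ~3 s leg-lift marker used for synchronization.
    """

    exercise: str
    foot: str = "right"
    repetitions: int | None = None
    duration_s: float | None = None
    tempo_bpm: float = 60.0
    marker_duration_s: float = 3.0

    def __post_init__(self) -> None:
        if self.exercise not in EXERCISES:
            raise ValueError(f"unknown exercise {self.exercise!r}")
        if self.foot not in ("left", "right"):
            raise ValueError("foot must be 'left' or 'right'")
        if self.tempo_bpm <= 0:
            raise ValueError("tempo must be positive")
        if self.exercise == SINGLE_LEG:
            if self.repetitions is None or self.duration_s is not None:
                raise ValueError("single-leg squat takes repetitions, not duration")
            if self.repetitions <= 0:
                raise ValueError("repetitions must be positive")
        else:
            if self.duration_s is None or self.repetitions is not None:
                raise ValueError("bilateral squat takes a duration, not repetitions")
            if self.duration_s <= 0:
                raise ValueError("duration must be positive")

    @classmethod
    def single_leg(cls, foot: str = "right", repetitions: int = 10, **kw) -> "TrialSpec":
        return cls(SINGLE_LEG, foot=foot, repetitions=repetitions, **kw)

    @classmethod
    def both_leg(cls, foot: str = "right", duration_s: float = 30.0, **kw) -> "TrialSpec":
        return cls(BOTH_LEG, foot=foot, duration_s=duration_s, **kw)

    @property
    def exercise_duration_s(self) -> float:
        if self.exercise == SINGLE_LEG:
            return self.repetitions * 60.0 / self.tempo_bpm
        return float(self.duration_s)


@dataclass(frozen=True)
class TrajectoryParams:
    """Amplitudes and noise of the ground-truth CoP trajectory (mm, Hz).

    The anteroposterior excursion tracks the squat cycle at the metronome
    frequency; the mediolateral sway is a slower oscillation; band-limited
    noise models trial-to-trial balance adjustments.  ``x_bounds`` /
    ``y_bounds`` clip the trajectory to the excursion box the exercise is
    known to occupy (which also keeps it inside the sensor hull).
    """

    x_amp_mm: float
    x_freq_hz: float
    y_amp_mm: float
    y_offset_mm: float
    noise_sd_mm: float
    noise_cutoff_hz: float
    x_bounds: tuple[float, float]
    y_bounds: tuple[float, float]

    @classmethod
    def for_exercise(cls, exercise: str) -> "TrajectoryParams":
        if exercise == SINGLE_LEG:
            return cls(
                x_amp_mm=12.0, x_freq_hz=0.25,
                y_amp_mm=30.0, y_offset_mm=0.0,
                noise_sd_mm=2.0, noise_cutoff_hz=3.0,
                x_bounds=(-20.0, 20.0), y_bounds=(-40.0, 40.0),
            )
        return cls(
            x_amp_mm=12.0, x_freq_hz=0.2,
            y_amp_mm=50.0, y_offset_mm=5.0,
            noise_sd_mm=2.0, noise_cutoff_hz=3.0,
            x_bounds=(-20.0, 20.0), y_bounds=(-50.0, 60.0),
        )

    @classmethod
    def silent(cls) -> "TrajectoryParams":
        """All-zero trajectory (degenerate reference case)."""
        return cls(0.0, 0.25, 0.0, 0.0, 0.0, 3.0, (-20.0, 20.0), (-50.0, 60.0))


def _band_limited_noise(
    n: int, rate_hz: float, sd: float, cutoff_hz: float, rng: np.random.Generator
) -> np.ndarray:
    if sd == 0 or n < 20:
        return np.zeros(n)
    cutoff = min(cutoff_hz, 0.45 * rate_hz)
    sos = sps.butter(4, cutoff, fs=rate_hz, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    s = x.std()
    return x * (sd / s) if s > 0 else np.zeros(n)


def simulate_true_cop(
    spec: TrialSpec,
    params: TrajectoryParams | None = None,
    seed: int | np.random.Generator | None = None,
    rate_hz: float = 125.0,
) -> CoPSeries:
    """Ground-truth CoP trajectory for one exercise set.

    The series starts with the spec's leg-lift marker window (near-zero
    load, flagged invalid) followed by the exercise proper.  Identical
    seeds give identical series.
    """
    if params is None:
        params = TrajectoryParams.for_exercise(spec.exercise)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total_s = spec.marker_duration_s + spec.exercise_duration_s
    n = int(round(total_s * rate_hz)) + 1
    t = np.arange(n) / rate_hz
    te = t - spec.marker_duration_s
    valid = te >= 0

    f_y = spec.tempo_bpm / 60.0
    phase = rng.uniform(0, 2 * np.pi)
    y = params.y_offset_mm + params.y_amp_mm * np.sin(2 * np.pi * f_y * te)
    x = params.x_amp_mm * np.sin(2 * np.pi * params.x_freq_hz * te + phase)
    x = x + _band_limited_noise(n, rate_hz, params.noise_sd_mm, params.noise_cutoff_hz, rng)
    y = y + _band_limited_noise(n, rate_hz, params.noise_sd_mm, params.noise_cutoff_hz, rng)
    x = np.clip(x, *params.x_bounds)
    y = np.clip(y, *params.y_bounds)
    x[~valid] = 0.0
    y[~valid] = 0.0
    return CoPSeries(
        t=t, x=x, y=y, source="truth", valid=valid,
        annotations={"exercise": spec.exercise, "foot": spec.foot},
    )


def _fan_triangles(geometry: SensorGeometry) -> tuple[np.ndarray, ConvexHull]:
    hull = ConvexHull(geometry.positions_mm)
    v = hull.vertices  # counterclockwise order, deterministic
    tris = np.array([(v[0], v[i], v[i + 1]) for i in range(1, len(v) - 1)])
    return tris, hull


def distribute_load(
    cop_xy: np.ndarray,
    total_pressure_kpa: float | np.ndarray,
    geometry: SensorGeometry | None = None,
    scheme: str = "barycentric",
    sigma_mm: float = 60.0,
) -> np.ndarray:
    """Invert the weighted-centroid map: CoP -> six nonnegative pressures.

    The inverse problem is under-determined (six unknowns, three
    constraints); the default ``barycentric`` scheme places all load on
    the three sensors of the fan-triangulation triangle containing the
    point, with barycentric weights — deterministic, nonnegative, and the
    weighted centroid of the result reproduces the input CoP exactly.
    The ``gaussian`` scheme spreads load over all sensors with weights
    ``exp(-d^2 / 2 sigma^2)`` (smoother, physically more plausible, but
    the round trip is only approximate).

    Parameters
    ----------
    cop_xy : array of shape (2,) or (N, 2)
        Target CoP points (mm); must lie inside the sensor convex hull.
    total_pressure_kpa : float or array of shape (N,)
        Total pressure to distribute at each sample.

    Returns
    -------
    ndarray of shape (6,) or (N, 6), matching the input.
    """
    if geometry is None:
        geometry = default_geometry()
    pts = np.atleast_2d(np.asarray(cop_xy, dtype=float))
    if pts.shape[1] != 2:
        raise ValueError("cop_xy must have shape (2,) or (N, 2)")
    total = np.broadcast_to(np.asarray(total_pressure_kpa, dtype=float), (pts.shape[0],))
    weights = np.zeros((pts.shape[0], N_SENSORS))

    if scheme == "gaussian":
        d2 = ((pts[:, None, :] - geometry.positions_mm[None, :, :]) ** 2).sum(axis=2)
        w = np.exp(-d2 / (2 * sigma_mm**2))
        weights = w / w.sum(axis=1, keepdims=True)
    elif scheme == "barycentric":
        tris, _ = _fan_triangles(geometry)
        tol = 1e-9
        unassigned = np.ones(pts.shape[0], dtype=bool)
        for tri in tris:
            a, b, c = geometry.positions_mm[tri]
            m = np.column_stack([b - a, c - a])  # 2x2
            rhs = pts - a
            bc = rhs @ np.linalg.inv(m).T  # (N, 2): weights of b and c
            w0 = 1.0 - bc.sum(axis=1)
            inside = unassigned & (bc[:, 0] >= -tol) & (bc[:, 1] >= -tol) & (w0 >= -tol)
            if inside.any():
                tri_w = np.clip(np.column_stack([w0, bc])[inside], 0.0, None)
                tri_w /= tri_w.sum(axis=1, keepdims=True)
                for col, sensor in enumerate(tri):
                    weights[inside, sensor] = tri_w[:, col]
                unassigned &= ~inside
        if unassigned.any():
            i = int(np.flatnonzero(unassigned)[0])
            raise ValueError(
                f"CoP point {tuple(pts[i])} lies outside the sensor convex hull"
            )
    else:
        raise ValueError("scheme must be 'barycentric' or 'gaussian'")

    pressures = weights * total[:, None]
    return pressures[0] if np.asarray(cop_xy).ndim == 1 else pressures


@dataclass(frozen=True)
class SensorModel:
    """Textile-sensor response model for one sock design.

    Sensitivity (uS/kPa) is drawn per sensor per sock application from
    ``sensitivity_range`` — putting the sock on strains the knit and
    changes each sensor's gain — and sensor positions get Gaussian
    placement jitter per application.  Conductance saturates at a ceiling
    (hard clip) and carries additive Gaussian noise above a baseline.
    """

    sensitivity_range: tuple[float, float] = (0.5, 3.0)
    baseline_uS: float = 0.5
    saturation_uS: float = 400.0
    noise_sd_uS: float = 0.5
    placement_jitter_sd_mm: float = 2.0
    total_pressure_kpa: float = 100.0

    def __post_init__(self) -> None:
        lo, hi = self.sensitivity_range
        if not 0 < lo <= hi:
            raise ValueError("sensitivity range must be positive and ordered")
        if self.baseline_uS < 0 or self.saturation_uS <= self.baseline_uS:
            raise ValueError("need saturation > baseline >= 0")
        if self.noise_sd_uS < 0 or self.placement_jitter_sd_mm < 0:
            raise ValueError("noise and jitter must be nonnegative")
        if self.total_pressure_kpa <= 0:
            raise ValueError("total pressure must be positive")

    @classmethod
    def ideal(cls) -> "SensorModel":
        """Noiseless, equal-gain, jitter-free sensors (exact round trip)."""
        return cls(
            sensitivity_range=(1.5, 1.5), baseline_uS=0.0,
            saturation_uS=math.inf, noise_sd_uS=0.0,
            placement_jitter_sd_mm=0.0,
        )


@dataclass(frozen=True)
class SockApplication:
    """Parameters drawn for one putting-on of the sock."""

    sensitivities_uS_per_kpa: np.ndarray  # (6,)
    geometry: SensorGeometry              # jittered (and possibly scaled)


def draw_application(
    model: SensorModel,
    geometry: SensorGeometry,
    rng: np.random.Generator,
) -> SockApplication:
    sens = rng.uniform(*model.sensitivity_range, size=N_SENSORS)
    offsets = rng.normal(0.0, model.placement_jitter_sd_mm, size=(N_SENSORS, 2))
    return SockApplication(sens, geometry.jittered(offsets))


def simulate_sock(
    truth: CoPSeries,
    model: SensorModel,
    geometry: SensorGeometry | None = None,
    rate_hz: float = 125.0,
    seed: int | np.random.Generator | None = None,
    application: SockApplication | None = None,
    scheme: str = "barycentric",
) -> ConductanceSeries:
    """Forward-simulate the six sock conductance channels from true CoP.

    The true CoP is sampled on the sock's clock (up to 200 Hz), converted
    to per-sensor pressures at the *applied* (jittered) sensor positions
    via :func:`distribute_load`, then to conductance::

        u_i = baseline + min(sensitivity_i * p_i, saturation) + noise

    clipped at zero.  Invalid truth samples (no contact) produce baseline
    and noise only.  If no ``application`` is given, one is drawn from
    ``seed``.
    """
    if not 0 < rate_hz <= 200.0:
        raise ValueError("sock sampling rate must be in (0, 200] Hz")
    if geometry is None:
        geometry = default_geometry()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if application is None:
        application = draw_application(model, geometry, rng)

    t = _phase_grid(float(truth.t[0]), float(truth.t[-1]), rate_hz)
    x = np.interp(t, truth.t, truth.x)
    y = np.interp(t, truth.t, truth.y)
    vfrac = np.interp(t, truth.t, truth.valid.astype(float))
    valid = vfrac > 1.0 - 1e-9

    pressures = np.zeros((t.size, N_SENSORS))
    if valid.any():
        pressures[valid] = distribute_load(
            np.column_stack([x, y])[valid],
            model.total_pressure_kpa,
            application.geometry,
            scheme=scheme,
        )
    loaded = np.minimum(
        pressures * application.sensitivities_uS_per_kpa, model.saturation_uS
    )
    u = model.baseline_uS + loaded
    if model.noise_sd_uS > 0:
        u = u + rng.normal(0.0, model.noise_sd_uS, size=u.shape)
    u = np.clip(u, 0.0, None)
    ann = truth.annotations
    return ConductanceSeries(
        t=t, values=u,
        foot=ann.get("foot", "right"),
        participant=ann.get("participant"),
        exercise=ann.get("exercise"),
        repetition=ann.get("repetition"),
    )


@dataclass(frozen=True)
class SideStep:
    """Abrupt foot reposition: a baseline offset from ``time_s`` onward."""

    time_s: float
    offset_mm: tuple[float, float]


@dataclass(frozen=True)
class PlatformModel:
    """Force-platform measurement model.

    The platform reports absolute CoP in its own global frame at 125 Hz:
    the truth plus a per-trial foot-placement offset and Gaussian noise,
    on a clock lagging the sock's by ``lag_s`` (set per trial).  An
    optional side-step event adds a second offset from its onset onward.
    """

    rate_hz: float = 125.0
    offset_mm: tuple[float, float] = (0.0, 0.0)
    noise_sd_mm: float = 1.0
    sidestep: SideStep | None = None

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("platform rate must be positive")
        if self.noise_sd_mm < 0:
            raise ValueError("noise sd must be nonnegative")


def simulate_platform(
    truth: CoPSeries,
    model: PlatformModel,
    lag_s: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> CoPSeries:
    """Platform CoP recording of a ground-truth trajectory.

    Timestamps are on the platform clock (truth time + ``lag_s``) at the
    platform rate.  The side-step onset is given in truth (trial) time.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = _phase_grid(float(truth.t[0]) + lag_s, float(truth.t[-1]) + lag_s, model.rate_hz)
    t_truth = t - lag_s
    x = np.interp(t_truth, truth.t, truth.x) + model.offset_mm[0]
    y = np.interp(t_truth, truth.t, truth.y) + model.offset_mm[1]
    vfrac = np.interp(t_truth, truth.t, truth.valid.astype(float))
    valid = vfrac > 1.0 - 1e-9
    if model.sidestep is not None:
        after = t_truth >= model.sidestep.time_s
        x[after] += model.sidestep.offset_mm[0]
        y[after] += model.sidestep.offset_mm[1]
    if model.noise_sd_mm > 0:
        x = x + rng.normal(0.0, model.noise_sd_mm, size=t.size)
        y = y + rng.normal(0.0, model.noise_sd_mm, size=t.size)
    return CoPSeries(
        t=t, x=x, y=y, source="platform", valid=valid,
        annotations=dict(truth.annotations),
    )


@dataclass(frozen=True)
class StudyDesign:
    """Factorial design of a simulated validation study.

    The default mirrors the target protocol: 10 participants x
    {unilateral squat right/left, bilateral squat-with-heel-raise
    right/left foot} x 2 sock applications, each trial yielding an X and
    a Y waveform pair — 160 pairs per modality.  A per-participant
    anthropometric scale factor perturbs the true sensor geometry
    (foot-morphology effect); per-trial draws cover sensor sensitivity
    and placement, platform foot-placement offset, and clock lag.
    """

    n_participants: int = 10
    exercises: tuple[str, ...] = EXERCISES
    feet: tuple[str, ...] = ("right", "left")
    n_applications: int = 2
    sensor_model: SensorModel = field(default_factory=SensorModel)
    platform_noise_sd_mm: float = 1.0
    offset_range_mm: float = 30.0
    lag_range_s: float = 1.0
    scale_range: tuple[float, float] = (0.92, 1.08)
    sock_rate_hz: float = 200.0
    platform_rate_hz: float = 125.0
    tempo_bpm: float = 60.0
    repetitions: int = 10
    both_leg_duration_s: float = 30.0
    marker_duration_s: float = 3.0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_applications < 1:
            raise ValueError("design must include at least one participant and application")
        if not self.exercises or not self.feet:
            raise ValueError("design must list at least one exercise and foot")

    @property
    def conditions(self) -> list[tuple[str, str]]:
        return [(ex, foot) for ex in self.exercises for foot in self.feet]

    @property
    def n_trials(self) -> int:
        return self.n_participants * len(self.conditions) * self.n_applications

    @property
    def n_waveform_pairs(self) -> int:
        return 2 * self.n_trials  # X and Y per trial

    def trial_spec(self, exercise: str, foot: str) -> TrialSpec:
        common = dict(tempo_bpm=self.tempo_bpm, marker_duration_s=self.marker_duration_s)
        if exercise == SINGLE_LEG:
            return TrialSpec.single_leg(foot, repetitions=self.repetitions, **common)
        return TrialSpec.both_leg(foot, duration_s=self.both_leg_duration_s, **common)

    @classmethod
    def ideal(cls, **kw) -> "StudyDesign":
        """Noise-free design in which sock and platform agree exactly."""
        defaults = dict(
            sensor_model=SensorModel.ideal(),
            platform_noise_sd_mm=0.0,
            offset_range_mm=0.0,
            lag_range_s=0.0,
            scale_range=(1.0, 1.0),
            sock_rate_hz=125.0,
        )
        defaults.update(kw)
        return cls(**defaults)


@dataclass(frozen=True)
class Trial:
    """One simulated exercise set with its ground truth and drawn params."""

    trial_id: str
    annotations: dict
    sock: ConductanceSeries
    platform: CoPSeries
    truth: CoPSeries
    params: dict


@dataclass(frozen=True)
class Study:
    design: StudyDesign
    seed: int
    trials: tuple[Trial, ...]

    def manifest(self) -> dict:
        """Enumerate every waveform pair (trial x axis) with its draws."""
        pairs = [
            {"trial_id": tr.trial_id, "axis": axis, **tr.annotations}
            for tr in self.trials
            for axis in ("x", "y")
        ]
        return {
            "seed": self.seed,
            "n_trials": len(self.trials),
            "n_waveform_pairs": len(pairs),
            "trials": [
                {"trial_id": tr.trial_id, **tr.annotations, "params": tr.params}
                for tr in self.trials
            ],
            "waveform_pairs": pairs,
        }


def generate_study(design: StudyDesign | None = None, seed: int = 0) -> Study:
    """Simulate the full factorial study deterministically from one seed.

    Each trial gets an independent child random stream, so the dataset is
    reproducible and insensitive to trial ordering.
    """
    if design is None:
        design = StudyDesign()
    root = np.random.SeedSequence(seed)
    participant_ss, trial_ss = root.spawn(2)
    p_streams = participant_ss.spawn(design.n_participants)
    scales = [
        float(np.random.default_rng(s).uniform(*design.scale_range)) for s in p_streams
    ]
    nominal = default_geometry()

    trials = []
    trial_streams = iter(trial_ss.spawn(design.n_trials))
    for p in range(design.n_participants):
        participant = f"P{p + 1:02d}"
        true_geometry = nominal.scaled(scales[p])
        for ex, foot in design.conditions:
            for app in range(1, design.n_applications + 1):
                rng = np.random.default_rng(next(trial_streams))
                spec = design.trial_spec(ex, foot)
                truth = simulate_true_cop(spec, seed=rng, rate_hz=design.sock_rate_hz)
                truth = truth.replace(
                    annotations={
                        "participant": participant, "exercise": ex,
                        "foot": foot, "repetition": app,
                    }
                )
                application = draw_application(design.sensor_model, true_geometry, rng)
                sock = simulate_sock(
                    truth, design.sensor_model,
                    geometry=true_geometry, rate_hz=design.sock_rate_hz,
                    seed=rng, application=application,
                )
                offset = tuple(rng.uniform(-design.offset_range_mm, design.offset_range_mm, 2))
                lag = float(rng.uniform(-design.lag_range_s, design.lag_range_s))
                platform_model = PlatformModel(
                    rate_hz=design.platform_rate_hz,
                    offset_mm=offset,
                    noise_sd_mm=design.platform_noise_sd_mm,
                )
                platform = simulate_platform(truth, platform_model, lag_s=lag, seed=rng)
                trial_id = f"{participant}_{ex}_{foot}_a{app}"
                trials.append(
                    Trial(
                        trial_id=trial_id,
                        annotations={
                            "participant": participant, "exercise": ex,
                            "foot": foot, "repetition": app,
                        },
                        sock=sock,
                        platform=platform,
                        truth=truth,
                        params={
                            "scale": scales[p],
                            "sensitivities_uS_per_kpa":
                                application.sensitivities_uS_per_kpa.tolist(),
                            "platform_offset_mm": [float(v) for v in offset],
                            "lag_s": lag,
                        },
                    )
                )
    return Study(design=design, seed=seed, trials=tuple(trials))


def sidestep_trial(
    seed: int = 0,
    offset_mm: tuple[float, float] = (40.0, 0.0),
    design: StudyDesign | None = None,
) -> Trial:
    """One bilateral-squat trial with a mid-exercise side-step event.

    The participant abruptly repositions the foot halfway through the set:
    the platform sees a sudden baseline shift in its absolute CoP, while
    the sock — fixed to the sole — does not.  Whole-waveform concordance
    collapses although within-segment tracking stays high.
    """
    if design is None:
        design = StudyDesign(
            sensor_model=SensorModel(
                sensitivity_range=(1.2, 1.8),
                noise_sd_uS=0.5,
                placement_jitter_sd_mm=1.0,
            ),
            platform_noise_sd_mm=0.5,
            lag_range_s=0.0,
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 977]))
    spec = design.trial_spec(BOTH_LEG, "right")
    truth = simulate_true_cop(spec, seed=rng, rate_hz=design.sock_rate_hz)
    truth = truth.replace(
        annotations={"participant": "S01", "exercise": BOTH_LEG,
                     "foot": "right", "repetition": 1}
    )
    application = draw_application(design.sensor_model, default_geometry(), rng)
    sock = simulate_sock(
        truth, design.sensor_model, rate_hz=design.sock_rate_hz,
        seed=rng, application=application,
    )
    onset = spec.marker_duration_s + spec.exercise_duration_s / 2.0
    platform_model = PlatformModel(
        rate_hz=design.platform_rate_hz,
        noise_sd_mm=design.platform_noise_sd_mm,
        sidestep=SideStep(time_s=onset, offset_mm=offset_mm),
    )
    platform = simulate_platform(truth, platform_model, lag_s=0.0, seed=rng)
    return Trial(
        trial_id="S01_sidestep",
        annotations=dict(truth.annotations),
        sock=sock,
        platform=platform,
        truth=truth,
        params={"sidestep_onset_s": onset, "sidestep_offset_mm": list(offset_mm)},
    )
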
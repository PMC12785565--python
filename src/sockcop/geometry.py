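"""Sensor coordinate system and center-of-pressure reconstruction.

A textile pressure-sensing sock carries six knitted conductance sensors on
the plantar surface: two under the metatarsal heads, two under the midfoot,
and two under the heel.  Each sensor's electrical conductance rises with the
pressure applied to it, so the instantaneous center of pressure (CoP) can be
estimated as the conductance-weighted centroid of the sensor positions:

    CoP = sum_i(U_i * e_i) / sum_i(U_i)

where ``U_i`` is the conductance of sensor *i* and ``e_i`` its position
vector (mm) in a sock-local frame whose X axis is mediolateral and whose
Y axis is anteroposterior.  The estimate is homogeneous of degree zero in
the conductances, so the conductance unit (mS vs uS) never matters, and it
always lies inside the convex hull of the sensor positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "SensorGeometry",
    "ConductanceSeries",
    "CoPSample",
    "CoPSeries",
    "default_geometry",
    "resistance_to_conductance",
    "compute_cop",
    "cop_series",
]

N_SENSORS = 6

#: Printed sensor positions (mm) in the sock-local frame, indexed 0-5:
#: forefoot pair, midfoot pair, heel pair.  Their centroid is the origin.
DEFAULT_SENSOR_POSITIONS_MM = (
    (50.0, 100.0),
    (-50.0, 100.0),
    (50.0, 0.0),
    (-50.0, 0.0),
    (25.0, -100.0),
    (-25.0, -100.0),
)


def _as_readonly(a: np.ndarray) -> np.ndarray:
    a = np.ascontiguousarray(a, dtype=float)
    a.flags.writeable = False
    return a


@dataclass(frozen=True)
class SensorGeometry:
    """Positions of the six sock sensors in the sock-local frame.

    Parameters
    ----------
    positions_mm : array-like of shape (6, 2)
        Sensor position vectors ``e_0 .. e_5`` in mm.  X is mediolateral
        (positive toward sensors 0/2/4), Y is anteroposterior (positive
        toward the forefoot).
    mirror_x : bool
        If True, the X axis is flipped (anatomical left-foot convention).
        The default keeps a single convention for both feet.
    """

    positions_mm: np.ndarray
    mirror_x: bool = False
    axis_labels: tuple[str, str] = ("X mediolateral", "Y anteroposterior")

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_mm, dtype=float)
        if pos.shape != (N_SENSORS, 2):
            raise ValueError(
                f"expected {N_SENSORS} sensor positions of dimension 2, "
                f"got array of shape {pos.shape}"
            )
        if not np.all(np.isfinite(pos)):
            raise ValueError("sensor positions must be finite")
        if self.mirror_x:
            pos = pos * np.array([-1.0, 1.0])
        object.__setattr__(self, "positions_mm", _as_readonly(pos))

    @property
    def centroid_mm(self) -> np.ndarray:
        return self.positions_mm.mean(axis=0)

    def scaled(self, factor: float) -> "SensorGeometry":
        """Geometry scaled about the origin (foot-morphology scale factor)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return SensorGeometry(self.positions_mm * factor)

    def jittered(self, offsets_mm: np.ndarray) -> "SensorGeometry":
        """Geometry with per-sensor placement offsets added (shape (6, 2))."""
        offsets = np.asarray(offsets_mm, dtype=float)
        if offsets.shape != (N_SENSORS, 2):
            raise ValueError("offsets must have shape (6, 2)")
        return SensorGeometry(self.positions_mm + offsets)

    def permuted(self, order: Sequence[int]) -> "SensorGeometry":
        idx = np.asarray(order)
        if sorted(idx.tolist()) != list(range(N_SENSORS)):
            raise ValueError("order must be a permutation of 0..5")
        return SensorGeometry(self.positions_mm[idx])


def default_geometry() -> SensorGeometry:
    """The printed sock sensor geometry (mm), centroid at the origin."""
    return SensorGeometry(np.array(DEFAULT_SENSOR_POSITIONS_MM))


def _validate_timestamps(t: np.ndarray, context: str) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError(f"{context}: timestamps must be a nonempty 1-D array")
    if not np.all(np.isfinite(t)):
        raise ValueError(f"{context}: timestamps must be finite")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise ValueError(
            f"{context}: timestamps must be strictly increasing "
            f"(violation at sample index {bad}, t={t[bad]!r})"
        )
    return _as_readonly(t)


@dataclass(frozen=True)
class ConductanceSeries:
    """Timestamped 6-channel sensor conductance recording for one foot.

    ``values`` has shape (N, 6); units are scale-free (nominally mS when
    converted from kOhm resistances).  Timestamps are seconds, strictly
    increasing.  All conductances must be nonnegative.
    """

    t: np.ndarray
    values: np.ndarray
    foot: str = "right"
    participant: str | None = None
    exercise: str | None = None
    repetition: int | None = None

    def __post_init__(self) -> None:
        t = _validate_timestamps(self.t, "ConductanceSeries")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != N_SENSORS:
            raise ValueError(
                f"conductance values must have shape (N, {N_SENSORS}), got {v.shape}"
            )
        if v.shape[0] != t.size:
            raise ValueError("timestamps and values disagree in length")
        if not np.all(np.isfinite(v)):
            raise ValueError("conductances must be finite")
        if np.any(v < 0):
            i, j = np.argwhere(v < 0)[0]
            raise ValueError(
                f"negative conductance in channel u{j} at t={t[i]:g} s"
            )
        if self.foot not in ("left", "right"):
            raise ValueError("foot must be 'left' or 'right'")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "values", _as_readonly(v))

    def __len__(self) -> int:
        return self.t.size

    @property
    def total(self) -> np.ndarray:
        """Summed conductance over all channels (load proxy)."""
        return self.values.sum(axis=1)


@dataclass(frozen=True)
class CoPSample:
    """One CoP estimate (mm).  ``valid`` is False for no-contact frames."""

    x: float
    y: float
    valid: bool = True

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass(frozen=True)
class CoPSeries:
    """Timestamped CoP waveform in mm with per-sample validity flags.

    Invalid samples mark intervals with no foot contact (e.g. the leg-lift
    marker, swing phases); they are flagged rather than dropped so the
    time base stays intact.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    source: str = "sock"
    valid: np.ndarray | None = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = _validate_timestamps(self.t, "CoPSeries")
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != t.shape or y.shape != t.shape:
            raise ValueError("x, y must match timestamps in shape")
        if self.source not in ("sock", "platform", "truth"):
            raise ValueError("source must be 'sock', 'platform' or 'truth'")
        valid = self.valid
        if valid is None:
            valid = np.ones(t.shape, dtype=bool)
        else:
            valid = np.asarray(valid, dtype=bool)
            if valid.shape != t.shape:
                raise ValueError("valid flags must match timestamps in shape")
        valid = valid.copy()
        valid.flags.writeable = False
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", _as_readonly(x))
        object.__setattr__(self, "y", _as_readonly(y))
        object.__setattr__(self, "valid", valid)

    def __len__(self) -> int:
        return self.t.size

    def __iter__(self) -> Iterator[CoPSample]:
        for xi, yi, vi in zip(self.x, self.y, self.valid):
            yield CoPSample(float(xi), float(yi), bool(vi))

    @property
    def xy(self) -> np.ndarray:
        """(N, 2) array of CoP coordinates."""
        return np.column_stack([self.x, self.y])

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def axis(self, name: str) -> np.ndarray:
        if name not in ("x", "y"):
            raise ValueError("axis must be 'x' or 'y'")
        return self.x if name == "x" else self.y

    def replace(self, **kwargs) -> "CoPSeries":
        base = dict(
            t=self.t, x=self.x, y=self.y, source=self.source,
            valid=self.valid, annotations=dict(self.annotations),
        )
        base.update(kwargs)
        return CoPSeries(**base)


def resistance_to_conductance(
    t: np.ndarray,
    resistance_kohm: np.ndarray,
    **meta,
) -> ConductanceSeries:
    """Convert a 6-channel sensor resistance recording (kOhm) to conductance.

    The acquisition unit logs per-sensor electrical resistance in kOhm;
    the CoP weighting works on conductance, its elementwise reciprocal
    (mS when the input is kOhm).  Timestamps are preserved.

    Raises
    ------
    ValueError
        If any resistance is zero or negative; the message identifies the
        offending channel and timestamp.
    """
    t = np.asarray(t, dtype=float)
    r = np.asarray(resistance_kohm, dtype=float)
    if r.ndim != 2 or r.shape[1] != N_SENSORS:
        raise ValueError(f"resistances must have shape (N, {N_SENSORS}), got {r.shape}")
    if np.any(~np.isfinite(r)) or np.any(r <= 0):
        bad = np.argwhere(~np.isfinite(r) | (r <= 0))[0]
        i, j = int(bad[0]), int(bad[1])
        raise ValueError(
            f"nonpositive resistance in channel u{j} at t={t[i]:g} s "
            f"(value {r[i, j]!r} kOhm)"
        )
    return ConductanceSeries(t=t, values=1.0 / r, **meta)


def compute_cop(
    conductances: np.ndarray,
    geometry: SensorGeometry | None = None,
) -> CoPSample:
    """CoP of a single 6-channel conductance frame.

    Implements the conductance-weighted sensor centroid.  A frame whose
    total conductance is zero carries no contact information and is
    returned flagged invalid (at the geometry centroid) rather than
    raising, so whole-series processing survives swing phases.
    """
    if geometry is None:
        geometry = default_geometry()
    u = np.asarray(conductances, dtype=float)
    if u.shape != (N_SENSORS,):
        raise ValueError(f"expected {N_SENSORS} conductances, got shape {u.shape}")
    if np.any(u < 0):
        j = int(np.flatnonzero(u < 0)[0])
        raise ValueError(f"negative conductance in channel u{j}")
    total = u.sum()
    if total == 0.0:
        cx, cy = geometry.centroid_mm
        return CoPSample(float(cx), float(cy), valid=False)
    cop = u @ geometry.positions_mm / total
    return CoPSample(float(cop[0]), float(cop[1]), valid=True)


def cop_series(
    series: ConductanceSeries,
    geometry: SensorGeometry | None = None,
) -> CoPSeries:
    """CoP waveform from a conductance recording (vectorised weighting).

    Zero-load frames are flagged invalid; everything else is the weighted
    centroid of the sensor positions.  The output carries the recording's
    annotations and a ``source='sock'`` tag.
    """
    if geometry is None:
        geometry = default_geometry()
    if len(series) == 0:
        raise ValueError("empty conductance series")
    u = series.values
    total = u.sum(axis=1)
    valid = total > 0
    safe_total = np.where(valid, total, 1.0)
    xy = (u @ geometry.positions_mm) / safe_total[:, None]
    cx, cy = geometry.centroid_mm
    xy[~valid] = (cx, cy)
    return CoPSeries(
        t=series.t,
        x=xy[:, 0],
        y=xy[:, 1],
        source="sock",
        valid=valid,
        annotations={
            "participant": series.participant,
            "exercise": series.exercise,
            "repetition": series.repetition,
            "foot": series.foot,
        },
    )
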
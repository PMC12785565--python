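"""Marker detection, resampling, time alignment and mean-centering.

Sock and platform run on independent clocks and rates (sock up to 200 Hz,
platform 125 Hz), and the platform reports absolute coordinates that depend
on where the foot landed, while the sock frame is fixed to the sole.  Before
any agreement statistic the two CoP waveforms are therefore

1. resampled to a common uniform rate (default the platform's 125 Hz),
2. aligned by a single global time shift found by exhaustive integer-sample
   cross-correlation, and
3. mean-centered individually over the full overlapping duration, which
   removes both the platform's foot-placement offset and the sock's
   placement-dependent bias.

A leg-lift calibration marker (about 3 s of near-zero load at the start of a
set) can be detected from the summed sock conductance to sanity-check
synchronization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ConductanceSeries, CoPSeries

__all__ = [
    "MarkerEvent",
    "AlignedPair",
    "detect_lift_marker",
    "resample",
    "normalize",
    "align",
]

#: Default preprocessing parameters.
RESAMPLE_RATE_HZ = 125.0
MAX_LAG_S = 5.0
MARKER_REL_THRESHOLD = 0.1
MARKER_MIN_DURATION_S = 2.0
MAX_GAP_S = 0.2


@dataclass(frozen=True)
class MarkerEvent:
    """One low-load calibration interval (leg lift)."""

    start: float
    end: float
    kind: str = "lift"
    foot: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("marker end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class AlignedPair:
    """One sock/platform waveform pair on a common timeline, mean-centered.

    ``sock`` and ``platform`` are the centered CoP values (mm) for a single
    axis; the original means are kept so raw (uncentered) values can be
    recovered for absolute-shift analyses.
    """

    t: np.ndarray
    sock: np.ndarray
    platform: np.ndarray
    axis: str
    lag_s: float
    correlation: float = np.nan
    sock_mean_mm: float = 0.0
    platform_mean_mm: float = 0.0
    annotations: dict | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        s = np.asarray(self.sock, dtype=float)
        p = np.asarray(self.platform, dtype=float)
        if not (t.shape == s.shape == p.shape) or t.ndim != 1:
            raise ValueError("t, sock, platform must be 1-D arrays of equal length")
        if t.size < 3:
            raise ValueError("aligned pair needs at least 3 samples")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
            raise ValueError("aligned pair must be uniformly sampled")
        for name, arr in (("sock", s), ("platform", p)):
            if abs(arr.mean()) > 1e-9:
                raise ValueError(f"{name} values are not mean-centered")
        if self.axis not in ("x", "y"):
            raise ValueError("axis must be 'x' or 'y'")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "sock", s)
        object.__setattr__(self, "platform", p)

    def __len__(self) -> int:
        return self.t.size

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def rate_hz(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])

    def raw(self) -> tuple[np.ndarray, np.ndarray]:
        """Uncentered (sock, platform) values, means restored."""
        return self.sock + self.sock_mean_mm, self.platform + self.platform_mean_mm


def detect_lift_marker(
    series: ConductanceSeries,
    rel_threshold: float = MARKER_REL_THRESHOLD,
    min_duration_s: float = MARKER_MIN_DURATION_S,
) -> list[MarkerEvent]:
    """Find near-zero-load intervals (leg lifts) in a sock recording.

    An interval qualifies when the summed conductance stays below
    ``rel_threshold`` times its trial median for at least ``min_duration_s``.
    Returns maximal qualifying intervals in time order; an empty list means
    no marker was found.
    """
    if len(series) == 0:
        raise ValueError("empty conductance series")
    if not 0 < rel_threshold < 1:
        raise ValueError("rel_threshold must be in (0, 1)")
    if min_duration_s <= 0:
        raise ValueError("min_duration_s must be positive")
    total = series.total
    threshold = rel_threshold * float(np.median(total))
    low = total < threshold
    events: list[MarkerEvent] = []
    # maximal runs of consecutive low samples
    padded = np.diff(np.concatenate([[0], low.view(np.int8), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1) - 1
    for i0, i1 in zip(starts, ends):
        duration = float(series.t[i1] - series.t[i0])
        if duration >= min_duration_s:
            events.append(
                MarkerEvent(float(series.t[i0]), float(series.t[i1]), foot=series.foot)
            )
    return events


def _phase_grid(t0: float, t1: float, rate: float) -> np.ndarray:
    """Uniform grid at ``rate`` inside [t0, t1], anchored to absolute phase.

    Anchoring grid points to integer multiples of the sampling interval
    (rather than to each series' own first sample) puts every series
    resampled at the same rate on a common phase, so integer-sample lag
    alignment is an exact array shift.
    """
    eps = 1e-9
    k0 = int(np.ceil(t0 * rate - eps))
    k1 = int(np.floor(t1 * rate + eps))
    if k1 < k0:
        raise ValueError("resampling grid is empty for the given range")
    return np.arange(k0, k1 + 1) / rate


def resample(
    series: CoPSeries,
    rate_hz: float = RESAMPLE_RATE_HZ,
    max_gap_s: float = MAX_GAP_S,
) -> CoPSeries:
    """Linearly interpolate a CoP series onto a uniform grid.

    The grid spans the series' valid time range only (no extrapolation).
    Output samples that fall inside a gap between valid input samples
    longer than ``max_gap_s`` are flagged invalid rather than interpolated
    across.
    """
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    tv = series.t[series.valid]
    if tv.size < 2:
        raise ValueError("resampling needs at least 2 valid samples")
    xv = series.x[series.valid]
    yv = series.y[series.valid]
    grid = _phase_grid(float(tv[0]), float(tv[-1]), rate_hz)
    x = np.interp(grid, tv, xv)
    y = np.interp(grid, tv, yv)
    # flag output samples bridging an over-long invalid gap
    right = np.searchsorted(tv, grid, side="left")
    right = np.clip(right, 1, tv.size - 1)
    gap = tv[right] - tv[right - 1]
    on_sample = np.isclose(grid, tv[np.clip(right, 0, tv.size - 1)], atol=1e-9) | np.isclose(
        grid, tv[right - 1], atol=1e-9
    )
    valid = (gap <= max_gap_s) | on_sample
    return series.replace(t=grid, x=x, y=y, valid=valid)


def normalize(series: CoPSeries) -> CoPSeries:
    """Subtract each axis' mean over valid samples (per-waveform centering)."""
    if series.n_valid == 0:
        raise ValueError("cannot normalize a series with no valid samples")
    m = series.valid
    return series.replace(x=series.x - series.x[m].mean(), y=series.y - series.y[m].mean())


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return np.nan
    return float((a @ b) / denom)


def _best_lag(
    sock: np.ndarray,
    platform: np.ndarray,
    offset: int,
    max_shift: int,
    min_overlap: int = 3,
) -> tuple[int, float]:
    """Integer-sample lag maximizing Pearson correlation.

    ``offset`` is the platform grid's starting index relative to the sock
    grid.  A candidate lag ``k`` (samples the platform clock runs behind
    the sock clock) pairs platform sample ``j`` with sock sample
    ``j + offset - k``.  Ties are broken toward the smallest ``|k|``.
    """
    ns, npf = sock.size, platform.size
    best_k, best_r = 0, -np.inf
    for k in sorted(range(-max_shift, max_shift + 1), key=abs):
        lo = max(0, k - offset)        # platform index range overlapping sock
        hi = min(npf, ns + k - offset)
        if hi - lo < min_overlap:
            continue
        s_seg = sock[lo + offset - k: hi + offset - k]
        p_seg = platform[lo:hi]
        r = _pearson(s_seg, p_seg)
        if np.isnan(r):
            continue
        if r > best_r:
            best_k, best_r = k, r
    if not np.isfinite(best_r):
        raise ValueError("flat signal, alignment undefined")
    return best_k, best_r


def align(
    sock: CoPSeries,
    platform: CoPSeries,
    max_lag_s: float = MAX_LAG_S,
    annotations: dict | None = None,
) -> tuple[AlignedPair, AlignedPair]:
    """Align a sock and a platform CoP series; return per-axis centered pairs.

    Both inputs must already be on the same uniform rate (see
    :func:`resample`).  One shared lag is estimated — the two instruments
    have a single clock offset — from the axis in which the platform signal
    has the larger variance, by maximizing the Pearson correlation of the
    overlapping segments over integer-sample lags in ``[-max_lag_s,
    +max_lag_s]`` (ties toward zero lag).  Both axes are then cropped to
    the overlap and mean-centered.

    The returned lag is the platform clock's delay relative to the sock
    clock: platform features occur ``lag_s`` later in platform time.
    """
    dt_s = float(np.median(np.diff(sock.t)))
    dt_p = float(np.median(np.diff(platform.t)))
    if not np.isclose(dt_s, dt_p, rtol=1e-6):
        raise ValueError("sock and platform must share a sampling rate; resample first")
    dt = dt_s
    max_shift = int(round(max_lag_s / dt))
    offset = int(round((platform.t[0] - sock.t[0]) / dt))

    drive = "y" if platform.y.var() >= platform.x.var() else "x"
    k, r = _best_lag(sock.axis(drive), platform.axis(drive), offset, max_shift)
    lag_s = k * dt + (platform.t[0] - sock.t[0] - offset * dt)

    # crop both series to the overlap under lag k
    lo_p = max(0, k - offset)
    hi_p = min(len(platform), len(sock) + k - offset)
    if hi_p - lo_p < 3:
        raise ValueError("overlap after alignment shorter than 3 samples")
    lo_s = lo_p + offset - k
    hi_s = hi_p + offset - k
    t = sock.t[lo_s:hi_s]

    pairs = []
    for axis in ("x", "y"):
        s_seg = sock.axis(axis)[lo_s:hi_s]
        p_seg = platform.axis(axis)[lo_p:hi_p]
        if s_seg.var() == 0 or p_seg.var() == 0:
            raise ValueError(f"flat signal on axis {axis}, alignment undefined")
        s_mean, p_mean = float(s_seg.mean()), float(p_seg.mean())
        pairs.append(
            AlignedPair(
                t=t,
                sock=s_seg - s_mean,
                platform=p_seg - p_mean,
                axis=axis,
                lag_s=float(lag_s),
                correlation=r,
                sock_mean_mm=s_mean,
                platform_mean_mm=p_mean,
                annotations=dict(annotations or {}),
            )
        )
    return pairs[0], pairs[1]
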
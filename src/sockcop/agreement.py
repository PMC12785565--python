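"""Method-comparison statistics for paired CoP waveforms.

Agreement between the sock-derived and platform CoP is quantified per
waveform pair with three complementary statistics:

* **RMSE** of the pointwise difference, reported absolutely (mm) and
  relative to an inter-quantile span of the reference (platform) waveform.
* **Bland–Altman** bias and limits of agreement, ``LoA = <d> ± 1.96 S(d)``
  at 95% confidence, with the fraction of differences outside the limits.
* **Lin's concordance correlation coefficient (CCC)**, the Pearson
  correlation rho scaled by an accuracy coefficient
  ``chi = 2 / (v^2 + omega + 1/omega)`` built from the location shift
  ``v^2 = (mu_s - mu_p)^2 / (s_s s_p)`` and the scale shift
  ``omega = s_s / s_p``.  Unlike rho, the CCC penalizes departures from
  the identity line, not just from any straight line.  Confidence
  intervals come from the Fisher transform ``lambda = atanh(CCC)`` with
  an asymptotic normal variance.

Classification of CCC values follows two published vocabularies: a strict
scheme for instrument-replacement claims and a looser correlation-oriented
scheme for relative waveform tracking.

All standard deviations use the sample (N-1) convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import AlignedPair

__all__ = [
    "RmseResult",
    "BlandAltmanResult",
    "CccResult",
    "ConcordanceClass",
    "rmse",
    "bland_altman",
    "lin_ccc",
    "ccc_confidence_interval",
    "classify_concordance",
    "segment_ccc",
    "summarize",
]

DEFAULT_QUANTILE_PAIR = (2.5, 97.5)

STRICT_BINS = (
    (0.99, "almost perfect"),
    (0.95, "substantial"),
    (0.90, "moderate"),
)
LOOSE_BINS = (
    (0.80, "high"),
    (0.60, "moderate"),
    (0.40, "fair"),
)


def _pair_values(pair) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pair, AlignedPair):
        return pair.sock, pair.platform
    s, p = pair
    s = np.asarray(s, dtype=float)
    p = np.asarray(p, dtype=float)
    if s.shape != p.shape or s.ndim != 1:
        raise ValueError("paired series must be 1-D arrays of equal length")
    return s, p


@dataclass(frozen=True)
class RmseResult:
    rmse_abs_mm: float
    delta_q_mm: float
    rmse_rel: float            # NaN when delta_q == 0
    quantile_pair: tuple[float, float] = DEFAULT_QUANTILE_PAIR

    @property
    def rel_defined(self) -> bool:
        return not math.isnan(self.rmse_rel)


def rmse(
    pair,
    quantile_pair: tuple[float, float] = DEFAULT_QUANTILE_PAIR,
    reference: str = "platform",
) -> RmseResult:
    """Root-mean-square error of the sock-platform difference.

    ``rmse_abs = sqrt(mean((sock_i - platform_i)^2))``.  The relative form
    divides by ``delta_q``, the span between the two given percentiles of
    the reference waveform (the platform by default: the reference
    instrument defines the scale of motion).  When the reference waveform
    is flat (``delta_q == 0``) the relative error is returned as NaN and
    the absolute error still stands.
    """
    s, p = _pair_values(pair)
    if s.size < 2:
        raise ValueError("RMSE needs at least 2 samples")
    lo, hi = quantile_pair
    if not 0 <= lo < hi <= 100:
        raise ValueError("quantile_pair must satisfy 0 <= low < high <= 100")
    ref = p if reference == "platform" else s
    rmse_abs = float(np.sqrt(np.mean((s - p) ** 2)))
    q_lo, q_hi = np.percentile(ref, [lo, hi])
    delta_q = float(q_hi - q_lo)
    rmse_rel = rmse_abs / delta_q if delta_q > 0 else math.nan
    return RmseResult(rmse_abs, delta_q, rmse_rel, (float(lo), float(hi)))


@dataclass(frozen=True)
class BlandAltmanResult:
    bias_mm: float
    sd_diff_mm: float
    loa_low_mm: float
    loa_high_mm: float
    frac_outside: float
    alpha: float = 0.95


def bland_altman(pair, alpha: float = 0.95) -> BlandAltmanResult:
    """Bias and limits of agreement of the differences d = sock - platform.

    At the conventional ``alpha = 0.95`` the limits are ``bias ± 1.96 *
    S(d)`` with the z-quantile fixed at 1.96; other confidence levels use
    the exact normal quantile.  ``frac_outside`` is the fraction of
    differences strictly outside the limits (about 5% for Gaussian
    differences).
    """
    s, p = _pair_values(pair)
    if s.size < 3:
        raise ValueError("Bland-Altman needs at least 3 samples")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    d = s - p
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    z = 1.96 if abs(alpha - 0.95) < 1e-12 else float(stats.norm.ppf(0.5 + alpha / 2))
    loa_low, loa_high = bias - z * sd, bias + z * sd
    frac = float(np.mean((d < loa_low) | (d > loa_high)))
    return BlandAltmanResult(bias, sd, loa_low, loa_high, frac, alpha)


@dataclass(frozen=True)
class CccResult:
    ccc: float
    rho: float
    v2: float                  # squared location shift
    omega: float               # scale shift s_s / s_p
    chi: float                 # accuracy coefficient
    mu_s: float
    mu_p: float
    s_s: float
    s_p: float
    n: int
    lam: float = math.nan      # Fisher transform atanh(ccc)
    var_lam: float = math.nan
    ci_low: float = math.nan
    ci_high: float = math.nan
    ci_alpha: float = 0.05
    degenerate: bool = False   # |ccc| == 1: CI collapses to a point
    ci_defined: bool = True


def lin_ccc(pair, alpha: float = 0.05) -> CccResult:
    """Lin's concordance correlation coefficient with Fisher-transform CI.

    Computed from the moment decomposition ``CCC = rho * chi`` with
    ``chi = 2 / (v^2 + omega + 1/omega)``; this equals the covariance form
    ``2 cov(s, p) / (s_s^2 + s_p^2 + (mu_s - mu_p)^2)`` identically, which
    the test-suite verifies.  Sample (N-1) moments throughout.

    Raises
    ------
    ValueError
        If either series has zero variance (CCC undefined for a flat
        signal) or fewer than 3 samples.
    """
    s, p = _pair_values(pair)
    n = s.size
    if n < 3:
        raise ValueError("CCC needs at least 3 samples")
    mu_s, mu_p = float(s.mean()), float(p.mean())
    s_s, s_p = float(s.std(ddof=1)), float(p.std(ddof=1))
    if s_s == 0 or s_p == 0:
        raise ValueError("CCC undefined for flat signal")
    cov = float(np.cov(s, p, ddof=1)[0, 1])
    rho = cov / (s_s * s_p)
    v2 = (mu_s - mu_p) ** 2 / (s_s * s_p)
    omega = s_s / s_p
    chi = 2.0 / (v2 + omega + 1.0 / omega)
    ccc = rho * chi
    # identical inputs can land a few ulp either side of |1| in floating point
    if 1.0 - 1e-12 < abs(rho) <= 1.0 + 1e-9:
        rho = math.copysign(1.0, rho)
    if 1.0 - 1e-12 < abs(ccc) <= 1.0 + 1e-9:
        ccc = math.copysign(1.0, ccc)
    result = CccResult(
        ccc=ccc, rho=rho, v2=v2, omega=omega, chi=chi,
        mu_s=mu_s, mu_p=mu_p, s_s=s_s, s_p=s_p, n=n, ci_alpha=alpha,
    )
    ci_low, ci_high = ccc_confidence_interval(result, alpha)
    lam = math.atanh(ccc) if abs(ccc) < 1 else math.copysign(math.inf, ccc)
    return CccResult(
        ccc=ccc, rho=rho, v2=v2, omega=omega, chi=chi,
        mu_s=mu_s, mu_p=mu_p, s_s=s_s, s_p=s_p, n=n,
        lam=lam, var_lam=_fisher_variance(result),
        ci_low=ci_low, ci_high=ci_high, ci_alpha=alpha,
        degenerate=abs(ccc) >= 1.0 - 1e-15,
        ci_defined=not (rho == 0 or n <= 2),
    )


def _fisher_variance(r: CccResult) -> float:
    """Asymptotic variance of lambda = atanh(CCC).

    For a mean-centered pair (v = 0, so CCC = rho when omega = 1) this
    reduces exactly to 1 / (n - 2).
    """
    ccc, rho, v2, n = r.ccc, r.rho, r.v2, r.n
    if n <= 2 or rho == 0 or abs(ccc) >= 1:
        return math.nan
    one_m = 1.0 - ccc**2
    term1 = (1.0 - rho**2) * ccc**2 / (one_m * rho**2)
    term2 = 2.0 * ccc**3 * (1.0 - ccc) * v2 / (rho * one_m**2)
    term3 = ccc**4 * v2**2 / (2.0 * rho**2 * one_m**2)
    return (term1 + term2 - term3) / (n - 2)


def ccc_confidence_interval(result: CccResult, alpha: float = 0.05) -> tuple[float, float]:
    """Fisher-transform confidence interval for a CCC estimate.

    ``lambda = atanh(CCC)`` is treated as normal with the asymptotic
    variance of :func:`_fisher_variance`; the interval is
    ``tanh(lambda -/+ z_{alpha/2} sigma_lambda)``.  Degenerate cases:
    ``|CCC| = 1`` returns the point interval ``(CCC, CCC)``; ``rho = 0``
    returns ``(nan, nan)`` (undefined); ``n <= 2`` raises.
    """
    if result.n <= 2:
        raise ValueError("CCC confidence interval needs n > 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    ccc = result.ccc
    if abs(ccc) >= 1.0 - 1e-15:
        return (ccc, ccc)
    if result.rho == 0:
        return (math.nan, math.nan)
    var_lam = _fisher_variance(result)
    if not math.isfinite(var_lam) or var_lam < 0:
        return (math.nan, math.nan)
    lam = math.atanh(ccc)
    z = 1.96 if abs(alpha - 0.05) < 1e-12 else float(stats.norm.ppf(1 - alpha / 2))
    half = z * math.sqrt(var_lam)
    return (math.tanh(lam - half), math.tanh(lam + half))


@dataclass(frozen=True)
class ConcordanceClass:
    scheme: str
    label: str


def classify_concordance(ccc: float, scheme: str = "strict") -> ConcordanceClass:
    """Map a CCC value to a published concordance vocabulary.

    * ``strict`` (instrument replacement): >= 0.99 almost perfect,
      [0.95, 0.99) substantial, [0.90, 0.95) moderate, < 0.90 poor.
    * ``loose`` (correlation strength): >= 0.80 high, [0.60, 0.80)
      moderate, [0.40, 0.60) fair, < 0.40 poor.
    """
    if not -1.0 <= ccc <= 1.0:
        raise ValueError(f"CCC must lie in [-1, 1], got {ccc!r}")
    if scheme == "strict":
        bins = STRICT_BINS
    elif scheme == "loose":
        bins = LOOSE_BINS
    else:
        raise ValueError("scheme must be 'strict' or 'loose'")
    for threshold, label in bins:
        if ccc >= threshold:
            return ConcordanceClass(scheme, label)
    return ConcordanceClass(scheme, "poor")


def segment_ccc(pair: AlignedPair, split_times_s: Sequence[float]) -> list[CccResult]:
    """CCC per segment, each segment mean-centered separately.

    Used for baseline-shift analysis: a mid-trial foot reposition (e.g. a
    side step) shifts the platform's absolute CoP baseline but not the
    sock's, collapsing the whole-waveform CCC; re-centering each stable
    segment on its own mean recovers the within-segment concordance.
    """
    edges = [float(pair.t[0])] + sorted(float(ts) for ts in split_times_s)
    edges.append(float(pair.t[-1]) + 1.0)
    results = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (pair.t >= lo) & (pair.t < hi)
        if m.sum() < 3:
            raise ValueError(f"segment [{lo:g}, {hi:g}) has fewer than 3 samples")
        s = pair.sock[m] - pair.sock[m].mean()
        p = pair.platform[m] - pair.platform[m].mean()
        results.append(lin_ccc((s, p)))
    return results


def summarize(records: Iterable[dict] | pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-pair agreement records into per-axis and overall rows.

    Expects records with at least ``axis``, ``ccc`` and ``rmse_abs_mm``
    fields (the metrics-table rows).  Reports counts and fractions at the
    CCC >= 0.90 (acceptable absolute agreement), >= 0.60 (at least
    moderate correlation) and < 0.40 (poor) thresholds, plus CCC and RMSE
    ranges.
    """
    df = pd.DataFrame(records) if not isinstance(records, pd.DataFrame) else records
    if df.empty:
        raise ValueError("cannot summarize an empty record list")
    rows = []
    groups = [("overall", df)] + [(ax, g) for ax, g in df.groupby("axis")]
    for name, g in groups:
        ccc = g["ccc"].to_numpy(float)
        rmse_abs = g["rmse_abs_mm"].to_numpy(float)
        rows.append(
            {
                "axis": name,
                "n": len(g),
                "n_ccc_ge_090": int((ccc >= 0.90).sum()),
                "frac_ccc_ge_090": float((ccc >= 0.90).mean()),
                "n_ccc_ge_060": int((ccc >= 0.60).sum()),
                "frac_ccc_ge_060": float((ccc >= 0.60).mean()),
                "n_ccc_lt_040": int((ccc < 0.40).sum()),
                "frac_ccc_lt_040": float((ccc < 0.40).mean()),
                "ccc_min": float(ccc.min()),
                "ccc_max": float(ccc.max()),
                "rmse_min_mm": float(rmse_abs.min()),
                "rmse_max_mm": float(rmse_abs.max()),
            }
        )
    return pd.DataFrame(rows).set_index("axis")
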
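"""Conventional (non-Bayesian) life-history trait estimators.

Estimates bacterial growth rates from growth curves, adsorption rates from
free-phage decay assays, latent periods from the first significant rise of a
one-step growth curve, and burst sizes from the pre/post-burst plateau ratio

    <beta> = (<V2> - <V1>) / (<T1> - <V1>)

where ``V1``/``V2`` are free-phage densities before/after the burst and
``T1`` is the total (free + infected-centre) density before the burst.
The first-appearance latent period systematically underestimates the mean
latent period whenever the latent-period distribution has positive variance;
the Bayesian fits in :mod:`seivd.inference` do not share this bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AssaySeries",
    "GrowthRateEstimate",
    "AdsorptionEstimate",
    "FirstRiseResult",
    "ConventionalTraits",
    "NoBurstDetected",
    "estimate_growth_rate",
    "estimate_adsorption_rate",
    "estimate_latent_period",
    "conventional_burst_size",
    "od_to_cfu_calibration",
]


class NoBurstDetected(Warning):
    """Issued when a one-step curve never rises above its baseline band."""


@dataclass(frozen=True)
class AssaySeries:
    """Replicated assay measurements on a common time grid.

    ``values`` has shape ``(n_replicates, n_times)``; densities are per ml.
    ``background_cells`` is the (constant) cell density of an adsorption
    assay, needed to convert the free-phage decay slope into phi.
    """

    time_h: np.ndarray
    values: np.ndarray
    background_cells: float | None = None

    def __post_init__(self):
        t = np.atleast_1d(np.asarray(self.time_h, dtype=float))
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if v.shape[1] != len(t):
            raise ValueError(f"values shape {v.shape} does not match {len(t)} time points")
        if len(t) < 3:
            raise ValueError("an assay series needs at least 3 time points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time points must be strictly increasing")
        object.__setattr__(self, "time_h", t)
        object.__setattr__(self, "values", v)

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.values.mean(axis=0)


@dataclass(frozen=True)
class GrowthRateEstimate:
    r: float  # 1/h, mean over replicates
    r_sd: float
    doubling_time_h: float
    window: tuple  # (index_lo, index_hi) of the fitted span, inclusive


@dataclass(frozen=True)
class AdsorptionEstimate:
    phi: float  # ml/h
    phi_sd: float


@dataclass(frozen=True)
class FirstRiseResult:
    time_h: float | None  # None when no burst was detected
    threshold: float

    @property
    def no_burst(self) -> bool:
        return self.time_h is None


@dataclass(frozen=True)
class ConventionalTraits:
    """Bundle of conventional estimates for one phage-host pair."""

    growth: GrowthRateEstimate | None = None
    adsorption: AdsorptionEstimate | None = None
    latent: FirstRiseResult | None = None
    burst_size: float | None = None


def _loglinear_slope(t: np.ndarray, v: np.ndarray) -> tuple:
    """Least-squares slope/intercept of ln(v) vs t; v must be positive."""
    if np.any(v <= 0):
        raise ValueError("log-linear fit requires strictly positive readings")
    slope, intercept = np.polyfit(t, np.log(v), 1)
    return slope, intercept


def _auto_window(t: np.ndarray, mean_v: np.ndarray, r2_min: float = 0.995) -> tuple:
    """Longest contiguous window (>= 3 points) whose log-linear fit has
    R^2 >= ``r2_min``; falls back to the single best-R^2 window."""
    n = len(t)
    best = None  # (length, r2, lo, hi)
    for lo in range(n - 2):
        for hi in range(lo + 2, n):
            v = mean_v[lo : hi + 1]
            if np.any(v <= 0):
                continue
            y = np.log(v)
            x = t[lo : hi + 1]
            slope, icpt = np.polyfit(x, y, 1)
            resid = y - (slope * x + icpt)
            ss_tot = np.sum((y - y.mean()) ** 2)
            r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum(resid**2) / ss_tot
            key = (hi - lo, r2) if r2 >= r2_min else (-1, r2)
            if best is None or key > best[0]:
                best = (key, lo, hi)
    if best is None:
        raise ValueError("no positive window of >= 3 points available")
    return best[1], best[2]


def estimate_growth_rate(series: AssaySeries, window: tuple | None = None) -> GrowthRateEstimate:
    """Exponential growth rate from the log-linear slope of a growth curve.

    ``window`` is an inclusive index pair into the time grid; by default the
    longest well-fitting (R^2 >= 0.995) log-linear run is used.
    """
    t = series.time_h
    if window is None:
        lo, hi = _auto_window(t, series.mean)
    else:
        lo, hi = window
        if hi - lo + 1 < 3:
            raise ValueError("growth window must contain at least 3 readings")
    rs = []
    for rep in series.values:
        slope, _ = _loglinear_slope(t[lo : hi + 1], rep[lo : hi + 1])
        rs.append(slope)
    rs = np.array(rs)
    r = float(rs.mean())
    if r <= 0:
        warnings.warn(f"growth-rate fit gave non-positive slope r = {r:.3g}/h", stacklevel=2)
    doubling = np.log(2) / r if r > 0 else np.inf
    return GrowthRateEstimate(
        r=r, r_sd=float(rs.std(ddof=1)) if len(rs) > 1 else 0.0,
        doubling_time_h=float(doubling), window=(lo, hi),
    )


def estimate_adsorption_rate(series: AssaySeries) -> AdsorptionEstimate:
    """Adsorption constant phi from exponential free-phage decay.

    With constant cell density ``B``, free phage decay as ``V0 e^{-phi B t}``
    so ``phi = -slope(ln V vs t) / B`` (ml/h).
    """
    if series.background_cells is None or not series.background_cells > 0:
        raise ValueError("adsorption assays need a positive background cell density B")
    b = series.background_cells
    phis = []
    for rep in series.values:
        slope, _ = _loglinear_slope(series.time_h, rep)
        phis.append(-slope / b)
    phis = np.array(phis)
    return AdsorptionEstimate(
        phi=float(phis.mean()), phi_sd=float(phis.std(ddof=1)) if len(phis) > 1 else 0.0
    )


def estimate_latent_period(
    one_step: AssaySeries, z: float = 3.0, n_baseline: int = 2
) -> FirstRiseResult:
    """First-rise latent period from a one-step free-phage curve.

    The baseline is the mean of the first ``n_baseline`` time points over all
    replicates; the latent period is the earliest time the replicate-mean
    curve exceeds baseline + ``z`` x (baseline SD), linearly interpolated
    between the bracketing samples.  Returns a no-burst sentinel when the
    curve never crosses the threshold.
    """
    if n_baseline < 2:
        raise ValueError("need at least 2 pre-rise points to establish a baseline")
    t = one_step.time_h
    base = one_step.values[:, :n_baseline]
    thr = float(base.mean() + z * base.std(ddof=0))
    thr *= 1.0 + 1e-12  # strict crossing even for noise-free baselines
    m = one_step.mean
    above = m > thr
    above[:n_baseline] = False
    if not above.any():
        warnings.warn("no significant rise in free phage", NoBurstDetected, stacklevel=2)
        return FirstRiseResult(time_h=None, threshold=thr)
    k = int(np.argmax(above))
    if k == 0 or m[k] == m[k - 1]:
        return FirstRiseResult(time_h=float(t[k]), threshold=thr)
    frac = (thr - m[k - 1]) / (m[k] - m[k - 1])
    frac = min(max(frac, 0.0), 1.0)
    return FirstRiseResult(time_h=float(t[k - 1] + frac * (t[k] - t[k - 1])), threshold=thr)


def conventional_burst_size(v1, v2, t1) -> float:
    """Average burst size (<V2> - <V1>) / (<T1> - <V1>).

    Arguments may be scalars or arrays (time points x replicates); averages
    are taken over all supplied values.
    """
    v1m = float(np.mean(v1))
    v2m = float(np.mean(v2))
    t1m = float(np.mean(t1))
    if t1m <= v1m:
        raise ValueError(
            f"no measurable infected centres: <T1> = {t1m:g} <= <V1> = {v1m:g}"
        )
    return (v2m - v1m) / (t1m - v1m)


def od_to_cfu_calibration(od: np.ndarray, cfu: np.ndarray):
    """Log-log regression of CFU on OD600 from paired calibration points.

    Returns a callable converting OD readings to cell densities.
    """
    od = np.asarray(od, dtype=float)
    cfu = np.asarray(cfu, dtype=float)
    if np.any(od <= 0) or np.any(cfu <= 0):
        raise ValueError("calibration points must be positive")
    slope, icpt = np.polyfit(np.log10(od), np.log10(cfu), 1)

    def convert(od_readings):
        od_readings = np.asarray(od_readings, dtype=float)
        return 10 ** (slope * np.log10(od_readings) + icpt)

    return convert
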
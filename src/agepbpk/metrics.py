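"""Non-compartmental parameters and model-validation statistics.

Implements the linear-trapezoid AUC(0-t), Cmax/Tmax, the average fold
error AFE = 10^(mean log10(pred/obs)), the average absolute prediction
error PE% = geomean(|pred - obs|/obs) x 100, two-fold coverage counts and
population percentile-band coverage of observed profiles.

Classification bands: AFE is *satisfactory* in [0.8, 1.25], *passable* in
[0.5, 0.8) or (1.25, 2], otherwise *poor*; PE% is satisfactory below 25,
passable in [25, 50), poor at or above 50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ObservedProfile",
    "auc_0_t",
    "cmax_tmax",
    "afe",
    "classify_afe",
    "pe_percent",
    "classify_pe",
    "fold_coverage",
    "band_coverage",
]


@dataclass(frozen=True)
class ObservedProfile:
    """A digitized/observed concentration-time profile (mg/L internally)."""

    times: np.ndarray  # h
    conc: np.ndarray  # mg/L
    regimen: tuple = ()
    age_group: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.conc, dtype=float)
        if t.ndim != 1 or t.shape != c.shape:
            raise ValueError("times and conc must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "conc", c)


def auc_0_t(times: Sequence[float], conc: Sequence[float], method: str = "linear") -> float:
    """Area under the curve on the given grid.

    ``linear`` applies the linear trapezoid throughout; ``linlog`` uses the
    log-trapezoid on strictly decreasing positive segments (down-slope) and
    the linear rule elsewhere.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two points for AUC")
    if method == "linear":
        return float(np.trapezoid(c, t))
    if method != "linlog":
        raise ValueError(f"unknown AUC method {method!r}")
    dt = np.diff(t)
    c0, c1 = c[:-1], c[1:]
    down = (c1 < c0) & (c1 > 0) & (c0 > 0)
    seg = np.where(down, (c0 - c1) / np.log(c0 / np.where(c1 > 0, c1, 1.0)), 0.5 * (c0 + c1))
    return float(np.sum(seg * dt))


def cmax_tmax(times: Sequence[float], conc: Sequence[float]) -> tuple[float, float]:
    """Peak concentration and the first time it is attained."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    i = int(np.argmax(c))  # argmax returns the first maximum
    return float(c[i]), float(t[i])


def _check_pairs(pred, obs, require_positive_pred=True):
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or p.size == 0:
        raise ValueError("pred and obs must be non-empty 1-D arrays of equal length")
    if np.any(o <= 0) or (require_positive_pred and np.any(p <= 0)):
        raise ValueError("values must be positive")
    return p, o


def afe(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Average fold error: ``10 ** mean(log10(pred/obs))``."""
    p, o = _check_pairs(pred, obs)
    return float(10.0 ** np.mean(np.log10(p / o)))


def classify_afe(value: float) -> str:
    if 0.8 <= value <= 1.25:
        return "satisfactory"
    if 0.5 <= value < 0.8 or 1.25 < value <= 2.0:
        return "passable"
    return "poor"


def pe_percent(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Average absolute prediction error (%): geometric mean of |pred-obs|/obs.

    Exact predictions give zero error terms, for which the geometric mean is
    undefined; such terms are excluded (with a warning) and an all-exact
    vector returns 0 by convention.
    """
    p, o = _check_pairs(pred, obs, require_positive_pred=False)
    rel = np.abs(p - o) / o
    nonzero = rel[rel > 0]
    if nonzero.size == 0:
        return 0.0
    if nonzero.size < rel.size:
        warnings.warn(
            f"{rel.size - nonzero.size} exact prediction(s) excluded from the "
            "geometric mean of absolute errors",
            stacklevel=2,
        )
    return float(np.exp(np.mean(np.log(nonzero))) * 100.0)


def classify_pe(value: float) -> str:
    if value < 25.0:
        return "satisfactory"
    if value < 50.0:
        return "passable"
    return "poor"


def fold_coverage(
    pred: Sequence[float], obs: Sequence[float], lo: float = 0.5, hi: float = 2.0
) -> tuple[int, int]:
    """Count predictions whose pred/obs ratio lies within [lo, hi] (inclusive)."""
    p, o = _check_pairs(pred, obs)
    ratio = p / o
    return int(np.sum((ratio >= lo) & (ratio <= hi))), int(ratio.size)


def band_coverage(observed: ObservedProfile, summary) -> float:
    """Fraction of observed points inside the interpolated p5-p95 band.

    ``summary`` is a :class:`~agepbpk.population.PopulationSummary` (or any
    object with ``times``, ``p05`` and ``p95`` arrays).
    """
    lo = np.interp(observed.times, summary.times, summary.p05)
    hi = np.interp(observed.times, summary.times, summary.p95)
    inside = (observed.conc >= lo) & (observed.conc <= hi)
    return float(np.mean(inside))
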
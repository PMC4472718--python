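"""Standard-curve analytics for dilution-series Ct data.

The threshold cycle Ct is linear in log10 of starting template amount; an
ordinary least-squares fit of mean Ct on log10(amount) gives the slope Y
(cycles per 10-fold dilution), R², and the amplification efficiency
``Ex = 10^(-1/Y) - 1`` (Y = -3.32 corresponds to perfect doubling, Ex = 1).
Fits are computed on replicate means by default, matching how such tables
are normally published; replicate-level fitting is available as a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "DilutionPoint",
    "DilutionSeries",
    "StandardCurveFit",
    "CurveError",
    "replicate_stats",
    "fit_standard_curve",
    "efficiency_from_slope",
    "detection_limit",
]

# amount unit multipliers to nanograms
UNIT_TO_NG = {"ng": 1.0, "pg": 1e-3, "fg": 1e-6}


class CurveError(ValueError):
    """Raised for unusable dilution series or invalid fits."""


@dataclass
class DilutionPoint:
    """One dilution level: template amount per reaction (ng) and replicate
    Ct values.  Published tables often carry only a mean and SD; those can
    be supplied instead of raw replicates."""

    amount_ng: float
    cts: List[float] = field(default_factory=list)
    mean: Optional[float] = None
    sd: Optional[float] = None

    def __post_init__(self):
        if self.amount_ng <= 0:
            raise CurveError(f"amount must be positive, got {self.amount_ng}")
        if not self.cts and self.mean is None:
            raise CurveError("point needs replicate Cts or a mean")
        for ct in self.cts:
            if math.isnan(ct):
                continue  # NaN marks an undetected replicate
            if math.isinf(ct):
                raise CurveError("infinite Ct value")
            if ct <= 0:
                raise CurveError(f"Ct must be positive, got {ct}")

    @property
    def finite_cts(self) -> List[float]:
        return [ct for ct in self.cts if math.isfinite(ct)]

    def stats(self) -> Tuple[float, Optional[float]]:
        """(mean, sample SD) over detected replicates; SD is absent for a
        single replicate."""
        cts = self.finite_cts
        if cts:
            m = float(np.mean(cts))
            s = float(np.std(cts, ddof=1)) if len(cts) > 1 else None
            return m, s
        if self.mean is not None:
            return float(self.mean), self.sd
        return float("nan"), None


@dataclass
class DilutionSeries:
    """Per-channel replicate Ct values over a strictly decreasing series of
    template amounts, with optional no-template control."""

    channel: str
    points: List[DilutionPoint]
    kit: str = ""
    ntc_cts: List[float] = field(default_factory=list)

    def __post_init__(self):
        if len(self.points) < 2:
            raise CurveError("series needs >= 2 dilution points")
        amounts = [p.amount_ng for p in self.points]
        if any(a2 >= a1 for a1, a2 in zip(amounts, amounts[1:])):
            raise CurveError("amounts must be strictly decreasing")
        if self.ntc_cts:
            raise CurveError("a clean series has no Ct in the no-template control")


@dataclass(frozen=True)
class StandardCurveFit:
    slope: float         # cycles per log10 amount (Y)
    intercept: float     # cycles at 1 ng
    r2: float
    efficiency: float    # fraction (Ex)
    point_means: Tuple[float, ...]
    point_sds: Tuple[Optional[float], ...]
    n_points: int

    @property
    def efficiency_percent(self) -> float:
        return 100.0 * self.efficiency


def replicate_stats(
    points: Sequence[DilutionPoint],
) -> List[Tuple[float, Optional[float]]]:
    """Arithmetic mean and sample SD (n-1) per dilution point."""
    if not points:
        raise CurveError("no points")
    return [p.stats() for p in points]


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency ``10^(-1/slope) - 1`` from a standard-curve
    slope; requires slope < 0."""
    if not slope < 0:
        raise CurveError(f"slope must be negative, got {slope}")
    return 10.0 ** (-1.0 / slope) - 1.0


def fit_standard_curve(
    series: DilutionSeries, per_replicate: bool = False
) -> StandardCurveFit:
    """OLS fit of Ct on log10(amount in ng) over >= 3 distinct amounts.

    By default the fit runs on per-point replicate means; with
    ``per_replicate`` every individual Ct contributes its own residual."""
    if len(series.points) < 3:
        raise CurveError("standard-curve fit needs >= 3 dilution points")
    stats_ = replicate_stats(series.points)
    if per_replicate:
        x = [
            math.log10(p.amount_ng)
            for p in series.points
            for _ in (p.finite_cts or [p.mean])
        ]
        y = [ct for p in series.points for ct in (p.finite_cts or [p.mean])]
        xy = [(a, b) for a, b in zip(x, y) if b is not None and math.isfinite(b)]
        x, y = [a for a, _ in xy], [b for _, b in xy]
    else:
        x = [
            math.log10(p.amount_ng)
            for p, (m, _) in zip(series.points, stats_)
            if math.isfinite(m)
        ]
        y = [m for m, _ in stats_ if math.isfinite(m)]
    if len(set(x)) < 3:
        raise CurveError("standard-curve fit needs >= 3 distinct amounts")
    res = stats.linregress(x, y)
    slope = float(res.slope)
    if not math.isfinite(slope):
        raise CurveError("degenerate fit")
    return StandardCurveFit(
        slope=slope,
        intercept=float(res.intercept),
        r2=float(res.rvalue) ** 2,
        efficiency=efficiency_from_slope(slope) if slope < 0 else float("nan"),
        point_means=tuple(m for m, _ in stats_),
        point_sds=tuple(s for _, s in stats_),
        n_points=len(series.points),
    )


def detection_limit(
    series: DilutionSeries, criterion: str = "all"
) -> Optional[float]:
    """Smallest template amount (ng) at which the detection criterion holds:
    ``"all"`` requires every replicate detected (finite Ct present), ``"any"``
    at least one.  ``None`` when nothing is detected."""
    if criterion not in ("all", "any"):
        raise ValueError(f"unknown criterion {criterion!r}")
    detected: Optional[float] = None
    for p in series.points:  # amounts strictly decreasing
        calls = [math.isfinite(ct) for ct in p.cts] or [p.mean is not None]
        ok = all(calls) if criterion == "all" else any(calls)
        if ok:
            detected = p.amount_ng
        else:
            break  # first undetected level ends the contiguous range
    return detected
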
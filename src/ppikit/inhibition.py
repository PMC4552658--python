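"""Tight-binding inhibition: Morrison model and the Henderson estimator.

When inhibitor concentration is comparable to enzyme concentration
(cyclosporin A at low-nanomolar Ki against ~4 nM cyclophilin), free and
total inhibitor differ and the classical IC50 treatment fails.  The
fractional activity is then the root of the Morrison binding quadratic,
and the Henderson plot -- [I]/(1 - v/v0) against v0/v -- is its exact
linearization: the slope is the apparent Ki and the intercept the total
active enzyme.  ``henderson_fit`` implements that estimator by ordinary
(unweighted) least squares, as a "line of best fit" implies.

Two variants of the rate used in the plot are provided.  The observed
rate constant contains an uncatalysed background ku; using raw k/k0
biases the estimate when ku is not negligible, so the default variant
works on the enzymatic component v = k - ku.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "InhibitionSeries",
    "HendersonResult",
    "ResidualActivity",
    "morrison_fraction",
    "henderson_fit",
    "percent_residual_activity",
    "dose_response_table",
]

logger = logging.getLogger(__name__)

Variant = Literal["enzymatic-rate", "raw-rate"]


@dataclass(frozen=True)
class InhibitionSeries:
    """(inhibitor concentration, rate constant) pairs with references.

    ``k0`` is the uninhibited catalysed rate constant and ``ku`` the
    uncatalysed background; both are required to express rates as
    enzymatic components.  ``replicates`` optionally carries the raw
    per-point replicate rate constants (one sequence per concentration)
    from which the ``points`` rates were averaged.
    """

    inhibitor_name: str
    concentrations: np.ndarray
    rate_constants: np.ndarray
    k0: float
    ku: float
    replicates: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        k = np.asarray(self.rate_constants, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "rate_constants", k)
        if conc.shape != k.shape or conc.ndim != 1:
            raise ValueError("concentrations and rate_constants must be equal-length 1-D")
        if np.any(conc < 0):
            raise ValueError("inhibitor concentrations must be >= 0")
        if np.any(k < 0):
            raise ValueError("rate constants must be >= 0")
        if not self.k0 > self.ku:
            raise ValueError(f"k0 ({self.k0}) must exceed ku ({self.ku})")
        if self.ku < 0:
            raise ValueError("ku must be >= 0")
        if self.replicates is not None and len(self.replicates) != conc.size:
            raise ValueError("one replicate tuple per concentration required")

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.concentrations.tolist(), self.rate_constants.tolist()))

    def __len__(self) -> int:
        return int(self.concentrations.size)


@dataclass(frozen=True)
class HendersonResult:
    """Ki (slope) and active-enzyme estimate (intercept) of the linear fit."""

    ki: float
    enzyme_est: float
    r_squared: float
    n_used: int
    variant: Variant

    def __post_init__(self) -> None:
        if self.n_used < 2:
            raise ValueError("a Henderson fit needs >= 2 usable points")


class ResidualActivity(NamedTuple):
    percent: float
    clipped: bool


def morrison_fraction(enzyme: float, inhibitor, ki: float):
    """Fractional activity under exact tight-binding (Morrison) inhibition.

    a = 1 - [(E + I + Ki) - sqrt((E + I + Ki)^2 - 4*E*I)] / (2*E)

    which is the free-enzyme fraction when inhibitor depletion matters.
    Accepts a scalar or array inhibitor concentration.  Bounded in
    [0, 1] and monotone decreasing in I; reduces to Ki/(Ki + I) as
    E -> 0.
    """
    inhibitor = np.asarray(inhibitor, dtype=float)
    if enzyme <= 0:
        raise ValueError("enzyme must be > 0")
    if ki <= 0:
        raise ValueError("ki must be > 0")
    if np.any(inhibitor < 0):
        raise ValueError("inhibitor must be >= 0")
    s = enzyme + inhibitor + ki
    disc = s * s - 4.0 * enzyme * inhibitor
    bound = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * enzyme)
    a = np.clip(1.0 - bound, 0.0, 1.0)
    return float(a) if a.ndim == 0 else a


def henderson_fit(
    series: InhibitionSeries, variant: Variant = "enzymatic-rate"
) -> HendersonResult:
    """Estimate Ki and active enzyme from a titration by the Henderson plot.

    Regresses y = I/(1 - v/v0) on x = v0/v by unweighted ordinary least
    squares.  For the default ``enzymatic-rate`` variant the rate v is
    the enzymatic component k - ku and v0 = k0 - ku; the ``raw-rate``
    variant uses v = k, v0 = k0 directly.  On noiseless data generated
    from the Morrison model the enzymatic-rate recovery is exact
    (Henderson is an algebraic rearrangement of Morrison).

    Points with I = 0 (undefined y), v <= 0, or v >= v0 are excluded
    with a logged warning.  Fewer than 2 usable points is an error.
    """
    if variant not in ("enzymatic-rate", "raw-rate"):
        raise ValueError(f"unknown variant {variant!r}")
    conc = series.concentrations
    k = series.rate_constants
    if variant == "enzymatic-rate":
        v = k - series.ku
        v0 = series.k0 - series.ku
    else:
        v = k.copy()
        v0 = series.k0

    usable = (conc > 0) & (v > 0) & (v < v0)
    n_dropped = int(np.sum(~usable))
    if n_dropped:
        logger.warning(
            "henderson_fit(%s): excluded %d point(s) with I=0 or rate outside (0, v0)",
            series.inhibitor_name, n_dropped,
        )
    if int(np.sum(usable)) < 2:
        raise ValueError(
            "henderson_fit needs >= 2 points with I > 0 and rate strictly "
            "inside the inhibited range (no inhibition signal?)"
        )
    vi = v[usable]
    x = v0 / vi
    y = conc[usable] / (1.0 - vi / v0)
    slope, intercept = np.polyfit(x, y, 1)
    y_hat = slope * x + intercept
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return HendersonResult(
        ki=float(slope),
        enzyme_est=float(intercept),
        r_squared=r2,
        n_used=int(np.sum(usable)),
        variant=variant,
    )


def percent_residual_activity(k: float, k0: float, ku: float) -> ResidualActivity:
    """Residual activity, percent of the uninhibited control.

    100 * (k - ku) / (k0 - ku), clipped to [0, 100]; ``clipped`` flags
    when the raw value fell outside that range (noise can push it out).
    """
    if not k0 > ku:
        raise ValueError(f"k0 ({k0}) must exceed ku ({ku})")
    raw = 100.0 * (k - ku) / (k0 - ku)
    clipped = not 0.0 <= raw <= 100.0
    return ResidualActivity(percent=float(min(max(raw, 0.0), 100.0)), clipped=clipped)


def dose_response_table(series: InhibitionSeries) -> pd.DataFrame:
    """Per-concentration residual-activity table.

    Columns: ``conc_M``, ``percent_residual`` (from the averaged rate),
    ``mean`` and ``sd`` (over replicates when present, else equal to
    ``percent_residual`` and NaN).
    """
    rows = []
    for i, (conc, k) in enumerate(zip(series.concentrations, series.rate_constants)):
        pct = percent_residual_activity(float(k), series.k0, series.ku).percent
        if series.replicates is not None:
            reps = [
                percent_residual_activity(r, series.k0, series.ku).percent
                for r in series.replicates[i]
            ]
            mean = float(np.mean(reps))
            sd = float(np.std(reps, ddof=1)) if len(reps) > 1 else 0.0
        else:
            mean, sd = pct, float("nan")
        rows.append(
            {"conc_M": float(conc), "percent_residual": pct, "mean": mean, "sd": sd}
        )
    return pd.DataFrame(rows, columns=["conc_M", "percent_residual", "mean", "sd"])
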
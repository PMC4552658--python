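"""Seeded generators for every input the pipeline consumes.

All generators are pure functions of their arguments and the seed
carried by :class:`NoiseSpec`; with sd = 0 their output satisfies the
model equations to machine precision.  Noise is additive Gaussian — on
absorbance for traces and on rate constants for titrations, matching
how the assay reports mean +/- SD of triplicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ppikit.assay import AssayConditions, ProgressCurve, closed_form_trace
from ppikit.inhibition import InhibitionSeries, morrison_fraction

__all__ = [
    "NoiseSpec",
    "TitrationDesign",
    "generate_trace",
    "generate_titration",
    "generate_inactivation_timecourse",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise: ``sd_abs`` in AU for traces, in 1/s when
    applied to rate constants.  The seed is mandatory so every generator
    is reproducible."""

    sd_abs: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_abs < 0:
            raise ValueError("sd_abs must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class TitrationDesign:
    """Design of one inhibitor titration under the tight-binding model.

    ``k0`` is the uninhibited catalysed rate, ``ku`` the uncatalysed
    background; rate constants are generated as
    k(I) = ku + a(E, I, Ki) * (k0 - ku) with the Morrison fractional
    activity a.  ``replicates`` rate constants are drawn per
    concentration (default 3, emulating triplicate assays).
    """

    inhibitor_name: str
    concentrations: tuple[float, ...]
    true_ki: float
    enzyme: float
    k0: float = 0.036
    ku: float = 0.015
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    replicates: int = 3

    def __post_init__(self) -> None:
        conc = tuple(float(c) for c in self.concentrations)
        object.__setattr__(self, "concentrations", conc)
        if any(c < 0 for c in conc):
            raise ValueError("concentrations must be >= 0")
        if sum(c > 0 for c in conc) < 4:
            raise ValueError("need at least 4 strictly positive concentrations")
        if self.true_ki <= 0:
            raise ValueError("true_ki must be > 0")
        if self.enzyme <= 0:
            raise ValueError("enzyme must be > 0")
        if not self.k0 > self.ku >= 0:
            raise ValueError("need k0 > ku >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def generate_trace(
    conditions: AssayConditions,
    k_obs: float,
    noise: NoiseSpec = NoiseSpec(),
    n_points: int = 361,
) -> ProgressCurve:
    """Closed-form trace plus i.i.d. Gaussian absorbance noise."""
    clean = closed_form_trace(conditions, k_obs, n_points)
    if noise.sd_abs == 0:
        return clean
    a = clean.absorbances + noise.rng().normal(0.0, noise.sd_abs, size=len(clean))
    return ProgressCurve(clean.times, a, conditions, provenance="simulated-closed-form")


def generate_titration(design: TitrationDesign) -> InhibitionSeries:
    """Rate-constant titration under the Morrison tight-binding model.

    For each concentration I the noiseless rate is
    k(I) = ku + a(E, I, Ki)*(k0 - ku); Gaussian noise of the design's sd
    is added independently to each replicate and the reported rate is
    the replicate mean.  Identical designs (including seed) give
    identical series.
    """
    conc = np.asarray(design.concentrations, dtype=float)
    a = morrison_fraction(design.enzyme, conc, design.true_ki)
    k_true = design.ku + np.asarray(a) * (design.k0 - design.ku)
    rng = design.noise.rng()
    if design.noise.sd_abs == 0:
        reps = np.tile(k_true[:, None], (1, design.replicates))
    else:
        reps = k_true[:, None] + rng.normal(
            0.0, design.noise.sd_abs, size=(conc.size, design.replicates)
        )
        reps = np.maximum(reps, 0.0)
    k_mean = reps.mean(axis=1)
    return InhibitionSeries(
        inhibitor_name=design.inhibitor_name,
        concentrations=conc,
        rate_constants=k_mean,
        k0=design.k0,
        ku=design.ku,
        replicates=tuple(tuple(row) for row in reps.tolist()),
    )


def generate_inactivation_timecourse(
    k_inact: float,
    times,
    k0: float,
    ku: float,
    noise: NoiseSpec = NoiseSpec(),
) -> list[tuple[float, float]]:
    """Single-exponential enzyme inactivation time course.

    k(t) = ku + (k0 - ku)*exp(-k_inact*t) plus Gaussian noise; with
    k_inact = 0 the activity stays at k0 (the inactivation-insensitive
    phenotype).
    """
    if k_inact < 0:
        raise ValueError("k_inact must be >= 0")
    t = np.asarray(times, dtype=float)
    k = ku + (k0 - ku) * np.exp(-k_inact * t)
    if noise.sd_abs > 0:
        k = k + noise.rng().normal(0.0, noise.sd_abs, size=t.size)
    return list(zip(t.tolist(), k.tolist()))
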
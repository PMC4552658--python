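"""Models of the chymotrypsin-coupled cis-trans isomerization assay.

The assay monitors release of p-nitroaniline at 390 nm: the protease
cleaves the chromophore only from the trans isomer of the test peptide,
so the slow cis->trans conversion appears as a first-order absorbance
phase.  Two simulators are provided:

* :func:`closed_form_trace` -- the pseudo-first-order closed form used
  for fitting, valid in the limit of instantaneous proteolysis of the
  trans pool.
* :func:`ode_trace` -- the full three-species mechanism (cis, trans,
  cleaved product) with finite protease rate, used as an internal
  oracle for the closed form.

Catalysis is modeled as a first-order acceleration of the cis->trans
step (kcat/Km regime): the cis substrate pool (~8 uM at the default 10%
cis fraction) is assumed well below Km, so the enzymatic contribution to
the observed rate constant is ``catalytic_efficiency * [E]``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "AssayConditions",
    "ProgressCurve",
    "IntegrationError",
    "observed_rate_constant",
    "closed_form_trace",
    "ode_trace",
]


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails; carries its diagnostic."""


@dataclass(frozen=True)
class AssayConditions:
    """Concentrations and physical constants defining one coupled-assay run.

    Parameters
    ----------
    substrate_total : float
        Total peptide substrate, mol/L (default 80 uM).
    cis_fraction : float
        Equilibrium fraction of substrate with the Xaa-Pro bond in cis,
        in (0, 1).  The default 0.10 is the conventional aqueous value
        for this peptide; it is not a measured quantity and only scales
        amplitudes, never rate constants.
    enzyme : float
        Isomerase concentration, mol/L.
    protease_rate : float
        Pseudo-first-order cleavage rate of the trans isomer, 1/s.
        Proportional to protease concentration; the default is fast
        relative to typical observed rates (protease in large excess).
    uncat_rate : float
        Uncatalysed cis->trans rate constant k_u, 1/s.
    catalytic_efficiency : float
        kcat/Km of the isomerase, 1/(M*s).
    extinction_coeff : float
        Molar absorptivity of released p-nitroaniline at 390 nm,
        1/(M*cm).  The default 13300 is the conventional literature
        value; it affects only absorbance scaling.
    path_length : float
        Optical path, cm.
    baseline_abs : float
        Absorbance offset, AU.
    temperature_c : float
        Assay temperature, degrees C (metadata only).
    duration : float
        Trace length, s (default 360).
    """

    substrate_total: float = 80e-6
    cis_fraction: float = 0.10
    enzyme: float = 0.0
    protease_rate: float = 10.0
    uncat_rate: float = 0.015
    catalytic_efficiency: float = 0.0
    extinction_coeff: float = 13300.0
    path_length: float = 1.0
    baseline_abs: float = 0.0
    temperature_c: float = 15.0
    duration: float = 360.0

    def __post_init__(self) -> None:
        nonneg = (
            "substrate_total",
            "enzyme",
            "protease_rate",
            "uncat_rate",
            "catalytic_efficiency",
            "extinction_coeff",
            "path_length",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 < self.cis_fraction < 1.0:
            raise ValueError(f"cis_fraction must lie in (0, 1), got {self.cis_fraction}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")

    @property
    def cis_substrate(self) -> float:
        """Initial cis substrate pool, mol/L."""
        return self.cis_fraction * self.substrate_total

    @property
    def trans_substrate(self) -> float:
        """Initial trans substrate pool, mol/L."""
        return (1.0 - self.cis_fraction) * self.substrate_total

    def with_(self, **changes) -> "AssayConditions":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class ProgressCurve:
    """A time/absorbance series and the conditions it was recorded under."""

    times: np.ndarray
    absorbances: np.ndarray
    conditions: AssayConditions
    provenance: str = "measured"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.absorbances, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "absorbances", a)
        if t.ndim != 1 or a.ndim != 1:
            raise ValueError("times and absorbances must be 1-D")
        if t.shape != a.shape:
            raise ValueError(
                f"length mismatch: {t.size} times vs {a.size} absorbances"
            )
        if t.size < 4:
            raise ValueError("a progress curve needs >= 4 points")
        if t[0] < 0:
            raise ValueError("times must start at >= 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


def observed_rate_constant(
    uncat_rate: float, catalytic_efficiency: float, enzyme: float
) -> float:
    """Observed first-order rate constant k_obs = k_u + (kcat/Km)*[E].

    The observed cis->trans rate is the uncatalysed background plus the
    enzymatic acceleration, which in the kcat/Km regime is linear in
    enzyme concentration.  Monotone non-decreasing in every argument.
    """
    if uncat_rate < 0 or catalytic_efficiency < 0 or enzyme < 0:
        raise ValueError("rate constants and concentrations must be >= 0")
    return uncat_rate + catalytic_efficiency * enzyme


def time_grid(duration: float, n_points: int) -> np.ndarray:
    """Uniform time grid from 0 to ``duration`` inclusive."""
    if n_points < 4:
        raise ValueError("n_points must be >= 4")
    return np.linspace(0.0, duration, n_points)


def closed_form_trace(
    conditions: AssayConditions, k_obs: float, n_points: int = 361
) -> ProgressCurve:
    """Absorbance trace in the instantaneous-proteolysis limit.

    A(t) = baseline + eps*l*[S_trans0 + S_cis0*(1 - exp(-k_obs*t))]

    The trans pool is cleaved instantly (burst at t = 0); the cis pool
    relaxes with the single observed rate constant ``k_obs``.
    """
    if k_obs < 0:
        raise ValueError("k_obs must be >= 0")
    t = time_grid(conditions.duration, n_points)
    eps_l = conditions.extinction_coeff * conditions.path_length
    a = conditions.baseline_abs + eps_l * (
        conditions.trans_substrate
        + conditions.cis_substrate * (1.0 - np.exp(-k_obs * t))
    )
    return ProgressCurve(t, a, conditions, provenance="simulated-closed-form")


def ode_trace(
    conditions: AssayConditions,
    uncat_reverse_rate: float | None = None,
    n_points: int = 361,
    rtol: float = 1e-10,
    atol: float = 1e-14,
) -> ProgressCurve:
    """Integrate the full cis/trans/product mechanism.

    Species: cis and trans substrate, cleaved product P.

        d[cis]/dt   = -(k_ct_u + k_E_ct)*cis + (k_tc_u + k_E_tc)*trans
        d[trans]/dt = +(k_ct_u + k_E_ct)*cis - (k_tc_u + k_E_tc)*trans
                      - k_p*trans
        d[P]/dt     = k_p*trans

    with ``k_ct_u = conditions.uncat_rate`` (uncatalysed cis->trans),
    ``k_tc_u = uncat_reverse_rate`` (uncatalysed trans->cis), protease
    rate ``k_p = conditions.protease_rate``, and the enzymatic rates
    obeying microscopic reversibility ``k_E_ct/k_E_tc = k_ct_u/k_tc_u``.
    When ``uncat_reverse_rate`` is None it is chosen so the cis/trans
    equilibrium matches ``conditions.cis_fraction``.
    A(t) = baseline + eps*l*P(t).  Mass is conserved: at every output
    time, cis + trans + P = substrate_total to integrator tolerance.

    Raises
    ------
    IntegrationError
        If the integrator fails, with its diagnostic message.
    """
    k_ct_u = conditions.uncat_rate
    if uncat_reverse_rate is None:
        uncat_reverse_rate = _equilibrium_reverse_rate(conditions)
    if uncat_reverse_rate < 0:
        raise ValueError("uncat_reverse_rate must be >= 0")
    k_tc_u = uncat_reverse_rate
    k_e_ct = conditions.catalytic_efficiency * conditions.enzyme
    # microscopic reversibility: enzyme accelerates both directions with
    # the same equilibrium constant as the uncatalysed step
    k_e_tc = k_e_ct * (k_tc_u / k_ct_u) if k_ct_u > 0 else 0.0
    k_ct = k_ct_u + k_e_ct
    k_tc = k_tc_u + k_e_tc
    k_p = conditions.protease_rate

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        cis, trans, _p = y
        flux_ct = k_ct * cis - k_tc * trans
        return [-flux_ct, flux_ct - k_p * trans, k_p * trans]

    t = time_grid(conditions.duration, n_points)
    y0 = [conditions.cis_substrate, conditions.trans_substrate, 0.0]
    sol = solve_ivp(
        rhs,
        (t[0], t[-1]),
        y0,
        t_eval=t,
        method="LSODA",
        rtol=rtol,
        atol=atol * max(conditions.substrate_total, 1e-30),
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    product = sol.y[2]
    eps_l = conditions.extinction_coeff * conditions.path_length
    a = conditions.baseline_abs + eps_l * product
    return ProgressCurve(t, a, conditions, provenance="simulated-ode")


def closed_form_deviation(
    conditions: AssayConditions,
    k_obs: float,
    burn_in: float = 30.0,
    n_points: int = 361,
) -> float:
    """Max |A_ode - A_closed| after the burst transient, relative to the
    total absorbance amplitude eps*l*substrate_total.

    The closed form places the trans-pool burst at t = 0+ while the ODE
    resolves it over ~1/protease_rate, so the two are compared only for
    t >= ``burn_in``.  The deviation tends to 0 as protease_rate grows:
    the closed form is the fast-proteolysis limit of the mechanism.
    """
    cf = closed_form_trace(conditions, k_obs, n_points)
    ode = ode_trace(conditions, n_points=n_points)
    mask = cf.times >= burn_in
    if not np.any(mask):
        raise ValueError("burn_in excludes every sample")
    amplitude = (
        conditions.extinction_coeff * conditions.path_length * conditions.substrate_total
    )
    return float(
        np.max(np.abs(ode.absorbances[mask] - cf.absorbances[mask])) / amplitude
    )


def _equilibrium_reverse_rate(conditions: AssayConditions) -> float:
    # trans->cis rate consistent with the stated equilibrium cis fraction:
    # f = k_tc / (k_ct + k_tc)
    f = conditions.cis_fraction
    return conditions.uncat_rate * f / (1.0 - f)


def ode_species(
    conditions: AssayConditions,
    uncat_reverse_rate: float | None = None,
    n_points: int = 361,
    rtol: float = 1e-10,
    atol: float = 1e-14,
) -> tuple[np.ndarray, np.ndarray]:
    """Like :func:`ode_trace` but returns (times, species matrix).

    Species matrix rows are (cis, trans, product); exposed so tests can
    check mass conservation directly.
    """
    k_ct_u = conditions.uncat_rate
    if uncat_reverse_rate is None:
        uncat_reverse_rate = _equilibrium_reverse_rate(conditions)
    k_tc_u = uncat_reverse_rate
    k_e_ct = conditions.catalytic_efficiency * conditions.enzyme
    k_e_tc = k_e_ct * (k_tc_u / k_ct_u) if k_ct_u > 0 else 0.0
    k_ct = k_ct_u + k_e_ct
    k_tc = k_tc_u + k_e_tc
    k_p = conditions.protease_rate

    def rhs(_t, y):
        cis, trans, _p = y
        flux_ct = k_ct * cis - k_tc * trans
        return [-flux_ct, flux_ct - k_p * trans, k_p * trans]

    t = time_grid(conditions.duration, n_points)
    y0 = [conditions.cis_substrate, conditions.trans_substrate, 0.0]
    sol = solve_ivp(
        rhs, (t[0], t[-1]), y0, t_eval=t, method="LSODA",
        rtol=rtol, atol=atol * max(conditions.substrate_total, 1e-30),
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    return t, sol.y
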
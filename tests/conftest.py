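import numpy as np
import pytest

from ppikit.assay import AssayConditions
from ppikit.synth import NoiseSpec, TitrationDesign

# Study regime constants used across the suite.
K_UNCAT = 0.015          # 1/s, uncatalysed background
K_CAT = 0.036            # 1/s, catalysed at 4.34 nM enzyme
ENZYME = 4.34e-9         # mol/L
EFFICIENCY = (K_CAT - K_UNCAT) / ENZYME
KI_CSA = 18.75e-9        # mol/L
KI_CU_LOOSE = 11.16e-6   # mol/L, loose-binding regime
KI_CU_TIGHT = 3.83e-9    # mol/L, tight-binding regime
ENZYME_CU = 22e-9        # mol/L, thiol-modification experiments


@pytest.fixture
def conditions() -> AssayConditions:
    return AssayConditions(enzyme=ENZYME, catalytic_efficiency=EFFICIENCY)


@pytest.fixture
def uncat_conditions() -> AssayConditions:
    return AssayConditions(enzyme=0.0)


@pytest.fixture
def csa_design() -> TitrationDesign:
    return TitrationDesign(
        inhibitor_name="CsA",
        concentrations=tuple(c * 1e-9 for c in (5, 10, 20, 40, 60, 80, 100, 120)),
        true_ki=KI_CSA,
        enzyme=ENZYME,
        k0=K_CAT,
        ku=K_UNCAT,
        noise=NoiseSpec(sd_abs=0.0, seed=0),
    )


def make_titration_design(
    ki: float,
    enzyme: float,
    concentrations,
    sd: float = 0.0,
    seed: int = 0,
    name: str = "inhibitor",
) -> TitrationDesign:
    return TitrationDesign(
        inhibitor_name=name,
        concentrations=tuple(concentrations),
        true_ki=ki,
        enzyme=enzyme,
        k0=K_CAT,
        ku=K_UNCAT,
        noise=NoiseSpec(sd_abs=sd, seed=seed),
    )


def binding_fraction_oracle(enzyme: float, inhibitor: float, ki: float) -> float:
    """Brute-force free-enzyme fraction: solve the binding equilibrium
    EI = (E - EI)(I - EI)/Ki numerically, independent of the quadratic
    closed form under test."""
    from scipy.optimize import brentq

    if inhibitor == 0:
        return 1.0

    def f(ei: float) -> float:
        return (enzyme - ei) * (inhibitor - ei) / ki - ei

    hi = min(enzyme, inhibitor)
    ei = brentq(f, 0.0, hi, xtol=1e-30, rtol=1e-15)
    return 1.0 - ei / enzyme
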
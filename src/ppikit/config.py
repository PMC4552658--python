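"""Run configuration, inhibitor-design presets, and the reproduction report.

The presets encode the study's assay regimes: the CsA titration at
4.34 nM enzyme, and the Cu2+ titrations at 22 nM enzyme in the
loose-binding (Ki ~ 11 uM) and tight-binding (Ki ~ 4 nM) regimes.  The
``reproduce`` report regenerates all of them from seeds, runs the
estimators, and tabulates computed values against the published
reference values.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from ppikit.assay import AssayConditions, closed_form_trace, observed_rate_constant
from ppikit.fitting import catalytic_efficiency, fit_first_order
from ppikit.inhibition import henderson_fit
from ppikit.synth import NoiseSpec, TitrationDesign, generate_titration

__all__ = [
    "RunConfig",
    "REFERENCE_VALUES",
    "PRESETS",
    "default_config",
    "load_config",
    "run_reproduction_report",
]

# Published reference values the pipeline is expected to reproduce.
REFERENCE_VALUES = {
    "k_uncat_per_s": 0.015,
    "k_cat_per_s": 0.036,
    "enzyme_M": 4.34e-9,
    "catalytic_efficiency_M1s1": 4.88e6,
    "ki_csa_M": 18.75e-9,
    "ki_cu_atcyp19_3_M": 11.16e-6,
    "ki_cu_tacypa_1_M": 3.83e-9,
}

# Rate constants used when generating titrations: the uninhibited
# catalysed rate at 4.34 nM enzyme and the uncatalysed background.
_K0 = REFERENCE_VALUES["k_cat_per_s"]
_KU = REFERENCE_VALUES["k_uncat_per_s"]


def _nM(*values: float) -> tuple[float, ...]:
    return tuple(v * 1e-9 for v in values)


def _uM(*values: float) -> tuple[float, ...]:
    return tuple(v * 1e-6 for v in values)


PRESETS: dict[str, TitrationDesign] = {
    "csa": TitrationDesign(
        inhibitor_name="CsA",
        concentrations=_nM(5, 10, 20, 40, 60, 80, 100, 120),
        true_ki=REFERENCE_VALUES["ki_csa_M"],
        enzyme=REFERENCE_VALUES["enzyme_M"],
        k0=_K0,
        ku=_KU,
    ),
    "cu-atcyp19-3": TitrationDesign(
        inhibitor_name="Cu2+",
        concentrations=_uM(1, 2, 5, 10, 20, 40, 70, 100),
        true_ki=REFERENCE_VALUES["ki_cu_atcyp19_3_M"],
        enzyme=22e-9,
        k0=_K0,
        ku=_KU,
    ),
    "cu-tacypa-1": TitrationDesign(
        inhibitor_name="Cu2+",
        concentrations=_nM(1, 2, 5, 10, 25, 50, 100, 200),
        true_ki=REFERENCE_VALUES["ki_cu_tacypa_1_M"],
        enzyme=22e-9,
        k0=_K0,
        ku=_KU,
    ),
}


@dataclass(frozen=True)
class RunConfig:
    """Seeds, assay defaults, noise defaults, and fit tolerances."""

    seed: int = 20150915
    conditions: AssayConditions = field(default_factory=AssayConditions)
    trace_noise_sd: float = 0.0
    titration_noise_sd: float = 0.0
    n_points: int = 361
    output_dir: str = "."
    verbosity: int = 0

    def preset(self, name: str) -> TitrationDesign:
        try:
            design = PRESETS[name]
        except KeyError:
            raise ValueError(
                f"unknown preset {name!r}; available: " + ", ".join(sorted(PRESETS))
            ) from None
        return replace(
            design, noise=NoiseSpec(sd_abs=self.titration_noise_sd, seed=self.seed)
        )


def default_config() -> RunConfig:
    return RunConfig()


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config; unspecified keys keep their defaults."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    cond = AssayConditions(**data.pop("conditions", {}))
    return RunConfig(conditions=cond, **data)


def config_to_yaml(config: RunConfig) -> str:
    data = {
        "seed": config.seed,
        "trace_noise_sd": config.trace_noise_sd,
        "titration_noise_sd": config.titration_noise_sd,
        "n_points": config.n_points,
        "output_dir": config.output_dir,
        "verbosity": config.verbosity,
        "conditions": {
            "substrate_total": config.conditions.substrate_total,
            "cis_fraction": config.conditions.cis_fraction,
            "enzyme": config.conditions.enzyme,
            "protease_rate": config.conditions.protease_rate,
            "uncat_rate": config.conditions.uncat_rate,
            "catalytic_efficiency": config.conditions.catalytic_efficiency,
            "extinction_coeff": config.conditions.extinction_coeff,
            "path_length": config.conditions.path_length,
            "baseline_abs": config.conditions.baseline_abs,
            "temperature_c": config.conditions.temperature_c,
            "duration": config.conditions.duration,
        },
    }
    return yaml.safe_dump(data, sort_keys=False)


def run_reproduction_report(config: RunConfig | None = None) -> str:
    """Run the full pipeline on generated fixtures and tabulate results.

    Rows: rate-constant recovery for the uncatalysed and catalysed
    traces, catalytic efficiency, and the three inhibition constants.
    Deterministic under a fixed config seed.
    """
    cfg = config or default_config()
    out = io.StringIO()
    rows: list[tuple[str, float, float]] = []

    # Rate-constant recovery from simulated traces.
    enzyme = REFERENCE_VALUES["enzyme_M"]
    eff_true = (_K0 - _KU) / enzyme
    base = cfg.conditions.with_(uncat_rate=_KU)
    for label, cond, k_true in (
        ("k_uncat (1/s)", base.with_(enzyme=0.0), _KU),
        (
            "k_cat @4.34nM (1/s)",
            base.with_(enzyme=enzyme, catalytic_efficiency=eff_true),
            observed_rate_constant(_KU, eff_true, enzyme),
        ),
    ):
        trace = closed_form_trace(cond, k_true, cfg.n_points)
        fit = fit_first_order(trace)
        rows.append((label, fit.k, k_true))

    k_unc, k_cat = rows[0][1], rows[1][1]
    eff = catalytic_efficiency(k_cat, k_unc, enzyme)
    rows.append(
        ("kcat/Km (1/(M*s))", eff, REFERENCE_VALUES["catalytic_efficiency_M1s1"])
    )

    for preset_name, ref_key, label in (
        ("csa", "ki_csa_M", "Ki CsA (M)"),
        ("cu-atcyp19-3", "ki_cu_atcyp19_3_M", "Ki Cu2+ AtCyp19-3 (M)"),
        ("cu-tacypa-1", "ki_cu_tacypa_1_M", "Ki Cu2+ TaCypA-1 (M)"),
    ):
        try:
            series = generate_titration(cfg.preset(preset_name))
            result = henderson_fit(series)
        except Exception as exc:  # surface the failing stage by name
            raise RuntimeError(f"stage {preset_name!r} failed: {exc}") from exc
        rows.append((label, result.ki, REFERENCE_VALUES[ref_key]))

    out.write(f"# reproduction report (seed={cfg.seed})\n")
    out.write(f"{'quantity':<28}{'computed':>14}{'reference':>14}{'rel_err':>10}\n")
    for label, computed, reference in rows:
        rel = abs(computed - reference) / abs(reference)
        out.write(f"{label:<28}{computed:>14.6g}{reference:>14.6g}{rel:>10.2e}\n")
    return out.getvalue()
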
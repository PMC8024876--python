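"""Validated YAML configuration schemas for CLI runs.

Unknown keys are rejected (``extra='forbid'``) so a typo in a config file
fails loudly with the offending field named.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MModelConfig(_Strict):
    N: int = 100
    k0: float = 0.42
    k_fb: float = 20.0
    reach: int = 99
    hill_n: float = 3.0
    alpha: float = 1.95
    T_div: Optional[float] = 20.0
    theta_act: float = 0.1


class DilutionConfig(_Strict):
    N: int = 40
    T_div: float = 20.0
    theta_act: float = 0.1
    residual_alpha: float = 0.0


class MCModelConfig(_Strict):
    N: int = 60
    k_me: float = 20.0
    gamma_c: float = 2.0
    alpha: float = 20.0
    beta_c: float = 0.5
    k_on: float = 0.05714285714285714
    k_off: float = 0.4
    a_me: float = 1.2
    d_me: float = 0.8333333333333334
    u_adhesion: float = 1.0
    C_min: int = 47
    phi: float = 0.01
    T_div: Optional[float] = 20.0


class TFConfig(_Strict):
    N_B: int = 2
    tf_conc: float = 1.0
    k_bind_per_conc: float = 10.0
    k_unbind: float = 1.0
    mechanism: Literal["blocking", "demethylation"] = "blocking"
    N_R: int = 0
    alpha_mult: float = 20.0


class SimulateConfig(_Strict):
    model: Literal["m", "mc", "dilution"]
    n_runs: int = 200
    t_max: float = 2000.0
    m_params: Optional[MModelConfig] = None
    mc_params: Optional[MCModelConfig] = None
    dilution_params: Optional[DilutionConfig] = None


class ScanConfig(_Strict):
    model: Literal["m", "mc"]
    kind: Literal["dose", "cell_cycle"]
    target: Literal["k_me", "alpha"] = "alpha"  # dose scans only
    multipliers: list[float] = [0.5, 1.0, 2.0]
    T_div_list: list[float] = [10.0, 20.0, 40.0]
    n_runs: int = 200
    t_max: float = 2000.0
    m_params: Optional[MModelConfig] = None
    mc_params: Optional[MCModelConfig] = None


class TFDoseConfig(_Strict):
    mc_params: MCModelConfig = MCModelConfig()
    tf_params: TFConfig = TFConfig()
    tf_grid: list[float] = [0.0, 0.25, 0.5, 1.0, 2.0, 4.0]
    n_runs: int = 100
    t_max: float = 2000.0


class FitActivationConfig(_Strict):
    events_csv: str
    bin_width_h: float = 20.0
    early_window_h: float = 20.0
    n_bins: int = 64
    plateau: Literal["fixed_1", "free_F"] = "fixed_1"


class FitPopulationConfig(_Strict):
    counts_csv: str
    clearance_csv: Optional[str] = None  # columns tau_h, fraction
    delta: Optional[float] = None


class SynthFlowConfig(_Strict):
    lambda_: float = 0.02
    sample_times: list[float] = [10.0, 30.0, 50.0, 70.0, 90.0]
    n_per_time: int = 2000
    start_fraction2: float = 0.0


class SynthPopulationConfig(_Strict):
    kb: float = 0.05
    kd: float = 0.02
    delta: float = 0.10
    X0: int = 100
    Y0: int = 5
    t_end: float = 90.0
    dt: float = 1.0


class SynthClearanceConfig(_Strict):
    delta: float = 0.08
    n_cells: int = 30


class SynthConfig(_Strict):
    kind: Literal["flow", "population", "clearance"]
    flow: SynthFlowConfig = SynthFlowConfig()
    population: SynthPopulationConfig = SynthPopulationConfig()
    clearance: SynthClearanceConfig = SynthClearanceConfig()


SCHEMAS = {
    "simulate-m": SimulateConfig,
    "simulate-mc": SimulateConfig,
    "simulate-dilution": SimulateConfig,
    "scan": ScanConfig,
    "tf-dose": TFDoseConfig,
    "fit-activation": FitActivationConfig,
    "fit-population": FitPopulationConfig,
    "synth": SynthConfig,
}


class ConfigError(ValueError):
    pass


def load_config(path: str | Path, schema: type[_Strict]) -> _Strict:
    """Load and validate a YAML config against its schema."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return schema.model_validate(raw)
    except ValidationError as exc:
        fields = ", ".join(
            ".".join(str(loc) for loc in err["loc"]) or "<root>" for err in exc.errors()
        )
        raise ConfigError(f"invalid config {path}: offending field(s): {fields}\n{exc}") from exc
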
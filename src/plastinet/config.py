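"""Schema-validated pipeline configuration (YAML-backed, unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class GeneratorConfig(_Strict):
    n_nodes: int = Field(100, ge=2)
    conn_prob: float = Field(0.05, ge=0.0, le=1.0)
    mean_syn_per_conn: float = Field(4.1, ge=1.0)
    sd_syn_per_conn: float = Field(2.3, ge=0.0)
    n_fibers: int = Field(200, ge=10)
    n_bundles: int = Field(20, ge=4)
    base_fraction: float = Field(0.12, gt=0.0, lt=0.25)
    n_repetitions: int = Field(5, ge=1)
    isi_ms: float = Field(500.0, gt=0.0)
    rate_max_hz: float = Field(17.5, gt=0.0)
    stim_duration_ms: float = Field(100.0, gt=0.0)
    noise_rate_hz: float = Field(1.0, ge=0.0)
    p_potentiated: float = Field(0.5, ge=0.0, le=1.0)


class PlasticityConfig(_Strict):
    tau_rho_s: float = Field(70.0, gt=0)
    rho_star: float = Field(0.5, gt=0, lt=1)
    gamma_d: float = Field(101.5, gt=0)
    gamma_p: float = Field(216.2, gt=0)
    eta: float = Field(0.04, gt=0, le=1)
    spine_volume_um3: float = Field(0.09, gt=0)
    ca_rest_uM: float = Field(0.07, ge=0)
    tau_ca_ms: float = Field(12.0, gt=0)
    e_nmda_mV: float = -3.0
    mg_theta: float = Field(2.552, gt=0)
    mg_kappa: float = Field(0.072, gt=0)
    mg_out_mM: float = Field(1.0, gt=0)
    tau_star_ms: float = Field(278.318, gt=0)
    tau_change_s: float = Field(100.0, gt=0)
    dt_ms: float = Field(0.1, gt=0)
    report_dt_ms: float = Field(1000.0, gt=0)
    duration_ms: float = Field(10000.0, gt=0)
    u_se_scale: float = Field(1.0, gt=0)


class KernelConfig(_Strict):
    epsp_amplitude_mV: float = Field(8.0, ge=0)
    epsp_rise_ms: float = Field(1.0, gt=0)
    epsp_decay_ms: float = Field(18.0, gt=0)
    bap_amplitude_mV: float = Field(60.0, ge=0)
    bap_rise_ms: float = Field(1.0, gt=0)
    bap_decay_ms: float = Field(4.0, gt=0)
    bap_attenuation_um: float = Field(200.0, gt=0)
    nmda_rise_ms: float = Field(2.0, gt=0)
    nmda_decay_ms: float = Field(40.0, gt=0)
    synaptic_delay_ms: float = Field(1.0, ge=0)
    vdcc_impulse_gain_uM: float = Field(0.02, ge=0)
    v_rest_mV: float = -70.0


class AnalysisConfig(_Strict):
    run_assemblies: bool = True
    run_topology: bool = True
    run_changes: bool = True
    bin_ms: float = Field(20.0, gt=0)
    k_min: int = Field(5, ge=2)
    k_max_clusters: int = Field(20, ge=2)
    k_max_simplices: int = Field(4, ge=1)
    change_tolerance: float = Field(1e-3, ge=0)


class PipelineConfig(_Strict):
    seed: int = Field(0, ge=0, lt=2**31)
    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    plasticity: PlasticityConfig = Field(default_factory=PlasticityConfig)
    kernels: KernelConfig = Field(default_factory=KernelConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    analysis_only: bool = False
    trace_path: Optional[str] = None


def validate_config(raw: dict | None) -> PipelineConfig:
    """Typed, defaulted, range-checked config; pydantic errors name the key."""
    return PipelineConfig.model_validate(raw or {})


def load_config(path) -> PipelineConfig:
    text = Path(path).read_text()
    raw = yaml.safe_load(text) if text.strip() else {}
    return validate_config(raw)


def dump_config(cfg: PipelineConfig) -> str:
    return yaml.safe_dump(cfg.model_dump(), sort_keys=True)
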
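"""Configuration loading/validation and run manifests.

Configs are YAML or JSON trees validated against a strict schema
(unknown keys are rejected, defaults injected).  All physical quantities
carry unit suffixes in their key names (``_ms``, ``_um``, ``_ua``,
``_hz``, ``_mv``).
"""

from __future__ import annotations

import json
import platform
import time
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from . import __version__
from .errors import ConfigError
from .morphology import BCGeometry, RGCGeometry
from .mechanisms import BCParams
from .synapse import ReleaseParams


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SimSection(_Strict):
    dt_ms: float = 0.025
    settle_ms: float = 50.0
    temperature_c: float = 23.0
    record_stride: int = 1

    @field_validator("dt_ms")
    @classmethod
    def _dt_positive(cls, v):
        if v <= 0:
            raise ValueError("dt_ms must be positive")
        return v


class MediumSection(_Strict):
    rho_ext_ohm_cm: float = 1000.0
    electrode_offset_um: tuple[float, float, float] = (0.0, 0.0, -15.0)

    @field_validator("rho_ext_ohm_cm")
    @classmethod
    def _rho_positive(cls, v):
        if v <= 0:
            raise ValueError("rho_ext_ohm_cm must be positive")
        return v


class BCGeometrySection(_Strict):
    soma_diameter_um: float = 6.0
    soma_z_um: float = 25.0
    n_dendrites: int = 4
    dendrite_length_um: float = 4.0
    dendrite_diameter_um: float = 1.0
    dendrite_depth_um: float = 1.5
    axon_length_um: float = 30.0
    axon_diameter_um: float = 0.55
    n_terminals: int = 8
    terminal_diameter_um: float = 3.0
    terminal_length_um: float = 4.0
    terminal_spread_um: float = 4.0
    max_compartment_length_um: float = 5.0

    def build(self) -> BCGeometry:
        return BCGeometry(**self.model_dump())


class RGCGeometrySection(_Strict):
    soma_diameter_um: float = 15.0
    soma_z_um: float = 85.0
    n_dendrites: int = 4
    dendrite_length_um: float = 60.0
    dendrite_diameter_um: float = 1.5
    dendrite_depth_um: float = 15.0
    hillock_length_um: float = 10.0
    hillock_diameter_um: float = 2.5
    ais_length_um: float = 40.0
    ais_diameter_um: float = 1.2
    axon_length_um: float = 1000.0
    axon_diameter_um: float = 1.0
    max_compartment_length_um: float = 5.0
    min_compartment_length_um: float = 3.0

    def build(self) -> RGCGeometry:
        return RGCGeometry(**self.model_dump())


class BCMembraneSection(_Strict):
    e_l_mv: float = -60.0
    ca_e_um: float = 1800.0
    ca_res_um: float = 0.1
    shell_depth_nm: float = 50.0
    tau_ca_ms: float = 50.0
    tau_h_ms: float = 292.0
    act_tau_scale: float = 1.0
    density_table_path: str | None = None

    def build(self) -> BCParams:
        return BCParams(**self.model_dump())


class ReleaseSection(_Strict):
    a_fast_per_ms: float = 0.7596
    kd_um: float = 60.0
    hill_n: float = 2.0
    slow_sensor: str = "independent"
    a_slow_per_ms: float = 0.008
    slow_kd_um: float = 300.0
    slow_hill_n: float = 2.0
    fast_slow_ratio: float = 40.0
    refill_tau_ms: float = 1000.0
    advance: str = "refill"

    def build(self) -> ReleaseParams:
        return ReleaseParams(**self.model_dump())


class SDCurveSection(_Strict):
    n_durations: int = 13
    duration_min_ms: float = 0.1
    duration_max_ms: float = 100.0
    repetitions: int = 20
    criterion: str | None = None
    vesicle_count: float = 3.0


class PulseTrainSection(_Strict):
    frequencies_hz: list[float] = [2.0, 5.0, 10.0, 25.0, 50.0, 0.0]
    amplitude_ua: float = 4.0
    pulse_ms: float = 4.0
    total_s: float = 2.0
    n_seeds: int = 10


class SweepSection(_Strict):
    durations_ms: list[float] = [1.0, 4.0, 10.0]
    amplitudes_ua: list[float] = [1, 2, 3, 5, 8, 12, 16, 20]
    carrier_hz: float = 2.0
    total_s: float = 1.5
    n_seeds: int = 3


class GratingSection(_Strict):
    carrier_hz: float = 50.0
    reversal_hz: float = 1.0
    pulse_ms: float = 4.0
    amplitude_ua: float = 4.0
    total_s: float = 3.0
    refill_tau_ms: float = 500.0
    n_seeds: int = 4


class RetstimConfig(_Strict):
    """Top-level configuration tree with study-condition defaults."""

    sim: SimSection = SimSection()
    medium: MediumSection = MediumSection()
    bc_geometry: BCGeometrySection = BCGeometrySection()
    rgc_geometry: RGCGeometrySection = RGCGeometrySection()
    bc_membrane: BCMembraneSection = BCMembraneSection()
    release: ReleaseSection = ReleaseSection()
    sd_curve: SDCurveSection = SDCurveSection()
    pulse_train: PulseTrainSection = PulseTrainSection()
    sweep: SweepSection = SweepSection()
    grating: GratingSection = GratingSection()
    seed: int = 0


def load_config(path=None) -> RetstimConfig:
    """Load and validate a YAML/JSON config; an empty or missing file
    yields the full default tree.  Schema violations raise
    :class:`ConfigError` naming the offending key path."""
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
    try:
        return RetstimConfig(**data)
    except ValidationError as exc:
        locs = "; ".join(
            "/".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors())
        raise ConfigError(f"invalid config: {locs}") from None


def save_config(config: RetstimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(json.loads(config.model_dump_json()), fh,
                       sort_keys=False)


class RunManifest:
    """Record of one protocol run: config snapshot, seed, outputs."""

    def __init__(self, protocol: str, seed: int, config: RetstimConfig):
        self.data = {
            "protocol": protocol,
            "seed": seed,
            "version": __version__,
            "python": platform.python_version(),
            "started_unix": time.time(),
            "config": json.loads(config.model_dump_json()),
            "outputs": [],
        }

    def add_output(self, path) -> None:
        self.data["outputs"].append(str(path))

    def write(self, path) -> None:
        self.data["finished_unix"] = time.time()
        for out in self.data["outputs"]:
            p = Path(out)
            if not p.exists() or p.stat().st_size == 0:
                raise ConfigError(f"manifest lists missing/empty output {out}")
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2)
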
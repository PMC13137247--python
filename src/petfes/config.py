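"""Structured run configuration.

Pydantic models with unknown keys rejected; a resolved copy of the
configuration is echoed into every run's output directory so results
can be regenerated from the artifacts alone.
"""
from __future__ import annotations

from pathlib import Path
from typing import List, Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import ConfigError


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Section):
    n_units: int = 4
    ring_bond: float = 0.514
    ester_bond: float = 0.24
    glycol_bond: float = 0.15
    angle_ester: float = 112.0
    angle_glycol: float = 77.5


class PotentialConfig(_Section):
    gt_gap: float = -4.09
    barrier: float = 12.0
    gauche_angle: float = 70.0


class RestraintConfig(_Section):
    cv: str = "d1"
    limit: float = 2.4
    k: float = 1500.0
    side: str = "lower"
    exponent: int = 2


class SamplingConfig(_Section):
    T: float = 300.0
    n_sweeps: int = 100_000
    seed: int = 0


class CalibrationConfig(_Section):
    target_gauche: float = 0.91
    target_trans: float = 0.09
    T: float = 303.15
    tolerance: float = 0.002


class ScanConfig(_Section):
    d1_values: List[float] = [0.1, 0.5, 1.0, 1.5, 2.0, 2.4, 2.8,
                              3.2, 3.4, 3.6, 3.8, 4.0]
    n_sweeps: int = 20_000


class MetadConfig(_Section):
    cvs: List[str] = ["d1"]
    w0: float = 0.5
    sigma: float = 0.05
    gamma: float = 15.0
    pace: int = 500


class HrexConfig(_Section):
    n_replicas: int = 8
    lambda_min: float = 0.426934
    exchange_interval: int = 500
    n_steps: int = 20_000
    record_stride: int = 10


class WallConfig(_Section):
    cv: str = "h0"
    limit: float = 0.6
    k: float = 5000.0
    side: str = "upper"


class AnalysisConfig(_Section):
    distance_bin: float = 0.01      # nm
    angle_bin: float = 5.0          # degrees
    transient_fraction: float = 0.2
    n_blocks: int = 5
    bound_threshold: float = 3.0    # nm on d_COM
    bound_side: str = "below"


class ThermoConfig(_Section):
    T: float = 298.15
    V_box: float = 1728.0           # 12 nm cubic box
    dF_box_cpet: float = -60.0
    dF_box_apet: float = -25.0
    penalty: float = 25.0
    n_monomers: int = 4
    sigma_e: float = 0.106
    A_chain: float = 0.20


class RunConfig(_Section):
    geometry: GeometryConfig = GeometryConfig()
    potential: PotentialConfig = PotentialConfig()
    restraint: RestraintConfig = RestraintConfig()
    sampling: SamplingConfig = SamplingConfig()
    calibration: CalibrationConfig = CalibrationConfig()
    scan: ScanConfig = ScanConfig()
    metad: MetadConfig = MetadConfig()
    hrex: HrexConfig = HrexConfig()
    walls: List[WallConfig] = []
    analysis: AnalysisConfig = AnalysisConfig()
    thermo: ThermoConfig = ThermoConfig()

    @classmethod
    def load(cls, path: Optional[str] = None,
             overrides: Optional[list] = None) -> "RunConfig":
        data: dict = {}
        if path is not None:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        for item in overrides or []:
            if "=" not in item:
                raise ConfigError(f"override {item!r} is not key.path=value")
            key, value = item.split("=", 1)
            node = data
            parts = key.split(".")
            for p in parts[:-1]:
                node = node.setdefault(p, {})
            node[parts[-1]] = yaml.safe_load(value)
        try:
            return cls.model_validate(data)
        except ValidationError as exc:
            raise ConfigError(str(exc)) from None

    def echo(self, outdir) -> Path:
        """Write the resolved configuration into the output directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / "config.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)
        return path
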
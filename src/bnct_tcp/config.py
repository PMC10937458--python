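"""YAML configuration for the pipeline.

Schema (all blocks optional; defaults are the published SCC values)::

    survival:
      alpha: 0.2111       # 1/Gy
      d0: 0.9603          # Gy
      dq: 1.8588          # Gy
      beta: 0.0890        # 1/Gy^2, optional: derived from the smooth join if absent
      dt: 4.6628          # Gy, optional: derived if absent
    tcp:
      tcd50: 46.8         # Gy
      gamma50: 2.0
      a: -13
    weighting:
      rbe_neutron: 3.2
      cbe_boron: 3.8
      gamma_weight: 1.0
    fractions: 1
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import yaml

from .dose import WeightingFactors
from .pipeline import PipelineConfig
from .survival import SurvivalParamsUSC
from .tcp import TCPParams

__all__ = ["load_config", "load_weighting_factors", "dump_config"]


def _survival_from_dict(block: dict) -> SurvivalParamsUSC:
    alpha, d0, dq = block["alpha"], block["d0"], block["dq"]
    if "beta" in block or "dt" in block:
        derived = SurvivalParamsUSC.from_smooth_join(alpha, d0, dq)
        return SurvivalParamsUSC(
            alpha=alpha,
            beta=block.get("beta", derived.beta),
            d0=d0,
            dq=dq,
            dt=block.get("dt", derived.dt),
        )
    return SurvivalParamsUSC.from_smooth_join(alpha, d0, dq)


def load_config(source: Union[str, Path, None]) -> PipelineConfig:
    """Load a PipelineConfig from YAML; None returns the defaults."""
    if source is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(source).read_text()) or {}
    kwargs = {}
    if "survival" in raw:
        kwargs["survival"] = _survival_from_dict(raw["survival"])
    if "tcp" in raw:
        kwargs["tcp"] = TCPParams(**raw["tcp"])
    if "fractions" in raw:
        kwargs["fractions"] = int(raw["fractions"])
    return PipelineConfig(**kwargs)


def load_weighting_factors(source: Union[str, Path, None]) -> WeightingFactors:
    if source is None:
        return WeightingFactors()
    raw = yaml.safe_load(Path(source).read_text()) or {}
    return WeightingFactors(**raw.get("weighting", {}))


def dump_config(config: PipelineConfig, sink: Union[str, Path]) -> None:
    data = {
        "survival": {
            "alpha": config.survival.alpha,
            "beta": config.survival.beta,
            "d0": config.survival.d0,
            "dq": config.survival.dq,
            "dt": config.survival.dt,
        },
        "tcp": {
            "tcd50": config.tcp.tcd50,
            "gamma50": config.tcp.gamma50,
            "a": config.tcp.a,
        },
        "fractions": config.fractions,
    }
    Path(sink).write_text(yaml.safe_dump(data, sort_keys=False))
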
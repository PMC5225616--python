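"""Run configuration: YAML document + CLI overrides, validated at load.

Precedence is CLI flag > config file > built-in default.  The ``mapping:``
block overrides the Healthy Days → EQ-5D coefficient table; the
``generator:`` block overrides synthetic-cohort spec fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .errors import ConfigurationError
from .hrqol import MappingCoefficients
from .simulate import CohortSpec, default_spec

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    cohort_path: Optional[Path] = None
    out_dir: Path = Path("results")
    horizon: Optional[float] = None  # L, years; None = max observed time
    bootstrap: int = 500
    seed: int = 0
    log_level: str = "INFO"
    mapping: MappingCoefficients = field(default_factory=MappingCoefficients)
    generator: CohortSpec = field(default_factory=default_spec)

    def validate(self) -> None:
        if self.bootstrap < 0:
            raise ConfigurationError(f"bootstrap must be >= 0, got {self.bootstrap}")
        if self.horizon is not None and self.horizon <= 0:
            raise ConfigurationError(f"horizon must be > 0, got {self.horizon}")
        self.generator.validate()


def _build(cls, block: Dict[str, Any], base=None):
    known = {f.name for f in dc_fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise ConfigurationError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}")
    merged = {**(base.__dict__ if base is not None else {}), **block}
    try:
        return cls(**merged)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"bad {cls.__name__} block: {exc}") from exc


def load_config(path: Optional[Path] = None, **overrides: Any) -> RunConfig:
    """Load configuration, applying keyword overrides (CLI flags) last.

    Overrides with value None are ignored, so absent CLI flags fall
    through to the file or built-in default.
    """
    doc: Dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")

    mapping = _build(MappingCoefficients, doc.pop("mapping", {}) or {})
    gen_block = doc.pop("generator", {}) or {}
    # tuples arrive from YAML as lists
    for key in ("followup_window", "age_range", "weight_distribution"):
        if key in gen_block:
            gen_block[key] = tuple(gen_block[key])
    generator = _build(CohortSpec, gen_block, base=default_spec())

    cfg = _build(RunConfig, doc)
    cfg.mapping = mapping
    cfg.generator = generator

    for key, value in overrides.items():
        if value is None:
            continue
        if key == "n":
            cfg.generator = _build(CohortSpec, {"n": int(value)},
                                   base=cfg.generator)
        elif key == "gen_seed":
            cfg.generator = _build(CohortSpec, {"seed": int(value)},
                                   base=cfg.generator)
        elif hasattr(cfg, key):
            setattr(cfg, key, type(getattr(RunConfig(), key))(value)
                    if getattr(RunConfig(), key) is not None else value)
        else:
            raise ConfigurationError(f"unknown override {key!r}")
    if cfg.cohort_path is not None:
        cfg.cohort_path = Path(cfg.cohort_path)
    cfg.out_dir = Path(cfg.out_dir)
    cfg.validate()
    return cfg
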
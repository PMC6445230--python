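"""Run configuration: validated defaults for the unit-resolution workflow.

The default configuration is the unit-resolution (nominal-mass) setup:
the generic NPS element bounds, the packaged neutral-loss table and
compound database, and ranking weights favouring fragment evidence.  A
JSON file may override any field; unknown keys are rejected with a
suggestion, so a typo never silently falls back to a default.
"""

from __future__ import annotations

import difflib
import json
import re
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

from .enumeration import DEFAULT_ELEMENT_BOUNDS

__all__ = ["RunConfig", "ConfigError", "load_config", "parse_bounds_spec"]


class ConfigError(ValueError):
    """Raised for malformed or unknown configuration input."""


_BOUND_RE = re.compile(r"^\s*([A-Z][a-z]?)\s*=\s*(\d+)\s*:\s*(\d+)\s*$")


def parse_bounds_spec(spec: str) -> Dict[str, Tuple[int, int]]:
    """Parse a bounds string like ``"C=8:15,H=7:20,N=2:4"``."""
    bounds: Dict[str, Tuple[int, int]] = {}
    for part in spec.split(","):
        m = _BOUND_RE.match(part)
        if not m:
            raise ConfigError(
                f"invalid bound syntax {part!r}; expected e.g. C=8:15"
            )
        bounds[m.group(1)] = (int(m.group(2)), int(m.group(3)))
    return bounds


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration."""

    mode: str = "nominal"  # nominal | exact
    tolerance: float = 0.5  # Da in nominal mode; Da or ppm (see tolerance_unit)
    tolerance_unit: str = "Da"  # Da | ppm
    bounds: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_ELEMENT_BOUNDS)
    )
    weights: Tuple[float, float, float] = (0.3, 0.5, 0.2)
    loss_table_path: str = "packaged"
    db_path: str = "packaged"
    precursor_mz: Optional[int] = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("nominal", "exact"):
            raise ConfigError(f"mode must be nominal or exact, got {self.mode!r}")
        if self.tolerance_unit not in ("Da", "ppm"):
            raise ConfigError(f"tolerance_unit must be Da or ppm, got {self.tolerance_unit!r}")
        if self.tolerance <= 0:
            raise ConfigError("tolerance must be positive")
        if len(self.weights) != 3 or any(w < 0 for w in self.weights):
            raise ConfigError("weights must be three non-negative numbers")

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "tolerance": self.tolerance,
            "tolerance_unit": self.tolerance_unit,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "weights": list(self.weights),
            "loss_table_path": self.loss_table_path,
            "db_path": self.db_path,
            "precursor_mz": self.precursor_mz,
            "seed": self.seed,
            "log_level": self.log_level,
        }


def load_config(path: Optional[Union[str, Path]] = None, **overrides) -> RunConfig:
    """Load a RunConfig from a JSON file and/or keyword overrides.

    With no arguments the defaults above are returned.  Unknown keys raise
    :class:`ConfigError` listing valid keys and a closest-match
    suggestion.
    """
    data: dict = {}
    if path is not None:
        try:
            data = json.loads(Path(path).read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: invalid JSON ({exc})") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top-level JSON must be an object")
    data.update(overrides)

    valid = {f.name for f in fields(RunConfig)}
    for key in data:
        if key not in valid:
            hint = difflib.get_close_matches(key, valid, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(
                f"unknown configuration key {key!r}{suggestion} "
                f"(valid keys: {', '.join(sorted(valid))})"
            )

    if "bounds" in data:
        raw = data["bounds"]
        if isinstance(raw, str):
            data["bounds"] = parse_bounds_spec(raw)
        elif isinstance(raw, dict):
            try:
                data["bounds"] = {k: (int(v[0]), int(v[1])) for k, v in raw.items()}
            except (TypeError, IndexError, ValueError) as exc:
                raise ConfigError(
                    f"invalid bounds {raw!r}; expected e.g. {{\"C\": [8, 15]}}"
                ) from exc
        else:
            raise ConfigError("bounds must be a string spec or an object")
    if "weights" in data:
        data["weights"] = tuple(float(w) for w in data["weights"])
    return RunConfig(**data)
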
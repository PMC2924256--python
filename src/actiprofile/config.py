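"""Run configuration: YAML loading, validation, and provenance echoing.

Every tunable threshold lives here with the NHANES-analysis values as
defaults; nothing is hard-coded downstream.  Unknown keys and out-of-range
values are hard errors listing every offender, so a silently misspelled
override can never change an analysis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .bouts import BoutParams
from .day_metrics import CutPointScheme


@dataclass(frozen=True)
class WearConfig:
    min_zero_run: int = 60
    min_wear_minutes: int = 600


@dataclass(frozen=True)
class AggregateConfig:
    averaging: str = "valid_days"  # or "worn_days"


@dataclass(frozen=True)
class SummaryConfig:
    include_underweight: bool = False
    ci_multiplier: float = 1.96
    adjust_for_wear: bool = False
    single_psu: str = "collapse"


@dataclass(frozen=True)
class RunConfig:
    wear: WearConfig = WearConfig()
    cutpoints: CutPointScheme = CutPointScheme()
    censor_below: int = 500
    bouts: BoutParams = BoutParams()
    aggregate: AggregateConfig = AggregateConfig()
    steplevel_bounds: tuple[float, ...] = (2500.0, 5000.0, 7500.0, 10000.0, 12500.0)
    summary: SummaryConfig = SummaryConfig()
    seed: int = 0


_SECTIONS = {
    "wear": WearConfig,
    "cutpoints": CutPointScheme,
    "bouts": BoutParams,
    "aggregate": AggregateConfig,
    "summary": SummaryConfig,
}
_SCALARS = {"censor_below": int, "steplevel_bounds": tuple, "seed": int}


def _build_section(cls, data: dict, errors: list[str], prefix: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    for k in sorted(unknown):
        errors.append(f"unknown key {prefix}.{k}")
    kwargs = {k: v for k, v in data.items() if k in fields}
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        errors.append(f"invalid {prefix}: {exc}")
        return cls()


def config_from_dict(data: dict | None) -> RunConfig:
    """Build a RunConfig from a (possibly nested) plain dict."""
    if not data:
        return RunConfig()
    errors: list[str] = []
    kwargs = {}
    for key, value in data.items():
        if key in _SECTIONS:
            if not isinstance(value, dict):
                errors.append(f"section {key} must be a mapping")
                continue
            kwargs[key] = _build_section(_SECTIONS[key], value, errors, key)
        elif key == "censor_below":
            if not isinstance(value, int) or value < 0:
                errors.append("censor_below must be a non-negative integer")
            else:
                kwargs[key] = value
        elif key == "steplevel_bounds":
            bounds = tuple(float(v) for v in value)
            if len(bounds) != 5 or list(bounds) != sorted(bounds):
                errors.append("steplevel_bounds must be 5 ascending values")
            else:
                kwargs[key] = bounds
        elif key == "seed":
            kwargs[key] = int(value)
        else:
            errors.append(f"unknown key {key}")
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    return RunConfig(**kwargs)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config file; an absent path yields all defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is not None and not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return config_from_dict(data)


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Echo the fully resolved config (with version stamp) for provenance."""
    from . import __version__

    payload = dataclasses.asdict(config)
    payload["actiprofile_version"] = __version__
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
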
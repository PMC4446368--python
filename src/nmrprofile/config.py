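"""Run configuration: a flat TOML file with reproducibility-first defaults.

CLI flags override file values; the effective configuration (including the
seed) is always recorded in the run manifest.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

from .model import InvalidParameterError
from .processing import ProcessingParams
from .profiling import InferenceConfig

__all__ = ["RunConfig", "read_config", "write_config"]


@dataclass
class RunConfig:
    library: str = ""
    input: str = ""
    output: str = "profile.json"
    frequency: float = 500.0
    seed: int = 0
    reference_compound: str = "DSS"
    reference_concentration: float = 500.0
    exclusion: list[tuple[float, float]] = field(default_factory=lambda: [(4.6, 5.0)])
    processing: ProcessingParams = field(default_factory=ProcessingParams)
    inference: InferenceConfig = field(default_factory=InferenceConfig)

    def __post_init__(self) -> None:
        self.exclusion = [tuple(e) for e in self.exclusion]
        self.processing.exclusion = self.exclusion[0] if self.exclusion else (0.0, 0.0)
        self.processing.seed = self.seed
        self.inference.exclusion = list(self.exclusion)
        self.inference.seed = self.seed
        if self.reference_concentration <= 0:
            raise InvalidParameterError("reference_concentration must be > 0")


def read_config(path: str | Path) -> RunConfig:
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    proc = data.pop("processing", {})
    inf = data.pop("inference", {})
    cfg = RunConfig(**data)
    if proc:
        zf = proc.get("zero_fill_to")
        if zf == 0:
            proc["zero_fill_to"] = None
        known = {k: v for k, v in proc.items() if hasattr(cfg.processing, k)}
        if "ref_window" in known:
            known["ref_window"] = tuple(known["ref_window"])
        cfg.processing = replace(cfg.processing, **known)
    if inf:
        known = {k: v for k, v in inf.items() if hasattr(cfg.inference, k)}
        cfg.inference = replace(cfg.inference, **known)
    cfg.__post_init__()
    return cfg


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise InvalidParameterError(f"cannot serialize {type(v).__name__} to TOML")


def write_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config that round-trips losslessly through read_config."""
    lines = []
    top = {
        k: v
        for k, v in asdict(cfg).items()
        if k not in ("processing", "inference")
    }
    for k, v in top.items():
        lines.append(f"{k} = {_toml_value(v)}")
    lines.append("")
    lines.append("[processing]")
    for k, v in asdict(cfg.processing).items():
        if k in ("exclusion", "seed"):
            continue  # owned by the top level
        if k == "zero_fill_to" and v is None:
            v = 0
        lines.append(f"{k} = {_toml_value(v)}")
    lines.append("")
    lines.append("[inference]")
    for k, v in asdict(cfg.inference).items():
        if k in ("exclusion", "seed"):
            continue
        lines.append(f"{k} = {_toml_value(v)}")
    Path(path).write_text("\n".join(lines) + "\n")
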
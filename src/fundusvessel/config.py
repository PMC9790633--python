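"""Run configuration: scan, labeling and statistics options in one place.

The defaults reproduce the reference operating point of the method:
detection threshold at 80% of the intensity scale, 30 sampling rings, and
a measurement annulus from 2x to 4x the optic-disc radius.  Configurations
round-trip losslessly through TOML (``dump_toml`` / ``load_toml``); CLI
flags override file values.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

from .av_labeling import LabelingPolicy
from .errors import ConfigError
from .radial_scan import ScanConfig


@dataclass(frozen=True)
class StatsOptions:
    alpha: float = 0.05
    welch: bool = False
    holm: bool = False


@dataclass(frozen=True)
class RunConfig:
    scan: ScanConfig = field(default_factory=ScanConfig)
    labeling: LabelingPolicy = field(default_factory=LabelingPolicy)
    stats: StatsOptions = field(default_factory=StatsOptions)
    log_level: str = "INFO"

    def with_overrides(self, **kw) -> "RunConfig":
        """Return a copy with dotted-section overrides applied.

        Keys are the flat field names of the subsections (e.g.
        ``threshold_fraction``, ``mode``, ``alpha``); ``None`` values are
        ignored so optional CLI flags can be passed straight through.
        """
        scan_kw, label_kw, stats_kw, top_kw = {}, {}, {}, {}
        scan_fields = {f.name for f in fields(ScanConfig)}
        label_fields = {f.name for f in fields(LabelingPolicy)}
        stats_fields = {f.name for f in fields(StatsOptions)}
        for key, val in kw.items():
            if val is None:
                continue
            if key in scan_fields:
                scan_kw[key] = val
            elif key in label_fields:
                label_kw[key] = val
            elif key in stats_fields:
                stats_kw[key] = val
            elif key == "log_level":
                top_kw[key] = val
            else:
                raise ConfigError(f"unknown configuration key {key!r}")
        return RunConfig(
            scan=replace(self.scan, **scan_kw),
            labeling=replace(self.labeling, **label_kw),
            stats=replace(self.stats, **stats_kw),
            log_level=top_kw.get("log_level", self.log_level))


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    raise ConfigError(f"cannot serialise {type(v).__name__} to TOML")


def dump_toml(config: RunConfig, path: str | Path | None = None) -> str:
    """Serialise a RunConfig to TOML text (and optionally to a file).

    The stdlib reads TOML but cannot write it, so this emits the small
    subset the config needs: flat ``[scan]``/``[labeling]``/``[stats]``
    tables plus inline tables for the integer-keyed override maps.
    """
    lines = [f"log_level = {_toml_value(config.log_level)}", ""]
    for section, obj in (("scan", config.scan), ("labeling", config.labeling),
                         ("stats", config.stats)):
        lines.append(f"[{section}]")
        for key, val in asdict(obj).items():
            if val is None:
                continue    # omitted keys read back as defaults
            if isinstance(val, dict):
                items = ", ".join(f'"{k}" = {_toml_value(v)}'
                                  for k, v in val.items())
                lines.append(f"{key} = {{ {items} }}")
            else:
                lines.append(f"{key} = {_toml_value(val)}")
        lines.append("")
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text


def load_toml(path: str | Path) -> RunConfig:
    """Read a RunConfig from a TOML file written by :func:`dump_toml`
    (or hand-written with the same sections)."""
    try:
        data = tomllib.loads(Path(path).read_text())
    except (OSError, tomllib.TOMLDecodeError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    scan_kw = dict(data.get("scan", {}))
    if "inner_radius_overrides" in scan_kw:
        scan_kw["inner_radius_overrides"] = {
            int(k): float(v)
            for k, v in scan_kw["inner_radius_overrides"].items()}
    label_kw = dict(data.get("labeling", {}))
    if "manual_labels" in label_kw:
        label_kw["manual_labels"] = {int(k): v
                                     for k, v in label_kw["manual_labels"].items()}
    try:
        return RunConfig(scan=ScanConfig(**scan_kw),
                         labeling=LabelingPolicy(**label_kw),
                         stats=StatsOptions(**data.get("stats", {})),
                         log_level=data.get("log_level", "INFO"))
    except TypeError as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc
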
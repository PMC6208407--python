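"""Study configuration.

One YAML file describes an entire analysis: the channel layout of the
section TIFFs, the physical calibration, probe width, subsampling scheme and
the height-search tunables.  The CLI and the library share this object.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .thickness import HeightSearchConfig


@dataclass
class StudyConfig:
    channels: list[str] = field(default_factory=lambda: ["dapi", "marker1", "marker2"])
    dapi_channel: str = "dapi"
    microns_per_pixel: float = 0.64
    section_thickness_um: float = 50.0
    probe_width_um: float = 50.0
    n_sections: int = 43
    subsample_n: int = 1
    start_offset: int = 0
    height_search: HeightSearchConfig = field(default_factory=HeightSearchConfig)
    colormap: str = "jet"
    normalize_across_walls: bool = True
    intrasection: bool = True

    def __post_init__(self) -> None:
        if self.dapi_channel not in self.channels:
            raise ConfigError(
                f"counterstain channel {self.dapi_channel!r} not in channels {self.channels}"
            )
        for name, value in [
            ("microns_per_pixel", self.microns_per_pixel),
            ("section_thickness_um", self.section_thickness_um),
            ("probe_width_um", self.probe_width_um),
            ("n_sections", self.n_sections),
            ("subsample_n", self.subsample_n),
        ]:
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        if not 0 <= self.start_offset < self.subsample_n:
            raise ConfigError("start_offset must be in [0, subsample_n)")

    @property
    def probe_width_px(self) -> float:
        return self.probe_width_um / self.microns_per_pixel

    @property
    def marker_channels(self) -> list[str]:
        return [c for c in self.channels if c != self.dapi_channel]

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        try:
            data = yaml.safe_load(path.read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        data = dict(data)
        hs = data.pop("height_search", None)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            cfg = cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        if hs is not None:
            try:
                cfg.height_search = (
                    hs if isinstance(hs, HeightSearchConfig) else HeightSearchConfig(**hs)
                )
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"bad height_search block: {exc}") from exc
        return cfg
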
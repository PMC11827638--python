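"""Run configuration: every stage parameter and every seed in one
serializable object.

The config round-trips losslessly through YAML; CLI flags override keys
with dot notation (e.g. ``localize.threshold_k=5``).  A single integer
``seed`` feeds independent, reproducible substreams for site placement,
event simulation, rendering and Monte-Carlo checks.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["ParticleConfig", "MixtureConfig", "ImagingConfig", "LocalizeConfig",
           "AccessConfig", "KineticsConfig", "ElutionConfig", "RunConfig",
           "ALL_STAGES"]

ALL_STAGES = ("simulate", "localize", "access", "kinetics", "elute")


@dataclass
class ParticleConfig:
    center_x_nm: float = 3200.0
    center_y_nm: float = 3200.0
    a_nm: float = 2500.0
    b_nm: float = 2500.0
    tilt_rad: float = 0.0
    accessible_fraction: float = 1.0
    site_density_per_um2: float = 300.0


@dataclass
class MixtureConfig:
    # each component: [weight, k_d (1/s), k_a (1/s per site)]
    components: list = field(
        default_factory=lambda: [
            [0.5, 25.0, 0.0055],
            [0.35, 8.0, 0.0055],
            [0.15, 2.0, 0.0055],
        ]
    )


@dataclass
class ImagingConfig:
    pixel_size_nm: float = 100.0
    frame_interval_s: float = 0.032
    n_frames: int = 2000
    n_acquisitions: int = 4
    shape: list = field(default_factory=lambda: [64, 64])
    psf_sigma_nm: float = 130.0
    photons_per_frame: float = 800.0
    background: float = 10.0
    read_noise: float = 1.6
    sheet_fwhm_nm: float = 2300.0
    sheet_center_z_nm: float = 0.0


@dataclass
class LocalizeConfig:
    threshold_k: float = 4.0
    min_separation_px: int = 4
    roi_half: int = 3
    n_min_photons: float = 100.0
    sigma_window: list = field(default_factory=lambda: [0.5, 2.0])


@dataclass
class AccessConfig:
    map_pixel_nm: float = 30.0
    closing_radius_px: int = 3
    min_localizations: int = 500
    outlier_tol: float = 0.05


@dataclass
class KineticsConfig:
    r_link_nm: float = 100.0
    max_gap: int = 1
    site_radius_nm: float = 60.0
    concentration_nM: float = 1.0
    temperature_K: float = 298.15


@dataclass
class ElutionConfig:
    n_bar: float = 100.0
    t_m_s: float = 0.0
    bleach_rate_per_s: float = 0.0  # simulator-side; kept with elution knobs' peers


@dataclass
class RunConfig:
    seed: int = 1
    stages: list = field(default_factory=lambda: list(ALL_STAGES))
    outdir: str = "smchrom_run"
    particle: ParticleConfig = field(default_factory=ParticleConfig)
    mixture: MixtureConfig = field(default_factory=MixtureConfig)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    localize: LocalizeConfig = field(default_factory=LocalizeConfig)
    access: AccessConfig = field(default_factory=AccessConfig)
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    elution: ElutionConfig = field(default_factory=ElutionConfig)

    def validate(self) -> "RunConfig":
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ConfigError(f"unknown stage(s): {unknown}; valid: {list(ALL_STAGES)}")
        order = [ALL_STAGES.index(s) for s in self.stages]
        if sorted(order) != order or len(set(order)) != len(order):
            raise ConfigError("stages must be a subsequence of "
                              f"{list(ALL_STAGES)} in order")
        if order and order != list(range(order[0], order[0] + len(order))):
            raise ConfigError("stages must be contiguous (no gaps in the chain)")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        return self

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        kwargs = {}
        for f in fields(cls):
            if f.name not in data:
                continue
            kwargs[f.name] = data.pop(f.name)
        extra = set(data)
        if extra:
            raise ConfigError(f"unknown config key(s): {sorted(extra)}")
        sub = {
            "particle": ParticleConfig,
            "mixture": MixtureConfig,
            "imaging": ImagingConfig,
            "localize": LocalizeConfig,
            "access": AccessConfig,
            "kinetics": KineticsConfig,
            "elution": ElutionConfig,
        }
        for name, klass in sub.items():
            if name in kwargs and isinstance(kwargs[name], dict):
                valid = {f.name for f in fields(klass)}
                bad = set(kwargs[name]) - valid
                if bad:
                    raise ConfigError(
                        f"unknown key(s) in '{name}': {sorted(bad)}"
                    )
                kwargs[name] = klass(**kwargs[name])
        return cls(**kwargs).validate()

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        try:
            data = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
        return cls.from_dict(data or {})

    def apply_overrides(self, overrides: list[str]) -> "RunConfig":
        """Apply ``section.key=value`` (or ``key=value``) CLI overrides."""
        data = self.to_dict()
        for item in overrides:
            if "=" not in item:
                raise ConfigError(f"override must be key=value, got {item!r}")
            key, raw = item.split("=", 1)
            parts = key.strip().split(".")
            node = data
            for part in parts[:-1]:
                if part not in node or not isinstance(node[part], dict):
                    raise ConfigError(f"unknown config section: {key!r}")
                node = node[part]
            leaf = parts[-1]
            if leaf not in node:
                raise ConfigError(f"unknown config key: {key!r}")
            node[leaf] = _coerce(raw, node[leaf])
        return RunConfig.from_dict(data)

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _coerce(raw: str, template):
    raw = raw.strip()
    try:
        if isinstance(template, bool):
            if raw.lower() in ("true", "1", "yes"):
                return True
            if raw.lower() in ("false", "0", "no"):
                return False
            raise ValueError(raw)
        if isinstance(template, int):
            return int(raw)
        if isinstance(template, float):
            return float(raw)
        if isinstance(template, list):
            return yaml.safe_load(raw)
        return raw
    except (ValueError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot coerce {raw!r} to {type(template).__name__}") from exc
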
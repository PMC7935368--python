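"""Pipeline configuration: schema validation and run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .simulate import ArchiveModel, EVENT_KINDS
from .spectral import RuleConfig, default_rules
from .trajectory import Thresholds


class ConfigError(ValueError):
    """Raised when a pipeline configuration fails schema validation."""


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


@dataclass
class SceneConfig:
    rows: int = 40
    cols: int = 40
    event_rates: dict[str, float] = field(
        default_factory=lambda: {
            "degradation": 0.10,
            "deforestation": 0.08,
            "deforestation_after_degradation": 0.05,
            "regrowth_after_deforestation": 0.05,
        }
    )
    archive_preset: str = "dense"
    obs_per_year: float = 12.0
    invalid_fraction: float = 0.1
    first_year: int = 1990
    noise_sd: float = 0.0

    def archive(self) -> ArchiveModel:
        if self.archive_preset == "dense":
            return ArchiveModel.dense(
                obs_per_year=self.obs_per_year,
                invalid_fraction=self.invalid_fraction,
                first_year=self.first_year,
            )
        if self.archive_preset == "landsat_like":
            return ArchiveModel.landsat_like(invalid_fraction=self.invalid_fraction)
        raise ConfigError(f"unknown archive preset {self.archive_preset!r}")


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "tmf_output"
    scene: SceneConfig = field(default_factory=SceneConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    rules: Optional[RuleConfig] = None
    validation_plots: int = 150
    projection_horizon: int = 2050
    source: Optional[str] = None  # path of the config file, if loaded

    def get_rules(self) -> RuleConfig:
        return self.rules if self.rules is not None else default_rules()

    def canonical(self) -> dict[str, Any]:
        """JSON-serializable canonical form (for hashing and manifests)."""
        return {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "scene": dataclasses.asdict(self.scene),
            "thresholds": dataclasses.asdict(self.thresholds),
            "rules": self.get_rules().to_dict(),
            "validation_plots": self.validation_plots,
            "projection_horizon": self.projection_horizon,
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


_TOP_KEYS = {
    "seed",
    "output_dir",
    "scene",
    "thresholds",
    "rules",
    "validation",
    "projection",
}
_SCENE_KEYS = {
    "rows",
    "cols",
    "event_rates",
    "archive",
    "noise_sd",
}
_ARCHIVE_KEYS = {"preset", "obs_per_year", "invalid_fraction", "first_year"}
_THRESHOLD_KEYS = {f.name for f in dataclasses.fields(Thresholds)}


def parse_config(payload: dict, source: Optional[str] = None) -> PipelineConfig:
    if not isinstance(payload, dict):
        raise ConfigError("configuration root must be a mapping")
    _check_keys(payload, _TOP_KEYS, "the configuration root")

    scene = SceneConfig()
    if "scene" in payload:
        block = payload["scene"] or {}
        _check_keys(block, _SCENE_KEYS, "scene")
        if "event_rates" in block:
            for kind in block["event_rates"]:
                if kind not in EVENT_KINDS:
                    raise ConfigError(f"unknown event kind {kind!r} in scene.event_rates")
            scene.event_rates = {k: float(v) for k, v in block["event_rates"].items()}
        scene.rows = int(block.get("rows", scene.rows))
        scene.cols = int(block.get("cols", scene.cols))
        scene.noise_sd = float(block.get("noise_sd", scene.noise_sd))
        archive = block.get("archive") or {}
        _check_keys(archive, _ARCHIVE_KEYS, "scene.archive")
        scene.archive_preset = archive.get("preset", scene.archive_preset)
        scene.obs_per_year = float(archive.get("obs_per_year", scene.obs_per_year))
        scene.invalid_fraction = float(
            archive.get("invalid_fraction", scene.invalid_fraction)
        )
        scene.first_year = int(archive.get("first_year", scene.first_year))

    th_block = payload.get("thresholds") or {}
    _check_keys(th_block, _THRESHOLD_KEYS, "thresholds")
    thresholds = Thresholds(**th_block)

    rules = None
    if payload.get("rules") is not None:
        try:
            rules = RuleConfig.from_dict(payload["rules"])
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"invalid rules block: {exc}") from exc

    validation = payload.get("validation") or {}
    _check_keys(validation, {"n_plots"}, "validation")
    projection = payload.get("projection") or {}
    _check_keys(projection, {"horizon"}, "projection")

    return PipelineConfig(
        seed=int(payload.get("seed", 0)),
        output_dir=str(payload.get("output_dir", "tmf_output")),
        scene=scene,
        thresholds=thresholds,
        rules=rules,
        validation_plots=int(validation.get("n_plots", 150)),
        projection_horizon=int(projection.get("horizon", 2050)),
        source=source,
    )


def load_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    with path.open() as fh:
        payload = yaml.safe_load(fh)
    return parse_config(payload or {}, source=str(path))


def write_manifest(
    cfg: PipelineConfig,
    out_dir: Path,
    stages: list[str],
    artifacts: dict[str, str],
    counts: Optional[dict[str, Any]] = None,
) -> Path:
    """Write the run manifest (config hash, seed, versions, artifact digests)."""
    from . import __version__

    checksums = {}
    for name, rel in artifacts.items():
        p = out_dir / rel
        if p.exists():
            checksums[name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "package_version": __version__,
        "config_hash": cfg.config_hash(),
        "config": cfg.canonical(),
        "seed": cfg.seed,
        "stages": stages,
        "artifacts": checksums,
        "counts": counts or {},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path
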
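"""Pipeline configuration: YAML loading, validation and run provenance."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .metad import MetaDParams
from .structures import DomainPartition


@dataclass
class PipelineConfig:
    """Validated configuration with defaults filled.

    Unknown keys are rejected so typos fail loudly rather than silently
    falling back to defaults.
    """

    partition: DomainPartition = field(default_factory=DomainPartition)
    metad: MetaDParams = field(default_factory=lambda: MetaDParams(sigma=1.0))
    threshold_fraction: float = 0.25
    hbond_distance_cutoff: float = 3.5
    hbond_angle_cutoff: float = 20.0
    cluster_cutoff: float = 3.0
    seed: int = 0
    output_dir: str = "shp2meta_out"

    def to_dict(self) -> dict:
        return {
            "partition": self.partition.to_dict(),
            "metad": {
                "sigma": [float(s) for s in self.metad.sigma],
                "w0": self.metad.w0,
                "stride": self.metad.stride,
                "bias_factor": self.metad.bias_factor,
                "temperature": self.metad.temperature,
            },
            "threshold_fraction": self.threshold_fraction,
            "hbond_distance_cutoff": self.hbond_distance_cutoff,
            "hbond_angle_cutoff": self.hbond_angle_cutoff,
            "cluster_cutoff": self.cluster_cutoff,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }

    def config_hash(self) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


_TOP_KEYS = {
    "partition", "metad", "threshold_fraction", "hbond_distance_cutoff",
    "hbond_angle_cutoff", "cluster_cutoff", "seed", "output_dir",
}
_METAD_KEYS = {"sigma", "w0", "stride", "bias_factor", "temperature"}


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load and validate a YAML config; an empty or absent file gives defaults."""
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("config must be a YAML mapping")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    cfg = PipelineConfig()
    if "partition" in data:
        try:
            cfg.partition = DomainPartition.from_dict(data["partition"])
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"invalid partition: {exc}") from exc
    if "metad" in data:
        md = data["metad"] or {}
        unknown = set(md) - _METAD_KEYS
        if unknown:
            raise ConfigError(f"unknown metad keys: {sorted(unknown)}")
        defaults = cfg.metad
        try:
            cfg.metad = MetaDParams(
                sigma=md.get("sigma", [float(s) for s in defaults.sigma]),
                w0=float(md.get("w0", defaults.w0)),
                stride=int(md.get("stride", defaults.stride)),
                bias_factor=float(md.get("bias_factor", defaults.bias_factor)),
                temperature=float(md.get("temperature", defaults.temperature)),
            )
        except Exception as exc:
            raise ConfigError(f"invalid metad parameters: {exc}") from exc
    for key in ("threshold_fraction", "hbond_distance_cutoff", "hbond_angle_cutoff",
                "cluster_cutoff"):
        if key in data:
            setattr(cfg, key, float(data[key]))
    if "seed" in data:
        cfg.seed = int(data["seed"])
    if "output_dir" in data:
        cfg.output_dir = str(data["output_dir"])
    if not (0.0 < cfg.threshold_fraction < 0.5):
        raise ConfigError("threshold_fraction must lie in (0, 0.5)")
    return cfg


def write_provenance(out_dir: str | Path, cfg: PipelineConfig, command: str) -> Path:
    """Write a self-describing provenance block next to the artifacts."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    block = {
        "package": "shp2meta",
        "version": __version__,
        "command": command,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": cfg.to_dict(),
    }
    path = out_dir / "provenance.yaml"
    path.write_text(yaml.safe_dump(block, sort_keys=False))
    return path
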
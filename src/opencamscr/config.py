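"""Run configuration, labelled sub-seeding and provenance.

A single global seed drives every stochastic routine through
deterministic labelled sub-seeds, so individual pipeline stages are
independently reproducible.  Survey design constants (2.7 km grid cell,
100-day primary period, 5-day closed-model occasion, M = 400, 10-minute
event threshold, 5,000 bootstrap replicates, 1.1 convergence threshold,
18 km state-space buffer) live here as configuration defaults, never
hard-coded inside algorithms.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

DESIGN_DEFAULTS = {
    "cell_size_m": 2_700.0,
    "n_cells_x": 10,
    "n_cells_y": 11,
    "cameras_per_site": 2,
    "n_primary": 10,
    "n_secondary": 100,
    "days_per_occasion": 5,
    "buffer_width_m": 18_000.0,
    "mask_spacing_m": 1_000.0,
    "M": 400,
    "rai_threshold_min": 10.0,
    "rai_n_boot": 5_000,
    "psrf_threshold": 1.1,
}


def subseed(global_seed: int, label: str) -> int:
    """Deterministic sub-seed (< 2^31) for a labelled routine."""
    h = zlib.crc32(label.encode())
    return int((global_seed * 1_000_003 + h) % (2 ** 31 - 1))


@dataclass
class RunConfig:
    """Pipeline configuration: input paths, per-stage parameter blocks,
    global seed and output directory."""

    seed: int = 0
    out_dir: str = "opencamscr-out"
    log_level: str = "INFO"
    detectors: str | None = None
    effort: str | None = None
    captures: str | None = None
    species_events: str | None = None
    reproduction: str | None = None
    design: dict = field(default_factory=lambda: dict(DESIGN_DEFAULTS))
    simulation: dict = field(default_factory=dict)
    open_model: dict = field(default_factory=dict)
    closed_model: dict = field(default_factory=dict)
    rai: dict = field(default_factory=dict)
    stages: list[str] = field(default_factory=lambda: ["simulate"])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(getattr(cfg, key), dict) and isinstance(value, dict):
                getattr(cfg, key).update(value)
            else:
                setattr(cfg, key, value)
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def write_manifest(self, out_dir: Path, extra: dict | None = None) -> Path:
        """Provenance manifest (config hash, seed, package version)."""
        from opencamscr import __version__

        manifest = {
            "config_hash": self.config_hash(),
            "seed": self.seed,
            "opencamscr_version": __version__,
            "config": self.to_dict(),
        }
        if extra:
            manifest.update(extra)
        path = Path(out_dir) / "manifest.json"
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        return path
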
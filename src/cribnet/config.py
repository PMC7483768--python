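"""Run configuration: one YAML file drives every pipeline command.

A run directory accumulates artifacts stage by stage (dataset, folds,
models, maps, curves, report); every artifact embeds the hash of the
configuration that produced it so mixed-provenance directories are caught.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass(frozen=True)
class RunConfig:
    """User-facing configuration of a pipeline run."""

    run_dir: str = "runs/demo"
    profile: str = "desk"            # desk | full
    seed: int = 0
    n_biopsies: int = 16
    k_folds: int = 4
    fold: int = 1                    # validation fold for train/predict
    iterations: int | None = None    # None -> profile default
    checkpoint_interval: int | None = None
    n_repeats: int = 1
    alphas: tuple[float, ...] = (0.2, 0.3, 0.4, 1.0)
    min_area_mm2: float = 0.0
    connectivity: int = 8
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["alphas"] = list(self.alphas)
        return d


def load_config(path: str | Path) -> RunConfig:
    payload = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    kwargs = {k: v for k, v in payload.items() if k in known}
    extra = {k: v for k, v in payload.items() if k not in known}
    if "alphas" in kwargs:
        kwargs["alphas"] = tuple(kwargs["alphas"])
    if extra:
        kwargs["extra"] = extra
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Hash of the computation-relevant configuration.

    ``run_dir`` is excluded: it says where artifacts live, not what is
    computed, and two identically-seeded runs in different directories must
    agree byte for byte.
    """
    payload = cfg.to_dict()
    payload.pop("run_dir")
    canon = json.dumps(payload, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
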
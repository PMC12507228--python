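"""Run configuration, seed-stream derivation and manifests.

Every random draw in a run traces back to a single global seed: each stage
(and, inside a stage, each subject and repetition) derives its own
independent stream through :func:`derive_rng`, so any stage can be re-run in
isolation and reproduce its outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cohort import CohortSpec
from .harness import ExperimentConfig
from .meta import MetaHyperParams
from .personalize import HyperGrids, PersonalizationHyperParams

__all__ = ["RunConfig", "derive_seed", "derive_rng", "write_manifest",
           "load_run_config"]

_STAGE_CODES = {"simulate": 1, "init_difficulty": 2, "pretrain": 3,
                "adapt": 4, "evaluate": 5, "ablation": 6}


def derive_seed(global_seed: int, stage: str, subject: int = 0,
                repetition: int = 0) -> int:
    """A stable sub-seed (< 2**31) for one (stage, subject, repetition)."""
    ss = np.random.SeedSequence(
        [int(global_seed), _STAGE_CODES.get(stage, 0), subject, repetition])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def derive_rng(global_seed: int, stage: str, subject: int = 0,
               repetition: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        derive_seed(global_seed, stage, subject, repetition))


@dataclass
class RunConfig:
    """Serializable configuration for a CLI run."""
    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    experiment: ExperimentConfig | None = None

    def __post_init__(self):
        if self.experiment is None:
            self.experiment = ExperimentConfig(cohort=self.cohort)

    def to_dict(self) -> dict:
        d = {"seed": self.seed, "cohort": asdict(self.cohort)}
        e = self.experiment
        d["experiment"] = {
            "n_train_subjects": e.n_train_subjects,
            "n_val_subjects": e.n_val_subjects,
            "K": e.K,
            "pool_cap_per_class": e.pool_cap_per_class,
            "backbone_hidden": list(e.backbone_hidden),
            "difficulty_train_steps": e.difficulty_train_steps,
            "meta": asdict(e.meta),
            "adapt": asdict(e.adapt),
            "grids": asdict(e.grids),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cohort_d = dict(d.get("cohort", {}))
        if "noise_sd_range" in cohort_d:
            cohort_d["noise_sd_range"] = tuple(cohort_d["noise_sd_range"])
        cohort = CohortSpec(**cohort_d)
        e = d.get("experiment", {})
        exp = ExperimentConfig(
            cohort=cohort,
            n_train_subjects=e.get("n_train_subjects", 8),
            n_val_subjects=e.get("n_val_subjects", 2),
            K=e.get("K", 10),
            pool_cap_per_class=e.get("pool_cap_per_class", 120),
            backbone_hidden=tuple(e.get("backbone_hidden", (32,))),
            difficulty_train_steps=e.get("difficulty_train_steps", 30),
            meta=MetaHyperParams(**e.get("meta", {})),
            adapt=PersonalizationHyperParams(**e.get("adapt", {})),
            grids=HyperGrids(**{k: tuple(v) for k, v in
                                e.get("grids", {}).items()}),
        )
        return cls(seed=d.get("seed", 0), cohort=cohort, experiment=exp)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def load_run_config(path=None, seed: int | None = None) -> RunConfig:
    cfg = RunConfig.from_yaml(path) if path else RunConfig()
    if seed is not None:
        cfg.seed = seed
    return cfg


def write_manifest(out_dir, stage: str, config: RunConfig, extras=None):
    """Write the reproducibility manifest for a stage run."""
    from . import __version__
    d = config.to_dict()
    blob = json.dumps(d, sort_keys=True).encode()
    manifest = {"stage": stage, "seed": config.seed,
                "config": d,
                "config_sha256": hashlib.sha256(blob).hexdigest(),
                "package_version": __version__,
                "numpy_version": np.__version__}
    if extras:
        manifest.update(extras)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / f"manifest_{stage}.json").write_text(
        json.dumps(manifest, indent=2))
    return manifest
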
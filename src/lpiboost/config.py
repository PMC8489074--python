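"""Run configuration: defaults, YAML parsing, validation, seed derivation."""

from __future__ import annotations

from dataclasses import dataclass, fields, asdict
from pathlib import Path

import numpy as np
import yaml


@dataclass
class RunConfig:
    """Flat pipeline configuration.

    Model defaults are the published settings (target_lr 1.0, epsilon 0.3,
    n_rounds 3, d 100, max_depth 5, num_boost_round 5, n_epochs 15, with
    the input-16-16-output architecture).
    """

    # model
    target_lr: float = 1.0
    epsilon: float = 0.3
    n_rounds: int = 3
    d: int = 100
    max_depth: int = 5
    num_boost_round: int = 5
    n_epochs: int = 15
    shrinkage: float = 0.1
    hidden_dims: tuple[int, ...] = (16, 16)
    pseudo_label_mode: str = "head_gradient"
    head_C: float = 1.0
    scale_features: bool = False
    # evaluation
    cv_mode: str = "cv3"
    k: int = 5
    repeats: int = 20
    # run
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> "RunConfig":
        errors = []
        if self.target_lr <= 0:
            errors.append("target_lr must be > 0")
        if self.epsilon < 0:
            errors.append("epsilon must be >= 0")
        if self.d < 1:
            errors.append("d must be >= 1")
        for key in ("n_rounds", "max_depth", "num_boost_round", "k"):
            if getattr(self, key) < 1 + (key == "k"):
                errors.append(f"{key} must be >= {1 + (key == 'k')}")
        if self.n_epochs < 0:
            errors.append("n_epochs must be >= 0")
        if self.repeats < 1:
            errors.append("repeats must be >= 1")
        if not (0 < self.shrinkage <= 1):
            errors.append("shrinkage must be in (0, 1]")
        if self.cv_mode.lower() not in ("cv1", "cv2", "cv3"):
            errors.append("cv_mode must be cv1, cv2 or cv3")
        if not self.hidden_dims or any(w < 1 for w in self.hidden_dims):
            errors.append("hidden_dims needs >= 1 width, all >= 1")
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden_dims"] = list(self.hidden_dims)
        return d


def parse_config(path: str | Path | None = None,
                 overrides: dict | None = None) -> RunConfig:
    """Merge defaults < config file < overrides; unknown keys are
    rejected."""
    known = {f.name for f in fields(RunConfig)}
    merged: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a flat key-value map")
        merged.update(loaded)
    merged.update(overrides or {})
    unknown = sorted(set(merged) - known)
    if unknown:
        raise ValueError("unknown configuration keys: " + ", ".join(unknown))
    if "hidden_dims" in merged:
        merged["hidden_dims"] = tuple(merged["hidden_dims"])
    return RunConfig(**merged).validate()


def derive_seed(master_seed: int, stage: int) -> int:
    """Counter-based per-stage seed (< 2**31) from one master seed, so each
    pipeline stage is independently reproducible."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(stage,))
    return int(ss.generate_state(1)[0] % 2**31)


# fixed stage counters for the pipeline
STAGES = {"simulate": 0, "negatives": 1, "folds": 2, "model": 3,
          "experiment": 4}
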
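"""Structured run configuration and seed fan-out.

A :class:`RunConfig` gathers the sub-configurations of every pipeline
stage.  Construction from a plain dict (JSON or YAML) rejects unknown
keys so typos fail before any stage runs, and the full configuration is
serialized into the output directory for provenance.

One global seed is fanned out to per-stage seeds by stable hashing of
the stage name, so inserting or re-running one stage never perturbs the
randomness of another.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .dataset import DEFAULT_FRACTIONS, DEFAULT_LABEL_THRESHOLD
from .model import HeadConfig, TrainingConfig
from .simulate import GeneratorConfig


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed below 2**31 from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _from_dict(cls, data: dict[str, Any], context: str):
    """Instantiate a dataclass from a dict, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ValueError(f"{context}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"{context}: unknown keys {sorted(unknown)}")
    kwargs = dict(data)
    for key in (
        "length_range",
        "motif_length_range",
        "fractions",
        "hidden_sizes",
        "forced_test_ids",
    ):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


@dataclass
class BuilderConfig:
    threshold: float = DEFAULT_LABEL_THRESHOLD
    min_identity: float = 0.25
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS
    forced_test_ids: tuple[str, ...] = ()
    window_length: int = 10


@dataclass
class BackendConfig:
    kind: str = "onehot"
    radius: int = 7          # onehot
    dim: int = 32            # tinytransformer
    n_blocks: int = 4        # tinytransformer
    trainable_last_k: int = 0

    def build(self, seed: int = 0):
        from .embedder import load_backend

        if self.kind == "onehot":
            if self.trainable_last_k != 0:
                raise ValueError("the onehot backend has no trainable blocks")
            return load_backend("onehot", radius=self.radius)
        if self.kind == "tinytransformer":
            return load_backend(
                "tinytransformer",
                dim=self.dim,
                n_blocks=self.n_blocks,
                seed=seed,
                trainable_last_k=self.trainable_last_k,
            )
        return load_backend(self.kind)


@dataclass
class PrioritizerConfig:
    peptide_length: int = 15
    top_n: int = 6
    allow_overlap: bool = False


@dataclass
class EvaluationConfig:
    n_top: int = 10
    tau: float = -1.0
    average: str = "macro"


@dataclass
class PPIConfig:
    n_targets: int = 5
    partners_per_target: int = 2


@dataclass
class RunConfig:
    out_dir: str = "pepprior_run"
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    ppi: PPIConfig = field(default_factory=PPIConfig)
    builder: BuilderConfig = field(default_factory=BuilderConfig)
    backend: BackendConfig = field(default_factory=BackendConfig)
    head: HeadConfig = field(default_factory=HeadConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    prioritizer: PrioritizerConfig = field(default_factory=PrioritizerConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        if not isinstance(data, dict):
            raise ValueError("config must be a mapping")
        sub = {
            "generator": GeneratorConfig,
            "ppi": PPIConfig,
            "builder": BuilderConfig,
            "backend": BackendConfig,
            "head": HeadConfig,
            "training": TrainingConfig,
            "prioritizer": PrioritizerConfig,
            "evaluation": EvaluationConfig,
        }
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"config: unknown keys {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for key, value in data.items():
            if key in sub:
                kwargs[key] = _from_dict(sub[key], value, key)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
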
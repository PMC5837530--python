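"""Run configuration: YAML-serializable parameter blocks and seed derivation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .inference import PermutationScheme, TFCEParams
from .phantom import AtrophySpec, PhantomSpec
from .registration import RegistrationParams

__all__ = ["RunConfig", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return zlib.crc32(f"{master_seed}/{stage}".encode()) & 0x7FFFFFFF


def _to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_dict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Every stochastic stage derives its seed from ``seed`` via
    :func:`stage_seed`, so a fixed config is fully deterministic.
    """

    seed: int = 0
    out_dir: str = "jdmorph-out"
    n_case: int = 12
    n_control: int = 8
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    atrophy: AtrophySpec = field(default_factory=AtrophySpec)
    registration: RegistrationParams = field(default_factory=RegistrationParams)
    tfce: TFCEParams = field(default_factory=TFCEParams)
    permutations: int = 10_000
    smoothing_fwhm_mm: float = 8.0
    exclude_lesions: bool = False
    treatment_effectiveness: float = 0.25
    stages: tuple[str, ...] = (
        "simulate", "register", "jd", "summarize", "voxelwise", "cohort-stats", "power",
    )

    def to_dict(self) -> dict:
        return _to_dict(self)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (
            ("phantom", PhantomSpec), ("atrophy", AtrophySpec),
            ("registration", RegistrationParams), ("tfce", TFCEParams),
        ):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                for fname, f in ((f.name, f) for f in dataclasses.fields(typ)):
                    if fname in sub and isinstance(sub[fname], list):
                        sub[fname] = tuple(
                            tuple(x) if isinstance(x, list) else x for x in sub[fname]
                        )
                d[key] = typ(**sub)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def permutation_scheme(self, exhaustive: bool = False) -> PermutationScheme:
        return PermutationScheme(
            m=self.permutations, seed=stage_seed(self.seed, "permutations"),
            exhaustive=exhaustive,
        )
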
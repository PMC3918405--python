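"""Run configuration: a flat key=value text format with typed fields.

One :class:`RunConfig` drives the end-to-end strategy; every stage derives
its seed deterministically from the single run seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields
from pathlib import Path

__all__ = ["RunConfig"]


def _parse_floats(text: str):
    return tuple(float(v) for v in str(text).split(",") if str(v).strip())


def _parse_ints(text: str):
    return tuple(int(float(v)) for v in str(text).split(",") if str(v).strip())


@dataclass
class RunConfig:
    """Everything the end-to-end run needs.

    ``trait_matrix`` / ``observed`` are input paths; when both are empty a
    synthetic collection is generated.  Grids use percent units for
    sampling percentages and counts for traits.
    """
    trait_matrix: str = ""
    observed: str = ""
    metric: str = "seuclid"
    parameter: str = "CR"
    alpha: float = 0.05
    percentages: tuple = tuple(float(p) for p in range(10, 31))
    trait_counts: tuple = tuple(range(1, 21))
    replications: int = 20
    cr_threshold: float = 80.0
    r2_floor: float = 0.70
    error_tolerance: float = 0.20
    validation_percentages: tuple = (10.0, 15.0)
    validation_seeds: int = 20
    reestimate_reference: bool = False
    seed: int = 0

    _TUPLE_FLOAT = ("percentages", "validation_percentages")
    _TUPLE_INT = ("trait_counts",)
    _BOOL = ("reestimate_reference",)

    def validate(self):
        from .distance import METRICS
        from .evaluate import PARAMETERS
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not self.percentages or not self.trait_counts:
            raise ValueError("grids must be non-empty")
        if self.replications < 1 or self.validation_seeds < 1:
            raise ValueError("replications and validation_seeds must be >= 1")
        if not (0 < self.cr_threshold <= 100):
            raise ValueError("cr_threshold must be in (0, 100]")
        return self

    def to_file(self, path) -> None:
        lines = []
        for f in fields(self):
            val = getattr(self, f.name)
            if isinstance(val, tuple):
                val = ",".join(f"{v:g}" if isinstance(v, float) else str(v)
                               for v in val)
            lines.append(f"{f.name} = {val}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kv = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected key = value")
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        return cls.from_mapping(kv)

    @classmethod
    def from_mapping(cls, kv: dict) -> "RunConfig":
        kwargs = {}
        valid = {f.name: f for f in fields(cls)}
        for key, val in kv.items():
            if key not in valid:
                raise ValueError(f"unknown config key {key!r}")
            if key in cls._TUPLE_FLOAT:
                kwargs[key] = _parse_floats(val)
            elif key in cls._TUPLE_INT:
                kwargs[key] = _parse_ints(val)
            elif key in cls._BOOL:
                kwargs[key] = str(val).strip().lower() in ("1", "true", "yes")
            else:
                kwargs[key] = type(getattr(cls(), key))(val)
        return cls(**kwargs).validate()

    def canonical_text(self) -> str:
        parts = []
        for f in sorted(fields(self), key=lambda f: f.name):
            parts.append(f"{f.name}={getattr(self, f.name)!r}")
        return ";".join(parts)

    def digest(self) -> str:
        return hashlib.sha256(self.canonical_text().encode()).hexdigest()[:16]
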
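"""Run configuration: the knobs of a full MWSL estimation run."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from math import ceil
from pathlib import Path

import yaml

APPROXIMATIONS = ("identity", "mvnormal", "mvlognormal")
MEFF_METHODS = ("mwsl", "nyholt", "liji", "gao", "galwey")


@dataclass
class RunConfig:
    """Configuration of an MWSL run.

    ``K`` is the number of permutation replicates; it must be at least
    ``max(ceil(n/2), 100)`` for the empirical alpha-quantile of the min-p
    null to be meaningful. ``approximation`` selects the parametric surrogate
    used for the features (``identity`` = raw data).
    """

    alpha: float = 0.05
    K: int | None = None
    seed: int = 0
    approximation: str = "identity"
    meff_method: str = "mwsl"
    gao_fraction: float = 0.995

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 < self.gao_fraction < 1):
            raise ValueError("gao_fraction must lie in (0, 1)")
        if self.approximation not in APPROXIMATIONS:
            raise ValueError(f"approximation must be one of {APPROXIMATIONS}")
        if self.meff_method not in MEFF_METHODS:
            raise ValueError(f"meff_method must be one of {MEFF_METHODS}")
        if self.K is not None and self.K < 100:
            raise ValueError("K must be at least 100")

    def resolve_K(self, n: int) -> int:
        """Default K = max(10000, ceil(n/2)); explicit K checked against the floor."""
        floor = max(ceil(n / 2), 100)
        if self.K is None:
            return max(10_000, floor)
        if self.K < floor:
            raise ValueError(
                f"K={self.K} is below the required floor max(ceil(n/2), 100)={floor}"
            )
        return self.K

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} did not parse to a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
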
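"""Run configuration shared by the CLI and the analysis drivers."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline-wide knobs with their scientific defaults.

    temperature_K
        Work-sample temperature; 310 K (the physiological simulation
        temperature of the source ensembles).
    n_bootstrap
        Bootstrap replicates for dG standard errors (100).
    threshold_kJ
        Classification threshold tau in kJ/mol (4.0, the typical error scale
        of computational free-energy estimates).
    seed
        Master seed for every stochastic step.
    estimator
        'BAR' or 'crooks_crossing'.
    psi_convention
        'carbonyl' (N-CA-C-O) or 'amide' (N-CA-C-N+1) for psi metrics.
    """

    temperature_K: float = 310.0
    n_bootstrap: int = 100
    threshold_kJ: float = 4.0
    seed: int = 0
    estimator: str = "BAR"
    psi_convention: str = "carbonyl"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def override(self, **kwargs) -> "RunConfig":
        """New config with the given non-None fields replaced."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates)

    @property
    def hash(self) -> str:
        """Short stable digest of the canonicalized config."""
        canonical = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
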
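"""Run configuration: every tunable threshold of the method in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class Config:
    """Standard operating values of the method; all are overridable."""

    contact_cutoff: float = 5.0  # Å, heavy-atom interface contact
    asa_buried_cutoff: float = 5.0  # Å^2 side-chain ASA below which buried
    disorder_window: int = 11  # residues, sliding window for disorder
    disorder_cutoff: float = 0.5  # window-mean disorder >= cutoff -> disordered
    gap_fraction_cutoff: float = 0.09  # member excluded from redundancy grouping
    switch_threshold: float = 1.7  # |S_switch| >= tau calls a switch
    target_fpr: float = 0.05  # FPR bound for threshold selection
    n_shuffles: int = 10  # negatives per positive
    cv_folds: int = 5
    cv_reps: int = 100
    pseudocount: float = 1.0  # per unordered pair in potential estimation
    homolog_identity: float = 0.5  # the three >=50% interface-homology criteria
    homolog_coverage: float = 0.5
    homolog_shared_interface: float = 0.5
    species_fcons_fallback: float = 0.5  # used when no orthologue group covers a protein
    master_seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "master_seed":
                continue
            if v <= 0 and f.name not in ("species_fcons_fallback",):
                raise ValueError(f"{f.name} must be positive, got {v}")
        for name in (
            "disorder_cutoff", "gap_fraction_cutoff", "target_fpr",
            "homolog_identity", "homolog_coverage", "homolog_shared_interface",
            "species_fcons_fallback",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def replace(self, **overrides) -> "Config":
        data = asdict(self)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return Config(**data)
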
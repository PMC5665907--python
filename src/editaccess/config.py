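"""Run configuration with the analysis' canonical default thresholds."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from . import io as eio

__all__ = ["RunConfig", "CANONICAL_THRESHOLDS"]

# The filter and analysis thresholds the whole pipeline defaults to.
CANONICAL_THRESHOLDS = {
    "min_llr": 2.0,
    "min_depth": 10,
    "min_alt": 2,
    "min_level": 0.1,
    "homopolymer_max": 4,
    "splice_margin": 4,
    "intron_close_max": 300,
    "prevalence_rare_max": 10.0,
    "prevalence_prevalent_min": 90.0,
    "differential_p": 0.01,
    "differential_delta": 0.067,
    "max_target_distance": 500,
    "accessibility_u": 7,
    "accessibility_L": 300,
    "accessibility_W": 400,
    "fold_window": 1001,
    "distance_window": 10,
    "min_edited_individuals": 3,
    "min_coverage_fraction": 0.10,
    "top_k_mirnas": 20,
    "match_p": 0.1,
    "min_group": 3,
}


@dataclass
class RunConfig:
    """Pipeline configuration; thresholds default to the study's values."""

    # stage toggles
    run_syndata: bool = True
    run_sitecall: bool = True
    run_popstats: bool = True
    run_structacc: bool = True
    run_mirtarget: bool = True
    # inputs (used when the corresponding syndata stage is off)
    fasta: str | None = None
    pileup: str | None = None
    tracks_dir: str | None = None
    expression: str | None = None
    # simulation scale
    n_per_population: int = 100
    n_edited_target: int = 30
    n_edited_no_target: int = 10
    n_unedited_target: int = 10
    degradation_k: float = 1.0
    utr_length: int = 360
    # thresholds
    min_llr: float = 2.0
    min_depth: int = 10
    min_alt: int = 2
    min_level: float = 0.1
    homopolymer_max: int = 4
    splice_margin: int = 4
    intron_close_max: int = 300
    prevalence_rare_max: float = 10.0
    prevalence_prevalent_min: float = 90.0
    differential_p: float = 0.01
    differential_delta: float = 0.067
    max_target_distance: int = 500
    accessibility_u: int = 7
    accessibility_L: int = 300
    accessibility_W: int = 400
    fold_window: int = 1001
    distance_window: int = 10
    min_edited_individuals: int = 3
    min_coverage_fraction: float = 0.10
    top_k_mirnas: int = 20
    match_p: float = 0.1
    min_group: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_llr", "min_depth", "min_alt", "min_level",
                     "homopolymer_max", "splice_margin", "fold_window",
                     "accessibility_u", "accessibility_L", "accessibility_W"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = eio.load_config_yaml(path)
        valid = {f.name for f in fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        eio.dump_config_yaml(asdict(self), path)

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in every output."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
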
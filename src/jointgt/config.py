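"""Validated run configuration.

A run is reproducible from config + inputs + seed: every tunable default in
the package appears here, unknown keys are rejected, and the document
round-trips through YAML/JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import yaml

from . import ldimpute, seqlik
from .disputes import (
    DEFAULT_CONCORDANCE_CUTOFF,
    DEFAULT_DISPUTE_THRESHOLD,
    DEFAULT_LOD_THRESHOLD,
    MIN_KDE_POINTS,
)


@dataclass
class SimConfig:
    n_founders: int = 12
    n_haplotypes: int = 120
    n_snps: int = 200
    n_samples: int = 60
    recomb_prob: float = 0.05
    mutation_prob: float = 0.002
    mean_coverage: float = 1.0
    read_error: float = 0.001
    fragment_error: float = 1e-4
    overlap_fraction: float = 0.2
    noise_scale: float = 1.0
    missing_rate: float = 0.0
    artifact_config: dict = field(default_factory=dict)


@dataclass
class CallerConfig:
    outer_iterations: int = 3
    gq_threshold: float = 10.0
    gq_cap: float = 99.0
    use_array: bool = True
    use_sequence: bool = True
    use_imputation: bool = True
    recluster: bool = True
    seq_mode: str = "fragment"
    fragment_error: float = seqlik.DEFAULT_FRAGMENT_ERROR
    ld_iterations: int = ldimpute.DEFAULT_N_ITERATIONS
    ld_states: int = ldimpute.DEFAULT_N_STATES
    ld_recomb: float = ldimpute.DEFAULT_RECOMB
    ld_mismatch: float = ldimpute.DEFAULT_MISMATCH


@dataclass
class DisputeConfig:
    dispute_threshold: float = DEFAULT_DISPUTE_THRESHOLD
    concordance_cutoff: float = DEFAULT_CONCORDANCE_CUTOFF
    lod_threshold: float = DEFAULT_LOD_THRESHOLD
    min_kde_points: int = MIN_KDE_POINTS


@dataclass
class MetricsConfig:
    maf_bins: list = field(
        default_factory=lambda: [[0.0, 0.005], [0.005, 0.05], [0.05, 0.5]]
    )
    drop_ambiguous: bool = True
    by_zygosity: bool = True


@dataclass
class RunConfig:
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    caller: CallerConfig = field(default_factory=CallerConfig)
    disputes: DisputeConfig = field(default_factory=DisputeConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def _build(cls, data: dict, context: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config keys under {context}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        sub = {"sim": SimConfig, "caller": CallerConfig,
               "disputes": DisputeConfig, "metrics": MetricsConfig}.get(name)
        if sub is not None and isinstance(value, dict):
            kwargs[name] = _build(sub, value, f"{context}.{name}")
        else:
            kwargs[name] = value
        _ = ftype
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load a YAML or JSON run configuration, rejecting unknown keys."""
    with open(path) as fh:
        text = fh.read()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config document must be a mapping")
    return _build(RunConfig, data, "run")
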
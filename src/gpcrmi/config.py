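"""Analysis configuration."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class ScanConfig:
    """All tunables of a scan, with the defaults used throughout.

    gap_policy: 'drop' removes pairs whose receptor is gapped at a position
        (gaps are not residues); 'keep' treats the gap as a 21st symbol.
    k_min: minimum effective observations per (position, descriptor); 20.
    n_surrogates: permutation surrogates per test; 100.
    alpha: one-sided level of the S test; 0.005 (threshold 2.63 at 100
        surrogates).
    lilliefors_alpha: level of the per-ensemble normality audit; 0.05.
    top_fraction: fraction of MI values selected as hotspot candidates
        before the significance filter; 0.005, applied per subset.
    permutation_mode: 'per_descriptor' draws independent permutations per
        (position, descriptor); 'whole_row' shares one permutation set per
        position across descriptors, preserving descriptor covariance.
    master_seed: root of the deterministic per-test seed streams.
    continuous_bins: bin count for continuous descriptors; None = Sturges.
    """

    gap_policy: str = "drop"
    k_min: int = 20
    n_surrogates: int = 100
    alpha: float = 0.005
    lilliefors_alpha: float = 0.05
    top_fraction: float = 0.005
    permutation_mode: str = "per_descriptor"
    master_seed: int = 0
    continuous_bins: int | None = None
    agonist_includes_partial: bool = True
    g_subset_agonists_only: bool = False

    def __post_init__(self):
        if self.gap_policy not in {"drop", "keep"}:
            raise ConfigError(f"unknown gap_policy {self.gap_policy!r}")
        if self.permutation_mode not in {"per_descriptor", "whole_row"}:
            raise ConfigError(f"unknown permutation_mode {self.permutation_mode!r}")
        if not 0.0 < self.top_fraction <= 1.0:
            raise ConfigError("top_fraction must lie in (0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.n_surrogates < 2:
            raise ConfigError("n_surrogates must be at least 2")
        if self.k_min < 1:
            raise ConfigError("k_min must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "ScanConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config key(s) {sorted(unknown)}")
        return cls(**data)
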
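"""YAML run-configuration parsing with strict schema validation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

__all__ = ["RunConfig", "parse_config", "DEFAULTS", "ConfigError"]


class ConfigError(ValueError):
    pass


#: Defaults for every tunable; unknown keys are rejected.
DEFAULTS: dict[str, Any] = {
    "hbond_distance_cutoff": 3.0,  # Å
    "hbond_angle_cutoff": 45.0,  # degrees, at the donor
    "trivial_threshold": 0.10,  # occupancy fraction
    "rmsf_cutoff": 2.0,  # Å, flexible-loop exclusion
    "contact_cutoff": 4.0,  # Å, heavy-atom contact
    "contact_min_mean_pairs": 1.0,
    "alpha": 0.01,  # CI-test significance
    "iss": 5.0,  # imaginary sample size
    "tabu_length": 50,
    "max_nonimproving": 50,
    "permutations_for_df": 100,
    "max_cond_set": 3,
    "cv_repeats": 10,
    "cv_folds": 5,
    "arc_frequency_threshold": 0.9,
    "direction_agreement_threshold": 0.8,
    "if_of_threshold": 0.7,  # |ΔΔHB(OF→IF)| screening cutoff
    "ts_threshold": 0.5,  # |ΔΔHB(→TS)| screening cutoff
    "n_images": 51,
    "neighbor_rmsd_cutoff": 1.4,  # Å
    "n_windows": 30,
    "temperature": 310.0,  # K
    "wham_bins": 60,
    "wham_tol": 1e-7,
    "n_boot": 200,
    "seed": 0,
    "verbosity": 1,
}


@dataclass
class RunConfig:
    values: dict[str, Any] = field(default_factory=dict)

    def __getattr__(self, key: str) -> Any:
        try:
            return self.__dict__["values"][key]
        except KeyError as exc:
            raise AttributeError(key) from exc

    def __getitem__(self, key: str) -> Any:
        return self.values[key]


def parse_config(
    path=None, overrides: Mapping[str, Any] | None = None
) -> RunConfig:
    """Load defaults, then the YAML file, then explicit flag overrides.

    Unknown keys anywhere are rejected with a message naming them.
    """
    values = dict(DEFAULTS)
    for source in (_load_yaml(path) if path else {}, dict(overrides or {})):
        unknown = sorted(set(source) - set(DEFAULTS))
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {', '.join(unknown)}")
        for key, val in source.items():
            if val is not None:
                values[key] = type(DEFAULTS[key])(val) if DEFAULTS[key] is not None else val
    return RunConfig(values)


def _load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration file must contain a mapping")
    return data
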
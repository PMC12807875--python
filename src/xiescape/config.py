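"""Pipeline configuration.

All thresholds used by the analysis stages live in one nested mapping so that a
single YAML file can override any of them. Defaults follow the published
analysis of Xist-induced escapee silencing: escape requires an allelic ratio
strictly above 0.1, ratios above 0.8 are treated as technical artefacts, genes
with a mean allelic count below 10 are dropped, gene groups chain on 100-kb
start-to-start distance, and washout recovery thresholds are 50% / 10%.
"""

from __future__ import annotations

import copy
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError

DEFAULTS: dict[str, Any] = {
    "filters": {
        # genes with mean (xi + xa) count below this are excluded
        "min_mean_allelic_count": 10.0,
    },
    "escape": {
        "ratio_threshold": 0.1,        # escape: ratio strictly greater
        "high_ratio_threshold": 0.8,   # above this: strain/mapping artefact
        "rule": "all_replicates",      # or "fraction" (embryo-style calling)
        "fraction_threshold": 0.5,
        "untreated_condition": "untreated",
        "xist_gene": "Xist",
    },
    "meta": {
        "min_studies_detected": 3,
        "constitutive_fraction": 0.5,  # escaping in MORE than this fraction
        "n_studies": 19,
    },
    "imbalance": {
        "alpha": 0.05,
        "adjust_method": "holm",
        "reduction_threshold": 0.5,    # "significant >=50% reduction"
        "pool_replicates": False,
    },
    "kinetics": {
        "r2_threshold": 0.3,
        "k_bounds": [1e-4, 10.0],
        "b_bounds": [0.0, 1.0],
        "a_bounds": [-1.0, 1.0],
        "k_starts": [0.05, 0.2, 0.5, 1.5],
        "use_condition_means": False,  # fit replicate-level ratios
        "residual_b_threshold": 0.1,   # secondary residual-escape flag on b
        "neighbor_window_bp": 100_000,
        "n_permutations": 1000,
        # half-lives beyond the sampled time course are extrapolations and
        # are excluded from the neighbour-similarity statistic
        "neighbor_max_half_life_days": 21.0,
    },
    "groups": {
        "window_bp": 100_000,
    },
    "reversibility": {
        "reversible_min_recovery": 0.5,
        "partial_min_recovery": 0.1,
        "min_washout_ratio": 0.1,
    },
    "cpm": {
        "library": "allelic",          # or "external" (supplied totals)
        "reference_condition": "untreated",
    },
}


def default_config() -> dict[str, Any]:
    """A deep copy of the built-in defaults."""
    return copy.deepcopy(DEFAULTS)


def _deep_merge(base: dict, override: Mapping) -> dict:
    for key, value in override.items():
        if key not in base:
            raise ConfigurationError(f"unknown configuration key: {key!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, Mapping):
                raise ConfigurationError(
                    f"configuration key {key!r} must be a mapping"
                )
            _deep_merge(base[key], value)
        else:
            base[key] = value
    return base


def load_config(path: str | None = None) -> dict[str, Any]:
    """Load a YAML config file and merge it over the defaults.

    Unknown keys raise :class:`ConfigurationError` instead of being silently
    ignored, so typos in threshold names cannot change the analysis unnoticed.
    """
    config = default_config()
    if path is None:
        return config
    with open(path, "rt", encoding="utf-8") as handle:
        override = yaml.safe_load(handle) or {}
    if not isinstance(override, Mapping):
        raise ConfigurationError("config file must contain a mapping")
    return _deep_merge(config, override)
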
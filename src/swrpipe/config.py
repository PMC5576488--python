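"""Pipeline configuration: nested defaults plus YAML overrides.

Defaults encode the analysis parameters used throughout: the 4 cm/s
movement threshold, the 150-250 Hz ripple band, the 99.99th-percentile
mirrored-noise detection cutoff, the 20 ms minimum event duration, the
occupancy/rate-map binning and smoothing, the unit-selection rules, and
the permutation counts.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any

import yaml

__all__ = ["DEFAULTS", "load_config", "ConfigError"]


class ConfigError(ValueError):
    pass


DEFAULTS: dict[str, Any] = {
    "behavior": {
        "speed_threshold_cm_s": 4.0,
        "immobile_strict_cm_s": 1.0,   # stricter immobility cut used in theta analyses
        "speed_smoothing_sigma_s": 0.25,
        "occupancy_bin_cm": 2.0,
        "well_radius_cm": 10.0,
    },
    "swr_detection": {
        "ripple_band": [150.0, 250.0],
        "envelope_smoothing_sigma_s": 0.004,
        "min_channels": 3,
        "noise_percentile": 99.99,
        "min_event_ms": 20.0,
        "mode_bins": 200,
        "spectrogram_window_s": 0.1,
        "spectrogram_step_s": 0.01,
    },
    "place_coding": {
        "interneuron_max_width_ms": 0.4,
        "interneuron_min_rate_hz": 10.0,
        "min_spikes": 200,
        "iap_min_well_rate_hz": 3.0,
        "ratemap_sigma_cm": 2.0,
        "ratemap_extent_cm": 12.0,
        "coverage_threshold_frac": 0.2,
        "coverage_min_occupancy_s": 0.1,
    },
    "temporal_correlation": {
        "correlogram_bin_s": 0.010,
        "min_coincidences": 100,
        "near_window_s": 0.050,
        "far_window_s": 3.3,
        "peth_window_s": 5.0,
        "peth_bin_s": 0.1,
        "peth_smoothing_sigma_s": 0.1,
        "coincidence_bin_s": 0.1,
        "coincidence_window_s": 20.0,
    },
    "swr_content": {
        "n_permutations": 5000,
        "eligibility_peak_lag_s": 3.3,
    },
    "pfc_modulation": {
        "min_events": 10,
        "min_rate_hz": 1.0,
        "n_permutations": 1000,
        "alpha": 0.05,
        "peth_half_window_s": 0.5,
        "peth_bin_s": 0.010,
        "surround_window_s": 1.0,
        "combos_per_group": {"IAP-SWR+": 2, "MAP-SWR+": 2, "IAP/MAP-SWR-": 3,
                             "IAP-and-MAP-SWR+": 1},
    },
    "lfp": {
        "sample_rate_hz": 1500.0,
    },
}

# keys whose values must be strictly positive numbers
_POSITIVE = {
    "speed_threshold_cm_s", "immobile_strict_cm_s", "speed_smoothing_sigma_s",
    "occupancy_bin_cm", "well_radius_cm", "envelope_smoothing_sigma_s",
    "min_event_ms", "spectrogram_window_s", "spectrogram_step_s",
    "interneuron_max_width_ms", "interneuron_min_rate_hz", "iap_min_well_rate_hz",
    "ratemap_sigma_cm", "ratemap_extent_cm", "correlogram_bin_s", "near_window_s",
    "far_window_s", "peth_window_s", "peth_bin_s", "peth_smoothing_sigma_s",
    "coincidence_bin_s", "coincidence_window_s", "eligibility_peak_lag_s",
    "peth_half_window_s", "surround_window_s", "sample_rate_hz",
}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown configuration key {here!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"{here!r} must be a mapping")
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


def _validate(cfg: dict, path: str = "") -> None:
    for key, value in cfg.items():
        here = f"{path}.{key}" if path else key
        if isinstance(value, dict):
            _validate(value, here)
        elif key in _POSITIVE:
            if not isinstance(value, (int, float)) or not value > 0:
                raise ConfigError(f"{here!r} must be a positive number, got {value!r}")
        elif key == "ripple_band":
            lo, hi = value
            if not 0 < lo < hi:
                raise ConfigError(f"{here!r} must be an increasing positive pair")
        elif key in ("noise_percentile", "alpha"):
            if not 0 < value < 100:
                raise ConfigError(f"{here!r} out of range: {value!r}")


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load a YAML config file, filling every absent key with its default.

    An empty or absent file yields the full default mapping.  Unknown keys
    and out-of-range values raise :class:`ConfigError`.
    """
    override: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError("config file must contain a mapping")
            override = loaded
    cfg = _merge(DEFAULTS, override)
    _validate(cfg)
    return cfg
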
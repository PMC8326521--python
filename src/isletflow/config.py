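"""Pipeline configuration: defaults, YAML loading, and validation.

Unknown keys are rejected and ranges are checked before any frame is
processed, so a typo fails fast instead of silently running with defaults.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["DEFAULTS", "ConfigError", "validate_config"]


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


DEFAULTS: dict[str, Any] = {
    "input": None,
    "background": None,
    "frame_rate": 30.0,
    "output": "results",
    "scale": {
        "delta_um_per_px": None,
        "marker_px": None,
        "marker_um": 1000.0,
    },
    "segmentation": {
        "smoothing_radius": 1.0,
        "otsu_bias": 0.0,
        "min_threshold": 10.0,
        "dt_threshold_frac": 0.4,
        "opening_radius": 2,
    },
    "purity": {
        "hue_min_deg": 310.0,
        "hue_max_deg": 360.0,
    },
    "tracking": {
        "weights": [1.0, 0.5, 1.0],
        "j_max": 2.0,
        "max_missed": 2,
        "min_track_length": 2,
        "solver": "greedy",
    },
    "metrics": {
        "volume_variant": "major",
        "diameter_bin_um": 25.0,
        "ratio_bin": 0.1,
    },
    "debug_image_dump": False,
    "verbosity": "info",
}


def _merge(defaults: Mapping[str, Any], raw: Mapping[str, Any], prefix: str = "") -> dict:
    merged = copy.deepcopy(dict(defaults))
    for key, value in raw.items():
        dotted = f"{prefix}{key}"
        if key not in merged:
            raise ConfigError(f"unknown config key: {dotted!r}")
        if isinstance(merged[key], dict):
            if not isinstance(value, Mapping):
                raise ConfigError(f"config key {dotted!r} must be a mapping")
            merged[key] = _merge(merged[key], value, prefix=dotted + ".")
        else:
            merged[key] = value
    return merged


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ConfigError(message)


def validate_config(raw: Mapping[str, Any] | str | Path | None) -> dict[str, Any]:
    """Merge a raw config (dict or YAML file path) over the defaults.

    Checks key names, value ranges (hue in [0, 360], fractions in (0, 1),
    weights >= 0, positive scale), and that the pixel scale is resolvable
    either directly (``scale.delta_um_per_px``) or from a marker pair
    (``scale.marker_px`` + ``scale.marker_um``).
    """
    if raw is None:
        raw = {}
    elif isinstance(raw, (str, Path)):
        with open(raw) as fh:
            raw = yaml.safe_load(fh) or {}
    cfg = _merge(DEFAULTS, raw)

    seg = cfg["segmentation"]
    _require(seg["smoothing_radius"] >= 0, "segmentation.smoothing_radius must be >= 0")
    _require(seg["min_threshold"] >= 0, "segmentation.min_threshold must be >= 0")
    _require(
        0 < seg["dt_threshold_frac"] < 1,
        "segmentation.dt_threshold_frac must be in (0, 1)",
    )
    _require(seg["opening_radius"] >= 0, "segmentation.opening_radius must be >= 0")

    pur = cfg["purity"]
    for key in ("hue_min_deg", "hue_max_deg"):
        _require(0 <= pur[key] <= 360, f"purity.{key} must be in [0, 360]")
    _require(
        pur["hue_min_deg"] <= pur["hue_max_deg"],
        "purity.hue_min_deg must be <= purity.hue_max_deg",
    )

    trk = cfg["tracking"]
    _require(
        len(trk["weights"]) == 3 and min(trk["weights"]) >= 0,
        "tracking.weights must be three values >= 0",
    )
    _require(trk["j_max"] > 0, "tracking.j_max must be > 0")
    _require(trk["max_missed"] >= 0, "tracking.max_missed must be >= 0")
    _require(trk["min_track_length"] >= 1, "tracking.min_track_length must be >= 1")
    _require(
        trk["solver"] in ("greedy", "optimal"),
        "tracking.solver must be 'greedy' or 'optimal'",
    )

    met = cfg["metrics"]
    _require(
        met["volume_variant"] in ("major", "minor"),
        "metrics.volume_variant must be 'major' or 'minor'",
    )
    _require(met["diameter_bin_um"] > 0, "metrics.diameter_bin_um must be > 0")
    _require(met["ratio_bin"] > 0, "metrics.ratio_bin must be > 0")

    sc = cfg["scale"]
    if sc["delta_um_per_px"] is not None:
        _require(sc["delta_um_per_px"] > 0, "scale.delta_um_per_px must be > 0")
    elif sc["marker_px"] is not None:
        _require(
            sc["marker_px"] > 0 and sc["marker_um"] > 0,
            "scale.marker_px and scale.marker_um must be > 0",
        )
    _require(cfg["frame_rate"] > 0, "frame_rate must be > 0")
    return cfg


def resolve_scale(cfg: Mapping[str, Any]):
    """Build the ScaleCalibration a validated config describes."""
    from .frames_io import ScaleCalibration, calibrate_scale

    sc = cfg["scale"]
    if sc["delta_um_per_px"] is not None:
        return ScaleCalibration(delta_um_per_px=float(sc["delta_um_per_px"]))
    if sc["marker_px"] is not None:
        return calibrate_scale(float(sc["marker_px"]), float(sc["marker_um"]))
    raise ConfigError(
        "pixel scale unresolved: set scale.delta_um_per_px or scale.marker_px"
    )
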
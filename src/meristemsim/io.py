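"""Serialization of tissue states, parameter configs, and report tables."""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import pandas as pd
import yaml

from .analysis import ReferenceDistribution
from .mechanics import ModelParams
from .tissue import TissueState

__all__ = ["save_tissue", "load_tissue", "load_params", "save_params",
           "emit_report", "write_manifest"]

_FORMAT_VERSION = 1

#: config keys accepted by load_params, mapped to ModelParams fields
_PARAM_KEYS = {
    "spring_k": "spring_k", "k": "spring_k",
    "growth_k": "growth_k", "k_growth": "growth_k",
    "radial_k": "radial_k", "k_radial": "radial_k",
    "area_threshold": "area_threshold", "A_threshold": "area_threshold",
    "d_threshold": "d_threshold",
    "radius_threshold": "radius_threshold", "R_threshold": "radius_threshold",
    "division_enabled": "division_enabled",
    "radial_mode": "radial_mode",
    "signed_strain": "signed_strain",
    "strain_weight": "strain_weight",
    "ode_rel_tol": "ode_rel_tol", "ode_abs_tol": "ode_abs_tol",
}


class TissueFormatError(ValueError):
    """A tissue-state file violates the documented schema."""


def save_tissue(t: TissueState, path) -> None:
    """Write a tissue state as JSON (lossless float round-trip)."""
    d = t.to_dict()
    d["format_version"] = _FORMAT_VERSION
    Path(path).write_text(json.dumps(d) + "\n")


def load_tissue(path) -> TissueState:
    """Read a tissue state written by :func:`save_tissue`, validating it."""
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise TissueFormatError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("sim_time", "next_id", "vertices", "walls", "cells"):
        if key not in d:
            raise TissueFormatError(f"{path}: missing section {key!r}")
    try:
        t = TissueState.from_dict(d)
        t.check_integrity()
    except (KeyError, ValueError, AssertionError, TypeError) as exc:
        raise TissueFormatError(f"{path}: invalid tissue state ({exc})") from exc
    return t


def load_params(path=None, preset: str | None = None, **overrides) -> ModelParams:
    """Build :class:`ModelParams` from an optional YAML/JSON config file.

    Missing keys default to the standard parameter set (0.05, 0.01, 0.05,
    1.0, 0.1, 7.0).  ``preset="oryzalin"`` switches division off.
    """
    kwargs: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        if "preset" in raw:
            preset = preset or raw.pop("preset")
        for key, val in raw.items():
            if key not in _PARAM_KEYS:
                raise ValueError(f"{path}: unknown parameter {key!r}")
            kwargs[_PARAM_KEYS[key]] = val
    kwargs.update(overrides)
    params = ModelParams(**kwargs)
    if preset == "oryzalin":
        params = params.oryzalin()
    elif preset not in (None, "standard"):
        raise ValueError(f"unknown preset {preset!r}")
    return params


def save_params(params: ModelParams, path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(params)))


def load_reference(path) -> ReferenceDistribution:
    """Two-column TSV (neighbor number, fraction)."""
    return ReferenceDistribution.from_tsv(path)


def emit_report(summaries: dict[str, dict[str, float]], out_dir) -> pd.DataFrame:
    """Write the per-rule summary table as TSV + JSON; returns the frame.

    One row per division rule: neighbor-count std and skewness with
    across-snapshot errors, mean shape measure, and deviation from the
    reference distribution, sorted by deviation ascending.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rule, s in summaries.items():
        rows.append({"rule": rule, **s})
    df = pd.DataFrame(rows).sort_values("deviation_mean").reset_index(drop=True)
    df.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    (out_dir / "summary.json").write_text(json.dumps(summaries, indent=2) + "\n")
    return df


def write_manifest(out_dir, config_echo: dict, seed: int,
                   snapshot_files: list[str], started: float) -> Path:
    """Record everything needed to reproduce a run bit-exactly."""
    from . import __version__

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config": config_echo,
        "snapshot_files": snapshot_files,
        "started_unix": started,
        "finished_unix": time.time(),
    }
    p = Path(out_dir) / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2) + "\n")
    return p
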
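"""Run configuration: YAML/JSON files mapped onto the stage dataclasses.

A config file may carry any of the sections ``encoder``, ``nzv``,
``split``, ``sim`` and ``registry``; unknown sections or keys are
rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import yaml

from antiangio.encoders import EncoderConfig
from antiangio.models import ModelSpec, SplitSpec
from antiangio.selection import NZVConfig
from antiangio.simulate import SimSpec

_SECTIONS = ("encoder", "nzv", "split", "sim", "registry")


class ConfigError(ValueError):
    """The configuration file is malformed or carries unknown keys."""


def _build(cls, section: str, data: dict[str, Any], **overrides):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"unknown key(s) in section {section!r}: {sorted(unknown)}")
    merged = {**data, **overrides}
    # dataclass validation reports bad values
    try:
        return cls(**merged)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section {section!r}: {exc}") from exc


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Parse a YAML or JSON config file into a validated section dict."""
    if path is None:
        return {}
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"{path}: unknown section(s): {sorted(unknown)}")
    return data


def encoder_config(cfg: dict[str, Any], **overrides) -> EncoderConfig:
    data = dict(cfg.get("encoder", {}))
    if "kmer_ks" in data:
        data["kmer_ks"] = tuple(data["kmer_ks"])
    return _build(EncoderConfig, "encoder", data, **overrides)


def nzv_config(cfg: dict[str, Any], **overrides) -> NZVConfig:
    return _build(NZVConfig, "nzv", dict(cfg.get("nzv", {})), **overrides)


def split_spec(cfg: dict[str, Any], **overrides) -> SplitSpec:
    return _build(SplitSpec, "split", dict(cfg.get("split", {})), **overrides)


def sim_spec(cfg: dict[str, Any], **overrides) -> SimSpec:
    data = dict(cfg.get("sim", {}))
    if "length_range" in data:
        data["length_range"] = tuple(data["length_range"])
    if "signal_residues" in data:
        data["signal_residues"] = frozenset(data["signal_residues"])
    if "terminal_signal" in data and data["terminal_signal"] is not None:
        data["terminal_signal"] = tuple(data["terminal_signal"])
    return _build(SimSpec, "sim", data, **overrides)


def registry_specs(cfg: dict[str, Any]) -> list[ModelSpec] | None:
    """The classifier registry from config, or None to use the default."""
    entries = cfg.get("registry")
    if entries is None:
        return None
    specs = []
    for i, entry in enumerate(entries):
        data = dict(entry)
        if "class_weights" in data and data["class_weights"] is not None:
            data["class_weights"] = tuple(data["class_weights"])
        specs.append(_build(ModelSpec, f"registry[{i}]", data))
    return specs
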
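"""Run configuration: YAML file + flag overrides, strict about unknown keys."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .design import (
    DEFAULT_ADAPTERS,
    DEFAULT_MAX_NICK_TO_EDIT,
    DEFAULT_PBS_LEN,
    DEFAULT_RT_HOMOLOGY_LEN,
    DEFAULT_SHAM_GUIDE,
    SGRNA_SCAFFOLD,
    T7_PROMOTER,
    AdapterTable,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Unknown or invalid configuration key/value."""


@dataclass
class RunConfig:
    """Resolved configuration for one run; every run logs the full config."""

    scaffold_seq: str = SGRNA_SCAFFOLD
    t7_promoter: str = T7_PROMOTER
    sham_guide_seq: str = DEFAULT_SHAM_GUIDE
    pbs_len: int = DEFAULT_PBS_LEN
    rt_homology_len: int = DEFAULT_RT_HOMOLOGY_LEN
    max_nick_to_edit: int = DEFAULT_MAX_NICK_TO_EDIT
    second_nick_window: tuple = (-120, 120)
    second_nick_exclusion: tuple = (-10, 10)
    ptd_min_match: int = 3
    max_window_mismatches: int = 3
    min_read_len: int | None = None
    log_level: str = "INFO"
    seed: int = 0
    adapters: dict | None = None  # dialect -> slot -> [top, bottom]

    def adapter_table(self) -> AdapterTable:
        if self.adapters is None:
            return DEFAULT_ADAPTERS
        table = {
            dialect: {slot: tuple(pair) for slot, pair in slots.items()}
            for dialect, slots in self.adapters.items()
        }
        return AdapterTable(table=table)


def load_config(path=None, **overrides) -> RunConfig:
    """Load a YAML config file (optional) and apply keyword overrides.

    Unknown keys in either source are rejected outright rather than ignored.
    """
    known = {f.name for f in fields(RunConfig)}
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s) {sorted(unknown)}")
        data.update(raw)
    overrides = {k: v for k, v in overrides.items() if v is not None}
    unknown = set(overrides) - known
    if unknown:
        raise ConfigError(f"unknown config override(s) {sorted(unknown)}")
    data.update(overrides)
    for key in ("second_nick_window", "second_nick_exclusion"):
        if key in data:
            data[key] = tuple(data[key])
    cfg = RunConfig(**data)
    cfg.adapter_table()  # validate structure eagerly
    logger.info("resolved config: %s", cfg)
    return cfg
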
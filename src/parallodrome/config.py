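"""YAML configuration and logging setup.

A single config file holds one section per pipeline stage (simulate,
popgen, cluster, origin_test, pheno, classify); any CLI flag can be
pre-set there and is overridden by an explicit command-line value.
"""

from __future__ import annotations

import logging

import yaml

SECTIONS = ("simulate", "popgen", "cluster", "origin_test", "pheno", "classify")


def load_config(path=None) -> dict:
    """Load a YAML config; missing file/None gives an empty config."""
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping of sections")
    unknown = set(cfg) - set(SECTIONS) - {"seed", "log_level"}
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    return cfg


def stage_defaults(cfg: dict, stage: str) -> dict:
    out = dict(cfg.get(stage) or {})
    if "seed" in cfg and "seed" not in out:
        out["seed"] = cfg["seed"]
    return out


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
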
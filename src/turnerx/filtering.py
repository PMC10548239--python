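"""The two parallel exome filtering pipelines.

The *somatic-mosaic* pipeline keeps calls with at least 40x coverage and a
variant allele fraction between 0.05 and 0.25 (both bounds inclusive) —
sensitive enough for genuine low-fraction changes while excluding noise
below and likely heterozygous germline calls above the window.

The *standard* pipeline (germline and early-somatic variation) applies a
call-quality floor, a depth floor and a minimum VAF.  Its thresholds are
fully configuration-driven; the shipped defaults (quality >= 20,
depth >= 10, vaf >= 0.25) are conservative, conventional choices.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
import yaml


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds driving both pipelines.

    ``min_quality_somatic`` is an optional extra quality floor for the
    somatic pipeline, off (None) by default.
    """

    min_depth_somatic: int = 40
    vaf_low: float = 0.05
    vaf_high: float = 0.25
    min_quality_standard: float = 20.0
    min_depth_standard: int = 10
    vaf_min_standard: float = 0.25
    min_quality_somatic: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.vaf_low < self.vaf_high <= 1.0):
            raise ValueError(
                f"need 0 <= vaf_low < vaf_high <= 1, got ({self.vaf_low}, {self.vaf_high})")
        if self.min_depth_somatic < 0 or self.min_depth_standard < 0:
            raise ValueError("depth thresholds must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def somatic_filter(variants: pd.DataFrame, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Keep calls in the somatic-mosaic window.

    Kept iff depth >= ``min_depth_somatic`` and
    ``vaf_low`` <= vaf <= ``vaf_high`` (inclusive bounds); input order is
    preserved.  Empty input yields empty output.
    """
    cfg = cfg or FilterConfig()
    mask = (
        (variants["depth"] >= cfg.min_depth_somatic)
        & (variants["vaf"] >= cfg.vaf_low)
        & (variants["vaf"] <= cfg.vaf_high)
    )
    if cfg.min_quality_somatic is not None:
        mask &= variants["call_quality"] >= cfg.min_quality_somatic
    return variants.loc[mask]


def standard_filter(variants: pd.DataFrame, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Keep calls passing the standard (germline) thresholds.

    Kept iff call_quality >= ``min_quality_standard`` and
    depth >= ``min_depth_standard`` and vaf >= ``vaf_min_standard``.
    """
    cfg = cfg or FilterConfig()
    mask = (
        (variants["call_quality"] >= cfg.min_quality_standard)
        & (variants["depth"] >= cfg.min_depth_standard)
        & (variants["vaf"] >= cfg.vaf_min_standard)
    )
    return variants.loc[mask]


def apply_filter(variants: pd.DataFrame, mode: str,
                 cfg: FilterConfig | None = None) -> pd.DataFrame:
    if mode == "somatic":
        return somatic_filter(variants, cfg)
    if mode == "standard":
        return standard_filter(variants, cfg)
    raise ValueError(f"unknown filter mode {mode!r} (expected 'standard' or 'somatic')")
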
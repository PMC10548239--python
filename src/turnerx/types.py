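"""Core domain types shared across the package.

Variant and sample records are plain dataclasses; cohort-scale collections
are pandas DataFrames with the column contracts defined here (``VARIANT_COLUMNS``,
``SAMPLE_COLUMNS``).  Coordinates are 1-based, fully closed, VCF convention,
GRCh38 labels; chromosome names are stored without a ``chr`` prefix.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class Consequence(str, enum.Enum):
    """Predicted translational impact of a variant."""

    missense = "missense"
    synonymous = "synonymous"
    frameshift = "frameshift"
    inframe = "inframe"
    stop_gain = "stop_gain"
    other = "other"


class Group(str, enum.Enum):
    """Karyotype cohort of a sample.

    The Turner-syndrome groups are 45,X monosomy, ring-X mosaics
    (45,X/46,X,r(X)), complex/deletion karyotypes, and isochromosome Xq
    (45,X/46,X,i(Xq)).  Comparison groups are 46,XX controls, 46,XX women
    with primary ovarian insufficiency, and 46,XY controls.
    """

    TS_monosomy = "TS_monosomy"
    TS_ring = "TS_ring"
    TS_complex = "TS_complex"
    TS_isochromosome = "TS_isochromosome"
    XX_control = "XX_control"
    XX_POI = "XX_POI"
    XY_control = "XY_control"


#: Binary clinical condition flags tracked per sample.
CONDITIONS: tuple[str, ...] = (
    "diabetes",
    "obesity",
    "autoimmunity",
    "hypothyroidism",
    "hypertension",
    "cca",
    "hearing_loss",
)

#: Phenotype status values. ``unknown`` samples are excluded from the
#: corresponding burden analysis, never imputed.
PHENOTYPE_PRESENT = 1
PHENOTYPE_ABSENT = 0
PHENOTYPE_UNKNOWN = -1

VARIANT_COLUMNS: tuple[str, ...] = (
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "depth",
    "vaf",
    "call_quality",
    "pop_af",
)

SAMPLE_COLUMNS: tuple[str, ...] = ("sample_id", "group") + CONDITIONS

#: Canonical chromosome labels.
CANONICAL_CHROMS = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "MT")

#: GRCh38 pseudoautosomal regions on the X chromosome (1-based, closed).
PAR_REGIONS: dict[str, tuple[int, int]] = {
    "PAR1": (10_001, 2_781_479),
    "PAR2": (155_701_383, 156_030_895),
}


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant call in one sample."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    consequence: Consequence = Consequence.other
    depth: int = 0
    vaf: float = 0.0
    call_quality: float = 0.0
    pop_af: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt identical at {self.chrom}:{self.pos}")
        if not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf out of [0,1]: {self.vaf}")
        if self.depth < 0:
            raise ValueError(f"negative depth: {self.depth}")

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class SampleRecord:
    """Sample identity, karyotype group and binary phenotype flags.

    ``phenotypes`` maps each condition to 1 (present), 0 (absent) or
    -1 (unknown).
    """

    sample_id: str
    group: Group
    phenotypes: Mapping[str, int] = field(default_factory=dict)

    def status(self, condition: str) -> int:
        return int(self.phenotypes.get(condition, PHENOTYPE_UNKNOWN))


def variants_to_frame(records: Iterable[VariantRecord]) -> pd.DataFrame:
    """Materialize variant records into the canonical DataFrame layout."""
    rows = [
        (
            r.sample_id,
            r.chrom,
            r.pos,
            r.ref,
            r.alt,
            r.gene,
            r.consequence.value if isinstance(r.consequence, Consequence) else str(r.consequence),
            r.depth,
            r.vaf,
            r.call_quality,
            np.nan if r.pop_af is None else r.pop_af,
        )
        for r in records
    ]
    df = pd.DataFrame(rows, columns=list(VARIANT_COLUMNS))
    if df.empty:
        df = empty_variant_frame()
    return df


def empty_variant_frame() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        VARIANT_COLUMNS,
        ["object", "object", "int64", "object", "object", "object",
         "object", "int64", "float64", "float64", "float64"],
    )})
    return df


def samples_to_frame(records: Iterable[SampleRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"sample_id": r.sample_id, "group": r.group.value}
        for c in CONDITIONS:
            row[c] = r.status(c)
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(SAMPLE_COLUMNS))
    return df


@dataclass
class CohortTable:
    """Merged cohort-level container: one variant table, one sample table.

    Invariants: every variant's ``sample_id`` appears in ``samples`` and
    (sample_id, chrom, pos, ref, alt) is unique.
    """

    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing_v = set(VARIANT_COLUMNS) - set(self.variants.columns)
        if missing_v:
            raise ValueError(f"variant table missing columns: {sorted(missing_v)}")
        missing_s = set(SAMPLE_COLUMNS) - set(self.samples.columns)
        if missing_s:
            raise ValueError(f"sample table missing columns: {sorted(missing_s)}")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sample table")
        unknown = set(self.variants["sample_id"]) - set(self.samples["sample_id"])
        if unknown:
            raise ValueError(f"variants reference unknown samples: {sorted(unknown)[:5]}")
        bad_groups = set(self.samples["group"]) - {g.value for g in Group}
        if bad_groups:
            raise ValueError(f"unknown karyotype groups: {sorted(bad_groups)}")
        dup = self.variants.duplicated(subset=["sample_id", "chrom", "pos", "ref", "alt"])
        if dup.any():
            raise ValueError(f"{int(dup.sum())} duplicate (sample, variant) keys after merge")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def group_sizes(self) -> dict[str, int]:
        return self.samples["group"].value_counts().to_dict()

    def sample_ids_in_group(self, *groups: Group | str) -> list[str]:
        wanted = {g.value if isinstance(g, Group) else str(g) for g in groups}
        mask = self.samples["group"].isin(wanted)
        return self.samples.loc[mask, "sample_id"].tolist()
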
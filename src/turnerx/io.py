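"""Reading, writing and merging of cohort-level variant tables.

Three on-disk formats are supported:

* **VCF v4.2/4.3** via :mod:`cyvcf2`.  Per-sample depth comes from FORMAT
  ``DP``; VAF uses an explicit FORMAT ``AF``/``VAF`` field when present and
  otherwise is derived from ``AD`` as alt/(ref+alt).  Gene, consequence and
  population allele frequency are read from the INFO keys ``GENE``,
  ``CSQ`` and ``GNOMAD_AF`` when present.
* **Annotated export CSV** — a flat, UTF-8, comma-delimited dialect
  emulating clinical-annotation platform exports: one row per
  sample-variant with a fixed documented header (``VARIANT_COLUMNS``).
* **Sample metadata TSV** — columns ``sample_id``, ``group`` and one
  column per condition with values ``0``/``1``/``NA``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import (
    CANONICAL_CHROMS,
    CONDITIONS,
    PHENOTYPE_UNKNOWN,
    SAMPLE_COLUMNS,
    VARIANT_COLUMNS,
    CohortTable,
    Consequence,
    VariantRecord,
    empty_variant_frame,
)

logger = logging.getLogger(__name__)

#: Fixed mapping from annotation vocabulary to the consequence enum.
#: Anything unmapped falls through to ``other`` (counted and logged).
CONSEQUENCE_MAP: dict[str, Consequence] = {
    "missense": Consequence.missense,
    "missense_variant": Consequence.missense,
    "missense variant": Consequence.missense,
    "synonymous": Consequence.synonymous,
    "synonymous_variant": Consequence.synonymous,
    "synonymous variant": Consequence.synonymous,
    "frameshift": Consequence.frameshift,
    "frameshift_variant": Consequence.frameshift,
    "frameshift variant": Consequence.frameshift,
    "inframe": Consequence.inframe,
    "inframe_deletion": Consequence.inframe,
    "inframe deletion": Consequence.inframe,
    "inframe_insertion": Consequence.inframe,
    "inframe insertion": Consequence.inframe,
    "in-frame": Consequence.inframe,
    "stop_gain": Consequence.stop_gain,
    "stop gained": Consequence.stop_gain,
    "stop_gained": Consequence.stop_gain,
    "stopgain": Consequence.stop_gain,
    "nonsense": Consequence.stop_gain,
    "other": Consequence.other,
}


def map_consequence(annotation: str) -> Consequence:
    """Total mapping: every annotation string maps to exactly one enum value."""
    return CONSEQUENCE_MAP.get(str(annotation).strip().lower(), Consequence.other)


def normalize_chrom(chrom: str) -> str:
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    if c in ("M", "m", "mt"):
        c = "MT"
    return c


@dataclass
class ParseReport:
    """Record-level errors collected while reading a file."""

    n_parsed: int = 0
    n_skipped: int = 0
    skipped_reasons: list[str] = field(default_factory=list)
    n_unmapped_consequence: int = 0

    def skip(self, reason: str) -> None:
        self.n_skipped += 1
        self.skipped_reasons.append(reason)


def _info_float(v, key: str) -> float | None:
    val = v.INFO.get(key)
    if val is None:
        return None
    try:
        if isinstance(val, (tuple, list)):
            val = val[0]
        f = float(val)
    except (TypeError, ValueError):
        return None
    return f if np.isfinite(f) else None


def read_vcf(path: str | Path, sample_id: str,
             report: ParseReport | None = None) -> list[VariantRecord]:
    """Read one sample's calls from a VCF into variant records.

    Multiallelic sites are decomposed into one record per alternate
    allele; positions stay 1-based.  Records missing both DP and a usable
    AD/AF are skipped and counted in ``report``; an unreadable file raises.
    """
    from cyvcf2 import VCF

    report = report if report is not None else ParseReport()
    vcf = VCF(str(path))
    names = list(vcf.samples)
    if sample_id in names:
        sidx = names.index(sample_id)
    elif len(names) == 1:
        sidx = 0
    else:
        raise ValueError(f"sample {sample_id!r} not present in {path}")

    out: list[VariantRecord] = []
    for v in vcf:
        chrom = normalize_chrom(v.CHROM)
        dp = v.format("DP")
        depth = None
        if dp is not None:
            d = float(np.ravel(dp[sidx])[0])
            if np.isfinite(d) and d >= 0:
                depth = int(d)
        ad = v.format("AD")
        ad_row = None
        if ad is not None:
            ad_row = np.ravel(ad[sidx]).astype(float)
        gene = str(v.INFO.get("GENE") or "")
        csq = map_consequence(str(v.INFO.get("CSQ") or ""))
        pop_af = _info_float(v, "GNOMAD_AF")
        qual = float(v.QUAL) if v.QUAL is not None else 0.0

        for alt_i, alt in enumerate(v.ALT):
            vaf = None
            af = v.format("AF") if "AF" in (v.FORMAT or []) else None
            if af is not None:
                a = np.ravel(af[sidx]).astype(float)
                if alt_i < a.size and np.isfinite(a[alt_i]):
                    vaf = float(np.clip(a[alt_i], 0.0, 1.0))
            if vaf is None and ad_row is not None and ad_row.size > alt_i + 1:
                ref_n, alt_n = ad_row[0], ad_row[alt_i + 1]
                if np.isfinite(ref_n) and np.isfinite(alt_n) and ref_n + alt_n > 0:
                    vaf = float(alt_n / (ref_n + alt_n))
            if depth is None and ad_row is not None and np.all(np.isfinite(ad_row)):
                depth = int(ad_row.sum())
            if depth is None or vaf is None:
                report.skip(f"{chrom}:{v.POS} {v.REF}>{alt}: missing DP/AD")
                continue
            try:
                rec = VariantRecord(
                    sample_id=sample_id, chrom=chrom, pos=int(v.POS),
                    ref=str(v.REF), alt=str(alt), gene=gene,
                    consequence=csq, depth=depth, vaf=vaf,
                    call_quality=qual, pop_af=pop_af,
                )
            except ValueError as exc:
                report.skip(f"{chrom}:{v.POS}: {exc}")
                continue
            out.append(rec)
            report.n_parsed += 1
    if report.n_skipped:
        logger.warning("read_vcf(%s): skipped %d record(s)", path, report.n_skipped)
    return out


def read_annotated_export(path: str | Path,
                          report: ParseReport | None = None) -> pd.DataFrame:
    """Read the flat annotated-export CSV dialect into a variant frame.

    A header missing any required column is fatal and the error lists the
    missing columns.  An empty ``pop_af`` cell becomes missing (NaN).
    """
    report = report if report is not None else ParseReport()
    df = pd.read_csv(path, dtype={"chrom": str, "sample_id": str, "ref": str,
                                  "alt": str, "gene": str})
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotated export {path}: missing columns {missing}")
    df = df[list(VARIANT_COLUMNS)].copy()
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["gene"] = df["gene"].fillna("").astype(str)
    raw_csq = df["consequence"].fillna("").astype(str)
    mapped = raw_csq.map(lambda s: map_consequence(s).value)
    report.n_unmapped_consequence = int(
        ((mapped == Consequence.other.value)
         & (raw_csq.str.strip().str.lower() != "other")
         & (raw_csq.str.strip() != "")).sum())
    if report.n_unmapped_consequence:
        logger.info("read_annotated_export(%s): %d unmapped consequence value(s) -> other",
                    path, report.n_unmapped_consequence)
    df["consequence"] = mapped
    df["pos"] = df["pos"].astype(int)
    df["depth"] = df["depth"].astype(int)
    df["vaf"] = df["vaf"].astype(float)
    df["call_quality"] = df["call_quality"].astype(float)
    df["pop_af"] = pd.to_numeric(df["pop_af"], errors="coerce")
    report.n_parsed = len(df)
    return df


def write_annotated_export(variants: pd.DataFrame, path: str | Path) -> None:
    """Write a variant frame as the annotated-export CSV dialect.

    Floats are formatted at 6 significant digits, which bounds the
    round-trip error of write-then-read.
    """
    df = variants[list(VARIANT_COLUMNS)]
    df.to_csv(path, index=False, float_format="%.6g")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, group, condition flags).

    Condition cells are 0/1/NA; NA means unknown status and is stored as -1.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    missing = [c for c in ("sample_id", "group") if c not in df.columns]
    if missing:
        raise ValueError(f"metadata {path}: missing columns {missing}")
    out = df[["sample_id", "group"]].copy()
    for c in CONDITIONS:
        if c in df.columns:
            vals = pd.to_numeric(df[c], errors="coerce")
            out[c] = vals.fillna(PHENOTYPE_UNKNOWN).astype(int)
        else:
            out[c] = PHENOTYPE_UNKNOWN
    return out[list(SAMPLE_COLUMNS)]


def write_sample_metadata(samples: pd.DataFrame, path: str | Path) -> None:
    df = samples[list(SAMPLE_COLUMNS)].copy()
    for c in CONDITIONS:
        df[c] = df[c].map(lambda v: "NA" if int(v) == PHENOTYPE_UNKNOWN else str(int(v)))
    df.to_csv(path, sep="\t", index=False)


def merge_cohort(tables: Iterable[pd.DataFrame | Sequence[VariantRecord]],
                 samples: pd.DataFrame) -> CohortTable:
    """Merge per-sample variant tables into one cohort table.

    Duplicate (sample, chrom, pos, ref, alt) keys keep the record with the
    higher call quality; on an exact quality tie the first by input order
    wins and the collision is logged.  A variant naming a sample absent
    from ``samples`` is fatal.  Merging is order-independent up to row
    order (the output is sorted on the variant key).
    """
    from .types import variants_to_frame

    frames = []
    for t in tables:
        if isinstance(t, pd.DataFrame):
            frames.append(t[list(VARIANT_COLUMNS)])
        else:
            frames.append(variants_to_frame(t))
    if frames:
        allv = pd.concat(frames, ignore_index=True)
    else:
        allv = empty_variant_frame()

    unknown = set(allv["sample_id"]) - set(samples["sample_id"])
    if unknown:
        raise ValueError(f"variants reference sample_ids not in metadata: {sorted(unknown)[:5]}")

    key = ["sample_id", "chrom", "pos", "ref", "alt"]
    dup_mask = allv.duplicated(subset=key, keep=False)
    if dup_mask.any():
        ties = (allv[dup_mask].groupby(key)["call_quality"].nunique() == 1).sum()
        if ties:
            logger.warning("merge_cohort: %d duplicate key(s) tied on quality; keeping first", int(ties))
        # stable sort: highest quality first within key, ties keep input order
        allv = (allv.reset_index(names="_order")
                    .sort_values("call_quality", ascending=False, kind="stable")
                    .drop_duplicates(subset=key, keep="first")
                    .sort_values("_order", kind="stable")
                    .drop(columns="_order"))
    allv = allv.sort_values(key, kind="stable").reset_index(drop=True)
    return CohortTable(variants=allv, samples=samples.reset_index(drop=True))
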
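"""Shared fixtures: tiny in-memory cohorts and on-disk format fixtures.

Everything is generated programmatically at test time; nothing binary is
stored in the repository.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from turnerx.types import (
    CONDITIONS,
    PHENOTYPE_UNKNOWN,
    SAMPLE_COLUMNS,
    VARIANT_COLUMNS,
    CohortTable,
)

VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=chrX,length=156040895>
##contig=<ID=chr22,length=50818468>
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">
##INFO=<ID=GNOMAD_AF,Number=1,Type=Float,Description="Population AF">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
chrX\t1601004\t.\tC\tG\t50\tPASS\tGENE=AKAP17A;CSQ=missense;GNOMAD_AF=0.54\tGT:DP:AD\t1:100:80,20
chrX\t2000000\t.\tA\tT,G\t30\tPASS\tGENE=XG1;CSQ=stop_gained\tGT:DP:AD\t1/2:60:10,30,20
chr22\t32857305\t.\tC\tT\t99\tPASS\tGENE=TIMP3;CSQ=synonymous;GNOMAD_AF=0.09\tGT:DP:AD\t0/1:80:40,40
chrX\t3000000\t.\tG\tA\t10\tPASS\tGENE=XG2;CSQ=frameshift\tGT\t1
chrX\t4000000\t.\tT\tC\t40\tPASS\tGENE=XG3;CSQ=inframe deletion\tGT:DP:AD\t1:55:5,50
"""


@pytest.fixture
def vcf_path(tmp_path):
    path = tmp_path / "sample.vcf"
    path.write_text(VCF_TEXT)
    return path


def make_samples(spec: dict[str, int], phenotypes: dict[str, dict[str, int]] | None = None,
                 ) -> pd.DataFrame:
    """Sample table from {group: size}; phenotypes maps sample_id -> flags."""
    rows = []
    for group, size in spec.items():
        for i in range(size):
            sid = f"{group}_{i + 1:03d}"
            row = {"sample_id": sid, "group": group}
            flags = (phenotypes or {}).get(sid, {})
            for c in CONDITIONS:
                row[c] = flags.get(c, PHENOTYPE_UNKNOWN)
            rows.append(row)
    if not rows:
        return pd.DataFrame({c: pd.Series(dtype="object" if c in ("sample_id", "group")
                                          else "int64") for c in SAMPLE_COLUMNS})
    return pd.DataFrame(rows, columns=list(SAMPLE_COLUMNS))


def make_variants(rows: list[dict]) -> pd.DataFrame:
    """Variant frame from shorthand dicts with defaults for optional fields."""
    from turnerx.types import empty_variant_frame

    if not rows:
        return empty_variant_frame()
    defaults = dict(gene="", consequence="other", depth=60, vaf=0.98,
                    call_quality=50.0, pop_af=np.nan, ref="A", alt="G")
    full = [{**defaults, **r} for r in rows]
    return pd.DataFrame(full)[list(VARIANT_COLUMNS)]


@pytest.fixture
def toy_cohort() -> CohortTable:
    """Two monosomy samples with three variants each on chr1/chrX."""
    samples = make_samples({"TS_monosomy": 2})
    variants = make_variants([
        {"sample_id": "TS_monosomy_001", "chrom": "1", "pos": 100, "gene": "G1",
         "consequence": "missense"},
        {"sample_id": "TS_monosomy_001", "chrom": "1", "pos": 200, "gene": "G1",
         "consequence": "missense"},
        {"sample_id": "TS_monosomy_001", "chrom": "X", "pos": 300, "gene": "G2",
         "consequence": "synonymous"},
        {"sample_id": "TS_monosomy_002", "chrom": "2", "pos": 400, "gene": "G3",
         "consequence": "stop_gain"},
        {"sample_id": "TS_monosomy_002", "chrom": "X", "pos": 300, "gene": "G2",
         "consequence": "synonymous"},
        {"sample_id": "TS_monosomy_002", "chrom": "Y", "pos": 500, "gene": "G4",
         "consequence": "other"},
    ])
    return CohortTable(variants=variants, samples=samples)
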
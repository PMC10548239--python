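"""Candidate-gene allele-frequency replication on autosomes.

Compares the alternate-allele frequency of each common variant in a
candidate autosomal gene (e.g. TIMP3 on chromosome 22, whose variants have
been linked to congenital cardiovascular anomalies in Turner syndrome)
between a with-condition and a without-condition group.

Allele counting is diploid: a heterozygous individual contributes one
alternate allele, a homozygous-alternate individual two, so each group
contributes 2 x (group size) alleles per variant.  "MAF" here is the
alternate-allele frequency as tabulated — no folding to the rarer allele
is applied, so values above 0.5 are possible.  Significance uses the same
two-sided Fisher exact test as the burden module on the allele-count
table.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .burden import ContingencyTable2x2, PhenotypeGroups, fisher_exact_two_sided
from .types import CohortTable

#: VAF at or above which a diploid call is treated as homozygous-alternate
#: when no explicit genotype column is available.
HOM_ALT_VAF = 0.8


@dataclass
class AlleleCountComparison:
    """Per-variant allele-frequency comparison between two groups."""

    variant_key: str
    alt_with: int
    total_with: int
    alt_without: int
    total_without: int
    p_fisher: float
    reference_af: float | None = None

    @property
    def maf_with(self) -> float:
        return self.alt_with / self.total_with if self.total_with else float("nan")

    @property
    def maf_without(self) -> float:
        return self.alt_without / self.total_without if self.total_without else float("nan")


def genotype_alt_dosage(vaf: float, hom_alt_vaf: float = HOM_ALT_VAF) -> int:
    """Alternate-allele dosage of a diploid call inferred from its VAF."""
    return 2 if vaf >= hom_alt_vaf else 1


def allele_counts(cohort: CohortTable, gene: str, groups: PhenotypeGroups,
                  hom_alt_vaf: float = HOM_ALT_VAF) -> list[AlleleCountComparison]:
    """Per-variant allele-count comparison for one autosomal candidate gene.

    Individuals in either group without a record at a variant count as
    homozygous reference there.  Overlapping groups are fatal (enforced by
    ``PhenotypeGroups``).  Results are sorted by position.
    """
    v = cohort.variants
    sub = v[(v["gene"] == gene)
            & v["sample_id"].isin(groups.with_ids | groups.without_ids)]
    if not sub.empty and (sub["chrom"] == "X").any():
        raise ValueError(f"candidate gene {gene!r} has X-chromosome records; "
                         "allele counting here is diploid autosomal")
    total_with = 2 * len(groups.with_ids)
    total_without = 2 * len(groups.without_ids)
    out: list[AlleleCountComparison] = []
    keyed = sub.assign(_key=sub["chrom"].astype(str) + ":" + sub["pos"].astype(str)
                       + ":" + sub["ref"] + "-" + sub["alt"],
                       _dosage=sub["vaf"].map(lambda x: genotype_alt_dosage(x, hom_alt_vaf)))
    for key, grp in sorted(keyed.groupby("_key"), key=lambda kv: kv[1]["pos"].iloc[0]):
        per_sample = grp.groupby("sample_id")["_dosage"].max()
        alt_with = int(per_sample[per_sample.index.isin(groups.with_ids)].sum())
        alt_without = int(per_sample[per_sample.index.isin(groups.without_ids)].sum())
        ref_af = grp["pop_af"].dropna()
        table = ContingencyTable2x2(a=alt_with, b=total_with - alt_with,
                                    c=alt_without, d=total_without - alt_without)
        out.append(AlleleCountComparison(
            variant_key=str(key),
            alt_with=alt_with, total_with=total_with,
            alt_without=alt_without, total_without=total_without,
            p_fisher=fisher_exact_two_sided(table),
            reference_af=float(ref_af.iloc[0]) if len(ref_af) else None,
        ))
    return out


def candidate_frame(results: list[AlleleCountComparison]) -> pd.DataFrame:
    return pd.DataFrame([{
        "variant_key": r.variant_key,
        "alt_with": r.alt_with, "total_with": r.total_with, "maf_with": r.maf_with,
        "alt_without": r.alt_without, "total_without": r.total_without,
        "maf_without": r.maf_without,
        "p_fisher": r.p_fisher, "reference_af": r.reference_af,
    } for r in results])
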
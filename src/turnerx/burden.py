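"""Hemizygous X-chromosome gene/variant burden testing.

The central analysis of the package: within women carrying a single X
chromosome in all assayed cells (45,X monosomy), every X variant is
hemizygous, so carrier status per sample is binary and common population
variants are expressed from the only available allele.  For each clinical
condition the monosomy samples split into a with-condition and a
without-condition group (unknown status excluded, never imputed), and for
each gene (or each individual variant) a 2x2 carrier-by-condition table is
tested:

* effect size  Δ = carrier proportion (with) − carrier proportion (without);
  |Δ| strictly greater than 0.35 flags a unit as risk (Δ > 0) or
  protective (Δ < 0),
* a two-sided Fisher exact test using the point-probability rule (the
  convention of R's ``fisher.test``): p is the sum of hypergeometric point
  probabilities not exceeding the observed one, with a relative tolerance
  of 1e-7 on the comparison,
* the conditional maximum-likelihood odds ratio (root of the conditional
  score equation of Fisher's noncentral hypergeometric likelihood) with an
  exact conditional 95% CI obtained by inverting one-sided tests at 2.5%
  per side,
* Bonferroni adjustment over all units with data for the condition.

Only common variants (population allele frequency within a configurable
window, default 0.1–0.9 inclusive) enter the analysis: a carrier-proportion
difference of 0.35 between modest-sized groups is only attainable around a
mid-range population frequency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln

from .types import CONDITIONS, PAR_REGIONS, PHENOTYPE_ABSENT, PHENOTYPE_PRESENT, CohortTable, Group

logger = logging.getLogger(__name__)

#: Relative tolerance on the point-probability comparison of the two-sided
#: Fisher rule, matching the convention of the R statistical environment.
_FISHER_RELTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Carrier/non-carrier by with/without-condition counts.

    a = carriers with condition, b = non-carriers with condition,
    c = carriers without condition, d = non-carriers without condition.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0:
                raise ValueError(f"negative cell in {self}")

    @property
    def n_with(self) -> int:
        return self.a + self.b

    @property
    def n_without(self) -> int:
        return self.c + self.d

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    @property
    def prop_with(self) -> float:
        return self.a / self.n_with if self.n_with else math.nan

    @property
    def prop_without(self) -> float:
        return self.c / self.n_without if self.n_without else math.nan

    @property
    def effect_size(self) -> float:
        return self.prop_with - self.prop_without

    def is_degenerate(self) -> bool:
        """True when a row or column margin is zero (single-point support)."""
        return (self.a + self.b == 0 or self.c + self.d == 0
                or self.a + self.c == 0 or self.b + self.d == 0)


@dataclass(frozen=True)
class PhenotypeGroups:
    """Disjoint with/without sample sets for one condition."""

    condition: str
    with_ids: frozenset
    without_ids: frozenset

    def __post_init__(self) -> None:
        if self.with_ids & self.without_ids:
            raise ValueError("with/without groups overlap")

    @classmethod
    def from_cohort(cls, cohort: CohortTable, condition: str,
                    groups: tuple = (Group.TS_monosomy,)) -> "PhenotypeGroups":
        """Build condition groups from the sample table.

        Restricted to the given karyotype groups (monosomy X by default);
        samples with unknown status are excluded.
        """
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        ids = set(cohort.sample_ids_in_group(*groups))
        s = cohort.samples
        sub = s[s["sample_id"].isin(ids)]
        withs = frozenset(sub.loc[sub[condition] == PHENOTYPE_PRESENT, "sample_id"])
        withouts = frozenset(sub.loc[sub[condition] == PHENOTYPE_ABSENT, "sample_id"])
        return cls(condition=condition, with_ids=withs, without_ids=withouts)


@dataclass
class BurdenResult:
    """Per-gene or per-variant enrichment record."""

    unit_id: str
    level: str  # "gene" | "variant"
    condition: str
    table: ContingencyTable2x2
    prop_with: float
    prop_without: float
    effect_size: float
    or_cmle: float | None
    ci95: tuple[float, float] | None
    p_fisher: float
    p_adj: float
    m_tests: int
    flag: str  # "risk" | "protective" | "none"


def common_af_window(variants: pd.DataFrame, low: float = 0.1,
                     high: float = 0.9) -> pd.DataFrame:
    """Keep variants with population allele frequency inside [low, high].

    Records with missing pop_af are dropped (and counted in the log): a
    variant without a population frequency cannot satisfy the
    common-variant criterion.
    """
    af = variants["pop_af"]
    n_missing = int(af.isna().sum())
    if n_missing:
        logger.info("common_af_window: dropped %d record(s) with missing pop_af", n_missing)
    mask = af.notna() & (af >= low) & (af <= high)
    return variants.loc[mask]


def _carrier_tables(variants: pd.DataFrame, groups: PhenotypeGroups,
                    key_cols: list[str]) -> dict[str, ContingencyTable2x2]:
    part = variants[variants["sample_id"].isin(groups.with_ids | groups.without_ids)]
    n_with = len(groups.with_ids)
    n_without = len(groups.without_ids)
    tables: dict[str, ContingencyTable2x2] = {}
    if part.empty:
        return tables
    keyed = part.assign(_unit=part[key_cols].astype(str).agg("|".join, axis=1)
                        if len(key_cols) > 1 else part[key_cols[0]])
    for unit, sub in keyed.groupby("_unit", sort=True):
        carriers = set(sub["sample_id"])
        a = len(carriers & groups.with_ids)
        c = len(carriers & groups.without_ids)
        tables[str(unit)] = ContingencyTable2x2(a=a, b=n_with - a, c=c, d=n_without - c)
    return tables


def gene_level_carriers(variants: pd.DataFrame,
                        groups: PhenotypeGroups) -> dict[str, ContingencyTable2x2]:
    """Per-gene carrier tables: unique individuals with >=1 qualifying variant.

    A sample carrying several variants of one gene counts once.  Samples
    with zero qualifying variants anywhere still contribute to the
    denominators — they are genotyped non-carriers.  Records with an empty
    gene field are ignored (counted in the log).
    """
    n_nogene = int((variants["gene"].fillna("") == "").sum())
    if n_nogene:
        logger.info("gene_level_carriers: ignored %d record(s) without a gene symbol", n_nogene)
    named = variants[variants["gene"].fillna("") != ""]
    return _carrier_tables(named, groups, ["gene"])


def variant_level_carriers(variants: pd.DataFrame,
                           groups: PhenotypeGroups) -> dict[str, ContingencyTable2x2]:
    """Per-variant carrier tables keyed on chrom|pos|ref|alt."""
    return _carrier_tables(variants, groups, ["chrom", "pos", "ref", "alt"])


# ---------------------------------------------------------------------------
# Exact 2x2 inference


def _support_and_logpmf(t: ContingencyTable2x2) -> tuple[np.ndarray, np.ndarray]:
    """Central-hypergeometric support and log point probabilities.

    Conditioning is on both margins: A ~ Hypergeom(N, K=a+c carriers,
    n=a+b draws from the with-condition group).
    """
    n1, K, N = t.a + t.b, t.a + t.c, t.n
    kmin = max(0, n1 - (N - K))
    kmax = min(n1, K)
    k = np.arange(kmin, kmax + 1)
    logpmf = (
        gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
        + gammaln(N - K + 1) - gammaln(n1 - k + 1) - gammaln(N - K - n1 + k + 1)
        - (gammaln(N + 1) - gammaln(n1 + 1) - gammaln(N - n1 + 1))
    )
    return k, logpmf


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value by the point-probability rule.

    Sums the hypergeometric probabilities of all tables with the observed
    margins whose point probability is <= that of the observed table, with
    a relative tolerance of 1e-7 on the comparison.  A zero row or column
    margin is degenerate and returns p = 1.
    """
    if table.is_degenerate():
        return 1.0
    k, logpmf = _support_and_logpmf(table)
    pmf = np.exp(logpmf - logpmf.max())
    pmf /= pmf.sum()
    p_obs = pmf[k == table.a][0]
    p = float(pmf[pmf <= p_obs * (1.0 + _FISHER_RELTOL)].sum())
    return min(p, 1.0)


def _conditional_mean(logw: np.ndarray, k: np.ndarray, log_psi: float) -> float:
    """E[A] under the noncentral hypergeometric with odds ratio exp(log_psi)."""
    logterms = logw + k * log_psi
    logterms -= logterms.max()
    w = np.exp(logterms)
    return float((k * w).sum() / w.sum())


def _tail_prob(logw: np.ndarray, k: np.ndarray, log_psi: float,
               a: int, upper: bool) -> float:
    logterms = logw + k * log_psi
    logterms -= logterms.max()
    w = np.exp(logterms)
    w /= w.sum()
    return float(w[k >= a].sum() if upper else w[k <= a].sum())


def _solve_log_psi(fun, lo: float = -40.0, hi: float = 40.0) -> float:
    return float(brentq(fun, lo, hi, xtol=1e-12, rtol=1e-14))


def cmle_odds_ratio(table: ContingencyTable2x2,
                    confidence: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Conditional-MLE odds ratio with an exact conditional CI.

    The point estimate solves the conditional score equation
    E_psi[A] = a under the noncentral hypergeometric likelihood; the CI
    inverts one-sided exact tests at (1-confidence)/2 per side.  When the
    observed count sits on a support boundary the estimate is 0 or +inf
    with a one-sided interval.  Degenerate margins return (nan, (nan, nan)).
    """
    if table.is_degenerate():
        return math.nan, (math.nan, math.nan)
    k, logpmf = _support_and_logpmf(table)
    logw = logpmf  # proportional to log C(K,k) + log C(N-K, n1-k)
    a = table.a
    kmin, kmax = int(k[0]), int(k[-1])
    alpha = (1.0 - confidence) / 2.0

    # point estimate
    if a == kmin:
        or_hat = 0.0
    elif a == kmax:
        or_hat = math.inf
    else:
        or_hat = math.exp(_solve_log_psi(
            lambda t: _conditional_mean(logw, k, t) - a))

    # exact conditional CI: P_psi(A >= a) = alpha gives the lower bound,
    # P_psi(A <= a) = alpha the upper (tail probs are monotone in psi).
    if a == kmin:
        lo = 0.0
    else:
        lo = math.exp(_solve_log_psi(
            lambda t: _tail_prob(logw, k, t, a, upper=True) - alpha))
    if a == kmax:
        hi = math.inf
    else:
        hi = math.exp(_solve_log_psi(
            lambda t: _tail_prob(logw, k, t, a, upper=False) - alpha))
    return or_hat, (lo, hi)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni adjustment: min(1, m * p)."""
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p out of (0, 1]: {p}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return min(1.0, m * p)


def classify_effect(effect_size: float, threshold: float = 0.35) -> str:
    """Risk/protective flag; the threshold is strict (|Δ| must exceed it)."""
    if effect_size > threshold:
        return "risk"
    if effect_size < -threshold:
        return "protective"
    return "none"


def in_par(pos: int) -> bool:
    """Whether an X position falls in a GRCh38 pseudoautosomal region."""
    return any(lo <= pos <= hi for lo, hi in PAR_REGIONS.values())


def run_burden(cohort: CohortTable, condition: str, level: str = "gene",
               af_low: float = 0.1, af_high: float = 0.9,
               effect_threshold: float = 0.35,
               analysis_groups: tuple = (Group.TS_monosomy,),
               par_only: bool = False,
               compute_or: bool = True) -> list[BurdenResult]:
    """End-to-end burden screen for one condition.

    Pipeline: restrict to X-chromosome records of the analysis karyotype
    set -> common-AF window -> per-unit carrier tables -> Fisher exact
    test -> Bonferroni over the number of units with data.  Results are
    sorted by |effect size| descending.  ``par_only=True`` restricts to
    pseudoautosomal-region variants (used with a wider multi-karyotype
    ``analysis_groups``).  ``compute_or=False`` skips the conditional-MLE
    step (useful in large simulation sweeps).
    """
    if level not in ("gene", "variant"):
        raise ValueError(f"level must be 'gene' or 'variant', got {level!r}")
    groups = PhenotypeGroups.from_cohort(cohort, condition, groups=analysis_groups)
    if not groups.with_ids or not groups.without_ids:
        raise ValueError(
            f"empty analysis set for condition {condition!r}: "
            f"{len(groups.with_ids)} with / {len(groups.without_ids)} without")
    xvars = cohort.variants[cohort.variants["chrom"] == "X"]
    if par_only:
        xvars = xvars[xvars["pos"].map(in_par)]
    qualifying = common_af_window(xvars, low=af_low, high=af_high)
    if level == "gene":
        tables = gene_level_carriers(qualifying, groups)
    else:
        tables = variant_level_carriers(qualifying, groups)
    # units with >=1 qualifying carrier across both groups
    tables = {u: t for u, t in tables.items() if t.a + t.c > 0}
    m = len(tables)
    results: list[BurdenResult] = []
    for unit, t in tables.items():
        p = fisher_exact_two_sided(t)
        if compute_or:
            or_hat, ci = cmle_odds_ratio(t)
        else:
            or_hat, ci = None, None
        delta = t.effect_size
        results.append(BurdenResult(
            unit_id=unit, level=level, condition=condition, table=t,
            prop_with=t.prop_with, prop_without=t.prop_without,
            effect_size=delta, or_cmle=or_hat, ci95=ci,
            p_fisher=p, p_adj=bonferroni(p, m), m_tests=m,
            flag=classify_effect(delta, effect_threshold),
        ))
    results.sort(key=lambda r: (-abs(r.effect_size), r.unit_id))
    return results


def burden_frame(results: list[BurdenResult]) -> pd.DataFrame:
    """Tabular view of burden results (one row per unit)."""
    rows = []
    for r in results:
        rows.append({
            "unit_id": r.unit_id, "level": r.level, "condition": r.condition,
            "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
            "prop_with": r.prop_with, "prop_without": r.prop_without,
            "effect_size": r.effect_size, "or_cmle": r.or_cmle,
            "ci_low": r.ci95[0] if r.ci95 else None,
            "ci_high": r.ci95[1] if r.ci95 else None,
            "p_fisher": r.p_fisher, "p_adj": r.p_adj,
            "m_tests": r.m_tests, "flag": r.flag,
        })
    return pd.DataFrame(rows)
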
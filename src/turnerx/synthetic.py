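"""Synthetic cohort and SNP-array generation.

The generator emulates the statistical structure the analyses assume, so
every stage of the pipeline is testable without restricted human data:

* karyotype cohort sizes 45,X 75; ring 20; complex 5; isochromosome 34;
  46,XX 23; 46,XX POI 101; 46,XY 11 (269 samples);
* within the monosomy group, fixed with/without counts per condition
  (diabetes 25/24, obesity 19/53, autoimmunity 24/28, hypothyroidism
  32/43, hypertension 16/36, CCA 17/35, hearing loss 14/33), the
  remainder unknown; other karyotype groups draw phenotype status with
  the matching prevalence;
* per-variant carrier probability equal to a gnomAD-like population
  allele frequency, with X-chromosome variant counts scaled by the amount
  of X material per karyotype (carrier probability 1-(1-AF)^intensity);
* optional planted risk/protective genes whose carrier probability is
  shifted by a chosen effect size in with-condition samples;
* hemizygous germline VAF near 1, diploid het/hom VAF near 0.5/1, a
  configurable fraction of additional somatic-mosaic records with VAF in
  the low-fraction window, and read depth with mass on both sides of 40x;
* forward-simulated BAF/LRR marker profiles under the two-population
  copy-number mixture.

Output is deterministic given the seed: all randomness flows from one
``numpy.random.SeedSequence`` with fixed per-stage spawns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mosaicism import CopyMixtureModel, SNPArrayProfile, expected_baf, expected_lrr
from .types import (
    CONDITIONS,
    PHENOTYPE_ABSENT,
    PHENOTYPE_PRESENT,
    PHENOTYPE_UNKNOWN,
    SAMPLE_COLUMNS,
    VARIANT_COLUMNS,
    CohortTable,
    Group,
)

#: Cohort sizes of the seven karyotype groups.
DEFAULT_GROUP_SIZES: dict[str, int] = {
    Group.TS_monosomy.value: 75,
    Group.TS_ring.value: 20,
    Group.TS_complex.value: 5,
    Group.TS_isochromosome.value: 34,
    Group.XX_control.value: 23,
    Group.XX_POI.value: 101,
    Group.XY_control.value: 11,
}

#: (with, without) counts per condition inside the monosomy group; the
#: remaining monosomy samples have unknown status for that condition.
MONOSOMY_CONDITION_COUNTS: dict[str, tuple[int, int]] = {
    "diabetes": (25, 24),
    "obesity": (19, 53),
    "autoimmunity": (24, 28),
    "hypothyroidism": (32, 43),
    "hypertension": (16, 36),
    "cca": (17, 35),
    "hearing_loss": (14, 33),
}

#: X-variant rate multiplier per karyotype, proportionate to X material:
#: one X for 45,X and 46,XY, two for 46,XX/POI, intermediate for partial
#: second-X karyotypes (ring < complex < isochromosome Xq).
DEFAULT_X_INTENSITY: dict[str, float] = {
    Group.TS_monosomy.value: 1.0,
    Group.TS_ring.value: 1.2,
    Group.TS_complex.value: 1.4,
    Group.TS_isochromosome.value: 1.7,
    Group.XX_control.value: 2.0,
    Group.XX_POI.value: 2.0,
    Group.XY_control.value: 1.0,
}

_CSQ_VALUES = ("missense", "synonymous", "frameshift", "inframe", "stop_gain", "other")
_CSQ_PROBS = (0.45, 0.35, 0.05, 0.03, 0.02, 0.10)

# X gene placement (GRCh38-like coordinates, 1-based)
_PAR1_BASE, _PAR1_SPACING = 20_000, 100_000
_X_BASE, _X_SPACING = 3_000_000, 230_000
_VARIANT_SPACING = 150


@dataclass(frozen=True)
class PlantedEffect:
    """A gene whose carrier probability is shifted in condition carriers.

    ``baseline`` is the gene-level carrier probability in samples without
    the condition; with-condition samples carry at ``baseline + delta``.
    """

    gene: str
    condition: str
    delta: float
    baseline: float = 0.50


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the cohort generator (defaults = study conditions)."""

    seed: int = 0
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    monosomy_condition_counts: dict = field(
        default_factory=lambda: dict(MONOSOMY_CONDITION_COUNTS))
    n_x_genes: int = 650
    n_par_genes: int = 24
    variants_per_gene: int = 5
    n_autosomal_genes: int = 120
    af_low: float = 0.05
    af_high: float = 0.95
    planted_effects: tuple = ()
    x_intensity: dict = field(default_factory=lambda: dict(DEFAULT_X_INTENSITY))
    baf_noise_sd: float = 0.03
    lrr_noise_sd: float = 0.15
    somatic_fraction: float = 0.10
    depth_mean: float = 60.0
    depth_dispersion: float = 6.0

    def __post_init__(self) -> None:
        errors = []
        for pe in self.planted_effects:
            if pe.condition not in CONDITIONS:
                errors.append(f"planted {pe.gene}: unknown condition {pe.condition!r}")
            if not (0.0 <= pe.baseline + pe.delta <= 1.0) or not (0.0 <= pe.baseline <= 1.0):
                errors.append(f"planted {pe.gene}: infeasible baseline+delta "
                              f"({pe.baseline}+{pe.delta})")
        if not (0.0 <= self.af_low < self.af_high <= 1.0):
            errors.append(f"invalid AF range ({self.af_low}, {self.af_high})")
        if not (0.0 <= self.somatic_fraction <= 1.0):
            errors.append(f"somatic_fraction out of [0,1]: {self.somatic_fraction}")
        for cond, (n_with, n_without) in self.monosomy_condition_counts.items():
            if n_with + n_without > self.group_sizes.get(Group.TS_monosomy.value, 0):
                errors.append(f"{cond}: with+without exceeds monosomy group size")
        if errors:
            raise ValueError("infeasible simulation config: " + "; ".join(errors))

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def monosomy_screen_config(seed: int = 0, planted_effects: tuple = ()) -> SimulationConfig:
    """Reduced config for burden-screen simulation sweeps.

    Keeps the monosomy group (the burden analysis set) and the full X gene
    panel but drops the other karyotype groups and the autosomal
    background, which the screen never touches.
    """
    return SimulationConfig(
        seed=seed,
        group_sizes={Group.TS_monosomy.value: DEFAULT_GROUP_SIZES[Group.TS_monosomy.value]},
        n_autosomal_genes=0,
        planted_effects=planted_effects,
    )


def _sample_table(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for group, size in cfg.group_sizes.items():
        for i in range(size):
            rows.append({"sample_id": f"{group}_{i + 1:03d}", "group": group})
    df = pd.DataFrame(rows)
    for c in CONDITIONS:
        df[c] = PHENOTYPE_UNKNOWN

    mono_mask = df["group"] == Group.TS_monosomy.value
    mono_idx = df.index[mono_mask].to_numpy()
    n_mono = max(len(mono_idx), 1)
    for cond in CONDITIONS:
        n_with, n_without = cfg.monosomy_condition_counts.get(cond, (0, 0))
        # exact with/without counts inside the monosomy group
        if len(mono_idx):
            perm = rng.permutation(mono_idx)
            df.loc[perm[:n_with], cond] = PHENOTYPE_PRESENT
            df.loc[perm[n_with:n_with + n_without], cond] = PHENOTYPE_ABSENT
        # other groups: draw by the matching prevalence and known-fraction
        known_frac = (n_with + n_without) / n_mono
        prevalence = n_with / (n_with + n_without) if n_with + n_without else 0.0
        other_idx = df.index[~mono_mask].to_numpy()
        if len(other_idx):
            known = rng.random(len(other_idx)) < known_frac
            present = rng.random(len(other_idx)) < prevalence
            status = np.where(known,
                              np.where(present, PHENOTYPE_PRESENT, PHENOTYPE_ABSENT),
                              PHENOTYPE_UNKNOWN)
            df.loc[other_idx, cond] = status
    return df[list(SAMPLE_COLUMNS)]


def _gene_panel(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-variant panel: gene, chrom, pos, af, consequence, planted flag."""
    planted_by_gene = {pe.gene: pe for pe in cfg.planted_effects}
    rows = []
    planted_assigned = set()
    planted_names = list(planted_by_gene)
    for g in range(cfg.n_x_genes):
        in_par = g < cfg.n_par_genes
        if in_par:
            name = f"PARG{g + 1:03d}"
            base = _PAR1_BASE + g * _PAR1_SPACING
        else:
            name = f"XG{g + 1:04d}"
            base = _X_BASE + (g - cfg.n_par_genes) * _X_SPACING
        # planted genes take over panel slots (after the PAR block) by name
        if not in_par and len(planted_assigned) < len(planted_names):
            name = planted_names[len(planted_assigned)]
            planted_assigned.add(name)
        planted = planted_by_gene.get(name)
        if planted is not None:
            # single qualifying variant; population AF = baseline carrier prob
            rows.append({"gene": name, "chrom": "X", "pos": base,
                         "af": planted.baseline, "planted": True})
        else:
            for i in range(cfg.variants_per_gene):
                rows.append({"gene": name, "chrom": "X", "pos": base + i * _VARIANT_SPACING,
                             "af": rng.uniform(cfg.af_low, cfg.af_high), "planted": False})
    for g in range(cfg.n_autosomal_genes):
        name = f"AG{g + 1:03d}"
        chrom = str(g % 22 + 1)
        base = 1_000_000 + (g // 22) * 120_000
        for i in range(cfg.variants_per_gene):
            rows.append({"gene": name, "chrom": chrom, "pos": base + i * _VARIANT_SPACING,
                         "af": rng.uniform(cfg.af_low, cfg.af_high), "planted": False})
    panel = pd.DataFrame(rows)
    panel["consequence"] = rng.choice(_CSQ_VALUES, size=len(panel), p=_CSQ_PROBS)
    return panel


def simulate_cohort(cfg: SimulationConfig | None = None) -> CohortTable:
    """Generate a full synthetic cohort table, deterministic given the seed."""
    cfg = cfg or SimulationConfig()
    streams = np.random.SeedSequence(cfg.seed).spawn(4)
    rng_meta = np.random.default_rng(streams[0])
    rng_panel = np.random.default_rng(streams[1])
    rng_geno = np.random.default_rng(streams[2])
    rng_reads = np.random.default_rng(streams[3])

    samples = _sample_table(cfg, rng_meta)
    panel = _gene_panel(cfg, rng_panel)
    n_s, n_v = len(samples), len(panel)
    intensity = samples["group"].map(cfg.x_intensity).to_numpy(dtype=float)
    af = panel["af"].to_numpy()
    is_x = (panel["chrom"] == "X").to_numpy()
    planted_mask = panel["planted"].to_numpy()

    # carrier probability matrix (samples x variants)
    prob = np.empty((n_s, n_v))
    # X variants: dosage-scaled carrier probability
    prob[:, is_x] = 1.0 - (1.0 - af[np.newaxis, is_x]) ** intensity[:, np.newaxis]
    # autosomal variants: diploid carrier probability 1-(1-af)^2
    if (~is_x).any():
        prob[:, ~is_x] = 1.0 - (1.0 - af[np.newaxis, ~is_x]) ** 2

    # planted effects: gene-level carrier probability baseline (+ delta when
    # the sample has the condition); unknown status counts as baseline
    planted_by_gene = {pe.gene: pe for pe in cfg.planted_effects}
    for j in np.flatnonzero(planted_mask):
        pe = planted_by_gene[panel.loc[j, "gene"]]
        present = (samples[pe.condition] == PHENOTYPE_PRESENT).to_numpy()
        prob[:, j] = np.where(present, pe.baseline + pe.delta, pe.baseline)

    carrier = rng_geno.random((n_s, n_v)) < prob
    si, vi = np.nonzero(carrier)
    n_rec = si.size

    # VAF model: hemizygous X near 1; diploid het/hom by conditional
    # Hardy-Weinberg; a somatic_fraction of records redrawn in (0, 0.3)
    vaf = np.clip(rng_reads.normal(0.97, 0.02, n_rec), 0.0, 1.0)
    rec_is_x = is_x[vi]
    diploidish = (~rec_is_x) | (intensity[si] >= 2.0)
    if diploidish.any():
        af_rec = af[vi[diploidish]]
        p_hom = af_rec / (2.0 - af_rec)  # P(hom-alt | carrier) under HWE
        hom = rng_reads.random(diploidish.sum()) < p_hom
        het_vaf = np.clip(rng_reads.normal(0.5, 0.05, diploidish.sum()), 0.05, 0.95)
        hom_vaf = np.clip(rng_reads.normal(0.97, 0.02, diploidish.sum()), 0.0, 1.0)
        vaf[diploidish] = np.where(hom, hom_vaf, het_vaf)
    # somatic mosaic calls are separate low-fraction mutations, not degraded
    # germline records: extra records at offset positions, VAF in the
    # somatic window, no population frequency (they are not common variants)
    n_som = int(round(n_rec * cfg.somatic_fraction / max(1.0 - cfg.somatic_fraction, 1e-9)))
    som_si = rng_reads.integers(0, n_s, n_som)
    som_vi = rng_reads.integers(0, n_v, n_som)
    som_vaf = rng_reads.uniform(0.02, 0.30, n_som)

    all_si = np.concatenate([si, som_si])
    all_vi = np.concatenate([vi, som_vi])
    all_vaf = np.concatenate([vaf, som_vaf])
    pos = panel["pos"].to_numpy()[all_vi].copy()
    pos[n_rec:] += 37  # offset somatic sites away from the germline grid
    pop_af = np.round(af[all_vi], 6)
    pop_af[n_rec:] = np.nan
    n_all = n_rec + n_som

    r = cfg.depth_dispersion
    depth = rng_reads.negative_binomial(r, r / (r + cfg.depth_mean), n_all)
    quality = rng_reads.gamma(8.0, 6.0, n_all)

    variants = pd.DataFrame({
        "sample_id": samples["sample_id"].to_numpy()[all_si],
        "chrom": panel["chrom"].to_numpy()[all_vi],
        "pos": pos,
        "ref": "A",
        "alt": "G",
        "gene": panel["gene"].to_numpy()[all_vi],
        "consequence": panel["consequence"].to_numpy()[all_vi],
        "depth": depth.astype(int),
        "vaf": np.round(all_vaf, 6),
        "call_quality": np.round(quality, 3),
        "pop_af": pop_af,
    })[list(VARIANT_COLUMNS)]
    # a sample drawn twice for the same somatic site collapses to one record
    variants = variants.drop_duplicates(
        subset=["sample_id", "chrom", "pos", "ref", "alt"], keep="first")
    variants = variants.sort_values(
        ["sample_id", "chrom", "pos", "ref", "alt"], kind="stable").reset_index(drop=True)
    return CohortTable(variants=variants, samples=samples)


def simulate_baf_profile(model: CopyMixtureModel, n_markers: int = 500,
                         het_fraction: float = 0.5, noise_sd: float = 0.03,
                         lrr_noise_sd: float = 0.15, seed: int = 0,
                         region: tuple[str, int, int] = ("X", 10_001, 156_030_895),
                         ) -> SNPArrayProfile:
    """Forward-simulate a marker profile under a copy-number mixture.

    Homozygous markers sit near BAF 0/1; informative markers sit at the
    mixture BAF of the given model and at its mirror (alleles relabeled),
    all perturbed by truncated Gaussian noise and clipped to [0, 1].  LRR
    is the mixture expectation plus noise.
    """
    rng = np.random.default_rng(seed)
    chrom, start, end = region
    pos = np.sort(rng.choice(np.arange(start, end), size=n_markers, replace=False))
    het = rng.random(n_markers) < het_fraction
    baf = np.empty(n_markers)
    n_hom = int((~het).sum())
    hom_b = rng.random(n_hom) < 0.5  # BB vs AA homozygotes
    baf[~het] = np.where(hom_b, 1.0, 0.0)
    center = expected_baf(model)
    mirror = rng.random(int(het.sum())) < 0.5
    baf[het] = np.where(mirror, 1.0 - center, center)
    baf = np.clip(baf + rng.normal(0.0, noise_sd, n_markers), 0.0, 1.0)
    lrr = expected_lrr(model) + rng.normal(0.0, lrr_noise_sd, n_markers)
    markers = pd.DataFrame({"chrom": chrom, "pos": pos, "baf": baf, "lrr": lrr})
    return SNPArrayProfile(markers=markers, region=region)
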
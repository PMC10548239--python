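"""Mosaic cell-line fraction estimation from SNP-array BAF/LRR.

Turner-syndrome karyotypes are frequently mosaic: a 45,X line coexists
with a second line carrying extra X material (a ring X, or an
isochromosome Xq with three copies of the q arm).  At an informative
marker the B-allele frequency (BAF) of the pooled cell population is the
copy-weighted mixture

    BAF = ((1-f)·a1 + f·a2) / ((1-f)·c1 + f·c2)

where c1, c2 are the locus copy numbers in the two lines, a1, a2 the
B-allele copies, and f the fraction of cells of the second line.  The log
R ratio (LRR) encodes average copy number, LRR = log2(((1-f)c1 + f c2)/2).

Estimation inverts these relations: the BAF route locates the off-center
heterozygous-like bands and inverts the mixture formula; the LRR route
inverts the median signal intensity.  For a ring-X mosaic the second line
has c2 = 2 on the retained segment; for isochromosome Xq, c2 = 3 on the q
arm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

#: (c1, c2) copy numbers for the 45,X line vs the variant line.
MODEL_PRESETS: dict[str, tuple[int, int]] = {
    "ring": (1, 2),     # 45,X / 46,X,r(X) on the retained ring segment
    "isoXq": (1, 3),    # 45,X / 46,X,i(Xq) on the q arm
}

#: Markers with BAF outside this open interval are treated as homozygous.
HOM_LOW = 0.05
HOM_HIGH = 0.95

#: Minimum markers in the region for any estimate.
MIN_MARKERS = 30
#: Minimum non-homozygous markers to call a heterozygous band.
MIN_BAND_MARKERS = 10


@dataclass(frozen=True)
class CopyMixtureModel:
    """Two-population copy-number mixture at one locus class."""

    c1: int
    a1: int
    c2: int
    a2: int
    f: float

    def __post_init__(self) -> None:
        if not (0 <= self.a1 <= self.c1):
            raise ValueError(f"need 0 <= a1 <= c1, got a1={self.a1}, c1={self.c1}")
        if not (0 <= self.a2 <= self.c2):
            raise ValueError(f"need 0 <= a2 <= c2, got a2={self.a2}, c2={self.c2}")
        if self.c1 == self.c2 and self.a1 == self.a2:
            raise ValueError("non-informative model: both lines identical at locus")
        if not (0.0 <= self.f <= 1.0):
            raise ValueError(f"f out of [0,1]: {self.f}")


def expected_baf(model: CopyMixtureModel) -> float:
    """Mixture BAF: ((1-f)a1 + f a2) / ((1-f)c1 + f c2)."""
    num = (1.0 - model.f) * model.a1 + model.f * model.a2
    den = (1.0 - model.f) * model.c1 + model.f * model.c2
    return num / den


def expected_lrr(model: CopyMixtureModel) -> float:
    """Mixture LRR: log2 of average copy number over two."""
    den = (1.0 - model.f) * model.c1 + model.f * model.c2
    return math.log2(den / 2.0)


@dataclass
class SNPArrayProfile:
    """Per-marker BAF/LRR observations over one region."""

    markers: pd.DataFrame  # columns chrom, pos, baf, lrr
    region: tuple[str, int, int] | None = None  # (chrom, start, end), 1-based closed

    def __post_init__(self) -> None:
        need = {"chrom", "pos", "baf", "lrr"}
        missing = need - set(self.markers.columns)
        if missing:
            raise ValueError(f"marker table missing columns: {sorted(missing)}")
        baf = self.markers["baf"]
        if ((baf < 0) | (baf > 1)).any():
            raise ValueError("BAF outside [0,1]")
        if not self.markers["pos"].is_monotonic_increasing:
            self.markers = self.markers.sort_values("pos", kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.markers)


def read_marker_table(path: str | Path,
                      region: tuple[str, int, int] | None = None) -> SNPArrayProfile:
    """Read a GenomeStudio-export-like TSV (chrom, pos, baf, lrr)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    profile = SNPArrayProfile(markers=df, region=region)
    if region is not None:
        chrom, start, end = region
        m = profile.markers
        profile = SNPArrayProfile(
            markers=m[(m["chrom"] == chrom) & (m["pos"] >= start) & (m["pos"] <= end)]
            .reset_index(drop=True),
            region=region)
    return profile


@dataclass
class MosaicEstimate:
    """Inferred fraction of the variant (second) cell line."""

    f_hat: float
    method: str  # "baf" | "lrr" | "combined"
    n_markers: int
    band_positions: list[float] = field(default_factory=list)
    residual: float = 0.0
    no_band: bool = False


def _invert_band_distance(b: float, c1: int, c2: int) -> float:
    """Solve BAF = b for f under the informative model (a1=0, a2=1).

    b = f / ((1-f)c1 + f c2)  =>  f = b c1 / (1 - b (c2 - c1)),
    clamped to [0, 1]; for (c1=1, c2=2) this is the familiar b/(1-b).
    """
    den = 1.0 - b * (c2 - c1)
    if den <= 0:
        return 1.0
    return float(np.clip(b * c1 / den, 0.0, 1.0))


def estimate_fraction_from_baf(profile: SNPArrayProfile, c1: int = 1, c2: int = 2,
                               hom_low: float = HOM_LOW, hom_high: float = HOM_HIGH,
                               min_markers: int = MIN_MARKERS,
                               min_band_markers: int = MIN_BAND_MARKERS) -> MosaicEstimate:
    """Estimate the variant-line fraction from the heterozygous BAF bands.

    Markers with BAF below ``hom_low`` or above ``hom_high`` are excluded
    as homozygous.  The remaining markers form (up to) two mirror-image
    bands; b is the median distance of the band centers from the nearer
    BAF extreme (0 or 1), and the mixture formula is inverted for f.  With
    no detectable band the estimate is f = 0 flagged ``no_band``; the
    residual is the median absolute deviation of band members from their
    fitted center.
    """
    if len(profile) < min_markers:
        raise ValueError(f"need >= {min_markers} markers, got {len(profile)}")
    baf = profile.markers["baf"].to_numpy(dtype=float)
    mid = baf[(baf >= hom_low) & (baf <= hom_high)]
    if mid.size < min_band_markers:
        return MosaicEstimate(f_hat=0.0, method="baf", n_markers=len(profile),
                              band_positions=[], residual=0.0, no_band=True)
    lower = mid[mid < 0.5]
    upper = mid[mid >= 0.5]
    centers: list[float] = []
    distances: list[float] = []
    residuals: list[float] = []
    for side, vals in (("lower", lower), ("upper", upper)):
        if vals.size == 0:
            continue
        center = float(np.median(vals))
        centers.append(center)
        distances.append(center if side == "lower" else 1.0 - center)
        residuals.append(float(stats.median_abs_deviation(vals)))
    b = float(np.median(distances))
    f_hat = _invert_band_distance(b, c1, c2)
    return MosaicEstimate(f_hat=f_hat, method="baf", n_markers=len(profile),
                          band_positions=centers,
                          residual=float(np.median(residuals)), no_band=False)


def estimate_fraction_from_lrr(profile: SNPArrayProfile, c1: int = 1, c2: int = 2,
                               min_markers: int = MIN_MARKERS) -> MosaicEstimate:
    """Estimate the variant-line fraction from the median log R ratio.

    Median LRR m implies average copy number 2^(m+1); solving
    (1-f)c1 + f c2 = 2^(m+1) gives f, clamped to [0, 1].
    """
    if c1 == c2:
        raise ValueError("LRR estimation requires c1 != c2")
    if len(profile) < min_markers:
        raise ValueError(f"need >= {min_markers} markers, got {len(profile)}")
    med = float(np.median(profile.markers["lrr"].to_numpy(dtype=float)))
    f_hat = float(np.clip((2.0 ** (med + 1.0) - c1) / (c2 - c1), 0.0, 1.0))
    return MosaicEstimate(f_hat=f_hat, method="lrr", n_markers=len(profile))


def estimate_fraction(profile: SNPArrayProfile, preset: str = "ring",
                      method: str = "combined", **kwargs) -> MosaicEstimate:
    """Preset-based estimation: BAF preferred, LRR fallback when no band."""
    if preset not in MODEL_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(MODEL_PRESETS)}")
    c1, c2 = MODEL_PRESETS[preset]
    if method == "baf":
        return estimate_fraction_from_baf(profile, c1, c2, **kwargs)
    if method == "lrr":
        return estimate_fraction_from_lrr(profile, c1, c2)
    if method == "combined":
        est = estimate_fraction_from_baf(profile, c1, c2, **kwargs)
        if est.no_band:
            fallback = estimate_fraction_from_lrr(profile, c1, c2)
            return MosaicEstimate(f_hat=fallback.f_hat, method="combined",
                                  n_markers=fallback.n_markers, no_band=True)
        return MosaicEstimate(f_hat=est.f_hat, method="combined",
                              n_markers=est.n_markers,
                              band_positions=est.band_positions,
                              residual=est.residual)
    raise ValueError(f"unknown method {method!r}")


def paired_signed_rank(original, new) -> float:
    """Two-sided Wilcoxon matched-pairs signed-rank p-value.

    Used to compare historical karyotype-derived mosaic percentages with
    array-derived re-estimates in the same individuals.  Zero differences
    are dropped (the classic convention); the null distribution is exact
    for n <= 25 untied pairs and a tie-corrected normal approximation
    above.  All-zero differences give the degenerate p = 1.
    """
    x = np.asarray(original, dtype=float)
    y = np.asarray(new, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if x.size < 5:
        raise ValueError("need at least 5 pairs")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                         correction=False, method=method)
    return float(res.pvalue)
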
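"""Fetal-fraction estimation and fetal sex calling.

The primary estimator uses targeted SNP amplicon counts: at an
informative SNP (mother homozygous, fetus heterozygous) the paternal
allele appears in plasma at half the fetal fraction, so ff = 2 x the
paternal-allele read fraction, aggregated by the median over informative
sites.  A second, coarser estimator anchors the chromosome-Y fragment
share between a female background and a fully male cfDNA pool.  Sex is
called from the two estimates jointly: sufficient fetal signal with an
essentially absent Y share means a female fetus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FetalFractionEstimate",
    "coverage_qc",
    "classify_informative",
    "estimate_ff",
    "y_fraction",
    "ff_from_y",
    "call_sex",
]


@dataclass
class FetalFractionEstimate:
    sample_id: str
    method: str          # amplifet | chrY
    ff: float
    n_informative: int
    qc_pass: bool
    notes: str | None = None


def coverage_qc(counts: pd.DataFrame, min_mean_depth: float = 50.0) -> bool:
    """Panel-level depth QC: fail when mean SNP coverage is below 50x."""
    if len(counts) == 0:
        raise ValueError("empty SNP panel")
    depth = counts["ref_count"] + counts["alt_count"]
    return bool(depth.mean() >= min_mean_depth)


def classify_informative(counts: pd.DataFrame,
                         minor_fraction_floor: float = 0.005,
                         maternal_hom_ceiling: float = 0.20,
                         use_truth: bool | None = None) -> pd.DataFrame:
    """Select informative SNPs (mother homozygous, fetus heterozygous).

    Without parental genotypes the classification is by minor-allele read
    fraction m: informative iff floor <= m <= ceiling (above the ceiling
    the mother is heterozygous; below the floor there is no paternal
    signal).  When the table carries truth genotypes (simulation), the
    genotype rule is applied directly unless ``use_truth=False``.
    """
    if use_truth is None:
        use_truth = "informative" in counts.columns
    if use_truth:
        return counts[counts["informative"].astype(bool)].reset_index(drop=True)
    depth = (counts["ref_count"] + counts["alt_count"]).to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        minor = np.minimum(counts["ref_count"], counts["alt_count"]).to_numpy(float)
        m = np.where(depth > 0, minor / depth, np.nan)
    keep = (m >= minor_fraction_floor) & (m <= maternal_hom_ceiling)
    return counts[np.nan_to_num(keep, nan=False)].reset_index(drop=True)


def estimate_ff(informative: pd.DataFrame, min_informative: int = 5,
                sample_id: str = "sample") -> FetalFractionEstimate:
    """Median over informative SNPs of twice the minor-allele fraction."""
    n = len(informative)
    if n < min_informative:
        return FetalFractionEstimate(sample_id, "amplifet", float("nan"), n,
                                     False, f"only {n} informative SNPs "
                                     f"(< {min_informative})")
    depth = (informative["ref_count"] + informative["alt_count"]).to_numpy(float)
    minor = np.minimum(informative["ref_count"],
                       informative["alt_count"]).to_numpy(float)
    per_snp = 2.0 * minor / depth
    return FetalFractionEstimate(sample_id, "amplifet",
                                 float(np.median(per_snp)), n, True)


def y_fraction(fragments: pd.DataFrame) -> float:
    """Share of kept fragments mapped to chromosome Y."""
    if len(fragments) == 0:
        raise ValueError("no fragments")
    return float((fragments["chrom"].astype(str) == "chrY").mean())


def ff_from_y(y_frac: float, calibration: dict[str, float],
              sample_id: str = "sample") -> FetalFractionEstimate:
    """Anchored linear Y-share estimator.

    ``calibration`` holds ``y_frac_female_bg`` (Y share with no fetal Y,
    i.e. mismapping background) and ``y_frac_full_male`` (Y share if 100%
    of cfDNA were male); the estimate interpolates between them, clamped
    to [0, 1].
    """
    bg = calibration["y_frac_female_bg"]
    full = calibration["y_frac_full_male"]
    if not full > bg:
        raise ValueError("invalid calibration: y_frac_full_male must exceed "
                         "y_frac_female_bg")
    ff = float(np.clip((y_frac - bg) / (full - bg), 0.0, 1.0))
    return FetalFractionEstimate(sample_id, "chrY", ff, 0, True)


def call_sex(ff_amplifet: float, ff_y: float, male_floor: float = 0.02) -> str:
    """Female iff the SNP fetal fraction exceeds 4% while the Y-derived
    estimate stays at or below 1%; male when the Y estimate clears the
    floor; otherwise indeterminate."""
    if not np.isfinite(ff_amplifet) or ff_amplifet <= 0.04:
        return "indeterminate"
    if ff_y <= 0.01:
        return "female"
    if ff_y > male_floor:
        return "male"
    return "indeterminate"
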
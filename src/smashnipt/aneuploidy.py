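"""Copy-number calling from binned fragment counts.

Filtered fragment tags are binned genome-wide, bin counts pass through a
variation-reduction cascade (peak -> GC -> reduced-chi-squared, in that
fixed order), each sample's target-chromosome fraction is standardised
against a control set, and a trisomy is called at Z > 3.  A
cross-validation scheme (cases plus an equal number of random controls as
the test set, remaining controls as training, averaged over 200 runs)
yields sensitivity / specificity / AUC with SDs, and a threshold sweep
reports those metrics as a function of the minimum filtered-fragment
count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simkit import Reference

logger = logging.getLogger("smashnipt")

__all__ = [
    "BinMatrix",
    "ZScoreResult",
    "CvResult",
    "make_bins",
    "bin_counts",
    "stack_matrices",
    "peak_correction",
    "gc_correct",
    "chi2_variation_reduction",
    "match_qc",
    "chromosomal_fraction",
    "z_score",
    "cross_validate",
    "min_fragment_sweep",
]

#: chromosomes excluded from the normalising denominator: the clinically
#: tested trisomy chromosomes (so a trisomy cannot deflate its own
#: normaliser) and the sex chromosomes.
DENOMINATOR_EXCLUDED = {"chr13", "chr18", "chr21", "chrX", "chrY"}

CORRECTION_ORDER = ["raw", "peak_corrected", "gc_corrected", "chi2_corrected"]


@dataclass
class BinMatrix:
    """samples x bins fragment counts with per-bin GC and correction state."""
    bins: pd.DataFrame                 # chrom, start, end, gc
    counts: np.ndarray                 # (n_samples, n_bins) float
    samples: list[str]
    state: str = "raw"
    mask: np.ndarray | None = None     # valid-bin mask, shared by all samples

    def __post_init__(self):
        if self.counts.ndim != 2 or self.counts.shape[1] != len(self.bins):
            raise ValueError("counts shape does not match bins")
        if (self.counts < 0).any():
            raise ValueError("negative bin counts")
        if self.mask is None:
            self.mask = np.ones(len(self.bins), dtype=bool)

    def subset(self, sample_idx: Sequence[int]) -> "BinMatrix":
        return replace(self, counts=self.counts[list(sample_idx)],
                       samples=[self.samples[i] for i in sample_idx])


def _require_state(matrix: BinMatrix, expected: str) -> None:
    if matrix.state != expected:
        raise ValueError(f"correction order violated: expected state "
                         f"{expected!r}, got {matrix.state!r}")


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

def make_bins(reference: Reference, bin_size: int) -> pd.DataFrame:
    """Tile every chromosome into ``bin_size`` bins and annotate GC."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    for chrom in reference.chrom_names:
        L = reference.chrom_lengths[chrom]
        starts = np.arange(0, L, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, L)
        gc = reference.gc_fractions(chrom, starts, ends)
        for s, e, g in zip(starts, ends, gc):
            rows.append((chrom, int(s), int(e), float(g)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gc"])


def bin_counts(fragments: pd.DataFrame, bin_size: int, reference: Reference,
               sample_id: str = "sample",
               bins: pd.DataFrame | None = None) -> BinMatrix:
    """Count fragments per genomic bin (a fragment belongs to the bin
    containing its start position)."""
    if bins is None:
        bins = make_bins(reference, bin_size)
    counts = np.zeros(len(bins), dtype=float)
    offsets = {}
    pos = 0
    for chrom in reference.chrom_names:
        n_bins = int(np.ceil(reference.chrom_lengths[chrom] / bin_size))
        offsets[chrom] = pos
        pos += n_bins
    for chrom, grp in fragments.groupby("chrom", observed=True):
        chrom = str(chrom)
        if chrom not in offsets:
            raise ValueError(f"unknown chromosome {chrom!r}")
        starts = grp["start"].to_numpy(np.int64)
        if (starts >= reference.chrom_lengths[chrom]).any() or (starts < 0).any():
            raise ValueError(f"fragment beyond chromosome end on {chrom}")
        idx = offsets[chrom] + starts // bin_size
        np.add.at(counts, idx, 1.0)
    return BinMatrix(bins, counts[None, :], [sample_id])


def stack_matrices(matrices: Sequence[BinMatrix]) -> BinMatrix:
    """Stack per-sample matrices sharing the same bin definition."""
    first = matrices[0]
    for m in matrices[1:]:
        if len(m.bins) != len(first.bins) or m.state != first.state:
            raise ValueError("matrices do not share bins/state")
    return BinMatrix(first.bins, np.vstack([m.counts for m in matrices]),
                     [s for m in matrices for s in m.samples], first.state)


# ---------------------------------------------------------------------------
# Variation reduction
# ---------------------------------------------------------------------------

def peak_correction(matrix: BinMatrix) -> BinMatrix:
    """Per sample, replace bins exceeding mean + 3 SD of the sample's
    nonzero bins by the sample mean (single pass)."""
    _require_state(matrix, "raw")
    counts = matrix.counts.copy()
    for s in range(counts.shape[0]):
        row = counts[s]
        nz = row[matrix.mask & (row > 0)]
        if len(nz) == 0:
            warnings.warn(f"sample {matrix.samples[s]} has no nonzero bins; "
                          "peak correction skipped")
            continue
        mean, sd = nz.mean(), nz.std(ddof=1) if len(nz) > 1 else 0.0
        row[matrix.mask & (row > mean + 3 * sd)] = mean
    return replace(matrix, counts=counts, state="peak_corrected")


def gc_correct(matrix: BinMatrix) -> BinMatrix:
    """Stratify bins by GC rounded to 0.01 and rescale each stratum to the
    sample's global mean bin count; strata with < 10 bins are left as-is."""
    _require_state(matrix, "peak_corrected")
    counts = matrix.counts.copy()
    strata = np.round(matrix.bins["gc"].to_numpy(float), 2)
    valid = matrix.mask
    for s in range(counts.shape[0]):
        row = counts[s]
        global_mean = row[valid].mean()
        for g in np.unique(strata[valid]):
            in_stratum = valid & (strata == g)
            if in_stratum.sum() < 10:
                continue
            stratum_mean = row[in_stratum].mean()
            if stratum_mean > 0:
                row[in_stratum] *= global_mean / stratum_mean
    return replace(matrix, counts=counts, state="gc_corrected")


def chi2_variation_reduction(control_matrix: BinMatrix, all_matrix: BinMatrix,
                             reduced_chi2_cutoff: float = 3.5) -> BinMatrix:
    """Damp bins whose count varies across controls more than Poisson
    expectation: controls are scaled to a common total, the per-bin
    reduced chi-squared against the control mean is computed, and bins
    above the cutoff have all samples' counts divided by it.  Bins with a
    zero control mean are masked from all downstream fractions."""
    _require_state(all_matrix, "gc_corrected")
    ctrl = control_matrix.counts
    if ctrl.shape[0] < 2:
        raise ValueError("need >= 2 control samples")
    totals = ctrl[:, control_matrix.mask].sum(axis=1)
    scaled = ctrl * (totals.mean() / totals)[:, None]
    chat = scaled.mean(axis=0)
    mask = all_matrix.mask & (chat > 0)
    red = np.ones(len(chat))
    nz = chat > 0
    chi2 = np.zeros(len(chat))
    chi2[nz] = ((scaled[:, nz] - chat[nz]) ** 2 / chat[nz]).sum(axis=0)
    red[nz] = chi2[nz] / (ctrl.shape[0] - 1)
    counts = all_matrix.counts.copy()
    noisy = mask & (red > reduced_chi2_cutoff)
    counts[:, noisy] /= red[noisy]
    return replace(all_matrix, counts=counts, state="chi2_corrected", mask=mask)


@dataclass
class MatchQcResult:
    score: float
    passed: bool
    threshold: float | None = None
    note: str | None = None


def match_qc(sample_row: np.ndarray, control_matrix: BinMatrix) -> MatchQcResult:
    """Genome-wide profile similarity check: the sample's fraction profile
    must sit within mean + 3 SD of the controls' leave-one-out scores."""
    valid = control_matrix.mask
    ctrl = control_matrix.counts[:, valid]
    if ctrl.shape[0] < 3:
        warnings.warn("fewer than 3 controls; match QC skipped")
        return MatchQcResult(float("nan"), True, note="skipped: <3 controls")
    cf = ctrl / ctrl.sum(axis=1, keepdims=True)
    sf = sample_row[valid] / sample_row[valid].sum()
    score = float(((sf - cf.mean(axis=0)) ** 2).sum())
    loo = []
    for i in range(cf.shape[0]):
        rest = np.delete(cf, i, axis=0).mean(axis=0)
        loo.append(((cf[i] - rest) ** 2).sum())
    loo = np.asarray(loo)
    threshold = float(loo.mean() + 3 * loo.std(ddof=1))
    return MatchQcResult(score, score <= threshold, threshold)


# ---------------------------------------------------------------------------
# Chromosomal fractions and Z-scores
# ---------------------------------------------------------------------------

def chromosomal_fraction(matrix: BinMatrix, target_chrom: str) -> np.ndarray:
    """Per-sample fraction: counts on the target chromosome over counts on
    the normalising autosomes (chromosomes 13/18/21 and the sex
    chromosomes excluded from the denominator)."""
    if matrix.state != "chi2_corrected":
        logger.debug("chromosomal_fraction on state %s", matrix.state)
    chroms = matrix.bins["chrom"].to_numpy()
    on_target = (chroms == target_chrom) & matrix.mask
    denom_bins = (~np.isin(chroms, list(DENOMINATOR_EXCLUDED))) & matrix.mask
    num = matrix.counts[:, on_target].sum(axis=1)
    den = matrix.counts[:, denom_bins].sum(axis=1)
    if (den <= 0).any():
        raise ValueError("zero denominator counts for at least one sample")
    return num / den


@dataclass
class ZScoreResult:
    sample_id: str
    target_chrom: str
    chrom_fraction: float
    control_mean: float
    control_sd: float
    z: float
    call: str  # aneuploid | euploid


def z_score(sample_fraction: float, control_fractions: np.ndarray,
            threshold: float = 3.0, sample_id: str = "sample",
            target_chrom: str = "chr21") -> ZScoreResult:
    """Standardise a sample's chromosomal fraction against the control set
    and call aneuploid when Z exceeds the threshold (strictly)."""
    control_fractions = np.asarray(control_fractions, dtype=float)
    if len(control_fractions) < 2:
        raise ValueError("need >= 2 control fractions")
    mean = control_fractions.mean()
    sd = control_fractions.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate control set: zero standard deviation")
    z = (sample_fraction - mean) / sd
    return ZScoreResult(sample_id, target_chrom, float(sample_fraction),
                        float(mean), float(sd), float(z),
                        "aneuploid" if z > threshold else "euploid")


# ---------------------------------------------------------------------------
# Cross-validation and the threshold sweep
# ---------------------------------------------------------------------------

def _auc(case_scores: np.ndarray, control_scores: np.ndarray) -> float:
    """Rank-statistic AUC; ties count one half."""
    from scipy.stats import rankdata
    scores = np.concatenate([case_scores, control_scores])
    ranks = rankdata(scores)
    n1, n0 = len(case_scores), len(control_scores)
    return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class CvResult:
    sensitivity: float
    sensitivity_sd: float
    specificity: float
    specificity_sd: float
    auc: float
    auc_sd: float
    n_runs: int
    n_test: int
    n_train: int
    sample_ids: list[str]
    z_min: np.ndarray
    z_max: np.ndarray


def cross_validate(fractions: np.ndarray, labels: np.ndarray,
                   n_runs: int = 200, seed: int = 0, threshold: float = 3.0,
                   sample_ids: Sequence[str] | None = None) -> CvResult:
    """Repeated case/control split evaluation.

    Each run's test set is all cases plus an equal number of randomly
    chosen controls; the remaining controls form the training set that
    defines the Z-score mean/SD.  Sensitivity, specificity and AUC are
    averaged over runs; per-sample min/max Z across runs are retained.
    """
    fractions = np.asarray(fractions, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    case_idx = np.flatnonzero(labels)
    ctrl_idx = np.flatnonzero(~labels)
    n_cases = len(case_idx)
    if n_cases < 1:
        raise ValueError("need at least one case")
    if len(ctrl_idx) <= n_cases:
        raise ValueError("need more controls than cases")
    rng = np.random.default_rng(seed)
    sens, spec, aucs = [], [], []
    z_min = np.full(len(fractions), np.inf)
    z_max = np.full(len(fractions), -np.inf)
    for _ in range(n_runs):
        test_ctrl = rng.choice(ctrl_idx, size=n_cases, replace=False)
        train = np.setdiff1d(ctrl_idx, test_ctrl)
        mu = fractions[train].mean()
        sd = fractions[train].std(ddof=1)
        if sd == 0:
            raise ValueError("degenerate training controls")
        test = np.concatenate([case_idx, test_ctrl])
        z = (fractions[test] - mu) / sd
        z_min[test] = np.minimum(z_min[test], z)
        z_max[test] = np.maximum(z_max[test], z)
        z_cases, z_ctrl = z[:n_cases], z[n_cases:]
        sens.append(np.mean(z_cases > threshold))
        spec.append(np.mean(z_ctrl <= threshold))
        aucs.append(_auc(z_cases, z_ctrl))
    ids = list(sample_ids) if sample_ids is not None \
        else [f"s{i}" for i in range(len(fractions))]
    return CvResult(
        float(np.mean(sens)), float(np.std(sens, ddof=0)),
        float(np.mean(spec)), float(np.std(spec, ddof=0)),
        float(np.mean(aucs)), float(np.std(aucs, ddof=0)),
        n_runs, 2 * n_cases, len(ctrl_idx) - n_cases, ids, z_min, z_max)


DEFAULT_SWEEP_THRESHOLDS = (1_000_000, 1_500_000, 2_000_000, 2_500_000, 3_000_000)


def min_fragment_sweep(cohorts: Mapping[str, pd.DataFrame],
                       thresholds: Sequence[int] = DEFAULT_SWEEP_THRESHOLDS,
                       n_runs: int = 200, seed: int = 0,
                       z_threshold: float = 3.0) -> pd.DataFrame:
    """Sensitivity/specificity (with SDs) per chromosome and per minimum
    filtered-fragment threshold.

    ``cohorts`` maps a chromosome name to a DataFrame with columns
    ``fraction``, ``label`` (bool, case) and ``n_filtered``.  A cell with
    no qualifying cases (or insufficient controls) is reported as
    undefined (NaN), not zero.
    """
    rows = []
    for chrom, tab in cohorts.items():
        for i, thr in enumerate(thresholds):
            sub = tab[tab["n_filtered"] >= thr]
            cases = int(sub["label"].sum())
            controls = int((~sub["label"].astype(bool)).sum())
            row = {"chrom": chrom, "threshold": int(thr),
                   "n_cases": cases, "n_controls": controls}
            if cases < 1 or controls <= cases:
                row.update(sensitivity=np.nan, sensitivity_sd=np.nan,
                           specificity=np.nan, specificity_sd=np.nan)
            else:
                cv = cross_validate(sub["fraction"].to_numpy(),
                                    sub["label"].to_numpy(bool),
                                    n_runs=n_runs, seed=seed + i,
                                    threshold=z_threshold)
                row.update(sensitivity=cv.sensitivity,
                           sensitivity_sd=cv.sensitivity_sd,
                           specificity=cv.specificity,
                           specificity_sd=cv.specificity_sd)
            rows.append(row)
    return pd.DataFrame(rows)
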
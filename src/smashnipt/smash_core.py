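"""Deconstruction of chimeric reads into filtered genomic fragment tags.

A chimeric read carries several short genomic tags; the aligner reports
them as one primary plus supplementary split alignments.  This module
turns grouped alignment records into per-tag fragments, applies the
published filters (MAPQ >= 60, repeat overlap, amplicon overlap,
second-pass supplementary / minus-strand), merges read pairs FLASH-style
to measure molecule lengths, and computes fragment and sample-QC
statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
import pysam

from .io_cli import IntervalIndex

logger = logging.getLogger("smashnipt")

__all__ = [
    "FRAGMENT_COLUMNS",
    "MergeParams",
    "MergeResult",
    "SampleQcReport",
    "extract_subreads",
    "filter_fragments",
    "merge_read_pair",
    "fragment_stats",
    "sample_qc",
]

FRAGMENT_COLUMNS = ["read_id", "mate", "chrom", "start", "end", "strand", "mapq"]

#: fixed first-failing order for filter reasons
FILTER_ORDER = ["low_mapq", "repeat", "amplicon", "supplementary_pass2",
                "minus_strand_pass2"]


# ---------------------------------------------------------------------------
# Sub-read extraction
# ---------------------------------------------------------------------------

def extract_subreads(groups: Iterable[list[pysam.AlignedSegment]]) -> pd.DataFrame:
    """One fragment per aligned block of each primary/supplementary record.

    Block boundaries come from the CIGAR reference span; per-record MAPQ
    and strand are retained.  Unmapped reads contribute nothing; secondary
    alignments are ignored; a malformed CIGAR skips the record with a log
    entry.
    """
    rows = []
    for group in groups:
        for rec in group:
            if rec.is_secondary or rec.is_unmapped:
                continue
            try:
                start = rec.reference_start
                end = rec.reference_end
            except ValueError:
                logger.warning("malformed CIGAR for %s; record skipped",
                               rec.query_name)
                continue
            if end is None or start is None or end <= start:
                logger.warning("record without aligned span for %s; skipped",
                               rec.query_name)
                continue
            rows.append((
                rec.query_name,
                2 if rec.is_read2 else 1,
                rec.reference_name,
                start,
                end,
                "-" if rec.is_reverse else "+",
                rec.mapping_quality,
            ))
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_fragments(fragments: pd.DataFrame,
                     repeat_intervals: IntervalIndex,
                     amplicon_intervals: IntervalIndex,
                     min_mapq: int = 60) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove fragments that are imperfectly mapped (MAPQ < ``min_mapq``),
    overlap a repeat or amplicon interval by >= 1 bp, or carry second-pass
    supplementary / minus-strand flags.

    Reasons are assigned first-failing in the fixed order low_mapq ->
    repeat -> amplicon -> pass2 flags.  Returns the kept fragments and the
    per-reason removal counts (plus ``kept`` and ``total``).
    """
    n = len(fragments)
    reason = np.zeros(n, dtype=np.int8)  # 0 = kept, 1.. = FILTER_ORDER index+1
    mapq = fragments["mapq"].to_numpy()
    reason[(mapq < min_mapq) & (reason == 0)] = 1

    chrom_col = fragments["chrom"]
    starts_all = fragments["start"].to_numpy(np.int64)
    ends_all = fragments["end"].to_numpy(np.int64)
    for chrom in pd.unique(chrom_col):
        idx = np.flatnonzero((chrom_col == chrom).to_numpy())
        s, e = starts_all[idx], ends_all[idx]
        try:
            in_rep = repeat_intervals.overlaps_many(str(chrom), s, e)
            in_amp = amplicon_intervals.overlaps_many(str(chrom), s, e)
        except KeyError as exc:
            raise ValueError(f"fragment chromosome not in interval track: "
                             f"{chrom}") from exc
        sel = reason[idx]
        sel[(sel == 0) & in_rep] = 2
        sel[(sel == 0) & in_amp] = 3
        reason[idx] = sel

    if "supplementary_pass2" in fragments.columns:
        flag = fragments["supplementary_pass2"].to_numpy(bool)
        reason[(reason == 0) & flag] = 4
    if "minus_strand_pass2" in fragments.columns:
        flag = fragments["minus_strand_pass2"].to_numpy(bool)
        reason[(reason == 0) & flag] = 5

    stats = {name: int((reason == i + 1).sum())
             for i, name in enumerate(FILTER_ORDER)}
    stats["kept"] = int((reason == 0).sum())
    stats["total"] = n
    kept = fragments.loc[reason == 0].reset_index(drop=True)
    return kept, stats


# ---------------------------------------------------------------------------
# FLASH-style pair merging
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MergeParams:
    min_overlap: int = 20
    max_overlap: int = 250
    allow_outies: bool = True
    max_mismatch_density: float = 0.20

    def __post_init__(self):
        if not 0 < self.min_overlap <= self.max_overlap:
            raise ValueError("need 0 < min_overlap <= max_overlap")
        if not 0.0 <= self.max_mismatch_density <= 1.0:
            raise ValueError("max_mismatch_density must be in [0, 1]")


@dataclass(frozen=True)
class MergeResult:
    merged: bool
    length: int | None = None
    overlap: int | None = None
    mismatch_density: float | None = None
    geometry: str | None = None  # innie | outie


_REVCOMP_TABLE = str.maketrans("ACGTN", "TGCAN")


def _revcomp_str(seq: str) -> str:
    return seq.translate(_REVCOMP_TABLE)[::-1]


def _seq_to_arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def merge_read_pair(r1: str, r2: str, params: MergeParams = MergeParams()
                    ) -> MergeResult:
    """Find the best overlap between a read pair and report the merged
    (molecule) length ``len(r1) + len(r2) - overlap``.

    All candidate overlaps between ``min_overlap`` and ``max_overlap`` are
    scored in innie and (optionally) outie geometry; the candidate with
    the lowest mismatch density wins, ties going to the larger overlap.
    Ambiguous bases (N) count as mismatches.
    """
    a = _seq_to_arr(r1)
    b = _seq_to_arr(_revcomp_str(r2))
    n_mask_a = a == ord("N")
    n_mask_b = b == ord("N")
    best: tuple[float, int, str] | None = None  # (density, overlap, geometry)
    max_o = min(params.max_overlap, len(a), len(b))
    for o in range(max_o, params.min_overlap - 1, -1):
        cands = [("innie", a[len(a) - o:], b[:o], n_mask_a[len(a) - o:], n_mask_b[:o])]
        if params.allow_outies:
            cands.append(("outie", a[:o], b[len(b) - o:], n_mask_a[:o],
                          n_mask_b[len(b) - o:]))
        for geom, x, y, nx, ny in cands:
            mism = int(((x != y) | nx | ny).sum())
            density = mism / o
            if density <= params.max_mismatch_density:
                if best is None or density < best[0] or \
                        (density == best[0] and o > best[1]):
                    best = (density, o, geom)
    if best is None:
        return MergeResult(False)
    density, o, geom = best
    return MergeResult(True, len(a) + len(b) - o, o, density, geom)


# ---------------------------------------------------------------------------
# Fragment statistics and sample QC
# ---------------------------------------------------------------------------

def fragment_stats(fragments: pd.DataFrame, read_len: int,
                   n_pairs: int | None = None) -> dict[str, float]:
    """Mean tag length, information-content ratio (read length over mean
    tag length, one decimal) and unique filtered tags per read pair.

    Identical (chrom, start, end) tags seen by both mates of a pair are
    counted once: on short chimeras both 250 bp reads cover the molecule
    centre, so the raw records double-count central tags.
    """
    if len(fragments) == 0:
        raise ValueError("no fragments")
    mean_len = float((fragments["end"] - fragments["start"]).mean())
    stats = {
        "mean_fragment_len": mean_len,
        "info_content_ratio": round(read_len / mean_len, 1),
    }
    if "read_id" in fragments.columns:
        uniq = fragments.drop_duplicates(subset=["read_id", "chrom", "start", "end"])
        pairs = n_pairs if n_pairs is not None else fragments["read_id"].nunique()
        stats["fragments_per_pair_filtered"] = len(uniq) / pairs
    return stats


@dataclass
class SampleQcReport:
    n_filtered_fragments: int
    fetal_fraction: float | None
    passed: bool
    reasons: list[str] = field(default_factory=list)


def sample_qc(n_filtered: int, fetal_fraction: float | None,
              min_fragments: int = 2_500_000,
              min_ff: float = 0.04) -> SampleQcReport:
    """Sample-level exclusion: fewer than 2,500,000 filtered fragments or
    an estimated fetal fraction under 4% fails the sample.  The published
    rules are strict "less than", so equality passes."""
    reasons = []
    if n_filtered < min_fragments:
        reasons.append("fragments")
    if fetal_fraction is None or np.isnan(fetal_fraction) \
            or fetal_fraction < min_ff:
        reasons.append("fetal_fraction")
    return SampleQcReport(n_filtered, fetal_fraction, not reasons, reasons)
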
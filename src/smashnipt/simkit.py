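"""Synthetic data generation for the chimeric-read NIPT pipeline.

Everything the pipeline consumes can be generated here with known ground
truth: a toy multi-chromosome reference with a GC landscape, repeat and
amplicon tracks and a SNP panel; maternal/fetal cfDNA fragment mixtures
(166 / 143 bp length modes, trisomy dosage at 1.5x on one chromosome);
enzymatic fragmentation with double-sided size selection to 40-50 bp
pieces; random self-ligation into >300 bp chimeric molecules; PE250 read
pairs; a truth SAM of split alignments standing in for the first mapping
pass; and binomially sampled SNP amplicon allele counts at a configurable
fetal fraction.

Every generator is a pure function of (config, rng): the same seed yields
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import pysam

from .io_cli import IntervalIndex, write_bed

__all__ = [
    "SimulationConfig",
    "Reference",
    "ChimericMolecule",
    "Part",
    "make_reference",
    "simulate_cfdna",
    "attach_mapq",
    "fragmentase_and_select",
    "ligate_chimeras",
    "generate_reads",
    "emit_truth_sam",
    "simulate_amplifet",
    "simulate_informative_counts",
    "simulate_library",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G

# GRCh38 chromosome lengths, megabases; the toy genome scales these down.
_HUMAN_MB = {
    "chr1": 248.96, "chr2": 242.19, "chr3": 198.30, "chr4": 190.21,
    "chr5": 181.54, "chr6": 170.81, "chr7": 159.35, "chr8": 145.14,
    "chr9": 138.39, "chr10": 133.80, "chr11": 135.09, "chr12": 133.28,
    "chr13": 114.36, "chr14": 107.04, "chr15": 101.99, "chr16": 90.34,
    "chr17": 83.26, "chr18": 80.37, "chr19": 58.62, "chr20": 64.44,
    "chr21": 46.71, "chr22": 50.82, "chrX": 156.04, "chrY": 57.23,
}


def default_chrom_lengths(scale: float = 1e-3) -> dict[str, int]:
    """24 toy chromosomes with lengths proportional to the human genome."""
    return {c: int(round(mb * 1e6 * scale)) for c, mb in _HUMAN_MB.items()}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Length parameters reflect plasma biology: maternal cfDNA peaks at
    166 bp, fetal at 143 bp; fragmentase products are selected into a
    40-50 bp window with an observed mean of 43.8 bp; self-ligation is run
    until molecules exceed ``chimera_min_len``; sequencing is PE250.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(default_factory=default_chrom_lengths)
    gc_baseline: float = 0.41
    gc_amplitude: float = 0.10
    gc_period: int = 20_000
    fetal_fraction: float = 0.10
    trisomy_chrom: str | None = None
    fetal_sex: str = "male"
    n_cfdna_fragments: int = 100_000
    maternal_len_mean: float = 166.0
    maternal_len_sd: float = 10.0
    fetal_len_mean: float = 143.0
    fetal_len_sd: float = 10.0
    fragmentase_target_mean: float = 43.8
    size_select_window: tuple[int, int] = (40, 50)
    # upper-side selection softness (SPRI upper cuts are not sharp); the
    # slope is calibrated so retained pieces average fragmentase_target_mean
    size_select_taper: float = 0.65
    chimera_min_len: int = 300
    read_len: int = 250
    seq_error_rate: float = 0.0
    amplifet_coverage_mean: float = 5000.0
    n_snps: int = 102
    repeat_fraction: float = 0.5
    repeat_block: int = 150
    amplicon_len: int = 110
    nonunique_rate: float = 0.18
    amplicon_dropout_rate: float = 0.0

    def __post_init__(self):
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must be non-empty")
        if any(length <= 0 for length in self.chrom_lengths.values()):
            raise ValueError("zero-length chromosome in configuration")
        if not 0.0 <= self.fetal_fraction <= 1.0:
            raise ValueError("fetal_fraction must be in [0, 1]")
        lo, hi = self.size_select_window
        if lo >= hi:
            raise ValueError("size_select_window min must be < max")
        if self.read_len <= 0:
            raise ValueError("read_len must be positive")
        if self.trisomy_chrom is not None and self.trisomy_chrom not in self.chrom_lengths:
            raise ValueError(f"trisomy_chrom {self.trisomy_chrom!r} not in reference")
        if self.fetal_sex not in ("male", "female"):
            raise ValueError("fetal_sex must be 'male' or 'female'")


class Part(NamedTuple):
    """One source sub-fragment of a chimeric molecule."""
    chrom: str
    start: int
    end: int
    strand: str     # orientation within the molecule
    origin: str     # maternal | fetal


@dataclass
class ChimericMolecule:
    molecule_id: str
    parts: list[Part]

    @property
    def total_len(self) -> int:
        return sum(p.end - p.start for p in self.parts)


@dataclass
class Reference:
    """Reference bundle: sequences, tracks and the SNP panel."""
    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    seqs: dict[str, np.ndarray]          # uint8 base codes 0..3 = ACGT
    repeats: IntervalIndex
    amplicons: IntervalIndex
    snps: pd.DataFrame                   # snp_id, chrom, pos, ref, alt, af
    _gc_cumsum: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def genome_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def gc_fraction(self, chrom: str, start: int, end: int) -> float:
        return float(self.gc_fractions(chrom, np.array([start]), np.array([end]))[0])

    def gc_fractions(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Vectorised GC content of intervals on one chromosome."""
        if chrom not in self._gc_cumsum:
            is_gc = (self.seqs[chrom] == 1) | (self.seqs[chrom] == 2)
            self._gc_cumsum[chrom] = np.concatenate(
                [[0], np.cumsum(is_gc, dtype=np.int64)])
        cs = self._gc_cumsum[chrom]
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        return (cs[ends] - cs[starts]) / np.maximum(ends - starts, 1)

    def sequence(self, chrom: str, start: int, end: int) -> np.ndarray:
        return self.seqs[chrom][start:end]


def codes_to_str(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------

def make_reference(config: SimulationConfig) -> Reference:
    """Build the toy reference: sequences with a sinusoidal GC landscape,
    repeat blocks covering ``repeat_fraction`` of the genome, a SNP panel
    outside repeats on autosomes, and one amplicon interval per SNP."""
    rng = np.random.default_rng(config.seed)
    chroms = list(config.chrom_lengths)
    seqs: dict[str, np.ndarray] = {}
    repeat_ivs: list[tuple[str, int, int]] = []
    for ci, chrom in enumerate(chroms):
        L = config.chrom_lengths[chrom]
        pos = np.arange(L)
        phase = 2 * np.pi * ci / len(chroms)
        gc = np.clip(config.gc_baseline
                     + config.gc_amplitude * np.sin(2 * np.pi * pos / config.gc_period + phase),
                     0.05, 0.95)
        u = rng.random(L)
        is_gc = u < gc
        seq = np.where(is_gc,
                       rng.integers(1, 3, L).astype(np.uint8),   # C or G
                       np.where(rng.random(L) < 0.5, 0, 3).astype(np.uint8))
        seqs[chrom] = seq.astype(np.uint8)
        if config.repeat_fraction > 0:
            n_blocks = int(np.ceil(L / config.repeat_block))
            mask = rng.random(n_blocks) < config.repeat_fraction
            for b in np.flatnonzero(mask):
                repeat_ivs.append((chrom, int(b * config.repeat_block),
                                   int(min((b + 1) * config.repeat_block, L))))
    repeats = IntervalIndex(repeat_ivs, chroms=chroms)

    # SNP panel on autosomes, outside repeats, amplicon fits the chromosome
    autosomes = [c for c in chroms if c not in ("chrX", "chrY")]
    weights = np.array([config.chrom_lengths[c] for c in autosomes], dtype=float)
    weights /= weights.sum()
    half = config.amplicon_len // 2
    snp_rows = []
    amp_ivs = []
    taken: set[tuple[str, int]] = set()
    guard = 0
    while len(snp_rows) < config.n_snps:
        guard += 1
        if guard > 100 * config.n_snps:
            raise RuntimeError("could not place SNP panel outside repeats")
        chrom = autosomes[rng.choice(len(autosomes), p=weights)]
        L = config.chrom_lengths[chrom]
        if L <= config.amplicon_len + 2:
            continue
        pos = int(rng.integers(half + 1, L - half - 1))
        if repeats.overlaps(chrom, pos, pos + 1) or (chrom, pos) in taken:
            continue
        taken.add((chrom, pos))
        ref_code = int(seqs[chrom][pos])
        alt_code = int((ref_code + rng.integers(1, 4)) % 4)
        snp_rows.append({
            "snp_id": f"rs{900000 + len(snp_rows)}",
            "chrom": chrom, "pos": pos,
            "ref": codes_to_str(np.array([ref_code], dtype=np.uint8)),
            "alt": codes_to_str(np.array([alt_code], dtype=np.uint8)),
            "af": float(rng.uniform(0.4, 0.5)),
        })
        amp_ivs.append((chrom, pos - half, pos - half + config.amplicon_len))
    snps = pd.DataFrame(snp_rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    amplicons = IntervalIndex(amp_ivs, chroms=chroms)
    return Reference(chroms, dict(config.chrom_lengths), seqs, repeats, amplicons, snps)


# ---------------------------------------------------------------------------
# cfDNA fragments
# ---------------------------------------------------------------------------

def _copy_weights(config: SimulationConfig, origin: str) -> np.ndarray:
    """Per-chromosome sampling weights = length x (copy number / 2)."""
    chroms = list(config.chrom_lengths)
    w = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    for i, c in enumerate(chroms):
        if origin == "maternal":
            copies = 0.0 if c == "chrY" else 2.0
        else:
            if c == "chrY":
                copies = 1.0 if config.fetal_sex == "male" else 0.0
            elif c == "chrX":
                copies = 1.0 if config.fetal_sex == "male" else 2.0
            else:
                copies = 3.0 if c == config.trisomy_chrom else 2.0
        w[i] *= copies / 2.0
    return w / w.sum()


def simulate_cfdna(reference: Reference, config: SimulationConfig,
                   n: int | None = None,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw cfDNA fragments as a DataFrame (chrom, start, end, origin).

    Fetal origin is Bernoulli(fetal_fraction); chromosomes are sampled
    proportional to length x copy number (a trisomy contributes 3 fetal
    copies); lengths are normal with the stated maternal/fetal modes,
    truncated at >= 20 bp.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = int(config.n_cfdna_fragments if n is None else n)
    if n < 1:
        raise ValueError("need at least one fragment")
    chroms = np.array(list(config.chrom_lengths))
    lens = np.array([config.chrom_lengths[c] for c in chroms], dtype=np.int64)

    fetal = rng.random(n) < config.fetal_fraction
    chrom_idx = np.empty(n, dtype=np.int64)
    for origin, mask in (("maternal", ~fetal), ("fetal", fetal)):
        m = int(mask.sum())
        if m:
            chrom_idx[mask] = rng.choice(len(chroms), size=m,
                                         p=_copy_weights(config, origin))
    frag_len = np.where(fetal,
                        rng.normal(config.fetal_len_mean, config.fetal_len_sd, n),
                        rng.normal(config.maternal_len_mean, config.maternal_len_sd, n))
    frag_len = np.maximum(np.rint(frag_len).astype(np.int64), 20)
    cap = lens[chrom_idx]
    frag_len = np.minimum(frag_len, cap)
    start = np.floor(rng.random(n) * (cap - frag_len + 1)).astype(np.int64)
    return pd.DataFrame({
        "chrom": pd.Categorical.from_codes(chrom_idx, categories=list(chroms)),
        "start": start,
        "end": start + frag_len,
        "origin": pd.Categorical.from_codes(fetal.astype(np.int8),
                                            categories=["maternal", "fetal"]),
    })


def attach_mapq(fragments: pd.DataFrame, config: SimulationConfig,
                rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Assign per-fragment mapping quality for the identity second pass:
    a ``nonunique_rate`` share of tags is ambiguous (MAPQ < 60)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = len(fragments)
    mapq = np.full(n, 60, dtype=np.int64)
    amb = rng.random(n) < config.nonunique_rate
    mapq[amb] = rng.integers(0, 60, int(amb.sum()))
    out = fragments.copy()
    out["mapq"] = mapq
    out["strand"] = "+"
    return out


# ---------------------------------------------------------------------------
# Fragmentase and size selection
# ---------------------------------------------------------------------------

def fragmentase_and_select(fragments: pd.DataFrame, config: SimulationConfig,
                           rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Cut each fragment at Poisson(L/target - 1) uniform breakpoints and
    size-select pieces into the 40-50 bp window.

    The lower cut is sharp; the upper cut is a linear acceptance taper
    across the window (bead-based upper selection is soft), calibrated so
    retained pieces average ``fragmentase_target_mean``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = (fragments["end"] - fragments["start"]).to_numpy(np.int64)
    n = len(L)
    lam = np.maximum(L / config.fragmentase_target_mean - 1.0, 0.0)
    k = rng.poisson(lam)
    total_cuts = int(k.sum())
    frag_of_cut = np.repeat(np.arange(n), k)
    u = np.floor(rng.random(total_cuts) * L[frag_of_cut]).astype(np.int64)
    order = np.lexsort((u, frag_of_cut))
    u = u[order]

    pieces_per_frag = k + 1
    off = np.concatenate([[0], np.cumsum(pieces_per_frag)])[:-1]
    total = total_cuts + n
    ends = np.empty(total, dtype=np.int64)
    cut_slot = off[frag_of_cut] + (np.arange(total_cuts)
                                   - np.repeat(np.concatenate([[0], np.cumsum(k)])[:-1], k))
    ends[cut_slot] = u
    ends[off + k] = L
    starts = np.empty(total, dtype=np.int64)
    starts[1:] = ends[:-1]
    starts[off] = 0
    pid = np.repeat(np.arange(n), pieces_per_frag)

    plen = ends - starts
    lo, hi = config.size_select_window
    keep = (plen >= lo) & (plen <= hi)
    # soft upper selection: acceptance falls linearly across the window
    accept = rng.random(total) < 1.0 - config.size_select_taper * (plen - lo) / (hi - lo)
    keep &= accept
    abs_start = fragments["start"].to_numpy(np.int64)[pid] + starts
    out = pd.DataFrame({
        "chrom": fragments["chrom"].to_numpy()[pid[keep]],
        "start": abs_start[keep],
        "end": abs_start[keep] + plen[keep],
        "origin": fragments["origin"].to_numpy()[pid[keep]],
    })
    return out


# ---------------------------------------------------------------------------
# Self-ligation into chimeric molecules
# ---------------------------------------------------------------------------

def ligate_chimeras(sub_fragments: pd.DataFrame, config: SimulationConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[list[ChimericMolecule], pd.DataFrame]:
    """Consume sub-fragments in random order without replacement, each with
    a random orientation, closing a molecule once its total length exceeds
    ``chimera_min_len``.  The leftover short tail is discarded.

    Returns the molecules and a truth table with one row per part
    (molecule_id, part_index, coordinates, strand, junction offset)."""
    if len(sub_fragments) < 1:
        raise ValueError("need at least one sub-fragment")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(sub_fragments))
    strands = np.where(rng.random(len(sub_fragments)) < 0.5, "+", "-")
    chrom = sub_fragments["chrom"].astype(str).to_numpy()[order]
    start = sub_fragments["start"].to_numpy(np.int64)[order]
    end = sub_fragments["end"].to_numpy(np.int64)[order]
    origin = sub_fragments["origin"].astype(str).to_numpy()[order]

    molecules: list[ChimericMolecule] = []
    truth_rows = []
    parts: list[Part] = []
    total = 0
    for i in range(len(order)):
        parts.append(Part(chrom[i], int(start[i]), int(end[i]),
                          str(strands[i]), origin[i]))
        total += int(end[i] - start[i])
        if total > config.chimera_min_len:
            mol_id = f"mol{len(molecules):07d}"
            offset = 0
            for j, p in enumerate(parts):
                truth_rows.append((mol_id, j, p.chrom, p.start, p.end,
                                   p.strand, offset, p.end - p.start))
                offset += p.end - p.start
            molecules.append(ChimericMolecule(mol_id, parts))
            parts, total = [], 0
    truth = pd.DataFrame(truth_rows, columns=[
        "molecule_id", "part_index", "chrom", "start", "end", "strand",
        "junction_offset", "part_len"])
    return molecules, truth


def molecule_sequence(mol: ChimericMolecule, reference: Reference) -> np.ndarray:
    segs = []
    for p in mol.parts:
        seg = reference.sequence(p.chrom, p.start, p.end)
        segs.append(revcomp(seg) if p.strand == "-" else seg)
    return np.concatenate(segs)


# ---------------------------------------------------------------------------
# Reads and truth alignments
# ---------------------------------------------------------------------------

def _inject_errors(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return codes
    out = codes.copy()
    mask = rng.random(len(out)) < rate
    n_err = int(mask.sum())
    if n_err:
        out[mask] = (out[mask] + rng.integers(1, 4, n_err)) % 4
    return out


def generate_reads(molecules: Sequence[ChimericMolecule], reference: Reference,
                   config: SimulationConfig,
                   rng: np.random.Generator | None = None
                   ) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """PE reads: R1 is the first ``read_len`` bases of the molecule top
    strand, R2 the reverse complement of the last ``read_len`` bases (the
    whole molecule when it is shorter).  Substitution errors only."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    r1, r2 = [], []
    rl = config.read_len
    for mol in molecules:
        seq = molecule_sequence(mol, reference)
        a = _inject_errors(seq[:rl], config.seq_error_rate, rng)
        b = _inject_errors(revcomp(seq[-rl:] if len(seq) > rl else seq),
                           config.seq_error_rate, rng)
        r1.append((mol.molecule_id, codes_to_str(a)))
        r2.append((mol.molecule_id, codes_to_str(b)))
    return r1, r2


def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    records = (SeqRecord(Seq(seq), id=name, description="",
                         letter_annotations={"phred_quality": [40] * len(seq)})
               for name, seq in reads)
    SeqIO.write(records, str(path), "fastq")


def _part_offsets(mol: ChimericMolecule) -> list[tuple[int, int]]:
    offs = []
    pos = 0
    for p in mol.parts:
        offs.append((pos, pos + (p.end - p.start)))
        pos += p.end - p.start
    return offs


def emit_truth_sam(molecules: Sequence[ChimericMolecule], reference: Reference,
                   config: SimulationConfig, path: str | Path,
                   rng: np.random.Generator | None = None) -> Path:
    """Write split alignments that a first-pass aligner would produce.

    For each mate, every part fully contained in the read gets one record
    (the first is primary, the rest supplementary) with soft-clip CIGARs
    delimiting the part and SA tags linking the records.  Uniquely placed
    parts carry MAPQ 60; a ``nonunique_rate`` share draws MAPQ < 60.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    path = Path(path)
    header = pysam.AlignmentHeader.from_references(
        reference.chrom_names,
        [reference.chrom_lengths[c] for c in reference.chrom_names])
    rl = config.read_len
    flip = {"+": "-", "-": "+"}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for mol in molecules:
            L = mol.total_len
            offs = _part_offsets(mol)
            mapqs = [60 if rng.random() >= config.nonunique_rate
                     else int(rng.integers(0, 60)) for _ in mol.parts]
            seq = molecule_sequence(mol, reference)
            seq = _inject_errors(seq, config.seq_error_rate, rng)
            eff = min(rl, L)
            for mate in (1, 2):
                if mate == 1:
                    win = (0, eff)
                    read = seq[:eff]
                else:
                    win = (L - eff, L)
                    read = revcomp(seq[L - eff:])
                entries = []
                for pi, ((a, b), part) in enumerate(zip(offs, mol.parts)):
                    if a < win[0] or b > win[1]:
                        continue
                    if mate == 1:
                        qs, qe = a, b
                        strand = part.strand
                    else:
                        qs, qe = L - b, L - a
                        strand = flip[part.strand]
                    entries.append((qs, qe, strand, part, mapqs[pi]))
                if not entries:
                    continue
                entries.sort()
                sa_parts = []
                for qs, qe, strand, part, mapq in entries:
                    if strand == "+":
                        cigar = f"{qs}S{qe - qs}M{eff - qe}S" if eff > qe - qs \
                            else f"{qe - qs}M"
                    else:
                        cigar = f"{eff - qe}S{qe - qs}M{qs}S" if eff > qe - qs \
                            else f"{qe - qs}M"
                    sa_parts.append(f"{part.chrom},{part.start + 1},{strand},"
                                    f"{cigar},{mapq},0")
                for idx, (qs, qe, strand, part, mapq) in enumerate(entries):
                    rec = pysam.AlignedSegment(header)
                    rec.query_name = mol.molecule_id
                    flag = 0x1 | (0x40 if mate == 1 else 0x80)
                    if strand == "-":
                        flag |= 0x10
                    if idx > 0:
                        flag |= 0x800
                    rec.flag = flag
                    rec.reference_name = part.chrom
                    rec.reference_start = part.start
                    rec.mapping_quality = mapq
                    span = qe - qs
                    if strand == "+":
                        cig = [(4, qs)] if qs else []
                        cig.append((0, span))
                        if eff - qe:
                            cig.append((4, eff - qe))
                        rec.query_sequence = codes_to_str(read)
                    else:
                        cig = [(4, eff - qe)] if eff - qe else []
                        cig.append((0, span))
                        if qs:
                            cig.append((4, qs))
                        rec.query_sequence = codes_to_str(revcomp(read))
                    rec.cigartuples = cig
                    others = [s for j, s in enumerate(sa_parts) if j != idx]
                    if others:
                        rec.set_tag("SA", ";".join(others) + ";")
                    out.write(rec)
    return path


# ---------------------------------------------------------------------------
# Amplifet SNP allele counts
# ---------------------------------------------------------------------------

def simulate_amplifet(reference: Reference | pd.DataFrame, config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate per-SNP allele counts from the targeted amplicon assay.

    Maternal genotypes follow Hardy-Weinberg at the panel allele
    frequencies; the fetus inherits one maternal allele plus one paternal
    allele drawn from the population frequency; depth is Poisson around
    ``amplifet_coverage_mean``; the alternate-allele count is binomial at
    the plasma mixture fraction (paternal allele at an informative SNP
    appears at fetal_fraction / 2).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    panel = reference.snps if isinstance(reference, Reference) else reference
    if len(panel) == 0:
        raise ValueError("SNP panel is empty")
    af = panel["af"].to_numpy(float)
    n = len(panel)
    ff = config.fetal_fraction
    u = rng.random(n)
    maternal = np.where(u < (1 - af) ** 2, 0, np.where(u < (1 - af) ** 2
                                                       + 2 * af * (1 - af), 1, 2))
    transmitted = rng.random(n) < maternal / 2.0
    paternal = rng.random(n) < af
    fetal = transmitted.astype(int) + paternal.astype(int)
    depth = rng.poisson(config.amplifet_coverage_mean, n)
    if config.amplicon_dropout_rate > 0:
        depth = np.where(rng.random(n) < config.amplicon_dropout_rate, 0, depth)
    p = (1 - ff) * maternal / 2.0 + ff * fetal / 2.0
    e = config.seq_error_rate
    p_eff = p * (1 - e) + (1 - p) * e / 3.0
    alt = rng.binomial(depth, p_eff)
    return pd.DataFrame({
        "snp_id": panel["snp_id"].to_numpy(),
        "chrom": panel["chrom"].to_numpy(),
        "pos": panel["pos"].to_numpy(),
        "af": af,
        "maternal_dose": maternal,
        "fetal_dose": fetal,
        "ref_count": depth - alt,
        "alt_count": alt,
        "depth": depth,
        "informative": (maternal % 2 == 0) & (fetal == 1),
    })


def simulate_informative_counts(n_snps: int, fetal_fraction: float,
                                depth_mean: float,
                                rng: np.random.Generator,
                                seq_error_rate: float = 0.0) -> pd.DataFrame:
    """Allele counts at informative SNPs only (mother hom-ref, fetus het):
    the binomial oracle for the fetal-fraction estimator."""
    depth = rng.poisson(depth_mean, n_snps)
    p = fetal_fraction / 2.0
    p_eff = p * (1 - seq_error_rate) + (1 - p) * seq_error_rate / 3.0
    alt = rng.binomial(depth, p_eff)
    return pd.DataFrame({
        "snp_id": [f"inf{i}" for i in range(n_snps)],
        "ref_count": depth - alt, "alt_count": alt, "depth": depth,
    })


# ---------------------------------------------------------------------------
# Library writer
# ---------------------------------------------------------------------------

def write_fasta(reference: Reference, path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    records = (SeqRecord(Seq(codes_to_str(reference.seqs[c])), id=c, description="")
               for c in reference.chrom_names)
    SeqIO.write(records, str(path), "fasta")


def write_panel_vcf(reference: Reference, path: str | Path) -> None:
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">')
    for c in reference.chrom_names:
        header.contigs.add(c, length=reference.chrom_lengths[c])
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for _, row in reference.snps.iterrows():
            rec = out.new_record(contig=row["chrom"], start=int(row["pos"]),
                                 stop=int(row["pos"]) + 1,
                                 alleles=(row["ref"], row["alt"]),
                                 id=row["snp_id"])
            rec.info["AF"] = float(row["af"])
            out.write(rec)


def simulate_library(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the complete simulated input set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    ref = make_reference(config)
    paths = {
        "fasta": outdir / "reference.fasta",
        "repeats": outdir / "repeats.bed",
        "amplicons": outdir / "amplicons.bed",
        "panel": outdir / "panel.vcf",
        "r1": outdir / "reads_R1.fastq",
        "r2": outdir / "reads_R2.fastq",
        "truth_sam": outdir / "truth.sam",
        "truth_tsv": outdir / "truth_parts.tsv",
        "allele_counts": outdir / "allele_counts.tsv",
    }
    write_fasta(ref, paths["fasta"])
    write_bed(ref.repeats.intervals(), paths["repeats"])
    write_bed(ref.amplicons.intervals(), paths["amplicons"])
    write_panel_vcf(ref, paths["panel"])

    frags = simulate_cfdna(ref, config, rng=rng)
    pieces = fragmentase_and_select(frags, config, rng=rng)
    molecules, truth = ligate_chimeras(pieces, config, rng=rng)
    r1, r2 = generate_reads(molecules, ref, config, rng=rng)
    write_fastq(r1, paths["r1"])
    write_fastq(r2, paths["r2"])
    emit_truth_sam(molecules, ref, config, paths["truth_sam"], rng=rng)
    truth.to_csv(paths["truth_tsv"], sep="\t", index=False)
    counts = simulate_amplifet(ref, config, rng=rng)
    counts.to_csv(paths["allele_counts"], sep="\t", index=False)
    return paths
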
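"""SNP-panel selection and primer-candidate screening.

Population variants are filtered to common (MAF >= 0.4), biallelic,
rs-identified autosomal SNPs outside the HLA region, in Hardy-Weinberg
equilibrium (exact test, keep iff p >= 1e-5) and mutually unlinked
(sliding-window LD pruning at r^2 < 0.5).  Primer candidates are screened
with simple sequence-composition rules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from scipy.special import gammaln

__all__ = [
    "SnpRecord",
    "PanelCriteria",
    "read_snp_vcf",
    "filter_snps",
    "hwe_exact_test",
    "ld_prune",
    "primer_ok",
]


@dataclass
class SnpRecord:
    id: str
    chrom: str
    pos: int                       # 1-based
    ref: str
    alt: str
    maf: float | None = None
    genotype_counts: tuple[int, int, int] | None = None  # hom-ref, het, hom-alt
    dosages: np.ndarray | None = None                    # 0/1/2 per individual


@dataclass
class PanelCriteria:
    min_maf: float = 0.4
    hwe_p_min: float = 1e-5
    ld_r2_max: float = 0.5
    ld_window: int = 50
    ld_step: int = 5
    excluded_chroms: frozenset[str] = frozenset({"chrX", "chrY", "chrM", "chrMT", "MT", "X", "Y"})
    # chr6 p-arm (HLA); whole short arm since exact bounds are not standard
    excluded_intervals: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"chr6": (0, 61_000_000)})
    amplicon_max_len: int = 140


def read_snp_vcf(path: str) -> list[SnpRecord]:
    """Load variant records; MAF from INFO/AF, genotype counts and dosages
    from sample columns when present."""
    records = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            alt = alts[0] if alts else ""
            maf = None
            af = rec.info.get("AF")
            if af is not None:
                a = float(af[0] if isinstance(af, tuple) else af)
                maf = min(a, 1.0 - a)
            gcounts = None
            dosages = None
            if rec.samples:
                dos = []
                for s in rec.samples.values():
                    gt = s.get("GT")
                    if gt is None or any(a is None for a in gt):
                        dos.append(-1)
                    else:
                        dos.append(sum(1 for a in gt if a == 1))
                dos = np.asarray(dos)
                valid = dos >= 0
                if valid.any():
                    gcounts = (int((dos[valid] == 0).sum()),
                               int((dos[valid] == 1).sum()),
                               int((dos[valid] == 2).sum()))
                    dosages = dos[valid]
                    if maf is None:
                        a = dosages.mean() / 2.0
                        maf = min(a, 1.0 - a)
            records.append(SnpRecord(rec.id or "", rec.contig, rec.pos,
                                     rec.ref or "", alt, maf, gcounts, dosages))
    return records


_RULES = ["excluded_region", "indel", "not_biallelic", "no_rs_id", "low_maf",
          "hwe", "missing_af", "ld"]


def filter_snps(records: list[SnpRecord],
                criteria: PanelCriteria = PanelCriteria()
                ) -> tuple[list[SnpRecord], dict[str, int]]:
    """Apply the panel rules in their published order; each removed record
    is counted under its first failing rule.  LD pruning runs last, over
    the survivors, when genotype dosages are available."""
    removed = {r: 0 for r in _RULES}
    survivors: list[SnpRecord] = []
    for rec in sorted(records, key=lambda r: (r.chrom, r.pos)):
        iv = criteria.excluded_intervals.get(rec.chrom)
        if rec.chrom in criteria.excluded_chroms or \
                (iv is not None and iv[0] <= rec.pos - 1 < iv[1]):
            removed["excluded_region"] += 1
            continue
        if len(rec.ref) != 1 or len(rec.alt) != 1 or not rec.alt:
            removed["indel"] += 1
            continue
        if "," in rec.alt:
            removed["not_biallelic"] += 1
            continue
        if not rec.id.startswith("rs"):
            removed["no_rs_id"] += 1
            continue
        if rec.maf is None:
            removed["missing_af"] += 1
            continue
        if rec.maf < criteria.min_maf:
            removed["low_maf"] += 1
            continue
        if rec.genotype_counts is not None:
            p = hwe_exact_test(*rec.genotype_counts)
            if p < criteria.hwe_p_min:
                removed["hwe"] += 1
                continue
        survivors.append(rec)
    if survivors and all(r.dosages is not None for r in survivors):
        G = np.vstack([r.dosages for r in survivors]).T.astype(float)
        kept_idx = ld_prune(G, criteria.ld_r2_max, criteria.ld_window,
                            criteria.ld_step)
        removed["ld"] = len(survivors) - len(kept_idx)
        survivors = [survivors[i] for i in kept_idx]
    return survivors, removed


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test: the summed probability, over
    heterozygote counts consistent with the observed allele counts, of
    outcomes no more likely than the observed one."""
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotypes")
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if rare == 0:
        return 1.0  # monomorphic
    # feasible heterozygote counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    rare_hom = (rare - hets) // 2
    common_hom = n - hets - rare_hom
    # log P(h) up to a shared constant, conditional on allele counts
    logp = (hets * np.log(2.0)
            - gammaln(rare_hom + 1) - gammaln(hets + 1) - gammaln(common_hom + 1))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[hets == n_het]
    if len(obs) == 0:
        raise ValueError("observed het count inconsistent with allele counts")
    return float(min(probs[probs <= obs[0] * (1 + 1e-12)].sum(), 1.0))


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0  # constant genotype: correlation undefined, treated as 0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune(genotypes: np.ndarray, r2_max: float = 0.5, window: int = 50,
             step: int = 5) -> list[int]:
    """Sliding-window LD pruning over position-ordered SNP columns: within
    each window the later SNP of any pair with r^2 >= ``r2_max`` is
    dropped; the window advances by ``step``."""
    n_snps = genotypes.shape[1]
    keep = np.ones(n_snps, dtype=bool)
    start = 0
    while True:
        idx = [i for i in range(start, min(start + window, n_snps)) if keep[i]]
        for a in range(len(idx)):
            if not keep[idx[a]]:
                continue
            for b in range(a + 1, len(idx)):
                if not keep[idx[b]]:
                    continue
                if _r2(genotypes[:, idx[a]], genotypes[:, idx[b]]) >= r2_max:
                    keep[idx[b]] = False
        if start + window >= n_snps:
            break
        start += step
    return list(np.flatnonzero(keep))


_HOMOPOLYMER = re.compile(r"(A{4,}|C{4,}|G{4,}|T{4,})")
_DINUCLEOTIDE = re.compile(r"(..)\1{3,}")


def primer_ok(sequence: str) -> tuple[bool, str | None]:
    """Screen a primer candidate: no homopolymer run of four, no run of
    four dinucleotide units, at most 3 G/C among the last 5 bases, GC
    fraction within [0.4, 0.6].  Returns (pass, first failing reason)."""
    seq = sequence.upper()
    if re.search(r"[^ACGT]", seq):
        raise ValueError("primer sequence contains non-ACGT characters")
    if len(seq) < 15:
        raise ValueError("primer shorter than 15 nt")
    if _HOMOPOLYMER.search(seq):
        return False, "homopolymer"
    if _DINUCLEOTIDE.search(seq):
        return False, "dinucleotide_repeat"
    tail = seq[-5:]
    if sum(c in "GC" for c in tail) > 3:
        return False, "gc_3prime"
    gc = sum(c in "GC" for c in seq) / len(seq)
    if not 0.4 <= gc <= 0.6:
        return False, "gc_range"
    return True, None
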
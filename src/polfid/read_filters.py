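"""Read-level technical-error filters.

The estimation strategy is to be ruthless about technical error sources
before counting anything: only end-to-end ungapped alignments are kept
(one full-length match operation, e.g. 76M for 76 bp reads), reads with
more than two mismatches are discarded, the first and last 10 bases of
every read are masked to 'N' with quality 0, and sequencing cycles with
abnormally high error rates are masked the same way. What survives is the
read set from which per-position mismatch counts are tallied.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import encode
from .iomodel import AlignedRead


@dataclass
class FilterConfig:
    """Thresholds of the read-level gates, mirroring the pipeline defaults
    (76 bp full-length reads, <=2 mismatches, 10 bp end trim, mapq floor 30)."""

    read_length: int = 76
    max_mm: int = 2
    trim_n: int = 10
    min_mapq: int = 30
    drop_duplicates: bool = False
    bad_cycle_fold: float = 3.0


@dataclass
class CycleErrorProfile:
    """Per-sequencing-cycle mismatch rate against the reference.

    Cycles are in original machine orientation (reverse-strand alignments
    are un-reversed before tallying), since cycle artifacts live on the
    instrument side, not the genome side.
    """

    mismatches: np.ndarray
    bases: np.ndarray
    min_baseq: int

    @property
    def rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            r = self.mismatches / self.bases
        return np.where(self.bases > 0, r, np.nan)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cycle": np.arange(len(self.bases)),
            "bases": self.bases,
            "mismatches": self.mismatches,
            "rate": self.rates,
        })


def is_full_length(read: AlignedRead, expected_len: int) -> bool:
    """True iff the CIGAR is exactly one match op of ``expected_len``
    (no clips, indels or splices)."""
    return len(read.cigar) == 1 and read.cigar[0][0] in "M=" and read.cigar[0][1] == expected_len


def passes_mismatch_gate(read: AlignedRead, max_mm: int = 2) -> bool:
    """True iff the read carries at most ``max_mm`` substitutions."""
    if read.n_mismatches is None:
        raise ValueError(f"read {read.read_id}: n_mismatches not populated")
    return read.n_mismatches <= max_mm


def mask_ends(read: AlignedRead, n: int = 10) -> AlignedRead:
    """Return a copy with the first and last ``n`` bases set to N / quality 0.

    Masking is idempotent; a read of length <= 2n is fully masked (it then
    contributes nothing downstream) with a warning.
    """
    L = len(read.seq)
    if L <= 2 * n:
        warnings.warn(f"read {read.read_id}: length {L} <= 2*{n}, fully masked")
    quals = read.quals.copy()
    quals[:n] = 0
    if n > 0:
        quals[L - n:] = 0
    if L <= 2 * n:
        seq = "N" * L
    else:
        seq = "N" * n + read.seq[n:L - n] + "N" * n
    return AlignedRead(
        read_id=read.read_id, chrom=read.chrom, pos=read.pos, cigar=list(read.cigar),
        seq=seq, quals=quals, mapq=read.mapq, n_mismatches=read.n_mismatches,
        is_duplicate=read.is_duplicate, is_reverse=read.is_reverse,
    )


def mask_cycles(read: AlignedRead, cycles: Sequence[int]) -> AlignedRead:
    """Mask specific machine cycles to N / quality 0 (flipping indices for
    reverse-strand alignments, whose stored bases are genome-oriented)."""
    if not cycles:
        return read
    L = len(read.seq)
    idx = [L - 1 - c if read.is_reverse else c for c in cycles if 0 <= c < L]
    if not idx:
        return read
    quals = read.quals.copy()
    seq = list(read.seq)
    for i in idx:
        quals[i] = 0
        seq[i] = "N"
    return AlignedRead(
        read_id=read.read_id, chrom=read.chrom, pos=read.pos, cigar=list(read.cigar),
        seq="".join(seq), quals=quals, mapq=read.mapq, n_mismatches=read.n_mismatches,
        is_duplicate=read.is_duplicate, is_reverse=read.is_reverse,
    )


def cycle_error_profile(reads: Iterable[AlignedRead], genome: dict,
                        min_baseq: int = 39) -> CycleErrorProfile:
    """Mismatch rate per sequencing cycle over bases with quality >=
    ``min_baseq`` (N bases on read or reference excluded)."""
    enc_cache = {}
    mismatches = np.zeros(0, dtype=np.int64)
    bases = np.zeros(0, dtype=np.int64)
    for read in reads:
        L = len(read.seq)
        if L > len(bases):
            mismatches = np.concatenate([mismatches, np.zeros(L - len(mismatches), dtype=np.int64)])
            bases = np.concatenate([bases, np.zeros(L - len(bases), dtype=np.int64)])
        if read.chrom not in enc_cache:
            enc_cache[read.chrom] = encode(genome[read.chrom])
        ref = enc_cache[read.chrom]
        codes = encode(read.seq)
        quals = np.asarray(read.quals)
        for rpos, qpos, length in read.aligned_blocks():
            q = np.arange(qpos, qpos + length)
            rc = ref[rpos:rpos + length]
            bc = codes[qpos:qpos + length]
            ok = (quals[q] >= min_baseq) & (bc < 4) & (rc < 4)
            cyc = L - 1 - q if read.is_reverse else q
            np.add.at(bases, cyc[ok], 1)
            np.add.at(mismatches, cyc[ok & (bc != rc)], 1)
    return CycleErrorProfile(mismatches=mismatches, bases=bases, min_baseq=min_baseq)


def flag_bad_cycles(profile: CycleErrorProfile, fold: float = 3.0) -> set:
    """Cycles whose mismatch rate exceeds ``fold`` times the median rate
    over defined cycles (if the median is 0, any positive rate is flagged)."""
    rates = profile.rates
    defined = ~np.isnan(rates)
    if not defined.any():
        return set()
    med = float(np.median(rates[defined]))
    threshold = fold * med
    flagged = defined & (rates > threshold)
    return set(int(i) for i in np.nonzero(flagged)[0])


def apply_read_filters(reads: Iterable[AlignedRead], config: FilterConfig,
                       bad_cycles: Optional[Sequence[int]] = None) -> list:
    """Run the full gate-and-mask cascade: duplicate drop (optional), mapq
    floor, full-length gate, mismatch gate, end masking, bad-cycle masking.

    The gates commute; the masks are idempotent.
    """
    bad = sorted(bad_cycles) if bad_cycles else []
    out = []
    for read in reads:
        if config.drop_duplicates and read.is_duplicate:
            continue
        if read.mapq < config.min_mapq:
            continue
        if not is_full_length(read, config.read_length):
            continue
        if not passes_mismatch_gate(read, config.max_mm):
            continue
        read = mask_ends(read, config.trim_n)
        if bad:
            read = mask_cycles(read, bad)
        out.append(read)
    return out
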
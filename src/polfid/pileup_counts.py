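"""Per-position counting of matches, mismatches and indels from filtered
reads; the recurrent-identical-mismatch filter; overall error-rate
estimation; and the expected mismatch-count distribution under a null
mismatch frequency.

The central idea: after aggressive read-level filtering, a base observed
exactly once as a non-reference base is a candidate polymerase error,
while the same alternative base seen at the same position in more than one
read is far more likely a subclonal DNA variant or a systematic artifact
and is discarded wholesale (the position's coverage leaves the denominator
too, keeping numerator and denominator filters symmetric).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import BASES, encode
from .iomodel import AlignedRead


@dataclass
class PositionCounts:
    """Dense per-position base counts over one or more chromosomes.

    ``base_counts[chrom]`` has shape (4, L): counts of A/C/G/T observed at
    each position among bases passing all filters. ``ref_codes[chrom]`` is
    the encoded reference. ``dropped[chrom]`` marks positions removed by
    the recurrent-mismatch filter; their coverage is excluded from rate
    denominators by default.
    """

    ref_codes: Dict[str, np.ndarray]
    base_counts: Dict[str, np.ndarray]
    dropped: Dict[str, np.ndarray]
    ins_counts: Dict[tuple, int] = field(default_factory=dict)
    del_counts: Dict[tuple, int] = field(default_factory=dict)

    @classmethod
    def empty(cls, genome: dict) -> "PositionCounts":
        refs = {c: encode(s) for c, s in genome.items()}
        return cls(
            ref_codes=refs,
            base_counts={c: np.zeros((4, len(r)), dtype=np.int64) for c, r in refs.items()},
            dropped={c: np.zeros(len(r), dtype=bool) for c, r in refs.items()},
        )

    def copy(self) -> "PositionCounts":
        return PositionCounts(
            ref_codes=self.ref_codes,
            base_counts={c: a.copy() for c, a in self.base_counts.items()},
            dropped={c: a.copy() for c, a in self.dropped.items()},
            ins_counts=dict(self.ins_counts),
            del_counts=dict(self.del_counts),
        )

    def coverage(self, chrom: str) -> np.ndarray:
        return self.base_counts[chrom].sum(axis=0)

    def alt_matrix(self, chrom: str) -> np.ndarray:
        """(4, L) counts with the reference base's own row zeroed per column."""
        bc = self.base_counts[chrom].copy()
        ref = self.ref_codes[chrom]
        valid = ref < 4
        cols = np.nonzero(valid)[0]
        bc[ref[valid], cols] = 0
        return bc

    def totals(self, include_dropped: bool = False) -> tuple:
        """(total mismatches, total counted bases) over retained positions."""
        mm = 0
        bases = 0
        for chrom in self.base_counts:
            keep = np.ones(len(self.ref_codes[chrom]), dtype=bool)
            if not include_dropped:
                keep &= ~self.dropped[chrom]
            cov = self.coverage(chrom)
            alt = self.alt_matrix(chrom).sum(axis=0)
            mm += int(alt[keep].sum())
            bases += int(cov[keep].sum())
        return mm, bases

    def to_dataframe(self, chrom: Optional[str] = None) -> pd.DataFrame:
        """Sparse table of covered positions (1-based output coordinates)."""
        frames = []
        for c in ([chrom] if chrom else self.base_counts):
            cov = self.coverage(c)
            pos = np.nonzero(cov > 0)[0]
            bc = self.base_counts[c][:, pos]
            ref = self.ref_codes[c][pos]
            frames.append(pd.DataFrame({
                "chrom": c,
                "pos": pos + 1,
                "ref": [("ACGTN")[r] for r in ref],
                "coverage": cov[pos],
                "A": bc[0], "C": bc[1], "G": bc[2], "T": bc[3],
                "dropped": self.dropped[c][pos].astype(int),
            }))
        if not frames:
            return pd.DataFrame(columns=["chrom", "pos", "ref", "coverage",
                                         "A", "C", "G", "T", "dropped"])
        return pd.concat(frames, ignore_index=True)


@dataclass
class ErrorRateEstimate:
    total_mismatches: int
    total_bases: int
    filter_config: dict = field(default_factory=dict)

    @property
    def rate(self) -> float:
        return self.total_mismatches / self.total_bases

    def binomial_sd(self) -> float:
        p = self.rate
        return float(np.sqrt(p * (1 - p) / self.total_bases))


class PileupError(ValueError):
    pass


def _flush_batch(counts: PositionCounts, chrom: str, batch: dict, min_baseq: int) -> None:
    from ._seq import CODE

    ref = counts.ref_codes[chrom]
    bc = counts.base_counts[chrom]
    for length, (positions, seq_bytes, qual_parts) in batch.items():
        pos = np.asarray(positions, dtype=np.int64)
        codes = CODE[np.frombuffer(b"".join(seq_bytes), dtype=np.uint8).reshape(-1, length)]
        quals = np.concatenate(qual_parts).reshape(-1, length)
        overhang = (pos + length > len(ref)) | (pos < 0)
        if overhang.any():
            bad = int(pos[overhang][0])
            raise PileupError(f"alignment block overhangs contig {chrom} at {bad}")
        idx = pos[:, None] + np.arange(length)
        refm = ref[idx]
        valid = (codes < 4) & (refm < 4) & (quals >= min_baseq)
        np.add.at(bc, (codes[valid], idx[valid]), 1)


def pileup(reads: Iterable[AlignedRead], genome: dict, min_mapq: int = 30,
           min_baseq: int = 39, batch_size: int = 65536) -> PositionCounts:
    """Tally per-position base counts from aligned reads.

    A base contributes iff its quality >= ``min_baseq``, its read's mapq >=
    ``min_mapq``, it is not 'N' and the reference base is not 'N'. Gapped
    alignments contribute each aligned block separately; insertions and
    deletions are tallied into ``ins_counts``/``del_counts`` keyed by
    (chrom, position, length).
    """
    counts = PositionCounts.empty(genome)
    # batches[chrom][block_length] = (positions, seq_byte_chunks, qual_chunks)
    batches: Dict[str, dict] = {}
    pending = 0

    def flush():
        nonlocal pending
        for chrom, batch in batches.items():
            _flush_batch(counts, chrom, batch, min_baseq)
        batches.clear()
        pending = 0

    for read in reads:
        if read.mapq < min_mapq:
            continue
        if read.chrom not in genome:
            raise PileupError(f"read {read.read_id} maps to unknown contig {read.chrom}")
        chrom_batches = batches.setdefault(read.chrom, {})
        rpos, qpos = read.pos, 0
        for op, n in read.cigar:
            if op in "M=X":
                group = chrom_batches.setdefault(n, ([], [], []))
                group[0].append(rpos)
                group[1].append(read.seq[qpos:qpos + n].encode("ascii"))
                group[2].append(np.asarray(read.quals[qpos:qpos + n], dtype=np.uint8))
                rpos += n
                qpos += n
                pending += 1
            elif op == "I":
                key = (read.chrom, rpos, n)
                counts.ins_counts[key] = counts.ins_counts.get(key, 0) + 1
                qpos += n
            elif op == "D":
                key = (read.chrom, rpos, n)
                counts.del_counts[key] = counts.del_counts.get(key, 0) + 1
                rpos += n
            elif op == "N":
                rpos += n
            elif op == "S":
                qpos += n
        if pending >= batch_size:
            flush()
    flush()
    return counts


def filter_recurrent(counts: PositionCounts, max_obs: Optional[int] = 1) -> PositionCounts:
    """Drop every position where any single alternative base was observed
    more than ``max_obs`` times.

    "Identical mismatch" means same (position, alternative base): two reads
    showing the same non-reference base at one position look like a DNA
    variant; two different alternative bases at one position are independent
    candidate errors and the position is retained. ``max_obs=None`` is the
    identity.
    """
    out = counts.copy()
    if max_obs is None:
        return out
    for chrom in out.base_counts:
        alt = out.alt_matrix(chrom)
        out.dropped[chrom] = out.dropped[chrom] | (alt > max_obs).any(axis=0)
    return out


def overall_error_rate(counts: PositionCounts, include_dropped: bool = False,
                       filter_config: Optional[dict] = None) -> ErrorRateEstimate:
    """Pooled mismatch frequency: sum of alternative-base counts over sum of
    coverage, over retained positions.

    This is an upper bound on the polymerase error rate, mixing residual
    technical and biological errors; the method's measurable is the
    *relative* change between samples counted under an identical filter
    configuration.
    """
    mm, bases = counts.totals(include_dropped=include_dropped)
    if bases == 0:
        raise PileupError("zero counted bases: error rate undefined")
    return ErrorRateEstimate(total_mismatches=mm, total_bases=bases,
                             filter_config=dict(filter_config or {}))


def recurrent_filter_sweep(counts: PositionCounts, max_obs_values: Sequence[Optional[int]]) -> pd.DataFrame:
    """Measured mismatch frequency as a function of the maximal allowed
    number of observed identical mismatches."""
    rows = []
    for mo in max_obs_values:
        est = overall_error_rate(filter_recurrent(counts, mo))
        rows.append({"max_obs": np.inf if mo is None else mo,
                     "mismatches": est.total_mismatches,
                     "bases": est.total_bases,
                     "rate": est.rate})
    return pd.DataFrame(rows)


def count_indels(reads: Iterable[AlignedRead]) -> dict:
    """Per-length insertion/deletion counts normalized per mapped read.

    Keys are "+N" (insertion of N bases) and "-N" (deletion). This analysis
    runs on the read set *before* the indel-free full-length gate.
    """
    tallies: Dict[str, int] = {}
    n_reads = 0
    for read in reads:
        n_reads += 1
        for op, n in read.cigar:
            if op == "I":
                tallies[f"+{n}"] = tallies.get(f"+{n}", 0) + 1
            elif op == "D":
                tallies[f"-{n}"] = tallies.get(f"-{n}", 0) + 1
    if n_reads == 0:
        raise PileupError("zero mapped reads: indel rate undefined")
    return {k: v / n_reads for k, v in sorted(tallies.items())}


def expected_mismatch_distribution(coverages: np.ndarray, rate: float,
                                   mode: str = "analytic", seed: Optional[int] = None,
                                   max_k: int = 10, n_draws: int = 1) -> np.ndarray:
    """Expected fraction of positions showing k mismatches (k=0..max_k)
    if every counted base were an independent error with probability
    ``rate``.

    Analytic mode averages Binomial(cov, rate) pmfs over the coverage
    vector; Monte-Carlo mode samples ``n_draws`` binomial draws per
    position with the given seed and converges to the analytic answer.
    Comparing this null to the observed mismatch-count histogram is the
    basis for the recurrent-mismatch cutoff.
    """
    coverages = np.asarray(coverages, dtype=np.int64)
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if len(coverages) == 0:
        raise ValueError("no positions")
    ks = np.arange(max_k + 1)
    if mode == "analytic":
        uniq, counts = np.unique(coverages, return_counts=True)
        pmf = stats.binom.pmf(ks[None, :], uniq[:, None], rate)
        return (pmf * counts[:, None]).sum(axis=0) / counts.sum()
    if mode == "montecarlo":
        rng = np.random.default_rng(seed)
        draws = rng.binomial(np.repeat(coverages, n_draws), rate)
        draws = np.clip(draws, 0, max_k)
        return np.bincount(draws, minlength=max_k + 1) / draws.size
    raise ValueError(f"unknown mode {mode!r}")
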
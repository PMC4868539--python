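"""Splice donor/acceptor error profiles, nucleotide-context background
rates, and intron-retention rates.

A polymerase error inside the donor GT or acceptor AG motif of a
spliceosomal intron should abolish splicing of that intron, so reads from
the resulting retained transcripts carry a mismatch concentrated at the
first/last intronic offsets. Profiles are pooled: the rate at an offset is
the sum of errors at that offset across all junctions divided by the sum
of counted bases — never an average of per-junction rates, because
coverage is wildly unbalanced between junctions.

Offset convention (strand-oriented, 5'->3' of the transcript): +1..+F are
intronic with +1 at the donor G (or, for the acceptor, at the G of AG),
-1..-F are exonic counting away from the boundary. There is no offset 0.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._seq import encode
from .iomodel import AlignedRead, IntronModel
from .pileup_counts import PositionCounts


@dataclass
class JunctionWindow:
    """Oriented window of offsets around a donor or acceptor site.

    ``offsets[i]`` is the transcript-oriented offset of genomic position
    ``positions[i]``; ``truncated`` is set when the intron is shorter than
    the flank and intronic offsets had to be clipped.
    """

    intron: IntronModel
    side: str  # "donor" | "acceptor"
    offsets: np.ndarray
    positions: np.ndarray
    truncated: bool = False


@dataclass
class OffsetProfile:
    """Pooled per-offset error totals for one side (donor or acceptor)."""

    offsets: np.ndarray
    errors: np.ndarray
    bases: np.ndarray

    @property
    def rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            r = self.errors / self.bases
        return np.where(self.bases > 0, r, np.nan)

    def to_dataframe(self, side: str = "") -> pd.DataFrame:
        df = pd.DataFrame({"offset": self.offsets, "errors": self.errors,
                           "bases": self.bases, "rate": self.rates})
        if side:
            df.insert(0, "side", side)
        return df


def canonical_introns(introns: Iterable[IntronModel]) -> List[IntronModel]:
    """Keep only introns flanked by GT and AG donor/acceptor dinucleotides
    (already strand-oriented in IntronModel)."""
    return [i for i in introns if i.is_canonical()]


def _window_coords(intron: IntronModel, side: str, flank: int) -> Tuple[np.ndarray, np.ndarray, bool]:
    s, e = intron.interval.start, intron.interval.end
    length = e - s
    intronic_max = min(flank, length)
    truncated = intronic_max < flank
    off_ex = np.arange(-flank, 0)              # -flank..-1
    off_in = np.arange(1, intronic_max + 1)    # 1..intronic_max
    if intron.strand == "+":
        if side == "donor":
            pos_ex = s + off_ex          # -1 -> s-1
            pos_in = s + off_in - 1      # +1 -> s
        else:
            pos_ex = e - 1 - off_ex      # -1 -> e
            pos_in = e - off_in          # +1 -> e-1 (G of AG)
    else:
        if side == "donor":
            pos_ex = e - 1 - off_ex      # -1 -> e
            pos_in = e - off_in          # +1 -> e-1
        else:
            pos_ex = s + off_ex
            pos_in = s + off_in - 1
    offsets = np.concatenate([off_ex, off_in])
    positions = np.concatenate([pos_ex, pos_in])
    return offsets, positions, truncated


def build_windows(introns: Iterable[IntronModel], flank: int = 10) -> List[JunctionWindow]:
    """Build donor and acceptor windows of ``flank`` exonic plus ``flank``
    intronic offsets for each intron (intronic side truncated with a flag
    when the intron is shorter than the flank)."""
    windows = []
    for intron in introns:
        for side in ("donor", "acceptor"):
            offsets, positions, truncated = _window_coords(intron, side, flank)
            # clip anything that would fall off the contig
            keep = positions >= 0
            windows.append(JunctionWindow(
                intron=intron, side=side,
                offsets=offsets[keep], positions=positions[keep],
                truncated=truncated or (~keep).any(),
            ))
    return windows


def junction_error_profile(counts: PositionCounts, windows: Sequence[JunctionWindow],
                           spanning_only: bool = False) -> Dict[str, OffsetProfile]:
    """Pool per-offset error and coverage totals over all windows.

    When ``spanning_only`` is requested the caller must supply counts
    derived from junction-spanning reads only (see
    :func:`select_junction_spanning_reads`); the pooling itself is
    identical. Positions dropped by the recurrent filter are excluded.
    """
    if not windows:
        raise ValueError("empty window list")
    out = {}
    for side in ("donor", "acceptor"):
        side_windows = [w for w in windows if w.side == side]
        if not side_windows:
            continue
        flank = max(int(w.offsets.max()) for w in side_windows)
        flank = max(flank, max(-int(w.offsets.min()) for w in side_windows))
        all_offsets = np.concatenate([np.arange(-flank, 0), np.arange(1, flank + 1)])
        index = {o: i for i, o in enumerate(all_offsets)}
        errors = np.zeros(len(all_offsets), dtype=np.int64)
        bases = np.zeros(len(all_offsets), dtype=np.int64)
        for w in side_windows:
            chrom = w.intron.chrom
            cov = counts.coverage(chrom)
            alt = counts.alt_matrix(chrom).sum(axis=0)
            dropped = counts.dropped[chrom]
            L = len(cov)
            for off, pos in zip(w.offsets, w.positions):
                if pos >= L or dropped[pos]:
                    continue
                i = index[int(off)]
                errors[i] += alt[pos]
                bases[i] += cov[pos]
        out[side] = OffsetProfile(offsets=all_offsets, errors=errors, bases=bases)
    return out


# ---------------------------------------------------------------------------
# Junction-spanning read classification and intron retention
# ---------------------------------------------------------------------------

def _read_blocks(read: AlignedRead) -> List[Tuple[int, int]]:
    blocks = []
    for rpos, _qpos, n in read.aligned_blocks():
        if blocks and blocks[-1][1] == rpos:
            blocks[-1] = (blocks[-1][0], rpos + n)
        else:
            blocks.append((rpos, rpos + n))
    return blocks


def classify_read_by_intron(read: AlignedRead, intron: IntronModel,
                            min_overhang: int = 6) -> Optional[str]:
    """Classify one read against one intron.

    Returns "spliced" if the read has a gap exactly matching the intron
    with >= min_overhang aligned bases on each side, "retained" if a single
    aligned block runs contiguously through the donor or acceptor boundary
    with >= min_overhang on each side, else None.
    """
    if read.chrom != intron.chrom:
        return None
    s, e = intron.interval.start, intron.interval.end
    blocks = _read_blocks(read)
    for (a0, a1), (b0, b1) in zip(blocks, blocks[1:]):
        if a1 == s and b0 == e and a1 - a0 >= min_overhang and b1 - b0 >= min_overhang:
            return "spliced"
    for b0, b1 in blocks:
        for boundary in (s, e):
            if b0 <= boundary - min_overhang and b1 >= boundary + min_overhang:
                return "retained"
    return None


def select_junction_spanning_reads(reads: Iterable[AlignedRead],
                                   introns: Sequence[IntronModel],
                                   min_overhang: int = 6) -> Tuple[list, list]:
    """Split reads into (retained, spliced) junction-spanning sets; reads
    spanning no junction of any intron appear in neither."""
    retained, spliced = [], []
    for read in reads:
        status = None
        for intron in introns:
            c = classify_read_by_intron(read, intron, min_overhang)
            if c == "retained":
                status = "retained"
                break
            if c == "spliced" and status is None:
                status = "spliced"
        if status == "retained":
            retained.append(read)
        elif status == "spliced":
            spliced.append(read)
    return retained, spliced


def intron_retention_rate(reads: Iterable[AlignedRead], introns: Sequence[IntronModel],
                          min_overhang: int = 6) -> Tuple[pd.DataFrame, float]:
    """Per-intron and pooled retention fraction.

    Spliced support for an intron is the count of reads with a gap exactly
    matching it; retained support is the *average* of the donor- and
    acceptor-boundary contiguous-spanning read counts (a retained
    transcript exposes two spanning boundaries where a spliced one exposes
    one junction, so averaging keeps the two supports on the same scale).
    retention = retained / (retained + spliced); reads spanning neither
    are ignored, and introns with zero junction-spanning reads get NaN
    per-intron values.
    """
    reads = list(reads)
    rows = []
    tot_ret = tot_spl = 0.0
    for k, intron in enumerate(introns):
        s, e = intron.interval.start, intron.interval.end
        n_d = n_a = n_spl = 0
        for read in reads:
            if read.chrom != intron.chrom:
                continue
            blocks = _read_blocks(read)
            for (a0, a1), (b0, b1) in zip(blocks, blocks[1:]):
                if a1 == s and b0 == e and a1 - a0 >= min_overhang and b1 - b0 >= min_overhang:
                    n_spl += 1
            for b0, b1 in blocks:
                if b0 <= s - min_overhang and b1 >= s + min_overhang:
                    n_d += 1
                if b0 <= e - min_overhang and b1 >= e + min_overhang:
                    n_a += 1
        n_ret = (n_d + n_a) / 2
        total = n_ret + n_spl
        rows.append({
            "intron_index": k,
            "chrom": intron.chrom,
            "start": s,
            "end": e,
            "strand": intron.strand,
            "gene_id": intron.gene_id,
            "retained_donor": n_d,
            "retained_acceptor": n_a,
            "retained": n_ret,
            "spliced": n_spl,
            "retention": n_ret / total if total else np.nan,
        })
        tot_ret += n_ret
        tot_spl += n_spl
    pooled = tot_ret / (tot_ret + tot_spl) if (tot_ret + tot_spl) else np.nan
    return pd.DataFrame(rows), pooled


# ---------------------------------------------------------------------------
# Nucleotide-context background rates
# ---------------------------------------------------------------------------

def _context_profile(counts: PositionCounts, genome: dict, k: int,
                     positions_mask: Optional[Dict[str, np.ndarray]] = None) -> pd.DataFrame:
    """Pooled error rate per k-mer context and within-context position,
    normalized to the (base-weighted) grand mean rate."""
    n_ctx = 4 ** k
    errors = np.zeros((n_ctx, k), dtype=np.int64)
    bases = np.zeros((n_ctx, k), dtype=np.int64)
    for chrom in counts.base_counts:
        ref = counts.ref_codes[chrom]
        L = len(ref)
        cov = counts.coverage(chrom)
        alt = counts.alt_matrix(chrom).sum(axis=0)
        counted = (cov > 0) & ~counts.dropped[chrom]
        if positions_mask is not None:
            counted = counted & positions_mask[chrom]
        for j in range(k):
            # context starts at p - j; valid when fully on the contig and ACGT-only
            p = np.nonzero(counted)[0]
            start = p - j
            ok = (start >= 0) & (start + k <= L)
            p, start = p[ok], start[ok]
            ctx = np.zeros(len(p), dtype=np.int64)
            good = np.ones(len(p), dtype=bool)
            for m in range(k):
                c = ref[start + m]
                good &= c < 4
                ctx = ctx * 4 + c
            p, ctx = p[good], ctx[good]
            np.add.at(errors[:, j], ctx, alt[p])
            np.add.at(bases[:, j], ctx, cov[p])
    tot_err, tot_bases = errors.sum(), bases.sum()
    grand = tot_err / tot_bases if tot_bases else np.nan
    rows = []
    letters = "ACGT"
    for ctx in range(n_ctx):
        name = "".join(letters[(ctx >> (2 * (k - 1 - m))) & 3] for m in range(k))
        for j in range(k):
            b = bases[ctx, j]
            r = errors[ctx, j] / b if b else np.nan
            rows.append({
                "context": name, "position": j, "errors": errors[ctx, j],
                "bases": b, "rate": r,
                "normalized": r / grand if b and grand else np.nan,
            })
    return pd.DataFrame(rows)


def trinucleotide_profile(counts: PositionCounts, genome: dict,
                          positions_mask: Optional[Dict[str, np.ndarray]] = None) -> Dict[str, pd.DataFrame]:
    """Mismatch rate per mono-, di- and trinucleotide context, each
    normalized to the grand mean rate so a uniform error process gives 1
    everywhere; the base-weighted average of normalized entries is exactly
    1 by construction.

    ``positions_mask`` optionally restricts the tally (e.g. to exonic
    positions matching splice motifs).
    """
    return {
        "mono": _context_profile(counts, genome, 1, positions_mask),
        "di": _context_profile(counts, genome, 2, positions_mask),
        "tri": _context_profile(counts, genome, 3, positions_mask),
    }
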
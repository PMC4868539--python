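"""Codons one substitution away from a stop codon.

A single polymerase error can convert a sense codon into TAA, TAG or TGA,
truncating the protein. This module counts such "near-stop" codons in
coding sequences, compares the in-frame (frame 0) rate against the two
out-of-frame readings, and bins near-stop codons by relative position
along the ORF. If coding sequences are under selection to soften the cost
of transcription errors, frame 0 should carry fewer near-stop codons than
the frame-shifted readings of the same nucleotides, and near-stop codons
should cluster toward ORF ends.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import BASES
from .iomodel import OrfRecord, STOP_CODONS


def near_stop_codons() -> frozenset:
    """The set of non-stop codons having at least one single-substitution
    neighbor among {TAA, TAG, TGA}."""
    out = set()
    for stop in STOP_CODONS:
        for i in range(3):
            for b in BASES:
                if b == stop[i]:
                    continue
                neighbor = stop[:i] + b + stop[i + 1:]
                if neighbor not in STOP_CODONS:
                    out.add(neighbor)
    return frozenset(out)


NEAR_STOP = near_stop_codons()


@dataclass
class StopProximityResult:
    gene_id: str
    frame: int
    n_codons_scanned: int
    n_near_stop: int
    near_positions: np.ndarray  # scanned-codon indices of near-stop codons

    @property
    def fraction(self) -> float:
        return self.n_near_stop / self.n_codons_scanned if self.n_codons_scanned else np.nan


def scan_orf(orf: OrfRecord, frame: int = 0) -> StopProximityResult:
    """Scan an ORF in the given frame for near-stop codons.

    Frame ``f`` reads codons starting at offset f; the trailing incomplete
    codon is ignored. In frame 0 the terminal stop codon is excluded from
    scanning (it *is* a stop); out-of-frame windows overlapping it are
    kept. Codons containing non-ACGT characters are skipped with a
    warning.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    seq = orf.cds_seq
    end = len(seq) - 3 if frame == 0 else len(seq)
    n_scanned = 0
    near = []
    for idx, start in enumerate(range(frame, end - 2, 3)):
        codon = seq[start:start + 3]
        if any(c not in BASES for c in codon):
            warnings.warn(f"{orf.gene_id}: non-ACGT codon at offset {start}, skipped")
            continue
        n_scanned += 1
        if codon in NEAR_STOP:
            near.append(idx)
    return StopProximityResult(
        gene_id=orf.gene_id, frame=frame, n_codons_scanned=n_scanned,
        n_near_stop=len(near), near_positions=np.asarray(near, dtype=np.int64),
    )


def positional_distribution(results: Sequence[StopProximityResult],
                            n_bins: int = 5) -> pd.DataFrame:
    """Near-stop density per ORF-length quantile bin, pooled across ORFs.

    Each scanned codon's index is normalized to [0,1) within its ORF; the
    density in a bin is (near-stop codons in bin) / (codons in bin). Bins
    with zero codons are flagged NaN.
    """
    if not results:
        raise ValueError("no ORF scan results")
    total = np.zeros(n_bins, dtype=np.int64)
    near = np.zeros(n_bins, dtype=np.int64)
    for res in results:
        n = res.n_codons_scanned
        if n == 0:
            continue
        idx = np.arange(n)
        bins = np.minimum((idx * n_bins) // n, n_bins - 1)
        np.add.at(total, bins, 1)
        if len(res.near_positions):
            nb = np.minimum((res.near_positions * n_bins) // n, n_bins - 1)
            np.add.at(near, nb, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(total > 0, near / total, np.nan)
    return pd.DataFrame({
        "bin": np.arange(1, n_bins + 1),
        "codons": total,
        "near_stop": near,
        "density": density,
    })


def frame_comparison(orfs: Iterable[OrfRecord]) -> dict:
    """Pooled near-stop fraction in frame 0 vs frames 1+2.

    The ratio frame0/frame12 below 1 is the signature of selection against
    error-induced premature stops; on nucleotide-shuffled null sequences
    it centers on 1.
    """
    n0 = s0 = n12 = s12 = 0
    for orf in orfs:
        r0 = scan_orf(orf, 0)
        n0 += r0.n_codons_scanned
        s0 += r0.n_near_stop
        for f in (1, 2):
            rf = scan_orf(orf, f)
            n12 += rf.n_codons_scanned
            s12 += rf.n_near_stop
    if n0 == 0:
        raise ValueError("no codons scanned")
    frame0 = s0 / n0
    frame12 = s12 / n12 if n12 else np.nan
    return {
        "frame0_rate": frame0,
        "frame12_rate": frame12,
        "ratio": frame0 / frame12 if frame12 else np.nan,
        "frame0_near": s0, "frame0_codons": n0,
        "frame12_near": s12, "frame12_codons": n12,
    }


def spectrum_weighted_near_stop(orf: OrfRecord, weights: Dict[tuple, float],
                                frame: int = 0) -> float:
    """Expected number of error-induced stops per codon, weighting each
    codon->stop single-substitution channel by the supplied (ref, alt)
    substitution rates (e.g. from a measured SubstitutionSpectrum)."""
    seq = orf.cds_seq
    end = len(seq) - 3 if frame == 0 else len(seq)
    total = 0.0
    n = 0
    for start in range(frame, end - 2, 3):
        codon = seq[start:start + 3]
        if any(c not in BASES for c in codon):
            continue
        n += 1
        for i in range(3):
            for b in BASES:
                if b == codon[i]:
                    continue
                if codon[:i] + b + codon[i + 1:] in STOP_CODONS:
                    total += weights.get((codon[i], b), 0.0)
    return total / n if n else np.nan
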
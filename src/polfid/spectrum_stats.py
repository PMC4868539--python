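"""Substitution spectrum over the 12 directed single-base changes,
transition/transversion summary, and the two between-sample rate
comparisons the pipeline performs (paired and Welch t-tests).

The spectrum is reported in mRNA space when transcript annotation is
supplied: ref and alt at positions inside a minus-strand transcript are
complemented, so a genomic G->A under a minus-strand gene is tallied as
the transcribed C->U (written C->T in DNA letters). Without annotation a
genomic-strand spectrum is emitted.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import BASES, COMP_CODE
from .iomodel import GenomeInterval
from .pileup_counts import PositionCounts

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
PAIRS = [(r, a) for r in BASES for a in BASES if r != a]


@dataclass
class SubstitutionSpectrum:
    """Error counts and source-base denominators for the 12 ordered
    ref->alt changes. ``errors[r, a]`` and ``bases[r]`` are indexed in
    A,C,G,T code order."""

    errors: np.ndarray  # (4, 4)
    bases: np.ndarray   # (4,)

    def rate(self, ref: str, alt: str) -> float:
        r, a = BASES.index(ref), BASES.index(alt)
        return self.errors[r, a] / self.bases[r] if self.bases[r] else np.nan

    @property
    def total_errors(self) -> int:
        return int(self.errors.sum())

    def to_dataframe(self) -> pd.DataFrame:
        total_bases = self.bases.sum()
        rows = []
        for ref, alt in PAIRS:
            r, a = BASES.index(ref), BASES.index(alt)
            rows.append({
                "ref": ref, "alt": alt,
                "errors": int(self.errors[r, a]),
                "bases": int(self.bases[r]),
                "rate": self.rate(ref, alt),
                "rate_per_total_base": self.errors[r, a] / total_bases if total_bases else np.nan,
                "class": "transition" if (ref, alt) in TRANSITIONS else "transversion",
            })
        return pd.DataFrame(rows)


def _strand_arrays(counts: PositionCounts,
                   transcripts: Sequence[GenomeInterval]) -> Dict[str, np.ndarray]:
    """Per-chromosome strand map: 0 = unannotated, 1 = '+', 2 = '-'."""
    out = {c: np.zeros(len(r), dtype=np.int8) for c, r in counts.ref_codes.items()}
    for iv in transcripts:
        if iv.chrom in out:
            out[iv.chrom][iv.start:iv.end] = 1 if iv.strand == "+" else 2
    return out


def substitution_spectrum(counts: PositionCounts,
                          transcripts: Optional[Sequence[GenomeInterval]] = None,
                          transcribed_strand: bool = False) -> SubstitutionSpectrum:
    """Tally the 12-class spectrum from recurrent-filtered position counts.

    With ``transcribed_strand`` set, ``transcripts`` must be provided;
    positions on minus-strand transcripts have ref and alt complemented and
    unannotated positions are excluded.
    """
    if transcribed_strand and transcripts is None:
        raise ValueError("transcribed-strand mode requires transcript annotation")
    strand = _strand_arrays(counts, transcripts) if transcribed_strand else None
    errors = np.zeros((4, 4), dtype=np.int64)
    bases = np.zeros(4, dtype=np.int64)
    for chrom in counts.base_counts:
        ref = counts.ref_codes[chrom]
        cov = counts.coverage(chrom)
        bc = counts.base_counts[chrom]
        counted = (cov > 0) & ~counts.dropped[chrom] & (ref < 4)
        if strand is not None:
            counted &= strand[chrom] > 0
        pos = np.nonzero(counted)[0]
        r = ref[pos].astype(np.int64)
        if strand is not None:
            minus = strand[chrom][pos] == 2
        else:
            minus = np.zeros(len(pos), dtype=bool)
        r_eff = np.where(minus, COMP_CODE[r], r)
        np.add.at(bases, r_eff, cov[pos])
        for a in range(4):
            c = bc[a, pos]
            nz = (c > 0) & (r != a)
            if not nz.any():
                continue
            a_eff = np.where(minus[nz], COMP_CODE[a], a)
            np.add.at(errors, (r_eff[nz], a_eff), c[nz])
    return SubstitutionSpectrum(errors=errors, bases=bases)


def ts_tv(spectrum: SubstitutionSpectrum) -> dict:
    """Pooled transition vs transversion rates and their ratio.

    Both rates share the total counted-base denominator, so the ratio is
    the transition:transversion *error* ratio: ts pools the 4 transition
    classes (A<->G, C<->T), tv the 8 transversions, and equal per-class
    rates give ratio 0.5. A zero transversion rate yields ratio NaN with
    ``tv_zero`` flagged.
    """
    ts_err = tv_err = 0
    for ref, alt in PAIRS:
        r, a = BASES.index(ref), BASES.index(alt)
        if (ref, alt) in TRANSITIONS:
            ts_err += spectrum.errors[r, a]
        else:
            tv_err += spectrum.errors[r, a]
    total = spectrum.bases.sum()
    ts_rate = ts_err / total if total else 0.0
    tv_rate = tv_err / total if total else 0.0
    return {
        "ts_rate": ts_rate,
        "tv_rate": tv_rate,
        "ratio": ts_rate / tv_rate if tv_rate > 0 else np.nan,
        "tv_zero": tv_rate == 0,
    }


def paired_rate_comparison(rates_a: Sequence[float], rates_b: Sequence[float]) -> dict:
    """Classical paired t-test (n-1 df, two-sided) on same-length
    per-sample rate vectors, e.g. nuclear vs cytoplasmic fractions of the
    same cell lines."""
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError("paired comparison needs n >= 2")
    diffs = a - b
    zero_var = bool(np.isclose(np.std(diffs, ddof=1), 0.0))
    if zero_var and np.isclose(diffs.mean(), 0.0):
        t, p = 0.0, 1.0
    elif zero_var:
        t, p = np.nan, np.nan
    else:
        t, p = stats.ttest_rel(a, b)
    return {"mean_diff": float(diffs.mean()), "t": float(t), "p": float(p),
            "n": n, "zero_variance": zero_var}


def group_rate_comparison(rates_high: Sequence[float], rates_low: Sequence[float]) -> dict:
    """Welch two-sample t-test between two independent groups of
    per-sample rates (unequal variances not assumed equal)."""
    a = np.asarray(rates_high, dtype=float)
    b = np.asarray(rates_low, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("group comparison needs n >= 2 per group")
    if np.isclose(np.std(a, ddof=1), 0) and np.isclose(np.std(b, ddof=1), 0):
        if np.isclose(a.mean(), b.mean()):
            return {"t": 0.0, "p": 1.0, "zero_variance": True}
        return {"t": np.nan, "p": np.nan, "zero_variance": True}
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {"t": float(t), "p": float(p), "zero_variance": False}
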
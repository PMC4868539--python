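"""Synthetic RNA-seq generator with full ground truth.

The generator builds a genome of protein-coding genes with canonical
GT..AG introns, transcribes molecules that independently accrue
polymerase errors (per transcribed base, inherited by every read of the
molecule), optionally retains introns when an error hits the donor or
acceptor motif, layers per-read sequencing errors with a two-level
quality model plus cycle-specific error spikes, and mixes in subclonal
DNA variants carried by a fraction of molecules. Reads are emitted as
truth-aligned SAM records (no aligner in the loop: spliced reads get
N-gapped CIGARs at the true junction) together with a truth table that
assigns every planted non-reference base to an event, so every pipeline
stage can be tested against known ground truth.

Default rates follow the regime the method targets: polymerase errors at
1e-5 per transcribed base (the plausible 1e-6..1e-5 band), sequencing
errors at 1e-4 per base for high-quality calls, with a small fraction of
low-quality (Q10) calls at 1e-2.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from ._seq import BASES, CODE, COMP_CODE, TRANSITION, decode, encode, revcomp
from .iomodel import (AlignedRead, GenomeInterval, IntronModel, OrfRecord,
                      STOP_CODONS, write_alignments, write_fastq, write_genome,
                      write_gff3)

NONSTOP_CODONS = sorted(
    a + b + c
    for a in BASES for b in BASES for c in BASES
    if a + b + c not in STOP_CODONS
)
STOP_LIST = sorted(STOP_CODONS)


# ---------------------------------------------------------------------------
# Configuration and truth records
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    seed: int = 0
    chrom_name: str = "chrS"
    n_genes: int = 10
    n_introns_range: Tuple[int, int] = (1, 3)
    exon_length_range: Tuple[int, int] = (150, 300)
    intron_length_range: Tuple[int, int] = (60, 120)
    intergenic_length_range: Tuple[int, int] = (80, 200)
    genome_length: Optional[int] = None  # pad with random sequence if set
    minus_strand_fraction: float = 0.5
    # polymerase (per-molecule) errors
    polymerase_error_rate: float = 1e-5
    transition_prob: float = 1 / 3  # uniform over the 3 alternatives by default
    splice_error_rate: float = 0.0  # targeted donor +1/+2 error per molecule per intron
    retention_on_splice_error: float = 1.0
    background_retention_rate: float = 0.0
    # sequencing (per-read) errors
    sequencing_error_rate: float = 1e-4
    low_quality_fraction: float = 0.02
    low_quality_error_rate: float = 1e-2
    high_qual: int = 40
    low_qual: int = 10
    bad_cycles: List[Tuple[int, float]] = field(default_factory=list)
    insertion_rate: float = 0.0  # per read base, single-base events
    deletion_rate: float = 0.0
    # library
    subclonal_variants: List[Tuple[str, int, str, float]] = field(default_factory=list)
    reads_per_molecule: int = 1
    read_length: int = 76
    coverage_target: float = 30.0

    def validate(self) -> None:
        for name in ("polymerase_error_rate", "sequencing_error_rate",
                     "low_quality_error_rate", "low_quality_fraction",
                     "splice_error_rate", "retention_on_splice_error",
                     "background_retention_rate", "minus_strand_fraction",
                     "transition_prob", "insertion_rate", "deletion_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.exon_length_range[0] < self.read_length:
            raise ValueError("exons must be at least one read length")
        if self.intron_length_range[0] < 8:
            raise ValueError("introns must be at least 8 bp")


@dataclass
class SimTruth:
    """One planted event; every non-reference base in the emitted reads
    traces back to at least one of these. ref/alt are genomic-strand
    letters; ``expressed`` is False for polymerase events transcribed into
    an intron that was subsequently spliced out."""

    event_id: str
    molecule_id: str
    chrom: str
    pos: int
    type: str  # polymerase | subclonal | sequencing | insertion | deletion
    ref: str
    alt: str
    retained_intron: Optional[str] = None
    read_id: Optional[str] = None
    expressed: bool = True


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Segment:
    kind: str               # exon | intron
    intron_index: Optional[int]  # sense-order intron index
    sense_start: int
    sense_end: int
    gstart: int
    gend: int


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: List[Tuple[int, int]]    # genomic, ascending
    introns: List[Tuple[int, int]]  # genomic, ascending

    @property
    def pre_len(self) -> int:
        return self.end - self.start

    def sense_segments(self) -> List[_Segment]:
        gsegs = sorted(
            [("exon", s, e) for s, e in self.exons]
            + [("intron", s, e) for s, e in self.introns],
            key=lambda x: x[1],
        )
        if self.strand == "-":
            gsegs = gsegs[::-1]
        out, t, n_introns = [], 0, 0
        for kind, gs, ge in gsegs:
            idx = None
            if kind == "intron":
                idx = n_introns
                n_introns += 1
            out.append(_Segment(kind, idx, t, t + (ge - gs), gs, ge))
            t += ge - gs
        return out

    def sense_to_genomic(self, t: int) -> int:
        return self.start + t if self.strand == "+" else self.end - 1 - t

    def sense_codes(self, genome: dict) -> np.ndarray:
        codes = encode(genome[self.chrom][self.start:self.end])
        if self.strand == "-":
            codes = COMP_CODE[codes][::-1]
        return codes

    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def intron_models(self, genome: dict) -> List[IntronModel]:
        out = []
        for seg in self.sense_segments():
            if seg.kind != "intron":
                continue
            iv = GenomeInterval(self.chrom, seg.gstart, seg.gend, self.strand)
            ref = genome[self.chrom]
            left, right = ref[seg.gstart:seg.gstart + 2], ref[seg.gend - 2:seg.gend]
            donor, acceptor = (left, right) if self.strand == "+" else (revcomp(right), revcomp(left))
            out.append(IntronModel(interval=iv, donor_dinuc=donor,
                                   acceptor_dinuc=acceptor, gene_id=self.gene_id))
        return out

    def orf_record(self, genome: dict) -> OrfRecord:
        segs = [s for s in self.sense_segments() if s.kind == "exon"]
        codes = self.sense_codes(genome)
        seq = "".join(decode(codes[s.sense_start:s.sense_end]) for s in segs)
        return OrfRecord(gene_id=self.gene_id, cds_seq=seq)


# ---------------------------------------------------------------------------
# Stage 1: genome
# ---------------------------------------------------------------------------

def _random_bases(rng, n: int) -> str:
    return decode(rng.integers(0, 4, size=n).astype(np.uint8))


def _random_orf(rng, n_codons: int) -> str:
    body = "".join(NONSTOP_CODONS[i] for i in rng.integers(0, len(NONSTOP_CODONS),
                                                           size=n_codons - 2))
    return "ATG" + body + STOP_LIST[rng.integers(0, 3)]


def simulate_genome(config: SimConfig, rng: Optional[np.random.Generator] = None):
    """Build the genome FASTA sequence and gene models.

    Every intron is canonical GT..AG and every gene's spliced CDS is a
    valid ORF. Deterministic under the config seed.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])
    chrom = config.chrom_name
    parts: List[str] = []
    genes: List[GeneModel] = []
    cursor = 0
    for g in range(config.n_genes):
        gap = int(rng.integers(*_incl(config.intergenic_length_range)))
        parts.append(_random_bases(rng, gap))
        cursor += gap
        k = int(rng.integers(*_incl(config.n_introns_range)))
        exon_lens = [int(rng.integers(*_incl(config.exon_length_range))) for _ in range(k + 1)]
        total = sum(exon_lens)
        exon_lens[-1] -= total % 3  # CDS length must be a codon multiple
        orf = _random_orf(rng, sum(exon_lens) // 3)
        intron_seqs = ["GT" + _random_bases(rng, int(rng.integers(*_incl(config.intron_length_range))) - 4) + "AG"
                       for _ in range(k)]
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        # assemble the transcript-sense gene body, recording sense segments
        sense_parts, sense_bounds = [], []
        off = 0
        epos = 0
        for i, elen in enumerate(exon_lens):
            sense_parts.append(orf[epos:epos + elen])
            sense_bounds.append(("exon", off, off + elen))
            off += elen
            epos += elen
            if i < k:
                ilen = len(intron_seqs[i])
                sense_parts.append(intron_seqs[i])
                sense_bounds.append(("intron", off, off + ilen))
                off += ilen
        sense_seq = "".join(sense_parts)
        gene_len = len(sense_seq)
        gstart, gend = cursor, cursor + gene_len
        if strand == "+":
            genomic_seq = sense_seq
            coords = [(kind, gstart + s, gstart + e) for kind, s, e in sense_bounds]
        else:
            genomic_seq = revcomp(sense_seq)
            coords = [(kind, gend - e, gend - s) for kind, s, e in sense_bounds]
        parts.append(genomic_seq)
        cursor = gend
        genes.append(GeneModel(
            gene_id=f"g{g}", chrom=chrom, strand=strand, start=gstart, end=gend,
            exons=sorted([(s, e) for kind, s, e in coords if kind == "exon"]),
            introns=sorted([(s, e) for kind, s, e in coords if kind == "intron"]),
        ))
    tail = int(rng.integers(*_incl(config.intergenic_length_range)))
    parts.append(_random_bases(rng, tail))
    cursor += tail
    if config.genome_length is not None and cursor < config.genome_length:
        parts.append(_random_bases(rng, config.genome_length - cursor))
    genome = {chrom: "".join(parts)}
    return genome, genes


def _incl(rng_pair: Tuple[int, int]) -> Tuple[int, int]:
    lo, hi = rng_pair
    return lo, hi + 1


def annotation_rows(genes: Sequence[GeneModel]) -> List[tuple]:
    """GFF3 rows (internal coordinates) for the simulated genes."""
    rows = []
    for gene in genes:
        gid, tid = gene.gene_id, f"{gene.gene_id}.t1"
        rows.append((gene.chrom, "polfid_sim", "gene", gene.start, gene.end,
                     gene.strand, f"ID={gid}"))
        rows.append((gene.chrom, "polfid_sim", "mRNA", gene.start, gene.end,
                     gene.strand, f"ID={tid};Parent={gid}"))
        for s, e in gene.exons:
            rows.append((gene.chrom, "polfid_sim", "exon", s, e, gene.strand, f"Parent={tid}"))
            rows.append((gene.chrom, "polfid_sim", "CDS", s, e, gene.strand, f"Parent={tid}"))
        for seg in gene.sense_segments():
            if seg.kind == "intron":
                rows.append((gene.chrom, "polfid_sim", "intron", seg.gstart, seg.gend,
                             gene.strand, f"ID={gid}.i{seg.intron_index};Parent={tid}"))
    return rows


def plant_subclonal_variants(genes: Sequence[GeneModel], genome: dict, n: int,
                             allele_fraction: float, seed: int,
                             margin: int = 100, junction_margin: int = 80) -> List[Tuple[str, int, str, float]]:
    """Pick ``n`` exonic positions and assign each a random non-reference
    alternative at the given allele fraction; convenience for planting DNA
    variants.

    Positions stay ``margin`` spliced bases from transcript ends and
    ``junction_margin`` bases from every exon edge: full-length ungapped
    reads cannot span an exon-intron boundary, so coverage decays toward
    junctions and only interior positions see the nominal read depth.
    """
    rng = np.random.default_rng(seed)
    candidates = []
    for gene in genes:
        # exonic genomic positions whose spliced offset is in the interior
        total = gene.spliced_length()
        m = 0
        for seg in gene.sense_segments():
            if seg.kind != "exon":
                continue
            seg_len = seg.sense_end - seg.sense_start
            for off in range(seg_len):
                interior = (margin <= m < total - margin
                            and junction_margin <= off < seg_len - junction_margin)
                if interior:
                    candidates.append(gene.sense_to_genomic(seg.sense_start + off))
                m += 1
    chrom = genes[0].chrom
    picks = rng.choice(len(candidates), size=min(n, len(candidates)), replace=False)
    out = []
    for i in sorted(int(p) for p in picks):
        pos = candidates[i]
        ref = genome[chrom][pos]
        alt = BASES[(BASES.index(ref) + 1 + rng.integers(0, 3)) % 4]
        out.append((chrom, pos, alt, allele_fraction))
    return out


# ---------------------------------------------------------------------------
# Stage 2: molecules
# ---------------------------------------------------------------------------

@dataclass
class _MolDelta:
    retained: frozenset
    # (sense_pos, alt_code) pairs applied to the molecule sequence
    changes: List[Tuple[int, int]]


@dataclass
class MoleculeSet:
    genes: List[GeneModel]
    genome: dict
    n_molecules: Dict[str, int]
    deltas: Dict[str, Dict[int, _MolDelta]]  # gene_id -> molecule index -> delta
    truth: List[SimTruth]


def _draw_alt(rng, ref_code: int, transition_prob: float) -> int:
    if rng.random() < transition_prob:
        return TRANSITION[int(ref_code)]
    tvs = [b for b in range(4) if b != ref_code and b != TRANSITION[int(ref_code)]]
    return tvs[int(rng.integers(0, 2))]


def simulate_molecules(genome: dict, genes: Sequence[GeneModel], config: SimConfig,
                       rng: Optional[np.random.Generator] = None) -> MoleculeSet:
    """Transcribe molecules with per-molecule polymerase errors.

    Each molecule accrues substitutions at ``polymerase_error_rate`` per
    pre-mRNA base; an error landing on a donor/acceptor critical offset
    (first two or last two intronic bases) triggers retention of that
    intron with probability ``retention_on_splice_error``. Retained
    molecules keep the intronic sequence (and any errors inside it);
    errors inside spliced-out introns are recorded as unexpressed truth.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[1])
    n_molecules: Dict[str, int] = {}
    deltas: Dict[str, Dict[int, _MolDelta]] = {}
    truth: List[SimTruth] = []
    ev_counter = 0
    for gene in genes:
        segs = gene.sense_segments()
        intron_segs = [s for s in segs if s.kind == "intron"]
        k = len(intron_segs)
        codes = gene.sense_codes(genome)
        pre_len = gene.pre_len
        n_mol = max(1, int(round(config.coverage_target * gene.spliced_length()
                                 / (config.read_length * config.reads_per_molecule))))
        n_molecules[gene.gene_id] = n_mol
        gene_deltas: Dict[int, _MolDelta] = {}

        n_err = rng.binomial(pre_len, config.polymerase_error_rate, size=n_mol)
        splice_hits = (rng.random((n_mol, k)) < config.splice_error_rate) if k else np.zeros((n_mol, 0), bool)
        bg_ret = (rng.random((n_mol, k)) < config.background_retention_rate) if k else np.zeros((n_mol, 0), bool)
        gene_variants = []
        for chrom, pos, alt, af in config.subclonal_variants:
            if chrom == gene.chrom and gene.start <= pos < gene.end:
                t = pos - gene.start if gene.strand == "+" else gene.end - 1 - pos
                alt_code = CODE[ord(alt)]
                if gene.strand == "-":
                    alt_code = COMP_CODE[alt_code]
                gene_variants.append((t, int(alt_code), pos, alt, af))
        carries = (np.column_stack([rng.random(n_mol) < af for *_, af in gene_variants])
                   if gene_variants else np.zeros((n_mol, 0), bool))

        active = np.nonzero(n_err + splice_hits.sum(1) + bg_ret.sum(1) + carries.sum(1))[0]
        exon_spans = [(s.sense_start, s.sense_end) for s in segs if s.kind == "exon"]
        for i in active:
            mol_id = f"{gene.gene_id}.m{i}"
            events: List[Tuple[int, int, str]] = []  # (sense_pos, alt_code, type)
            if n_err[i]:
                pos_arr = rng.choice(pre_len, size=int(n_err[i]), replace=False)
                for t in sorted(int(p) for p in pos_arr):
                    events.append((t, _draw_alt(rng, codes[t], config.transition_prob), "polymerase"))
            for j, seg in enumerate(intron_segs):
                if splice_hits[i, j]:
                    t = seg.sense_start + int(rng.integers(0, 2))
                    events.append((t, _draw_alt(rng, codes[t], config.transition_prob), "polymerase"))
            # retention: error at donor +1/+2 or acceptor -2/-1 of each intron
            retained = set()
            caused: Dict[int, int] = {}
            for j, seg in enumerate(intron_segs):
                crit = {seg.sense_start, seg.sense_start + 1, seg.sense_end - 2, seg.sense_end - 1}
                hit = any(t in crit for t, _a, ty in events if ty == "polymerase")
                if hit and rng.random() < config.retention_on_splice_error:
                    retained.add(j)
                    for t, _a, ty in events:
                        if t in crit:
                            caused[t] = j
                elif bg_ret[i, j]:
                    retained.add(j)
            for vi, (t, alt_code, gpos, alt, _af) in enumerate(gene_variants):
                if carries[i, vi]:
                    events.append((t, alt_code, "subclonal"))
            # expressed = position survives into the mature molecule
            def _expressed(t: int) -> bool:
                if any(a <= t < b for a, b in exon_spans):
                    return True
                for j, seg in enumerate(intron_segs):
                    if seg.sense_start <= t < seg.sense_end:
                        return j in retained
                return False

            changes = []
            for t, alt_code, etype in events:
                gpos = gene.sense_to_genomic(t)
                ref_code = codes[t]
                g_ref = genome[gene.chrom][gpos]
                g_alt_code = COMP_CODE[alt_code] if gene.strand == "-" else alt_code
                truth.append(SimTruth(
                    event_id=f"e{ev_counter}", molecule_id=mol_id, chrom=gene.chrom,
                    pos=gpos, type=etype, ref=g_ref, alt=BASES[int(g_alt_code)],
                    retained_intron=(f"{gene.gene_id}.i{caused[t]}" if t in caused else None),
                    expressed=_expressed(t),
                ))
                ev_counter += 1
                changes.append((t, int(alt_code)))
            gene_deltas[int(i)] = _MolDelta(retained=frozenset(retained), changes=changes)
        deltas[gene.gene_id] = gene_deltas
    return MoleculeSet(genes=list(genes), genome=genome, n_molecules=n_molecules,
                       deltas=deltas, truth=truth)


# ---------------------------------------------------------------------------
# Stage 3: reads
# ---------------------------------------------------------------------------

@dataclass
class SimReadSet:
    reads: List[AlignedRead]
    fastq: List[Tuple[str, str, np.ndarray]]
    truth: List[SimTruth]
    genome: dict
    genes: List[GeneModel]
    config: SimConfig
    read_molecule: Dict[str, str]


def _isoform_geometry(gene: GeneModel, retained: frozenset):
    """Mature segments, reference codes, and genomically contiguous runs
    for one splicing isoform."""
    segs = [s for s in gene.sense_segments()
            if s.kind == "exon" or s.intron_index in retained]
    m_off = []
    t = 0
    for s in segs:
        m_off.append(t)
        t += s.sense_end - s.sense_start
    mat_len = t
    # contiguous genomic runs: (m0, m1, anchor); g(t) = anchor +/- (t - m0)
    runs = []
    for s, m0 in zip(segs, m_off):
        length = s.sense_end - s.sense_start
        if runs:
            pm0, pm1, panchor = runs[-1]
            adjacent = (pm1 == m0) and (
                (gene.strand == "+" and panchor + (pm1 - pm0) == s.gstart)
                or (gene.strand == "-" and panchor - (pm1 - pm0) == s.gend - 1)
            )
            if adjacent:
                runs[-1] = (pm0, m0 + length, panchor)
                continue
        anchor = s.gstart if gene.strand == "+" else s.gend - 1
        runs.append((m0, m0 + length, anchor))
    return segs, m_off, mat_len, runs


def _sense_to_mature(segs, m_off, t: int) -> Optional[int]:
    for s, m0 in zip(segs, m_off):
        if s.sense_start <= t < s.sense_end:
            return m0 + (t - s.sense_start)
    return None


def _mature_to_genomic(runs, strand: str, m: int) -> int:
    for m0, m1, anchor in runs:
        if m0 <= m < m1:
            return anchor + (m - m0) if strand == "+" else anchor - (m - m0)
    raise ValueError("mature position outside isoform")


def _complex_cigar(segs, m_off, strand: str, st: int, L: int):
    """Genomic blocks and CIGAR for a read spanning splice junctions."""
    blocks = []
    for s, m0 in zip(segs, m_off):
        m1 = m0 + (s.sense_end - s.sense_start)
        a, b = max(st, m0), min(st + L, m1)
        if a >= b:
            continue
        if strand == "+":
            g0 = s.gstart + (a - m0)
            blocks.append((g0, g0 + (b - a)))
        else:
            g1 = s.gend - (a - m0)
            blocks.append((g1 - (b - a), g1))
    if strand == "-":
        blocks = blocks[::-1]
    merged = [blocks[0]]
    for b0, b1 in blocks[1:]:
        if merged[-1][1] == b0:
            merged[-1] = (merged[-1][0], b1)
        else:
            merged.append((b0, b1))
    cigar = []
    for i, (b0, b1) in enumerate(merged):
        if i:
            cigar.append(("N", b0 - merged[i - 1][1]))
        cigar.append(("M", b1 - b0))
    return merged[0][0], cigar


def simulate_reads(molset: MoleculeSet, config: SimConfig,
                   rng: Optional[np.random.Generator] = None) -> SimReadSet:
    """Sample reads from molecules and layer sequencing errors.

    Polymerase/subclonal changes are shared by all reads of a molecule;
    sequencing errors are drawn per read base at a quality-linked rate
    (``bad_cycles`` multiply the rate at specific machine cycles). SAM
    coordinates are the true genomic origin. Single-base read indels are
    planted at ``insertion_rate``/``deletion_rate`` on plus-strand,
    non-junction reads.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    L = config.read_length
    rpm = config.reads_per_molecule
    reads: List[AlignedRead] = []
    fastq: List[Tuple[str, str, np.ndarray]] = []
    truth = list(molset.truth)
    read_molecule: Dict[str, str] = {}
    ev_counter = len(truth)
    genome = molset.genome

    for gene in molset.genes:
        gid = gene.gene_id
        n_mol = molset.n_molecules[gid]
        gene_deltas = molset.deltas.get(gid, {})
        codes = gene.sense_codes(genome)
        groups: Dict[frozenset, List[int]] = {}
        for i in range(n_mol):
            retained = gene_deltas[i].retained if i in gene_deltas else frozenset()
            groups.setdefault(retained, []).append(i)
        for retained, mol_indices in sorted(groups.items(), key=lambda kv: sorted(kv[0])):
            segs, m_off, mat_len, runs = _isoform_geometry(gene, retained)
            if mat_len < L:
                continue
            mature_codes = np.concatenate(
                [codes[s.sense_start:s.sense_end] for s in segs]) if segs else np.zeros(0, np.uint8)
            mol_arr = np.repeat(np.asarray(mol_indices, dtype=np.int64), rpm)
            n_reads = len(mol_arr)
            starts = rng.integers(0, mat_len - L + 1, size=n_reads)
            R = mature_codes[starts[:, None] + np.arange(L)]
            refR = R.copy()
            # molecule-level changes
            for slot, i in enumerate(mol_indices):
                if i not in gene_deltas or not gene_deltas[i].changes:
                    continue
                rows = np.arange(slot * rpm, (slot + 1) * rpm)
                for t, alt_code in gene_deltas[i].changes:
                    mp = _sense_to_mature(segs, m_off, t)
                    if mp is None:
                        continue
                    rel = mp - starts[rows]
                    ok = (rel >= 0) & (rel < L)
                    R[rows[ok], rel[ok]] = alt_code
            # sequencing errors, quality model, bad cycles
            low = rng.random((n_reads, L)) < config.low_quality_fraction
            Q = np.where(low, config.low_qual, config.high_qual).astype(np.uint8)
            p = np.where(low, config.low_quality_error_rate, config.sequencing_error_rate)
            for cyc, fold in config.bad_cycles:
                if 0 <= cyc < L:
                    p[:, cyc] = np.minimum(p[:, cyc] * fold, 1.0)
            err = rng.random((n_reads, L)) < p
            er, ec = np.nonzero(err)
            if len(er):
                shift = rng.integers(1, 4, size=len(er)).astype(np.uint8)
                new = (R[er, ec] + shift) % 4
                R[er, ec] = new
            n_mm = (R != refR).sum(axis=1)
            # classification into simple vs junction-spanning reads
            run_m0 = np.asarray([r[0] for r in runs])
            run_m1 = np.asarray([r[1] for r in runs])
            run_anchor = np.asarray([r[2] for r in runs])
            ri = np.searchsorted(run_m0, starts, side="right") - 1
            simple = (starts + L) <= run_m1[ri]
            if gene.strand == "+":
                gpos = run_anchor[ri] + (starts - run_m0[ri])
            else:
                gpos = run_anchor[ri] - (starts - run_m0[ri]) - (L - 1)
            # orientation to genome
            if gene.strand == "-":
                Rg = COMP_CODE[R][:, ::-1]
                Qg = Q[:, ::-1]
            else:
                Rg, Qg = R, Q
            # indel planting (plus-strand simple reads only)
            p_ins, p_del = L * config.insertion_rate, L * config.deletion_rate
            u = rng.random(n_reads) if (p_ins or p_del) else None

            seq_bytes = np.frombuffer(b"ACGTN", dtype=np.uint8)[Rg]
            err_lo = np.searchsorted(er, np.arange(n_reads), side="left")
            err_hi = np.searchsorted(er, np.arange(n_reads), side="right")
            for r_idx in range(n_reads):
                i = int(mol_arr[r_idx])
                j = r_idx % rpm
                read_id = f"{gid}.m{i}.r{j}"
                mol_id = f"{gid}.m{i}"
                read_molecule[read_id] = mol_id
                seq = seq_bytes[r_idx].tobytes().decode("ascii")
                quals = Qg[r_idx].copy()
                st = int(starts[r_idx])
                if simple[r_idx]:
                    pos, cigar = int(gpos[r_idx]), [("M", L)]
                else:
                    pos, cigar = _complex_cigar(segs, m_off, gene.strand, st, L)
                # record this read's sequencing errors
                row_err = ec[err_lo[r_idx]:err_hi[r_idx]]
                for c in row_err:
                    mp = st + int(c)
                    g = _mature_to_genomic(runs, gene.strand, mp)
                    obs = R[r_idx, c]
                    g_alt = COMP_CODE[obs] if gene.strand == "-" else obs
                    truth.append(SimTruth(
                        event_id=f"e{ev_counter}", molecule_id=mol_id, chrom=gene.chrom,
                        pos=g, type="sequencing", ref=genome[gene.chrom][g],
                        alt=BASES[int(g_alt)], read_id=read_id,
                    ))
                    ev_counter += 1
                # single-base indels
                if u is not None and gene.strand == "+" and simple[r_idx]:
                    if u[r_idx] < p_ins:
                        k = int(rng.integers(12, L - 12))
                        ins_base = BASES[int(rng.integers(0, 4))]
                        seq = seq[:k] + ins_base + seq[k:L - 1]
                        quals = np.concatenate([quals[:k], [config.high_qual],
                                                quals[k:L - 1]]).astype(np.uint8)
                        cigar = [("M", k), ("I", 1), ("M", L - 1 - k)]
                        truth.append(SimTruth(
                            event_id=f"e{ev_counter}", molecule_id=mol_id, chrom=gene.chrom,
                            pos=pos + k, type="insertion", ref="-", alt=ins_base,
                            read_id=read_id))
                        ev_counter += 1
                    elif u[r_idx] < p_ins + p_del and pos + L < len(genome[gene.chrom]):
                        k = int(rng.integers(12, L - 12))
                        seq = seq[:k] + seq[k + 1:] + genome[gene.chrom][pos + L]
                        quals = np.concatenate([quals[:k], quals[k + 1:],
                                                [config.high_qual]]).astype(np.uint8)
                        cigar = [("M", k), ("D", 1), ("M", L - k)]
                        truth.append(SimTruth(
                            event_id=f"e{ev_counter}", molecule_id=mol_id, chrom=gene.chrom,
                            pos=pos + k, type="deletion",
                            ref=genome[gene.chrom][pos + k], alt="-", read_id=read_id))
                        ev_counter += 1
                read = AlignedRead(
                    read_id=read_id, chrom=gene.chrom, pos=pos, cigar=cigar,
                    seq=seq, quals=quals, mapq=60, n_mismatches=int(n_mm[r_idx]),
                    is_reverse=(gene.strand == "-"),
                )
                reads.append(read)
                # FASTQ carries the machine-orientation read
                if gene.strand == "-":
                    fastq.append((read_id, revcomp(seq), quals[::-1].copy()))
                else:
                    fastq.append((read_id, seq, quals.copy()))
    return SimReadSet(reads=reads, fastq=fastq, truth=truth, genome=genome,
                      genes=list(molset.genes), config=config,
                      read_molecule=read_molecule)


# ---------------------------------------------------------------------------
# Orchestration, outputs, truth summary
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    config: SimConfig
    genome: dict
    genes: List[GeneModel]
    molecules: MoleculeSet
    readset: SimReadSet

    def introns(self) -> List[IntronModel]:
        return [i for g in self.genes for i in g.intron_models(self.genome)]

    def orfs(self) -> List[OrfRecord]:
        return [g.orf_record(self.genome) for g in self.genes]

    def write(self, outdir) -> None:
        """Write genome.fa, genes.gff3, reads.fastq, reads.sam, truth.tsv
        and config.yaml. Byte-deterministic under the config seed."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genome(outdir / "genome.fa", self.genome)
        write_gff3(outdir / "genes.gff3", annotation_rows(self.genes))
        write_fastq(outdir / "reads.fastq", self.readset.fastq)
        ref_lengths = {c: len(s) for c, s in self.genome.items()}
        write_alignments(outdir / "reads.sam", self.readset.reads, ref_lengths)
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("event_id\tmolecule_id\tread_id\tchrom\tpos\ttype\tref\talt"
                     "\tretained_intron\texpressed\n")
            for t in self.readset.truth:
                fh.write(f"{t.event_id}\t{t.molecule_id}\t{t.read_id or '.'}\t{t.chrom}"
                         f"\t{t.pos}\t{t.type}\t{t.ref}\t{t.alt}"
                         f"\t{t.retained_intron or '.'}\t{int(t.expressed)}\n")
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(asdict(self.config), fh)


def simulate(config: SimConfig) -> SimResult:
    """Run all three stages (genome, molecules, reads) under one seed."""
    ss = np.random.SeedSequence(config.seed).spawn(3)
    genome, genes = simulate_genome(config, np.random.default_rng(ss[0]))
    molset = simulate_molecules(genome, genes, config, np.random.default_rng(ss[1]))
    readset = simulate_reads(molset, config, np.random.default_rng(ss[2]))
    return SimResult(config=config, genome=genome, genes=genes,
                     molecules=molset, readset=readset)


def truth_summary(readset: SimReadSet, read_length: Optional[int] = None,
                  trim: int = 10, min_baseq: int = 39, min_mapq: int = 30,
                  max_mm: int = 2, max_obs: int = 1,
                  bad_cycles: Sequence[int] = ()) -> dict:
    """Expected measured mismatch rate under a filter configuration,
    computed from the truth table and read geometry alone (no pileup).

    Walks the reads that would pass the gates, counts their unmasked
    quality-passing bases as the denominator, maps each truth event onto
    the counted bases it appears in, applies the recurrent-identical-
    mismatch rule (dropping affected positions' coverage from the
    denominator) and returns the surviving-event rate.
    """
    cfg = readset.config
    L = read_length or cfg.read_length
    bad = set(bad_cycles)
    # index events by chrom -> sorted positions
    mol_events: Dict[str, list] = {}
    read_events: Dict[str, list] = {}
    for t in readset.truth:
        if t.type in ("insertion", "deletion"):
            continue
        if t.type == "sequencing":
            read_events.setdefault(t.read_id, []).append(t)
        elif t.expressed:
            mol_events.setdefault(t.molecule_id, []).append(t)

    denom = 0
    cov_at: Dict[Tuple[str, int], int] = {}
    appearances: Dict[Tuple[str, int, str], int] = {}
    interesting = set()
    for tl in mol_events.values():
        interesting.update((t.chrom, t.pos) for t in tl)
    for tl in read_events.values():
        interesting.update((t.chrom, t.pos) for t in tl)

    for read in readset.reads:
        if read.mapq < min_mapq:
            continue
        if not (len(read.cigar) == 1 and read.cigar[0] == ("M", L)):
            continue
        if read.n_mismatches is None or read.n_mismatches > max_mm:
            continue
        counted = np.zeros(L, dtype=bool)
        for j in range(trim, L - trim):
            cyc = L - 1 - j if read.is_reverse else j
            if cyc in bad:
                continue
            if read.quals[j] >= min_baseq:
                counted[j] = True
        denom += int(counted.sum())
        # coverage at event positions
        span = [(read.chrom, read.pos + j) for j in range(L) if counted[j]]
        for key in span:
            if key in interesting:
                cov_at[key] = cov_at.get(key, 0) + 1
        # final observed base per event position in this read
        mol_id = readset.read_molecule[read.read_id]
        finals: Dict[Tuple[str, int], str] = {}
        for t in mol_events.get(mol_id, []):
            j = t.pos - read.pos
            if 0 <= j < L and counted[j]:
                finals[(t.chrom, t.pos)] = t.alt
        for t in read_events.get(read.read_id, []):
            j = t.pos - read.pos
            if 0 <= j < L and counted[j]:
                finals[(t.chrom, t.pos)] = t.alt  # sequencing overrides
        for (chrom, pos), alt in finals.items():
            ref = readset.genome[chrom][pos]
            if alt != ref:
                appearances[(chrom, pos, alt)] = appearances.get((chrom, pos, alt), 0) + 1

    dropped_pos = set()
    for (chrom, pos, alt), n in appearances.items():
        if n > max_obs:
            dropped_pos.add((chrom, pos))
    surviving = sum(n for (chrom, pos, alt), n in appearances.items()
                    if (chrom, pos) not in dropped_pos)
    denom -= sum(cov_at.get(key, 0) for key in dropped_pos)
    return {
        "expected_mismatches": surviving,
        "expected_bases": denom,
        "expected_rate": surviving / denom if denom else float("nan"),
        "dropped_positions": len(dropped_pos),
    }
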
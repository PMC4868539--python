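"""Core domain types and readers/writers for the standard formats the
pipeline touches: FASTA (genome, CDS), GFF3/BED (introns, ORFs), SAM/BAM
(alignments), FASTQ (simulated reads) and TSV for tabular results.

All internal coordinates are 0-based half-open on the forward genomic
strand; conversion to/from 1-based (GFF3) or BED conventions happens only
at the I/O boundary. Secondary and supplementary alignments are never
yielded. Reference bases are uppercased on load; an 'N' on either the read
or the reference never counts as a match or a mismatch.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import encode, revcomp

CIGAR_OPS = "MIDNSHP=XB"
QUERY_CONSUMING = frozenset("MIS=X")
REF_CONSUMING = frozenset("MDN=X")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class AlignedRead:
    """One mapped read.

    ``pos`` is the 0-based leftmost reference coordinate; ``cigar`` is a
    list of (op, length) with op in ``MIDNSHP=X``; ``n_mismatches`` counts
    substitutions only (indels excluded). ``seq``/``quals`` are stored in
    reference (forward genomic) orientation, with ``is_reverse`` recording
    the original sequencing orientation.
    """

    read_id: str
    chrom: str
    pos: int
    cigar: list
    seq: str
    quals: np.ndarray
    mapq: int = 60
    n_mismatches: Optional[int] = None
    is_duplicate: bool = False
    is_reverse: bool = False

    def query_length(self) -> int:
        return sum(n for op, n in self.cigar if op in QUERY_CONSUMING)

    def reference_span(self) -> int:
        return sum(n for op, n in self.cigar if op in REF_CONSUMING)

    def validate(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError(
                f"read {self.read_id}: seq length {len(self.seq)} != "
                f"qual length {len(self.quals)}"
            )
        if self.query_length() != len(self.seq):
            raise ValueError(
                f"read {self.read_id}: CIGAR consumes {self.query_length()} "
                f"query bases but seq has {len(self.seq)}"
            )
        if self.pos < 0:
            raise ValueError(f"read {self.read_id}: negative position")

    def aligned_blocks(self):
        """Yield (ref_start, query_start, length) for each aligned block."""
        rpos, qpos = self.pos, 0
        for op, n in self.cigar:
            if op in "M=X":
                yield rpos, qpos, n
                rpos += n
                qpos += n
            elif op in "DN":
                rpos += n
            elif op in "IS":
                qpos += n
            # H and P consume nothing we track


@dataclass(frozen=True, slots=True)
class GenomeInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str = "+"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class IntronModel:
    """A single intron with strand-aware boundary dinucleotides.

    ``donor_dinuc``/``acceptor_dinuc`` are read 5'->3' on the transcribed
    strand, so a canonical intron is always GT..AG regardless of genomic
    strand.
    """

    interval: GenomeInterval
    donor_dinuc: str
    acceptor_dinuc: str
    gene_id: str = ""

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    def is_canonical(self) -> bool:
        return self.donor_dinuc == "GT" and self.acceptor_dinuc == "AG"


@dataclass(frozen=True, slots=True)
class OrfRecord:
    """A protein-coding sequence: starts ATG, ends with a stop, no internal
    in-frame stop, length divisible by 3."""

    gene_id: str
    cds_seq: str

    def validate(self) -> None:
        s = self.cds_seq
        if len(s) % 3 != 0 or len(s) < 6:
            raise ValueError(f"{self.gene_id}: CDS length {len(s)} not a codon multiple >= 6")
        if s[:3] != "ATG":
            raise ValueError(f"{self.gene_id}: CDS does not start with ATG")
        if s[-3:] not in STOP_CODONS:
            raise ValueError(f"{self.gene_id}: CDS does not end with a stop codon")
        for i in range(3, len(s) - 3, 3):
            if s[i:i + 3] in STOP_CODONS:
                raise ValueError(f"{self.gene_id}: internal stop at codon {i // 3}")


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_genome(path) -> dict:
    """Load a FASTA file into a dict of uppercase sequences."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome(path, genome: dict) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_orf_fasta(path) -> list:
    """Load CDS sequences from FASTA as OrfRecords (invalid ones skipped
    with a warning)."""
    orfs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        orf = OrfRecord(gene_id=rec.id, cds_seq=str(rec.seq).upper())
        try:
            orf.validate()
        except ValueError as exc:
            warnings.warn(f"skipping ORF {rec.id}: {exc}")
            continue
        orfs.append(orf)
    return orfs


def write_fastq(path, records: Iterable[tuple]) -> None:
    """Write (read_id, seq, quals) triples as FASTQ (Phred+33)."""
    with open(path, "w") as fh:
        for read_id, seq, quals in records:
            qstr = "".join(chr(int(q) + 33) for q in quals)
            fh.write(f"@{read_id}\n{seq}\n+\n{qstr}\n")


def read_fastq(path) -> Iterator[tuple]:
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = np.asarray(rec.letter_annotations["phred_quality"], dtype=np.uint8)
        yield rec.id, str(rec.seq), quals


# ---------------------------------------------------------------------------
# SAM / BAM
# ---------------------------------------------------------------------------

def _recount_mismatches(read: AlignedRead, genome: dict) -> int:
    ref = genome[read.chrom]
    n = 0
    for rpos, qpos, length in read.aligned_blocks():
        rseq = ref[rpos:rpos + length]
        qseq = read.seq[qpos:qpos + length]
        n += sum(1 for a, b in zip(rseq, qseq) if a != "N" and b != "N" and a != b.upper())
    return n


def read_alignments(path, region: Optional[GenomeInterval] = None,
                    genome: Optional[dict] = None) -> Iterator[AlignedRead]:
    """Stream primary alignments from a SAM/BAM file.

    ``n_mismatches`` is populated from the NM tag (minus indel bases) when
    present, otherwise recomputed against ``genome`` if given. Records whose
    seq/qual lengths disagree are skipped with a warning naming the read.
    """
    with pysam.AlignmentFile(str(path), require_index=False) as af:
        for aln in af:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if region is not None:
                if aln.reference_name != region.chrom:
                    continue
                if aln.reference_end <= region.start or aln.reference_start >= region.end:
                    continue
            seq = aln.query_sequence or ""
            quals = aln.query_qualities
            if quals is None:
                quals = np.zeros(len(seq), dtype=np.uint8)
            else:
                quals = np.asarray(quals, dtype=np.uint8)
            if len(seq) != len(quals):
                warnings.warn(f"skipping malformed record {aln.query_name}: "
                              f"seq/qual length mismatch")
                continue
            cigar = [(CIGAR_OPS[op], n) for op, n in (aln.cigartuples or [])]
            read = AlignedRead(
                read_id=aln.query_name,
                chrom=aln.reference_name,
                pos=aln.reference_start,
                cigar=cigar,
                seq=seq.upper(),
                quals=quals,
                mapq=aln.mapping_quality,
                n_mismatches=None,
                is_duplicate=aln.is_duplicate,
                is_reverse=aln.is_reverse,
            )
            if aln.has_tag("NM"):
                indel = sum(n for op, n in cigar if op in "ID")
                read.n_mismatches = max(0, aln.get_tag("NM") - indel)
            elif genome is not None:
                read.n_mismatches = _recount_mismatches(read, genome)
            yield read


def write_alignments(path, reads: Iterable[AlignedRead], ref_lengths: dict) -> None:
    """Write AlignedReads as a (headered) SAM file.

    The NM tag is emitted as substitutions + indel bases so that a round
    trip through :func:`read_alignments` restores ``n_mismatches``.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": int(length)} for name, length in ref_lengths.items()],
    }
    op_codes = {op: i for i, op in enumerate(CIGAR_OPS)}
    with pysam.AlignmentFile(str(path), "w", header=header, add_sam_header=True) as af:
        tid = {name: i for i, name in enumerate(ref_lengths)}
        for read in reads:
            a = pysam.AlignedSegment(af.header)
            a.query_name = read.read_id
            a.flag = (16 if read.is_reverse else 0) | (1024 if read.is_duplicate else 0)
            a.reference_id = tid[read.chrom]
            a.reference_start = read.pos
            a.mapping_quality = read.mapq
            a.cigartuples = [(op_codes[op], n) for op, n in read.cigar]
            a.query_sequence = read.seq
            a.query_qualities = [int(q) for q in read.quals]
            if read.n_mismatches is not None:
                indel = sum(n for op, n in read.cigar if op in "ID")
                a.set_tag("NM", int(read.n_mismatches) + indel)
            af.write(a)


# ---------------------------------------------------------------------------
# Annotation (GFF3 / BED)
# ---------------------------------------------------------------------------

def _intron_from_interval(iv: GenomeInterval, genome: dict, gene_id: str = "") -> Optional[IntronModel]:
    if len(iv) < 4:
        warnings.warn(f"skipping intron {iv.chrom}:{iv.start}-{iv.end}: shorter than 4 bp")
        return None
    ref = genome[iv.chrom]
    left = ref[iv.start:iv.start + 2]
    right = ref[iv.end - 2:iv.end]
    if iv.strand == "+":
        donor, acceptor = left, right
    else:
        donor, acceptor = revcomp(right), revcomp(left)
    return IntronModel(interval=iv, donor_dinuc=donor, acceptor_dinuc=acceptor, gene_id=gene_id)


def _read_bed_introns(path, genome: dict) -> list:
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=cols, usecols=range(6), dtype={"chrom": str})
    introns = []
    for row in df.itertuples(index=False):
        strand = row.strand if row.strand in ("+", "-") else "+"
        iv = GenomeInterval(row.chrom, int(row.start), int(row.end), strand)
        intron = _intron_from_interval(iv, genome, gene_id=str(row.name))
        if intron is not None:
            introns.append(intron)
    return introns


def _gff_gene_id(db, feature) -> str:
    f = feature
    for _ in range(5):
        if f.featuretype == "gene":
            return f.id
        parents = list(db.parents(f, level=1))
        if not parents:
            break
        f = parents[0]
    return f.id


def _read_gff3(path, genome: dict):
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    introns = []
    # explicit intron features if present, else derive from exon gaps per mRNA
    explicit = list(db.features_of_type("intron"))
    if explicit:
        for f in explicit:
            iv = GenomeInterval(f.seqid, f.start - 1, f.end, f.strand or "+")
            intron = _intron_from_interval(iv, genome, gene_id=_gff_gene_id(db, f))
            if intron is not None:
                introns.append(intron)
    else:
        for mrna in db.features_of_type("mRNA"):
            exons = sorted(db.children(mrna, featuretype="exon"), key=lambda e: e.start)
            gene_id = _gff_gene_id(db, mrna)
            for a, b in zip(exons, exons[1:]):
                if b.start - 1 - a.end <= 0:
                    continue
                iv = GenomeInterval(mrna.seqid, a.end, b.start - 1, mrna.strand or "+")
                intron = _intron_from_interval(iv, genome, gene_id=gene_id)
                if intron is not None:
                    introns.append(intron)

    orfs = []
    for mrna in db.features_of_type("mRNA"):
        cds = sorted(db.children(mrna, featuretype="CDS"), key=lambda c: c.start)
        if not cds:
            continue
        seq = "".join(genome[c.seqid][c.start - 1:c.end] for c in cds)
        if (mrna.strand or "+") == "-":
            seq = revcomp(seq)
        orf = OrfRecord(gene_id=_gff_gene_id(db, mrna), cds_seq=seq)
        try:
            orf.validate()
        except ValueError as exc:
            warnings.warn(f"skipping ORF for {mrna.id}: {exc}")
            continue
        orfs.append(orf)
    return introns, orfs


def read_annotation(path, fmt: str, genome: dict):
    """Read gene annotation, returning (introns, orfs).

    ``fmt`` is "gff3" (1-based inclusive coordinates) or "bed" (0-based
    half-open; introns only). Donor/acceptor dinucleotides are filled from
    the genome, strand-aware.
    """
    if fmt == "bed":
        return _read_bed_introns(path, genome), []
    if fmt == "gff3":
        return _read_gff3(path, genome)
    raise ValueError(f"unknown annotation format {fmt!r}")


def write_intron_bed(path, introns: Iterable[IntronModel]) -> None:
    with open(path, "w") as fh:
        for intron in introns:
            iv = intron.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{intron.gene_id or '.'}\t0\t{iv.strand}\n")


def write_gff3(path, rows: Iterable[tuple]) -> None:
    """Write GFF3 rows given as (chrom, source, type, start0, end0, strand,
    attributes-string); internal half-open coordinates are converted to the
    1-based inclusive convention on output."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, source, ftype, start, end, strand, attrs in rows:
            fh.write(f"{chrom}\t{source}\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n")


def gff3_to_internal(start: int, end: int) -> tuple:
    """GFF3 1-based inclusive -> internal 0-based half-open."""
    return start - 1, end


def internal_to_gff3(start: int, end: int) -> tuple:
    """Internal 0-based half-open -> GFF3 1-based inclusive."""
    return start + 1, end


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
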
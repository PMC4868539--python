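"""Splice-site windows, donor/acceptor error profiles, context rates and
intron retention."""
import numpy as np
import pandas as pd
import pytest

from polfid import junction_analysis as ja
from polfid import pileup_counts, read_filters
from polfid.iomodel import GenomeInterval, IntronModel
from polfid.simulate import SimConfig, simulate

from conftest import make_read


def _intron(start, end, strand="+", donor="GT", acceptor="AG"):
    return IntronModel(interval=GenomeInterval("chr1", start, end, strand),
                       donor_dinuc=donor, acceptor_dinuc=acceptor, gene_id="g")


class TestCanonical:
    def test_gt_ag_kept(self):
        assert ja.canonical_introns([_intron(10, 100)]) == [_intron(10, 100)]

    def test_gc_ag_dropped(self):
        assert ja.canonical_introns([_intron(10, 100, donor="GC")]) == []

    def test_minus_strand_orientation_already_applied(self):
        """An intron whose plus-strand text is CT..AC is GT..AG on the
        minus strand, hence canonical (orientation done at annotation
        load)."""
        i = _intron(10, 100, strand="-")
        assert ja.canonical_introns([i]) == [i]


class TestWindows:
    def test_plus_strand_donor_coordinates(self):
        """Intron [100,200), flank 10: donor window spans [90,110) with
        offset +1 at genomic 100."""
        (donor, _acc) = ja.build_windows([_intron(100, 200)], flank=10)[:2]
        assert donor.side == "donor"
        span = (donor.positions.min(), donor.positions.max() + 1)
        assert span == (90, 110)
        assert donor.positions[list(donor.offsets).index(1)] == 100
        assert donor.positions[list(donor.offsets).index(-1)] == 99

    def test_minus_strand_donor_mirror(self):
        """Same intron on -: donor window spans [190,210), +1 at 199."""
        donor = ja.build_windows([_intron(100, 200, strand="-")], flank=10)[0]
        span = (donor.positions.min(), donor.positions.max() + 1)
        assert span == (190, 210)
        assert donor.positions[list(donor.offsets).index(1)] == 199
        assert donor.positions[list(donor.offsets).index(2)] == 198

    def test_acceptor_coordinates(self):
        _d, acc = ja.build_windows([_intron(100, 200)], flank=10)
        assert acc.positions[list(acc.offsets).index(1)] == 199  # G of AG
        assert acc.positions[list(acc.offsets).index(2)] == 198
        assert acc.positions[list(acc.offsets).index(-1)] == 200

    def test_flank_20_variant(self):
        donor = ja.build_windows([_intron(100, 200)], flank=20)[0]
        assert len(donor.offsets) == 40
        assert donor.positions.min() == 80 and donor.positions.max() == 119

    def test_short_intron_truncated_with_flag(self):
        donor = ja.build_windows([_intron(100, 106)], flank=10)[0]
        assert donor.truncated
        assert donor.offsets.max() == 6


class TestProfiles:
    def _counts_with(self, genome_len, entries):
        """entries: {pos: (coverage, errors)} on an all-A chr1."""
        counts = pileup_counts.PositionCounts.empty({"chr1": "A" * genome_len})
        for pos, (cov, err) in entries.items():
            counts.base_counts["chr1"][0, pos] = cov - err
            counts.base_counts["chr1"][1, pos] = err  # C alt
        return counts

    def test_pooled_rate_is_total_over_total(self):
        """Two donors with 1/100 and 0/100 at offset +1 pool to 0.005."""
        introns = [_intron(100, 200), _intron(300, 400)]
        windows = [w for w in ja.build_windows(introns, flank=2) if w.side == "donor"]
        counts = self._counts_with(500, {100: (100, 1), 300: (100, 0)})
        prof = ja.junction_error_profile(counts, windows)["donor"]
        df = prof.to_dataframe().set_index("offset")
        assert df.loc[1, "rate"] == pytest.approx(0.005)

    def test_pooling_beats_per_junction_mean(self):
        """Unbalanced coverage: pooled rate != mean of per-junction rates."""
        introns = [_intron(100, 200), _intron(300, 400)]
        windows = [w for w in ja.build_windows(introns, flank=2) if w.side == "donor"]
        counts = self._counts_with(500, {100: (1000, 10), 300: (10, 1)})
        prof = ja.junction_error_profile(counts, windows)["donor"]
        rate = prof.to_dataframe().set_index("offset").loc[1, "rate"]
        assert rate == pytest.approx(11 / 1010)
        assert rate != pytest.approx((10 / 1000 + 1 / 10) / 2)

    def test_empty_window_list_rejected(self):
        counts = self._counts_with(10, {})
        with pytest.raises(ValueError):
            ja.junction_error_profile(counts, [])

    def test_error_free_simulation_flat_zero(self, clean_sim):
        introns = clean_sim.introns()
        kept = read_filters.apply_read_filters(clean_sim.readset.reads,
                                               read_filters.FilterConfig())
        counts = pileup_counts.pileup(kept, clean_sim.genome)
        profs = ja.junction_error_profile(counts, ja.build_windows(introns))
        for prof in profs.values():
            assert prof.errors.sum() == 0


def _donor_error_sim(seed, minus_fraction):
    cfg = SimConfig(seed=seed, n_genes=8, n_introns_range=(1, 1),
                    coverage_target=40, polymerase_error_rate=0.0,
                    sequencing_error_rate=0.0, low_quality_fraction=0.0,
                    splice_error_rate=0.3, retention_on_splice_error=1.0,
                    minus_strand_fraction=minus_fraction)
    res = simulate(cfg)
    introns = res.introns()
    retained, _spliced = ja.select_junction_spanning_reads(res.readset.reads, introns)
    kept = read_filters.apply_read_filters(retained, read_filters.FilterConfig())
    counts = pileup_counts.pileup(kept, res.genome)
    return ja.junction_error_profile(counts, ja.build_windows(introns))["donor"]


class TestDonorSignature:
    def test_retained_reads_peak_at_plus1_plus2(self):
        """Donor-motif polymerase errors localize exactly at offsets +1/+2
        in the retained-read profile (no sequencing noise)."""
        prof = _donor_error_sim(seed=71, minus_fraction=0.5)
        df = prof.to_dataframe().set_index("offset")
        assert df.loc[1, "errors"] > 0 and df.loc[2, "errors"] > 0
        others = df.drop(index=[1, 2])
        assert others["errors"].sum() == 0

    def test_strand_symmetry_of_localization(self):
        """All-plus and all-minus gene sets localize the signal at the
        same offsets."""
        for frac in (0.0, 1.0):
            prof = _donor_error_sim(seed=72, minus_fraction=frac)
            df = prof.to_dataframe().set_index("offset")
            nonzero = set(df[df["errors"] > 0].index)
            assert nonzero <= {1, 2} and nonzero


class TestRetention:
    def test_arithmetic(self):
        """10 retained transcripts (spanning both boundaries) vs 90 spliced
        junction reads -> 0.10."""
        intron = _intron(100, 200)
        reads = []
        for i in range(90):
            reads.append(make_read("A" * 20, pos=90, read_id=f"s{i}",
                                   cigar=[("M", 10), ("N", 100), ("M", 10)]))
        for i in range(10):  # donor-boundary spanning
            reads.append(make_read("A" * 20, pos=92, read_id=f"t{i}"))
        for i in range(10):  # acceptor-boundary spanning
            reads.append(make_read("A" * 20, pos=192, read_id=f"u{i}"))
        table, pooled = ja.intron_retention_rate(reads, [intron])
        assert pooled == pytest.approx(0.10)
        assert table.loc[0, "retained"] == 10 and table.loc[0, "spliced"] == 90

    def test_all_spliced_gives_zero(self, clean_sim):
        _table, pooled = ja.intron_retention_rate(clean_sim.readset.reads,
                                                  clean_sim.introns())
        assert pooled == 0.0

    def test_no_junction_reads_undefined(self):
        table, pooled = ja.intron_retention_rate([], [_intron(100, 200)])
        assert np.isnan(table.loc[0, "retention"]) and np.isnan(pooled)

    def test_min_overhang_excludes_short_overlaps(self):
        intron = _intron(100, 200)
        read = make_read("A" * 10, pos=97)  # 3 bases past the donor boundary
        assert ja.classify_read_by_intron(read, intron, min_overhang=6) is None

    def test_planted_retention_recovered(self):
        """Background retention probability 0.2 is recovered within 3
        binomial SD of the junction-read estimate."""
        cfg = SimConfig(seed=77, n_genes=10, n_introns_range=(1, 2),
                        exon_length_range=(250, 350), intron_length_range=(60, 80),
                        coverage_target=40, polymerase_error_rate=0.0,
                        sequencing_error_rate=0.0, low_quality_fraction=0.0,
                        background_retention_rate=0.2)
        res = simulate(cfg)
        table, pooled = ja.intron_retention_rate(res.readset.reads, res.introns())
        n = int(table["retained"].sum() + table["spliced"].sum())
        assert n > 300
        sd = np.sqrt(0.2 * 0.8 / n)
        assert abs(pooled - 0.2) < 3 * sd


class TestContextProfile:
    def _uniform_counts(self, seed=5, n=3000, cov=1000):
        rng = np.random.default_rng(seed)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=n))}
        counts = pileup_counts.PositionCounts.empty(genome)
        ref = counts.ref_codes["chr1"]
        for p in range(n):
            counts.base_counts["chr1"][ref[p], p] = cov
        return genome, counts

    def test_uniform_errors_normalize_to_one(self):
        genome, counts = self._uniform_counts()
        ref = counts.ref_codes["chr1"]
        for p in range(0, 3000, 3):  # one error per third position
            alt = (ref[p] + 1) % 4
            counts.base_counts["chr1"][ref[p], p] -= 1
            counts.base_counts["chr1"][alt, p] += 1
        profs = ja.trinucleotide_profile(counts, genome)
        tri = profs["tri"].dropna(subset=["normalized"])
        weighted = (tri["normalized"] * tri["bases"]).sum() / tri["bases"].sum()
        assert weighted == pytest.approx(1.0)
        mono = profs["mono"].dropna(subset=["normalized"])
        assert ((mono["normalized"] - 1).abs() < 0.35).all()

    def test_planted_context_bias_recovered(self):
        """5x elevated errors at the C of ACG show up as a 5x normalized
        rate at that context position."""
        genome, counts = self._uniform_counts(seed=6)
        ref = counts.ref_codes["chr1"]
        seq = genome["chr1"]
        for p in range(1, 2999):
            is_acg_center = seq[p - 1:p + 2] == "ACG"
            n_err = 5 if is_acg_center else 1
            alt = (ref[p] + 1) % 4
            counts.base_counts["chr1"][ref[p], p] -= n_err
            counts.base_counts["chr1"][alt, p] += n_err
        tri = ja.trinucleotide_profile(counts, genome)["tri"]
        tri = tri.set_index(["context", "position"])
        acg_mid = tri.loc[("ACG", 1), "rate"]
        background = tri.drop(index=("ACG", 1))["rate"].dropna()
        assert acg_mid == pytest.approx(5 * background.median(), rel=0.05)
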
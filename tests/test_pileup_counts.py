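"""Pileup counting, recurrent-mismatch filter, rates, indels and the null
mismatch-count distribution."""
import numpy as np
import pytest
from scipy import stats

from polfid import iomodel, pileup_counts, read_filters
from polfid.pileup_counts import (PileupError, count_indels,
                                  expected_mismatch_distribution,
                                  filter_recurrent, overall_error_rate, pileup,
                                  recurrent_filter_sweep)
from polfid.simulate import SimConfig, simulate, truth_summary
from polfid.cli import RunConfig, run_error_pipeline

from conftest import make_read


def brute_force_recount(reads, genome, min_mapq=30, min_baseq=39):
    """Independent per-base oracle: walk every aligned base of every read
    and tally into dicts."""
    cov, alts = {}, {}
    for read in reads:
        if read.mapq < min_mapq:
            continue
        ref = genome[read.chrom]
        for rpos, qpos, n in read.aligned_blocks():
            for k in range(n):
                base = read.seq[qpos + k]
                refb = ref[rpos + k]
                if base == "N" or refb == "N" or read.quals[qpos + k] < min_baseq:
                    continue
                key = (read.chrom, rpos + k)
                cov[key] = cov.get(key, 0) + 1
                if base != refb:
                    akey = (read.chrom, rpos + k, base)
                    alts[akey] = alts.get(akey, 0) + 1
    return cov, alts


def assert_counts_equal_oracle(counts, cov, alts, genome):
    for chrom in genome:
        c = counts.coverage(chrom)
        got_cov = {(chrom, int(p)): int(c[p]) for p in np.nonzero(c)[0]}
        assert got_cov == {k: v for k, v in cov.items() if k[0] == chrom}
        bc = counts.base_counts[chrom]
        ref = counts.ref_codes[chrom]
        got_alts = {}
        for b, letter in enumerate("ACGT"):
            for p in np.nonzero(bc[b])[0]:
                if ref[p] != b:
                    got_alts[(chrom, int(p), letter)] = int(bc[b, p])
        assert got_alts == {k: v for k, v in alts.items() if k[0] == chrom}


class TestPileup:
    def test_direct_count_example(self):
        """5 reads over a position, one carrying G over ref A."""
        genome = {"chr1": "A" * 40}
        reads = [make_read("A" * 30, pos=0, read_id=f"r{i}") for i in range(4)]
        reads.append(make_read("A" * 15 + "G" + "A" * 14, pos=0, read_id="r4"))
        counts = pileup(reads, genome, min_baseq=30)
        assert counts.coverage("chr1")[15] == 5
        assert counts.base_counts["chr1"][2, 15] == 1  # G
        assert counts.alt_matrix("chr1")[:, 15].sum() == 1

    def test_masked_end_mismatch_not_counted(self):
        genome = {"chr1": "A" * 100}
        read = make_read("C" + "A" * 75, pos=0)  # mismatch at read start
        masked = read_filters.mask_ends(read, 10)
        counts = pileup([masked], genome, min_baseq=30)
        assert counts.alt_matrix("chr1").sum() == 0
        assert counts.coverage("chr1")[0] == 0

    def test_low_quality_base_not_counted(self):
        genome = {"chr1": "A" * 100}
        quals = np.full(76, 40)
        quals[30] = 30  # below the Q39 floor
        read = make_read("A" * 30 + "C" + "A" * 45, quals=quals)
        counts = pileup([read], genome, min_baseq=39)
        assert counts.alt_matrix("chr1").sum() == 0
        assert counts.coverage("chr1")[30] == 0

    def test_low_mapq_read_excluded(self):
        genome = {"chr1": "A" * 100}
        read = make_read("A" * 76, mapq=10)
        counts = pileup([read], genome, min_mapq=30, min_baseq=30)
        assert counts.coverage("chr1").sum() == 0

    def test_overhanging_read_fatal(self):
        genome = {"chr1": "A" * 50}
        read = make_read("A" * 76, pos=40)
        with pytest.raises(PileupError, match="overhang"):
            pileup([read], genome)

    def test_matches_brute_force_on_simulation(self, small_sim):
        """Exact oracle equivalence on a synthetic dataset including
        spliced and reverse-strand reads."""
        kept = read_filters.apply_read_filters(
            small_sim.readset.reads, read_filters.FilterConfig())
        counts = pileup(kept, small_sim.genome)
        cov, alts = brute_force_recount(kept, small_sim.genome)
        assert_counts_equal_oracle(counts, cov, alts, small_sim.genome)

    def test_spliced_reads_counted_per_block(self):
        genome = {"chr1": "A" * 200}
        read = make_read("A" * 20, pos=10, cigar=[("M", 10), ("N", 50), ("M", 10)])
        counts = pileup([read], genome, min_baseq=30)
        cov = counts.coverage("chr1")
        assert cov[10:20].sum() == 10 and cov[70:80].sum() == 10
        assert cov[20:70].sum() == 0


class TestFilterRecurrent:
    def _counts(self, alt_spec):
        """Build counts over a 10 bp A-genome; alt_spec: {pos: {base: n}}."""
        genome = {"chr1": "A" * 10}
        counts = pileup_counts.PositionCounts.empty(genome)
        counts.base_counts["chr1"][0, :] = 10  # baseline ref coverage
        for pos, spec in alt_spec.items():
            for base, n in spec.items():
                counts.base_counts["chr1"]["ACGT".index(base), pos] += n
        return counts

    def test_recurrent_identical_mismatch_dropped(self):
        counts = filter_recurrent(self._counts({3: {"C": 2}}), max_obs=1)
        assert counts.dropped["chr1"][3]

    def test_singleton_retained(self):
        counts = filter_recurrent(self._counts({3: {"C": 1}}), max_obs=1)
        assert not counts.dropped["chr1"].any()

    def test_two_distinct_alts_retained(self):
        """Identical means same (position, alternative base)."""
        counts = filter_recurrent(self._counts({3: {"C": 1, "G": 1}}), max_obs=1)
        assert not counts.dropped["chr1"].any()

    def test_max_obs_none_is_identity(self):
        base = self._counts({2: {"C": 5}, 7: {"T": 1}})
        out = filter_recurrent(base, max_obs=None)
        assert not out.dropped["chr1"].any()
        assert np.array_equal(out.base_counts["chr1"], base.base_counts["chr1"])

    def test_dropped_coverage_leaves_denominator(self):
        counts = filter_recurrent(self._counts({3: {"C": 2}}), max_obs=1)
        est = overall_error_rate(counts)
        # 9 retained positions x 10 ref bases, zero mismatches
        assert (est.total_mismatches, est.total_bases) == (0, 90)
        est_inc = overall_error_rate(counts, include_dropped=True)
        assert est_inc.total_bases == 102 and est_inc.total_mismatches == 2

    def test_sweep_monotone_in_max_obs(self):
        counts = self._counts({1: {"C": 1}, 3: {"C": 2}, 5: {"G": 4}})
        df = recurrent_filter_sweep(counts, [1, 2, 4, None])
        assert list(df["mismatches"]) == sorted(df["mismatches"])
        assert df["rate"].iloc[-1] == pytest.approx(7 / 107)


class TestOverallRate:
    def test_simple_arithmetic(self):
        genome = {"chr1": "A" * 20}
        counts = pileup_counts.PositionCounts.empty(genome)
        counts.base_counts["chr1"][0, :10] = 20  # 200 bases
        counts.base_counts["chr1"][0, 0] -= 1
        counts.base_counts["chr1"][2, 0] += 1   # one G mismatch
        est = overall_error_rate(counts)
        assert est.rate == pytest.approx(0.005)

    def test_error_free_simulation_rate_zero(self, clean_sim):
        _counts, est = run_error_pipeline(clean_sim.readset.reads,
                                          clean_sim.genome, RunConfig())
        assert est.total_mismatches == 0

    def test_zero_coverage_raises(self):
        counts = pileup_counts.PositionCounts.empty({"chr1": "AAAA"})
        with pytest.raises(PileupError, match="undefined"):
            overall_error_rate(counts)

    def test_planted_rate_recovered_within_3sd(self):
        """Combined per-base error 1e-3 is recovered to binomial accuracy."""
        cfg = SimConfig(seed=21, n_genes=30, n_introns_range=(0, 0),
                        exon_length_range=(900, 1200), coverage_target=30,
                        polymerase_error_rate=5e-4, sequencing_error_rate=5e-4,
                        low_quality_fraction=0.0)
        res = simulate(cfg)
        _counts, est = run_error_pipeline(res.readset.reads, res.genome, RunConfig())
        assert est.total_bases > 5e5
        planted = 5e-4 + 5e-4 * (1 - 5e-4)
        sd = np.sqrt(planted * (1 - planted) / est.total_bases)
        assert abs(est.rate - planted) < 3 * sd

    def test_monotone_in_planted_error_rate(self):
        rates = []
        for seq_rate in (1e-4, 1e-3, 5e-3):
            cfg = SimConfig(seed=33, n_genes=10, coverage_target=20,
                            polymerase_error_rate=0.0,
                            sequencing_error_rate=seq_rate,
                            low_quality_fraction=0.0)
            res = simulate(cfg)
            _c, est = run_error_pipeline(res.readset.reads, res.genome, RunConfig())
            rates.append(est.rate)
        assert rates == sorted(rates)

    def test_pipeline_matches_truth_summary(self, small_sim):
        _counts, est = run_error_pipeline(small_sim.readset.reads,
                                          small_sim.genome, RunConfig())
        ts = truth_summary(small_sim.readset)
        assert est.total_bases == ts["expected_bases"]
        assert est.total_mismatches == ts["expected_mismatches"]


class TestIndels:
    def test_arithmetic_per_mapped_read(self):
        reads = [make_read("A" * 76, read_id=f"r{i}") for i in range(9)]
        reads.append(make_read("A" * 76, read_id="ri",
                               cigar=[("M", 30), ("I", 1), ("M", 45)]))
        rates = count_indels(reads)
        assert rates == {"+1": 0.1}

    def test_no_indels_gives_empty(self, clean_sim):
        assert count_indels(clean_sim.readset.reads) == {}

    def test_zero_reads_error(self):
        with pytest.raises(PileupError):
            count_indels([])

    def test_planted_insertions_only(self):
        """Simulator planting only +1 insertions yields no deletion calls."""
        cfg = SimConfig(seed=44, n_genes=8, coverage_target=30,
                        minus_strand_fraction=0.0, insertion_rate=2e-4,
                        deletion_rate=0.0)
        res = simulate(cfg)
        rates = count_indels(res.readset.reads)
        n_ins = sum(1 for t in res.readset.truth if t.type == "insertion")
        assert n_ins > 0
        assert set(rates) == {"+1"}
        assert rates["+1"] == pytest.approx(n_ins / len(res.readset.reads))


class TestExpectedMismatchDistribution:
    def test_zero_rate_is_point_mass(self):
        p = expected_mismatch_distribution(np.full(50, 100), 0.0)
        assert p[0] == 1.0 and p[1:].sum() == 0

    def test_closed_form_binomial(self):
        p = expected_mismatch_distribution(np.full(10, 100), 1e-3)
        assert p[0] == pytest.approx((1 - 1e-3) ** 100)
        assert p[1] == pytest.approx(stats.binom.pmf(1, 100, 1e-3))

    def test_mixture_over_coverages(self):
        cov = np.array([10, 1000])
        p = expected_mismatch_distribution(cov, 1e-2)
        expected0 = 0.5 * (0.99 ** 10 + 0.99 ** 1000)
        assert p[0] == pytest.approx(expected0)

    def test_montecarlo_converges_to_analytic(self):
        cov = np.full(200_000, 100)
        ana = expected_mismatch_distribution(cov, 1e-3)
        mc = expected_mismatch_distribution(cov, 1e-3, mode="montecarlo", seed=7)
        for k in range(4):
            sd = np.sqrt(ana[k] * (1 - ana[k]) / len(cov))
            assert abs(mc[k] - ana[k]) < 3 * sd + 1e-12

    def test_bad_rate_rejected(self):
        with pytest.raises(ValueError):
            expected_mismatch_distribution(np.array([10]), 1.5)
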
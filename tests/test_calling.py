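import numpy as np
import pandas as pd
import pytest

from npskit.calling import (
    CoverageProfile,
    call_nucleosomes,
    coverage_from_reads,
    default_min_height,
    find_summits,
    first_best_phased,
    gaussian_smooth,
    nucleosome_interval,
    phasing_score,
    select_supporting_reads,
)
from npskit.io_formats import GenomicInterval
from npskit.simulate import PlantedCoverageSpec, generate_coverage_reads


def iv(start, end, strand="+", chrom="chr1"):
    return GenomicInterval(chrom, start, end, strand)


class TestCoverage:
    def test_single_read_pileup(self):
        cov = coverage_from_reads([iv(10, 13)], 20)
        expected = np.zeros(20)
        expected[10:13] = 1
        assert np.array_equal(cov.values, expected)

    def test_duplicate_reads_stack(self):
        cov = coverage_from_reads([iv(3, 8), iv(3, 8)], 10)
        assert np.array_equal(cov.values[3:8], np.full(5, 2.0))

    def test_matches_per_base_membership_oracle(self, rng):
        reads = []
        for _ in range(50):
            s = int(rng.integers(0, 400))
            reads.append(iv(s, s + int(rng.integers(1, 80))))
        cov = coverage_from_reads(reads, 500)
        oracle = np.array(
            [sum(r.start <= b < r.end for r in reads) for b in range(500)],
            dtype=float,
        )
        assert np.array_equal(cov.values, oracle)

    def test_read_beyond_chromosome_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            coverage_from_reads([iv(90, 120)], 100)


class TestGaussianSmooth:
    def test_constant_profile_is_fixed_point(self):
        prof = CoverageProfile("c", 0, np.full(300, 4.0))
        sm = gaussian_smooth(prof, window_bp=70)
        assert np.allclose(sm.values, 4.0, atol=1e-9)

    def test_unit_impulse_mass_and_mode(self):
        values = np.zeros(301)
        values[150] = 1.0
        sm = gaussian_smooth(CoverageProfile("c", 0, values), window_bp=70)
        assert abs(sm.values.sum() - 1.0) < 1e-9
        assert sm.values.argmax() == 150

    def test_matches_naive_renormalized_convolution(self, rng):
        values = np.zeros(400)
        values[100:130] += 5
        values[250:290] += 3
        values += rng.poisson(2, 400)
        prof = CoverageProfile("c", 0, values.astype(float))
        window = 21
        sm = gaussian_smooth(prof, window_bp=window)
        sigma = window / 6.0
        half = window // 2
        oracle = np.empty_like(prof.values)
        for i in range(values.size):
            lo, hi = max(0, i - half), min(values.size, i + half + 1)
            x = np.arange(lo, hi) - i
            w = np.exp(-0.5 * (x / sigma) ** 2)
            oracle[i] = (w * prof.values[lo:hi]).sum() / w.sum()
        assert np.allclose(sm.values, oracle, atol=1e-12)

    def test_window_larger_than_profile_rejected(self):
        with pytest.raises(ValueError, match="larger"):
            gaussian_smooth(CoverageProfile("c", 0, np.ones(10)), window_bp=71)


class TestFindSummits:
    def test_single_peak_above_threshold(self):
        values = np.concatenate([np.linspace(0, 12, 30), np.linspace(12, 0, 30)[1:]])
        summits = find_summits(CoverageProfile("c", 0, values), min_height=10)
        assert len(summits) == 1 and summits[0][0] == 29

    def test_low_peak_discarded(self):
        values = np.concatenate([np.linspace(0, 9, 20), np.linspace(9, 0, 20)[1:]])
        assert find_summits(CoverageProfile("c", 0, values), min_height=10) == []

    def test_matches_exhaustive_scan_oracle(self, rng):
        values = gaussian_smooth(
            CoverageProfile("c", 0, rng.poisson(5, 500).astype(float)), window_bp=31
        ).values
        got = find_summits(CoverageProfile("c", 0, values), min_height=4)

        def oracle():
            out = []
            for i in range(values.size):
                left = i - 1
                while left >= 0 and values[left] == values[i]:
                    left -= 1
                right = i + 1
                while right < values.size and values[right] == values[i]:
                    right += 1
                if (
                    left >= 0
                    and right < values.size
                    and values[left] < values[i]
                    and values[right] < values[i]
                    and (i == 0 or values[i - 1] != values[i])  # leftmost of plateau
                    and values[i] >= 4
                ):
                    out.append((i, float(values[i])))
            return out

        assert got == oracle()

    def test_plateau_reports_leftmost(self):
        values = np.array([0, 1, 5, 5, 5, 1, 0], dtype=float)
        summits = find_summits(CoverageProfile("c", 0, values), min_height=1)
        assert summits == [(2, 5.0)]


class TestSupportingReads:
    def test_exact_flank_boundary_kept(self):
        assert select_supporting_reads(100, [iv(70, 131)], min_flank=30) == [iv(70, 131)]

    def test_one_base_short_rejected(self):
        assert select_supporting_reads(100, [iv(71, 131)], min_flank=30) == []

    def test_matches_brute_force_filter(self, rng):
        reads = []
        for _ in range(100):
            s = int(rng.integers(0, 200))
            reads.append(iv(s, s + int(rng.integers(40, 120))))
        got = select_supporting_reads(100, reads, min_flank=30)
        oracle = [r for r in reads if 100 - r.start >= 30 and (r.end - 1) - 100 >= 30]
        assert got == oracle

    def test_monotone_in_min_flank(self, rng):
        reads = [iv(int(s), int(s) + 99) for s in rng.integers(0, 150, 60)]
        prev = None
        for flank in (10, 20, 30, 40):
            kept = set(select_supporting_reads(100, reads, min_flank=flank))
            if prev is not None:
                assert kept <= prev
            prev = kept


class TestNucleosomeInterval:
    def test_plus_strand_extension(self):
        assert nucleosome_interval(iv(1000, 1099, "+")) == iv(980, 1199, "+")

    def test_minus_strand_mirror(self):
        assert nucleosome_interval(iv(1000, 1099, "-")) == iv(900, 1119, "-")

    def test_start_clipped_at_zero(self):
        got = nucleosome_interval(iv(5, 104, "+"))
        assert got.start == 0 and got.end == 204


class TestFirstBestPhased:
    @staticmethod
    def _call(summit, score, chrom="chr1"):
        from npskit.calling import NucleosomeCall

        return NucleosomeCall(
            summit=GenomicInterval(chrom, summit, summit + 1, "."),
            summit_height=12.0,
            supporting_reads=[],
            sequence_interval=GenomicInterval(chrom, summit - 50, summit + 50, "."),
            phasing_score=score,
        )

    @staticmethod
    def _tss(rows):
        return pd.DataFrame(rows, columns=["chrom", "tss", "strand", "gene_id"])

    def test_single_downstream_call_selected(self):
        calls = [self._call(1500, 5)]
        tss = self._tss([("chr1", 1000, "+", "g1")])
        got = first_best_phased(calls, tss)
        assert got["g1"].summit.start == 1500 and got["g1"].distance_to_tss == 500

    def test_highest_phasing_score_wins_regardless_of_order(self):
        calls = [self._call(1200, 3), self._call(1800, 8)]
        tss = self._tss([("chr1", 1000, "+", "g1")])
        for ordering in (calls, calls[::-1]):
            assert first_best_phased(ordering, tss)["g1"].phasing_score == 8

    def test_minus_strand_downstream_is_decreasing(self):
        calls = [self._call(1500, 5), self._call(2500, 9)]
        tss = self._tss([("chr1", 2000, "-", "g1")])
        assert first_best_phased(calls, tss)["g1"].summit.start == 1500

    def test_gene_without_qualifying_call_absent(self):
        calls = [self._call(5000, 5)]
        tss = self._tss([("chr1", 1000, "+", "g1")])
        assert first_best_phased(calls, tss) == {}

    def test_matches_exhaustive_per_gene_oracle(self, rng):
        calls = [
            self._call(int(s), int(rng.integers(1, 10)))
            for s in rng.integers(0, 20_000, 60)
        ]
        genes = [
            ("chr1", int(t), str(rng.choice(["+", "-"])), f"g{i}")
            for i, t in enumerate(rng.integers(0, 20_000, 20))
        ]
        got = first_best_phased(calls, self._tss(genes))
        for chrom, tss, strand, gid in genes:
            qual = []
            for c in calls:
                d = c.summit.start - tss if strand == "+" else tss - c.summit.start
                if 0 < d <= 1000:
                    qual.append((-c.phasing_score, d, c.summit.start, c))
            if not qual:
                assert gid not in got
            else:
                best = min(qual)[3]
                assert got[gid].summit.start == best.summit.start
                assert got[gid].phasing_score == best.phasing_score


class TestPlantedRecovery:
    def test_planted_pileups_recovered_within_10bp(self):
        positions = list(range(1000, 5001, 400))
        spec = PlantedCoverageSpec(
            nucleosome_positions=positions,
            mean_depth=25,
            read_length=99,
            positional_jitter_sd=8.0,
            seed=42,
        )
        reads, cov = generate_coverage_reads(spec, 6000)
        assert cov.values.mean() >= 4
        calls = call_nucleosomes(
            reads, 6000, min_height=default_min_height(cov.values.mean())
        )
        summits = [c.summit.start for c in calls]
        # the pileup peak of a planted nucleosome sits at the centre of its
        # reads: planted 5'-start (dyad - 73) plus half the read length
        for pos in positions:
            expected = pos - 73 + (spec.read_length - 1) // 2
            assert min(abs(s - expected) for s in summits) <= 10
        assert all(
            c.sequence_interval.contains(c.summit.start) for c in calls
        )

    def test_perfect_phasing_with_zero_jitter(self):
        spec = PlantedCoverageSpec(
            nucleosome_positions=[500], mean_depth=20, positional_jitter_sd=0.0, seed=1
        )
        reads, _ = generate_coverage_reads(spec, 1200)
        assert len({r.start for r in reads}) == 1
        start, score = phasing_score(reads)
        assert start == 500 - 73 and score == len(reads)
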
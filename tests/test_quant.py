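"""Quantification: binning, enrichment, MA tables, size factors, bin calling."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from uvclap import event_caller as ec
from uvclap import quant as qt
from uvclap import synthetic_data as sd


def track(positions, chrom="chr1", strand="+"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "strand": strand,
            "crosslink_pos": list(positions),
            "read_count": 1,
        }
    )


SIZES = {"chr1": 10_000, "chr2": 10_000}


class TestBinning:
    def test_single_event_lands_in_its_bin(self):
        b = qt.bin_counts(track([150]), SIZES)
        assert b[("chr1", 100)] == 1
        assert b.sum() == 1

    def test_totals_conserved(self):
        rng = np.random.default_rng(0)
        t = track(rng.integers(0, 10_000, size=500))
        assert qt.bin_counts(t, SIZES).sum() == 500

    def test_matches_integer_division_oracle(self):
        rng = np.random.default_rng(1)
        pos = rng.integers(0, 10_000, size=1000)
        b = qt.bin_counts(track(pos), SIZES, bin_size=100)
        from collections import Counter

        oracle = Counter((p // 100) * 100 for p in pos)
        assert {k[1]: v for k, v in b.items()} == dict(oracle)

    def test_event_beyond_chromosome_end_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            qt.bin_counts(track([10_001]), SIZES)

    def test_stranded_mode_separates(self):
        t = pd.concat([track([150]), track([150], strand="-")])
        b = qt.bin_counts(t, SIZES, stranded=True)
        assert len(b) == 2


class TestTotalEnrichment:
    def test_simple_ratio(self):
        s, c = track(range(1000)), track(range(100))
        rep = qt.total_enrichment([s], [c])
        assert rep.ratio == 10

    def test_equal_totals_ratio_one(self):
        s = track(range(500))
        assert qt.total_enrichment([s], [s]).ratio == 1.0

    def test_zero_control_flagged_infinite(self):
        rep = qt.total_enrichment([track([1])], [track([])])
        assert math.isinf(rep.ratio) and rep.infinite

    def test_recovers_planted_molecular_ratio(self):
        """Library-wide enrichment tracks the planted signal:control
        molecular ratio on simulated data (within sampling error)."""
        rho = 4.0
        cfg = sd.SimConfig(seed=13, molecules_per_library=1000,
                           duplication_mean=1.0, duplication_bias=1.0)
        codebook = sd.default_codebook(cfg)
        libs = [
            sd.LibrarySpec("s1", codebook.tags[0], "DRYYR", "signal", depth_factor=rho),
            sd.LibrarySpec("c1", codebook.tags[1], "DRYYR", "control", depth_factor=1.0),
        ]
        sim = sd.simulate_multiplexed(cfg, libraries=libs, codebook=codebook)
        tr = sim["truth"]
        sig = ec.call_events(sd.simulate_alignments(tr[tr["library"] == "s1"]))
        ctl = ec.call_events(sd.simulate_alignments(tr[tr["library"] == "c1"]))
        rep = qt.total_enrichment([sig], [ctl])
        se = rho * math.sqrt(1 / len(sig) + 1 / len(ctl))
        assert abs(rep.ratio - rho) < 3 * se


class TestMATable:
    def test_identical_libraries_all_zero(self):
        b = qt.bin_counts(track([5, 5, 150, 150, 250, 250]), SIZES)
        table = qt.ma_table(b, b)
        assert (table["log2fc"] == 0).all()
        assert table.attrs["median_log2fc"] == 0

    def test_doubled_library_median_minus_one(self):
        rng = np.random.default_rng(2)
        pos = list(rng.integers(0, 10_000, size=300))
        a = qt.bin_counts(track(pos), SIZES)
        b = 2 * a
        b.name = "b"
        table = qt.ma_table(a, b)
        assert table.attrs["median_log2fc"] == -1

    def test_min_coverage_rule_excludes(self):
        a = qt.bin_counts(track([150]), SIZES)  # 1 event in bin
        b = qt.bin_counts(track([150] * 5), SIZES)  # 5 events
        assert len(qt.ma_table(a, b, min_events=2)) == 0

    def test_median_antisymmetric(self):
        rng = np.random.default_rng(3)
        a = qt.bin_counts(track(rng.integers(0, 10_000, 400)), SIZES)
        b = qt.bin_counts(track(rng.integers(0, 10_000, 600)), SIZES)
        m_ab = qt.ma_table(a, b).attrs["median_log2fc"]
        m_ba = qt.ma_table(b, a).attrs["median_log2fc"]
        assert m_ab == pytest.approx(-m_ba)


class TestMedianRatioFactors:
    def test_identical_libraries_unit_factors(self):
        b = qt.bin_counts(track([50, 150, 250, 350]), SIZES)
        rep = qt.median_ratio_factors(qt.align_bins(b, b.copy()))
        assert (rep.factors == 1).all()

    def test_worked_example_single_bin(self):
        counts = pd.DataFrame({"a": [4], "b": [9]})
        rep = qt.median_ratio_factors(counts)
        assert rep.factors["a"] == pytest.approx(4 / 6)
        assert rep.factors["b"] == pytest.approx(9 / 6)

    def test_scale_equivariance_exact(self):
        rng = np.random.default_rng(4)
        base = pd.DataFrame(rng.integers(1, 50, size=(60, 3)), columns=list("abc"))
        scaled = base.copy()
        scaled["b"] = base["b"] * 5
        rep = qt.median_ratio_factors(scaled)
        base_rep = qt.median_ratio_factors(base)
        # all-equal baseline: multiplying one library by c multiplies
        # its factor by c and the others by c**(-1/3) (geometric-mean shift)
        shift = 5 ** (1 / 3)
        assert rep.factors["b"] == pytest.approx(5 * base_rep.factors["b"] / shift)
        assert rep.factors["a"] == pytest.approx(base_rep.factors["a"] / shift)

    def test_noiseless_planted_factors_recovered_exactly(self):
        rng = np.random.default_rng(5)
        ref = rng.integers(2, 40, size=100)
        counts = pd.DataFrame({"a": ref, "b": 2 * ref, "c": 4 * ref})
        rep = qt.median_ratio_factors(counts)
        g = (1 * 2 * 4) ** (1 / 3)
        assert rep.factors["a"] == pytest.approx(1 / g)
        assert rep.factors["b"] == pytest.approx(2 / g)
        assert rep.factors["c"] == pytest.approx(4 / g)

    def test_no_common_bin_rejected(self):
        counts = pd.DataFrame({"a": [1, 0], "b": [0, 1]})
        with pytest.raises(ValueError, match="bin size"):
            qt.median_ratio_factors(counts)

    def test_agrees_with_external_estimator(self):
        """Cross-check against the DESeq-style estimator in pydeseq2."""
        from pydeseq2.preprocessing import deseq2_norm

        rng = np.random.default_rng(6)
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.3, size=(80, 4)) + 1, columns=list("abcd")
        )
        _, size_factors = deseq2_norm(counts.T.to_numpy())
        rep = qt.median_ratio_factors(counts)
        np.testing.assert_allclose(
            rep.factors.to_numpy(), np.asarray(size_factors).ravel(), rtol=1e-3
        )


class TestCorrelate:
    def test_identity_perfect(self):
        b = qt.bin_counts(track([5, 150, 150, 250]), SIZES)
        assert qt.correlate(b, b, "spearman") == pytest.approx(1.0)
        assert qt.correlate(b, b, "pearson") == pytest.approx(1.0)

    def test_rank_reversal_spearman_minus_one(self):
        idx = pd.MultiIndex.from_product([["chr1"], range(0, 500, 100)],
                                         names=["chrom", "bin"])
        a = pd.Series([1, 2, 3, 4, 5], index=idx)
        b = pd.Series([5, 4, 3, 2, 1], index=idx)
        assert qt.correlate(a, b, "spearman") == pytest.approx(-1.0)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(7)
        idx = pd.MultiIndex.from_product([["chr1"], range(0, 5000, 100)],
                                         names=["chrom", "bin"])
        a = pd.Series(rng.integers(1, 30, size=50), index=idx)
        b = pd.Series(rng.integers(1, 30, size=50), index=idx)
        assert qt.correlate(a, b, "pearson") == pytest.approx(
            stats.pearsonr(a, b).statistic
        )

    def test_too_few_regions_undefined(self):
        b = qt.bin_counts(track([150]), SIZES)
        assert math.isnan(qt.correlate(b, b))


class TestRelativeStd:
    def test_constant_vector_zero(self):
        assert qt.relative_std([7, 7, 7]) == 0

    def test_hand_computed_example(self):
        sd_ = np.std([8, 12], ddof=1)
        assert qt.relative_std([8, 12]) == pytest.approx(100 * sd_ / 10)

    def test_single_value_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert qt.relative_std([5]) == 0


class TestCallEnrichedBins:
    @staticmethod
    def _bins(counts, chrom="chr1"):
        idx = pd.MultiIndex.from_product(
            [[chrom], range(0, 100 * len(counts), 100)], names=["chrom", "bin"]
        )
        return pd.Series(counts, index=idx)

    def test_signal_equals_control_no_peaks(self):
        b = self._bins([5] * 50)
        assert len(qt.call_enriched_bins(b, b.copy())) == 0

    def test_single_strong_bin_called(self):
        s = self._bins([1] * 30 + [100] + [1] * 30)
        c = self._bins([1] * 30 + [1] + [1] * 30)
        peaks = qt.call_enriched_bins(s, c)
        assert len(peaks) == 1
        assert peaks["start"].iloc[0] == 3000
        # binomial tail for 100 signal vs 1 control at p0=0.5 is astronomically small
        assert stats.binom.sf(99, 101, 0.5) < 1e-20

    def test_infinite_fold_threshold_empty(self):
        s = self._bins([1] * 30 + [100] + [1] * 30)
        c = self._bins([1] * 61)
        assert len(qt.call_enriched_bins(s, c, min_fold=math.inf)) == 0

    def test_monotone_in_fold_and_alpha(self):
        rng = np.random.default_rng(8)
        s = self._bins(rng.poisson(3, 80) + rng.poisson(10, 80) * (rng.random(80) < 0.2))
        c = self._bins(rng.poisson(3, 80))
        n_loose = len(qt.call_enriched_bins(s, c, min_fold=1.5, alpha=0.1))
        n_tight = len(qt.call_enriched_bins(s, c, min_fold=3.0, alpha=0.01))
        assert n_tight <= n_loose

    def test_adjacent_bins_merge(self):
        s = self._bins([1] * 10 + [80, 80] + [1] * 10)
        c = self._bins([1] * 22)
        peaks = qt.call_enriched_bins(s, c)
        assert len(peaks) == 1
        assert peaks["end"].iloc[0] - peaks["start"].iloc[0] == 200


class TestEventTotalConcordance:
    def test_identical_totals_perfect(self):
        pairs = [(track(range(n)), track(range(n))) for n in (100, 200, 300)]
        totals, r = qt.event_total_concordance(pairs)
        assert r == pytest.approx(1.0)

    def test_two_pairs_refused(self):
        pairs = [(track(range(10)), track(range(12)))] * 2
        totals, r = qt.event_total_concordance(pairs)
        assert len(totals) == 2 and r is None

    def test_replicates_from_shared_sites_concordant(self, small_sim):
        """Replicate totals drawn from the same site set correlate highly."""
        truth = small_sim["truth"]
        pairs = []
        for cond in ("signal", "control"):
            a = truth[truth["library"] == f"{cond}_rep1"]
            b = truth[truth["library"] == f"{cond}_rep2"]
            pairs.append(
                (ec.call_events(sd.simulate_alignments(a)),
                 ec.call_events(sd.simulate_alignments(b)))
            )
        # add a deeper condition to span a range of totals
        cfg = sd.SimConfig(seed=31, molecules_per_library=2400)
        sim2 = sd.simulate_multiplexed(cfg)
        t2 = sim2["truth"]
        pairs.append(
            (ec.call_events(sd.simulate_alignments(t2[t2["library"] == "signal_rep1"])),
             ec.call_events(sd.simulate_alignments(t2[t2["library"] == "signal_rep2"])))
        )
        totals, r = qt.event_total_concordance(pairs)
        assert r > 0.98
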
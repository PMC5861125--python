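"""Priority annotation, peak standardization, overlaps, proximity, motifs."""

import numpy as np
import pandas as pd
import pytest

from uvclap import annotate as ann
from uvclap import synthetic_data as sd

from _oracles import overlap_counts_per_base


def peaks_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])


@pytest.fixture(scope="module")
def index(small_sim):
    return ann.build_annotation_index(small_sim["annotation"], small_sim["sizes"])


@pytest.fixture(scope="module")
def features(small_sim):
    a = small_sim["annotation"]
    out = {}
    for bt in ("rRNA", "lincRNA", "processed_pseudogene", "protein_coding"):
        g = a[(a["Feature"] == "gene") & (a["gene_biotype"] == bt)].iloc[0]
        out[bt] = g
    return out


class TestPriorityAssignment:
    def test_rrna_beats_everything(self, index, features):
        g = features["rRNA"]
        p = peaks_frame([(g.Chromosome, g.Start, g.Start + 10, g.Strand)])
        assert ann.classify_peaks(p, index)["target_class"].iloc[0] == "rRNA"

    def test_intergenic_when_nothing_overlaps(self, index, small_sim):
        chrom = list(small_sim["sizes"])[0]
        p = peaks_frame([(chrom, 0, 50, "+")])  # genes start at the gap offset
        assert ann.classify_peaks(p, index)["target_class"].iloc[0] == "intergenic"

    def test_antisense_for_opposite_strand_only_overlap(self, index, features):
        g = features["protein_coding"]
        anti = "-" if g.Strand == "+" else "+"
        mid = (g.Start + g.End) // 2
        p = peaks_frame([(g.Chromosome, mid, mid + 10, anti)])
        assert ann.classify_peaks(p, index)["target_class"].iloc[0] == "antisense"

    def test_utr_beats_exon(self, index, features, small_sim):
        a = small_sim["annotation"]
        utr = a[a["Feature"] == "five_prime_utr"].iloc[0]
        p = peaks_frame([(utr.Chromosome, utr.Start, utr.Start + 5, utr.Strand)])
        assert ann.classify_peaks(p, index)["target_class"].iloc[0] == "5UTR"

    def test_intron_between_exons(self, index, features, small_sim):
        g = features["protein_coding"]
        cfg = small_sim["config"]
        s = g.Start + cfg.exon_length + 10  # inside first intron
        p = peaks_frame([(g.Chromosome, s, s + 5, g.Strand)])
        assert ann.classify_peaks(p, index)["target_class"].iloc[0] == "intron"

    def test_ncrna_and_pseudogene_classes(self, index, features):
        rows, expect = [], []
        for bt, cls in (("lincRNA", "ncRNA"), ("processed_pseudogene", "pseudogene")):
            g = features[bt]
            rows.append((g.Chromosome, g.Start + 5, g.Start + 25, g.Strand))
            expect.append(cls)
        got = ann.classify_peaks(peaks_frame(rows), index)["target_class"].tolist()
        assert got == expect

    def test_every_peak_one_class_counts_partition(self, index, small_sim):
        rng = np.random.default_rng(0)
        chrom = list(small_sim["sizes"])[0]
        starts = rng.integers(0, small_sim["sizes"][chrom] - 50, size=100)
        p = peaks_frame([(chrom, s, s + 30, "+") for s in starts])
        assigned = ann.classify_peaks(p, index)
        counts = ann.class_counts(assigned)
        assert counts.sum() == len(p)

    def test_out_of_bounds_peak_rejected(self, index, small_sim):
        chrom, size = next(iter(small_sim["sizes"].items()))
        with pytest.raises(ValueError, match="bounds"):
            ann.classify_peaks(peaks_frame([(chrom, size - 1, size + 10, "+")]), index)


class TestStandardizeAndMerge:
    def test_short_peak_extended_to_41_containing_midpoint(self):
        out = ann.standardize_and_merge(peaks_frame([("chr1", 100, 110, "+")]))
        s, e = out.iloc[0][["start", "end"]]
        assert e - s == 41
        assert s <= 105 <= e

    def test_abutting_peaks_merge(self):
        out = ann.standardize_and_merge(
            peaks_frame([("chr1", 0, 41, "+"), ("chr1", 41, 82, "+")])
        )
        assert out.values.tolist() == [["chr1", 0, 82]]

    def test_long_isolated_peak_unchanged(self):
        out = ann.standardize_and_merge(peaks_frame([("chr1", 500, 600, "+")]))
        assert out.values.tolist() == [["chr1", 500, 600]]

    def test_idempotent_and_all_at_least_min_len(self):
        rng = np.random.default_rng(1)
        rows = [
            ("chr1", int(s), int(s + rng.integers(5, 120)), "+" if i % 2 else "-")
            for i, s in enumerate(rng.integers(0, 50_000, size=200))
        ]
        once = ann.standardize_and_merge(peaks_frame(rows))
        twice = ann.standardize_and_merge(once.assign(strand="+"))
        pd.testing.assert_frame_equal(once, twice)
        assert ((once["end"] - once["start"]) >= 41).all()
        # pairwise non-adjacent, non-overlapping
        for chrom, grp in once.groupby("chrom"):
            assert (grp["start"].to_numpy()[1:] > grp["end"].to_numpy()[:-1]).all()


class TestOverlapSets:
    def test_identical_sets_all_shared(self):
        a = peaks_frame([("chr1", 0, 50, "+"), ("chr1", 100, 150, "+")])
        rep = ann.overlap_sets(a, a.copy())
        shared = rep[(rep["set1"]) & (rep["set2"])]["regions"].sum()
        exclusive = rep[rep["set1"] != rep["set2"]]["regions"].sum()
        assert shared == 2 and exclusive == 0

    def test_disjoint_sets_zero_shared(self):
        a = peaks_frame([("chr1", 0, 50, "+")])
        b = peaks_frame([("chr1", 100, 150, "+")])
        rep = ann.overlap_sets(a, b)
        assert rep[(rep["set1"]) & (rep["set2"])]["regions"].sum() == 0

    @pytest.mark.parametrize("n_sets", [2, 3])
    def test_matches_per_base_oracle(self, n_sets):
        """Random standardized sets on a 1e5-nt genome vs the per-base oracle."""
        rng = np.random.default_rng(2)
        glen = 100_000
        sets = []
        for _ in range(n_sets):
            raw = peaks_frame(
                [
                    ("chr1", int(s), int(s + rng.integers(10, 200)), "+")
                    for s in rng.integers(0, glen - 300, size=120)
                ]
            )
            sets.append(ann.standardize_and_merge(raw))
        rep = ann.overlap_sets(*sets)
        labels = [f"set{i+1}" for i in range(n_sets)]
        got = {
            tuple(bool(r[l]) for l in labels): int(r["regions"])
            for _, r in rep.iterrows()
        }
        oracle = overlap_counts_per_base(sets, glen, ["chr1"])
        assert got == oracle

    def test_symmetric_under_relabeling(self):
        rng = np.random.default_rng(3)
        a = ann.standardize_and_merge(
            peaks_frame([("chr1", int(s), int(s) + 60, "+") for s in rng.integers(0, 5000, 20)])
        )
        b = ann.standardize_and_merge(
            peaks_frame([("chr1", int(s), int(s) + 60, "+") for s in rng.integers(0, 5000, 20)])
        )
        rab = ann.overlap_sets(a, b)
        rba = ann.overlap_sets(b, a)
        both_ab = rab[(rab["set1"]) & (rab["set2"])]["regions"].sum()
        both_ba = rba[(rba["set1"]) & (rba["set2"])]["regions"].sum()
        assert both_ab == both_ba


class TestProximity:
    def reads(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def test_no_control_reads_all_far(self):
        p = peaks_frame([("chr1", 0, 41, "+")])
        assert ann.peak_control_proximity(p, self.reads([])) == 1.0

    def test_overlapping_read_near(self):
        p = peaks_frame([("chr1", 100, 141, "+")])
        assert ann.peak_control_proximity(p, self.reads([("chr1", 120, 140)])) == 0.0

    def test_strict_distance_boundary(self):
        p = peaks_frame([("chr1", 0, 41, "+")])
        # gap of exactly 51 intervening nt -> far
        assert ann.peak_control_proximity(p, self.reads([("chr1", 92, 112)])) == 1.0
        # gap of exactly 50 -> near
        assert ann.peak_control_proximity(p, self.reads([("chr1", 91, 111)])) == 0.0


class TestMotifOccurrence:
    GENOME = {"chr1": "G" * 50 + "ACTAAC" + "G" * 50}

    def test_plus_strand_match(self):
        p = peaks_frame([("chr1", 40, 70, "+")])
        n, frac = ann.motif_occurrence(p, self.GENOME, "AYUAAY")
        assert (n, frac) == (1, 1.0)

    def test_all_g_no_match(self):
        p = peaks_frame([("chr1", 0, 40, "+")])
        assert ann.motif_occurrence(p, self.GENOME, "AYUAAY")[0] == 0

    def test_minus_strand_revcomp_match(self):
        from uvclap.barcode_design import revcomp

        genome = {"chr1": "G" * 50 + revcomp("ACTAAC") + "G" * 50}
        p = peaks_frame([("chr1", 40, 70, "-")])
        assert ann.motif_occurrence(p, genome, "AYUAAY")[0] == 1

    def test_strand_flip_invariance(self):
        """Mirroring the genome and flipping strands preserves the fraction."""
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        from uvclap.barcode_design import revcomp

        p = peaks_frame(
            [("chr1", int(s), int(s) + 60, "+") for s in rng.integers(0, 4900, 40)]
        )
        n_fwd, _ = ann.motif_occurrence(p, {"chr1": seq}, "AYUAAY")
        flipped = p.copy()
        flipped["start"] = 5000 - p["end"]
        flipped["end"] = 5000 - p["start"]
        flipped["strand"] = "-"
        n_rev, _ = ann.motif_occurrence(flipped, {"chr1": revcomp(seq)}, "AYUAAY")
        assert n_fwd == n_rev

    def test_planted_motif_sites_detected(self, small_sim):
        """Peaks around generator-planted motif instances all match."""
        sites = small_sim["sites"]
        p = pd.DataFrame(
            {
                "chrom": sites["chrom"],
                "start": sites["start"] - 10,
                "end": sites["end"] + 10,
                "strand": sites["strand"],
            }
        )
        n, frac = ann.motif_occurrence(p, small_sim["genome"], small_sim["config"].motif)
        assert frac == 1.0

    def test_out_of_bounds_rejected(self):
        p = peaks_frame([("chr1", 100, 1000, "+")])
        with pytest.raises(ValueError, match="bounds"):
            ann.motif_occurrence(p, self.GENOME, "AYUAAY")
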
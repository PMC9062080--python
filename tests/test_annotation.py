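import numpy as np
import pandas as pd
import pytest

from mosaic_hic import annotation
from mosaic_hic.annotation import (
    BorderSet,
    RegionSet,
    border_signal_matrix,
    chromhmm_enrichment,
    classify_borders,
    conservation_score,
    coverage_and_lengths,
    expand,
    filter_degs,
    neighborhood_enrichment,
    segment,
    signal_enrichment,
    switch_concordance,
)
from mosaic_hic.clustering import ABCall, CompartmentCall
from mosaic_hic.matrix_io import GenomicBinning, SignalTrack


def make_call(states, bin_size=100_000, chrom="chr1", ev1=None):
    states = np.asarray(states, dtype=object)
    binning = GenomicBinning(chrom, bin_size, len(states))
    binning.valid = states != "NA"
    if ev1 is None:
        ev1 = np.where(np.char.startswith(states.astype(str), "A"), 0.5, -0.5)
    ev = np.asarray(ev1, dtype=float).copy()
    ev[states == "NA"] = np.nan
    return CompartmentCall(binning, states, ev, ev.copy())


def regions_from(tuples, chrom="chr1"):
    return RegionSet(pd.DataFrame(tuples, columns=["chrom", "start", "end", "state"]))


class TestSegment:
    def test_maximal_runs(self):
        rs = segment(make_call(["A1", "A1", "B2", "B2", "B2"]))
        assert rs.regions.values.tolist() == [
            ["chr1", 0, 200_000, "A1"],
            ["chr1", 200_000, 500_000, "B2"],
        ]

    def test_single_bin(self):
        rs = segment(make_call(["A1"]))
        assert len(rs) == 1 and rs.lengths[0] == 100_000

    def test_na_splits_runs(self):
        rs = segment(make_call(["A1", "NA", "A1"]))
        assert len(rs) == 2
        assert rs.regions["state"].tolist() == ["A1", "A1"]

    def test_expand_is_inverse_on_non_na_bins(self):
        states = np.array(["A1", "NA", "B1", "B1", "A2"], dtype=object)
        call = make_call(states)
        back = expand(segment(call), call.binning)
        assert (back == states).all()


class TestCoverage:
    def test_fraction(self):
        rs = segment(make_call(["A1"] * 7 + ["B1"] * 3))
        fractions, lengths = coverage_and_lengths(rs)
        assert fractions["A1"] == pytest.approx(0.7)
        assert sum(fractions.values()) == pytest.approx(1.0)

    def test_equal_states(self):
        rs = segment(make_call(["A1", "A2", "B1", "B2"]))
        fractions, _ = coverage_and_lengths(rs)
        assert all(f == pytest.approx(0.25) for f in fractions.values())

    def test_micro_regions_shorter_on_synthetic_defaults(self, small_truth):
        call = make_call(small_truth.states)
        _, lengths = coverage_and_lengths(segment(call))
        micro = np.concatenate([lengths["A2"], lengths["B2"]])
        major = np.concatenate([lengths["A1"], lengths["B1"]])
        assert np.median(micro) < np.median(major)


def ab_call_from(labels, bin_size=100_000):
    labels = np.asarray(labels, dtype=object)
    binning = GenomicBinning("chr1", bin_size, len(labels))
    binning.valid = labels != "NA"
    return ABCall(binning, labels, np.zeros(len(labels)))


class TestConservation:
    def test_unanimous_votes(self):
        rs = regions_from([("chr1", 0, 300_000, "A1")])
        all_a = [ab_call_from(["A"] * 3) for _ in range(16)]
        assert conservation_score(all_a, rs)["conservation"].iloc[0] == pytest.approx(1.0)
        all_b = [ab_call_from(["B"] * 3) for _ in range(16)]
        assert conservation_score(all_b, rs)["conservation"].iloc[0] == pytest.approx(-1.0)

    def test_split_votes(self):
        rs = regions_from([("chr1", 0, 300_000, "A1")])
        half = [ab_call_from(["A"] * 3) for _ in range(8)] + [
            ab_call_from(["B"] * 3) for _ in range(8)
        ]
        assert conservation_score(half, rs)["conservation"].iloc[0] == pytest.approx(0.0)
        twelve_four = [ab_call_from(["A"] * 3) for _ in range(12)] + [
            ab_call_from(["B"] * 3) for _ in range(4)
        ]
        assert conservation_score(twelve_four, rs)["conservation"].iloc[0] == pytest.approx(0.5)

    def test_all_na_line_excluded(self):
        rs = regions_from([("chr1", 0, 300_000, "A1")])
        lines = [ab_call_from(["A"] * 3), ab_call_from(["NA"] * 3)]
        assert conservation_score(lines, rs)["conservation"].iloc[0] == pytest.approx(1.0)


class TestNeighborhoodEnrichment:
    def test_alternating_two_state_layout(self):
        states = ["A1", "B2"] * 6
        rs = segment(make_call(states))
        table = neighborhood_enrichment(rs, n_perm=50, seed=1).rows
        row = table.set_index("pair").loc["A1-B2"]
        # only one junction type exists; shuffling cannot change proportions
        assert row["observed"] == pytest.approx(1.0)
        assert row["enrichment"] == pytest.approx(1.0)

    def test_two_regions_degenerate_null(self):
        rs = segment(make_call(["A1"] * 3 + ["B1"] * 3))
        table = neighborhood_enrichment(rs, n_perm=20, seed=0).rows
        assert table.set_index("pair").loc["A1-B1", "enrichment"] == pytest.approx(1.0)

    def test_synthetic_defaults_favor_embedded_junctions(self, small_truth):
        rs = segment(make_call(small_truth.states))
        table = neighborhood_enrichment(rs, n_perm=200, seed=3).rows.set_index("pair")
        assert table.loc["A1-B2", "enrichment"] > 1
        assert table.loc["A2-B1", "enrichment"] > 1
        for pair in ("A1-B1", "A1-A2", "B1-B2", "A2-B2"):
            if pair in table.index:
                enr = table.loc[pair, "enrichment"]
                assert np.isnan(enr) or enr < 1


class TestClassifyBorders:
    def test_mosaic_specific_micro_border(self):
        mosaic = regions_from(
            [("chr1", 0, 300_000, "A1"), ("chr1", 300_000, 500_000, "B2")]
        )
        ab = regions_from([("chr1", 0, 500_000, "A")])
        bs = classify_borders(mosaic, ab)
        assert len(bs) == 1
        row = bs.borders.iloc[0]
        assert row["scheme_class"] == "mosaic_specific"
        assert row["micro_associated"]

    def test_shared_border_is_overlapping(self):
        mosaic = regions_from(
            [("chr1", 0, 300_000, "A1"), ("chr1", 300_000, 500_000, "B1")]
        )
        ab = regions_from([("chr1", 0, 300_000, "A"), ("chr1", 300_000, 500_000, "B")])
        bs = classify_borders(mosaic, ab)
        assert bs.counts() == {"overlapping": 1}

    def test_hand_enumerated_counts(self):
        # mosaic junctions at 1,2,3,4,5 x 100kb; ab junctions at 3, 5, 6
        mosaic = regions_from(
            [
                ("chr1", 0, 100_000, "A1"),
                ("chr1", 100_000, 200_000, "B2"),
                ("chr1", 200_000, 300_000, "A1"),
                ("chr1", 300_000, 400_000, "A2"),
                ("chr1", 400_000, 500_000, "B1"),
                ("chr1", 500_000, 700_000, "A1"),
            ]
        )
        ab = regions_from(
            [
                ("chr1", 0, 300_000, "A"),
                ("chr1", 300_000, 500_000, "B"),
                ("chr1", 500_000, 600_000, "A"),
                ("chr1", 600_000, 700_000, "B"),
            ]
        )
        bs = classify_borders(mosaic, ab)
        counts = bs.counts()
        assert counts == {"mosaic_specific": 3, "overlapping": 2, "ab_specific": 1}
        mj = mosaic.junctions()
        aj = ab.junctions()
        assert counts["mosaic_specific"] + counts["overlapping"] == len(mj)
        assert counts["ab_specific"] + counts["overlapping"] == len(aj)


class TestBorderSignalMatrix:
    def _borders(self, positions, chrom="chr1"):
        rows = [(chrom, p, "A1", "B2", "mosaic_specific", True) for p in positions]
        return BorderSet(
            pd.DataFrame(
                rows,
                columns=["chrom", "position", "left", "right", "scheme_class", "micro_associated"],
            )
        )

    def test_step_track(self):
        binning = GenomicBinning("chr1", 10_000, 40)
        vals = np.concatenate([np.zeros(20), np.ones(20)])
        track = SignalTrack(binning, vals)
        matrix, kept = border_signal_matrix(self._borders([200_000]), track)
        assert matrix.shape == (1, 20)
        assert np.array_equal(matrix[0], np.concatenate([np.zeros(10), np.ones(10)]))

    def test_flat_track_and_edge_borders_dropped(self):
        binning = GenomicBinning("chr1", 10_000, 40)
        track = SignalTrack(binning, np.full(40, 2.0))
        matrix, kept = border_signal_matrix(self._borders([50_000, 200_000]), track)
        assert matrix.shape == (1, 20)  # border at 50 kb is within a flank of the end
        assert np.allclose(matrix, 2.0)


class TestSignalEnrichment:
    def test_constant_track_is_flat(self):
        call = make_call(["A1", "A2", "B1", "B2"] * 3)
        track = SignalTrack(call.binning, np.full(12, 5.0))
        table = signal_enrichment(call, track).rows
        assert np.allclose(table["enrichment"], 1.0)

    def test_hand_computed_medians(self):
        call = make_call(["A1"] * 5 + ["B1"] * 5)
        track = SignalTrack(call.binning, np.array([2.0] * 5 + [1.0] * 5))
        table = signal_enrichment(call, track).rows.set_index("state")
        assert table.loc["A1", "enrichment"] == pytest.approx(2.0 / 1.5)

    def test_h3k27me3_peaks_in_b2(self, small_truth, small_tracks):
        call = make_call(small_truth.states)
        table = signal_enrichment(call, small_tracks["h3k27me3"]).rows.set_index("state")
        assert table["enrichment"].idxmax() == "B2"


class TestChromHMMEnrichment:
    def test_annotation_on_exactly_one_state(self):
        call = make_call(["A1", "A1", "B1", "B1"])
        ann = pd.DataFrame(
            [("chr1", 0, 200_000, "Active Promoter")],
            columns=["chrom", "start", "end", "label"],
        )
        table = chromhmm_enrichment(call, ann).rows.set_index("state")
        # overall proportion = 0.5, A1 proportion = 1 -> enrichment 2, B1 0
        assert table.loc["A1", "enrichment"] == pytest.approx(2.0)
        assert table.loc["B1", "enrichment"] == pytest.approx(0.0)

    def test_uniform_annotation_is_flat(self):
        call = make_call(["A1", "A2", "B1", "B2"])
        ann = pd.DataFrame(
            [("chr1", 0, 400_000, "Transcription")],
            columns=["chrom", "start", "end", "label"],
        )
        table = chromhmm_enrichment(call, ann).rows
        assert np.allclose(table["enrichment"], 1.0)

    def test_hand_computed_partial_coverage(self):
        call = make_call(["A1", "A1", "B1", "B1", "B1"])
        # 150 kb of label over bin 0 (full) and bin 1 (half)
        ann = pd.DataFrame(
            [("chr1", 0, 150_000, "Enhancer")],
            columns=["chrom", "start", "end", "label"],
        )
        table = chromhmm_enrichment(call, ann).rows.set_index("state")
        overall = (1.0 + 0.5) / 5
        assert table.loc["A1", "enrichment"] == pytest.approx((1.5 / 2) / overall)
        assert table.loc["B1", "enrichment"] == pytest.approx(0.0)


class TestSwitchConcordance:
    def _degs(self, rows):
        return pd.DataFrame(
            rows, columns=["gene", "chrom", "position", "expr1", "expr2", "pvalue"]
        )

    def test_ascending_switch_with_upregulation_is_concordant(self):
        call1 = make_call(["B2", "B2"])
        call2 = make_call(["A1", "A1"])
        degs = self._degs([("g1", "chr1", 50_000, 1.0, 9.0, 0.01)])
        report = switch_concordance(call1, call2, degs)
        assert report["mosaic_switched"] == 1
        assert report["mosaic_concordant"] == 1

    def test_unchanged_state_is_not_switched(self):
        call = make_call(["A1", "A1"])
        degs = self._degs([("g1", "chr1", 50_000, 1.0, 9.0, 0.01)])
        report = switch_concordance(call, call, degs)
        assert report["mosaic_switched"] == 0

    def test_na_bin_excluded_and_counted(self):
        call1 = make_call(["NA", "A1"])
        call2 = make_call(["NA", "A1"])
        degs = self._degs([("g1", "chr1", 50_000, 1.0, 9.0, 0.01)])
        report = switch_concordance(call1, call2, degs)
        assert report["n_genes"] == 0 and report["n_excluded"] == 1

    def test_micro_switch_invisible_to_ab_scheme(self):
        # A1 -> B2 with EV1 staying positive (a micro region embedded in
        # compartment A): MOSAIC sees the switch, the A/B scheme does not
        call1 = make_call(["A1"] * 4, ev1=[0.5] * 4)
        call2 = make_call(["B2"] * 4, ev1=[0.1] * 4)
        degs = self._degs(
            [
                ("g1", "chr1", 50_000, 8.0, 1.0, 0.01),
                ("g2", "chr1", 150_000, 6.0, 2.0, 0.01),
            ]
        )
        report = switch_concordance(call1, call2, degs)
        assert report["mosaic_switched"] == 2
        assert report["ab_switched"] == 0
        assert report["mosaic_concordant"] == 2  # descending switch, downregulated

    def test_hand_tallied_mixed_table(self):
        states1 = ["B1", "B2", "A2", "A1", "A1", "NA"]
        states2 = ["B2", "B1", "A2", "B2", "A1", "A1"]
        call1, call2 = make_call(states1), make_call(states2)
        degs = self._degs(
            [
                ("up_asc", "chr1", 50_000, 1.0, 4.0, 0.01),     # B1->B2 up: concordant
                ("up_desc", "chr1", 150_000, 1.0, 4.0, 0.01),   # B2->B1 up: discordant
                ("flat", "chr1", 250_000, 3.0, 3.0, 0.01),      # A2->A2: no switch
                ("down_desc", "chr1", 350_000, 9.0, 2.0, 0.01), # A1->B2 down: concordant
                ("up_same", "chr1", 450_000, 2.0, 5.0, 0.01),   # A1->A1: no switch
                ("na_gene", "chr1", 550_000, 1.0, 2.0, 0.01),   # NA in call1: excluded
            ]
        )
        report = switch_concordance(call1, call2, degs)
        assert report["n_genes"] == 5 and report["n_excluded"] == 1
        assert report["mosaic_switched"] == 3
        assert report["mosaic_concordant"] == 2
        assert report["ab_switched"] == 1  # only A1->B2 crosses the A/B line
        assert report["ab_concordant"] == 1


def test_filter_degs_thresholds():
    degs = pd.DataFrame(
        [
            ("keep", "chr1", 0, 1.0, 2.0, 0.01),     # 100% change, significant
            ("small", "chr1", 0, 1.0, 1.2, 0.01),    # 20% change
            ("nonsig", "chr1", 0, 1.0, 3.0, 0.2),    # p too large
            ("zero", "chr1", 0, 0.0, 1.0, 0.001),    # pseudocount saves the ratio
        ],
        columns=["gene", "chrom", "position", "expr1", "expr2", "pvalue"],
    )
    kept = filter_degs(degs)
    assert set(kept["gene"]) == {"keep", "zero"}
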
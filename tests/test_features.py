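"""Segmentation arithmetic and the CSLV segment-mean transform."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cslv.features import (
    build_segments,
    compute_cslv,
    feature_name,
    summarize_distribution,
)
from cslv.genome import GenomeBuild, default_build
from cslv.io import MarkerManifest

from conftest import random_manifest


def brute_force_cslv(lrr, segmap, min_markers=1):
    """Triple loop over (sample, segment, marker): the independent oracle."""
    out = pd.DataFrame(
        np.nan, index=lrr.index, columns=segmap.feature_names, dtype=float
    )
    for sample in lrr.index:
        for feat in segmap.feature_names:
            values = [
                lrr.loc[sample, m]
                for m in segmap.marker_ids[feat]
                if m in lrr.columns and np.isfinite(lrr.loc[sample, m])
            ]
            if len(values) >= min_markers:
                out.loc[sample, feat] = sum(values) / len(values)
    return out


class TestBuildSegments:
    def test_k1_is_identity_segmentation(self, toy_build, toy_manifest):
        segmap = build_segments(toy_build, toy_manifest, 1)
        assert len(segmap) == 3
        row = segmap.table.iloc[0]
        assert (row.start, row.end) == (1, 101)
        assert sum(len(v) for v in segmap.marker_ids.values()) == len(toy_manifest)

    def test_default_build_k4_gives_88_segments(self):
        manifest = random_manifest(default_build(), 10, seed=3)
        segmap = build_segments(default_build(), manifest, 4)
        assert len(segmap) == 88

    def test_hand_enumerated_boundaries_L100_k4(self, toy_build):
        table = pd.DataFrame(
            {"marker_id": ["m"], "chromosome": ["1"], "position": [26]}
        )
        manifest = MarkerManifest(table=table, build=toy_build)
        segmap = build_segments(toy_build, manifest, 4)
        chr1 = segmap.table[segmap.table.chromosome == "1"]
        assert list(zip(chr1.start, chr1.end)) == [(1, 26), (26, 51), (51, 76), (76, 101)]
        # position 26 sits at the closed start of segment 2
        assert segmap.marker_ids[feature_name("1", 2)] == ["m"]

    def test_k_below_one_rejected(self, toy_build, toy_manifest):
        with pytest.raises(ValueError, match=">= 1"):
            build_segments(toy_build, toy_manifest, 0)

    @settings(max_examples=60, deadline=None)
    @given(
        length=st.integers(min_value=1, max_value=10_000),
        k=st.integers(min_value=1, max_value=12),
    )
    def test_segments_tile_chromosome(self, length, k):
        """Intervals tile [1, L+1) with no gap/overlap; spans differ <= 1 bp."""
        build = GenomeBuild({"1": length})
        manifest = MarkerManifest(
            table=pd.DataFrame(columns=["marker_id", "chromosome", "position"]),
            build=build,
        )
        segmap = build_segments(build, manifest, k)
        starts = segmap.table["start"].tolist()
        ends = segmap.table["end"].tolist()
        assert starts[0] == 1 and ends[-1] == length + 1
        assert starts[1:] == ends[:-1]
        spans = [e - s for s, e in zip(starts, ends)]
        assert max(spans) - min(spans) <= 1

    def test_every_marker_in_exactly_one_segment(self):
        build = GenomeBuild({"1": 977, "2": 13})
        manifest = random_manifest(build, 9, seed=5)
        for k in (1, 2, 3, 5):
            segmap = build_segments(build, manifest, k)
            assigned = [m for v in segmap.marker_ids.values() for m in v]
            assert sorted(assigned) == sorted(manifest.marker_ids)
            per_chrom = segmap.table.groupby("chromosome")["n_markers"].sum()
            counts = manifest.table["chromosome"].value_counts()
            for chrom, total in per_chrom.items():
                assert total == counts.get(chrom, 0)

    def test_equal_marker_count_mode(self, toy_build, toy_manifest):
        segmap = build_segments(toy_build, toy_manifest, 2, mode="markers")
        chr1_counts = [
            len(segmap.marker_ids[feature_name("1", i)]) for i in (1, 2)
        ]
        assert chr1_counts == [2, 2]


class TestComputeCslv:
    def test_all_zero_lrr_gives_zero_features(self, toy_build, toy_manifest):
        segmap = build_segments(toy_build, toy_manifest, 2)
        lrr = pd.DataFrame(
            0.0, index=["s1", "s2"], columns=toy_manifest.marker_ids
        )
        table = compute_cslv(lrr, segmap)
        vals = table.to_numpy()
        # marker-free segments are missing by contract; everything else is 0
        assert np.all((vals == 0.0) | np.isnan(vals))
        assert np.isfinite(vals).any()

    def test_hand_arithmetic_two_segments(self, toy_build):
        table = pd.DataFrame(
            {
                "marker_id": ["a", "b", "c", "d"],
                "chromosome": "1",
                "position": [10, 40, 60, 90],
            }
        )
        manifest = MarkerManifest(table=table, build=toy_build)
        segmap = build_segments(toy_build, manifest, 2)
        lrr = pd.DataFrame(
            [[0.2, -0.4, 0.1, 0.3]], index=["s"], columns=["a", "b", "c", "d"]
        )
        out = compute_cslv(lrr, segmap)
        assert out.loc["s", "1_seg1"] == pytest.approx(-0.1)
        assert out.loc["s", "1_seg2"] == pytest.approx(0.2)

    def test_constant_shift_equivariance(self, toy_build, toy_manifest, toy_lrr):
        segmap = build_segments(toy_build, toy_manifest, 2)
        base = compute_cslv(toy_lrr, segmap)
        shifted = compute_cslv(toy_lrr + 0.05, segmap)
        pd.testing.assert_frame_equal(shifted, base + 0.05)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_triple_loop_oracle(self, seed):
        """Vectorised transform equals the brute-force oracle, missing included."""
        rng = np.random.default_rng(seed)
        build = GenomeBuild({str(i): int(rng.integers(50, 5000)) for i in range(1, 6)})
        manifest = random_manifest(build, 40, seed=seed)
        segmap = build_segments(build, manifest, int(rng.integers(1, 5)))
        lrr = pd.DataFrame(
            rng.normal(0, 0.2, (6, len(manifest))),
            index=[f"s{i}" for i in range(6)],
            columns=manifest.marker_ids,
        )
        mask = rng.random(lrr.shape) < 0.15
        lrr = lrr.mask(mask)
        for min_markers in (1, 3):
            fast = compute_cslv(lrr, segmap, min_markers=min_markers)
            slow = brute_force_cslv(lrr, segmap, min_markers=min_markers)
            pd.testing.assert_frame_equal(fast, slow, atol=1e-12)

    def test_weighted_mean_consistency_across_resolutions(self):
        """Marker-count-weighted mean of k=4 features equals the k=1 feature."""
        build = default_build()
        manifest = random_manifest(build, 30, seed=11)
        rng = np.random.default_rng(11)
        lrr = pd.DataFrame(
            rng.normal(0, 0.2, (5, len(manifest))),
            index=[f"s{i}" for i in range(5)],
            columns=manifest.marker_ids,
        )
        seg4 = build_segments(build, manifest, 4)
        seg1 = build_segments(build, manifest, 1)
        f4 = compute_cslv(lrr, seg4)
        f1 = compute_cslv(lrr, seg1)
        counts = seg4.table.set_index("feature")["n_markers"]
        for chrom in build.names:
            names = [feature_name(chrom, i) for i in range(1, 5)]
            w = counts[names].to_numpy()
            weighted = (f4[names] * w).sum(axis=1) / w.sum()
            np.testing.assert_allclose(
                weighted.to_numpy(),
                f1[feature_name(chrom, 1)].to_numpy(),
                atol=1e-12,
            )

    def test_invariant_to_row_and_column_order(self, toy_build, toy_manifest, toy_lrr):
        segmap = build_segments(toy_build, toy_manifest, 2)
        base = compute_cslv(toy_lrr, segmap)
        rng = np.random.default_rng(0)
        shuffled = toy_lrr.iloc[
            rng.permutation(len(toy_lrr)), rng.permutation(toy_lrr.shape[1])
        ]
        out = compute_cslv(shuffled, segmap)
        pd.testing.assert_frame_equal(out.loc[base.index, base.columns], base)

    def test_empty_segment_is_missing_with_warning(self, toy_build, caplog):
        table = pd.DataFrame(
            {"marker_id": ["a"], "chromosome": ["1"], "position": [10]}
        )
        manifest = MarkerManifest(table=table, build=toy_build)
        segmap = build_segments(toy_build, manifest, 4)
        lrr = pd.DataFrame([[0.5]], index=["s"], columns=["a"])
        with caplog.at_level(logging.WARNING):
            out = compute_cslv(lrr, segmap)
        assert "no markers" in caplog.text
        assert np.isnan(out.loc["s", "1_seg4"])
        assert out.loc["s", "1_seg1"] == 0.5

    def test_min_markers_threshold(self, toy_build, toy_manifest, toy_lrr):
        segmap = build_segments(toy_build, toy_manifest, 2)
        out = compute_cslv(toy_lrr, segmap, min_markers=3)
        # chromosome 1 has 2 markers per half; below threshold everywhere
        assert out[["1_seg1", "1_seg2"]].isna().all().all()

    def test_features_bounded_by_sample_lrr_range(self, toy_build, toy_manifest, toy_lrr):
        segmap = build_segments(toy_build, toy_manifest, 2)
        out = compute_cslv(toy_lrr, segmap)
        for s in toy_lrr.index:
            row = out.loc[s].dropna()
            assert row.min() >= toy_lrr.loc[s].min() - 1e-12
            assert row.max() <= toy_lrr.loc[s].max() + 1e-12


class TestSummarizeDistribution:
    def test_constant_feature_single_bin_sd_zero(self):
        table = pd.DataFrame({"1_seg1": [0.02] * 10})
        summary = summarize_distribution(table, "1_seg1")
        assert (summary.counts > 0).sum() == 1
        assert summary.sd == pytest.approx(0.0, abs=1e-15)

    def test_counts_sum_to_non_missing_n(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"1_seg1": rng.normal(0, 0.1, 500)})
        table.iloc[:20, 0] = np.nan
        summary = summarize_distribution(table, "1_seg1")
        assert summary.counts.sum() == 480 == summary.n

    def test_simulated_mean_within_clt_bound(self):
        rng = np.random.default_rng(42)
        sigma, n = 0.01, 10_000
        table = pd.DataFrame({"7_seg1": rng.normal(0, sigma, n)})
        summary = summarize_distribution(table, "7_seg1")
        assert abs(summary.mean) < 4 * sigma / np.sqrt(n)

    def test_all_missing_feature_is_error(self):
        table = pd.DataFrame({"1_seg1": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="missing for every sample"):
            summarize_distribution(table, "1_seg1")

    def test_unknown_feature_is_error(self):
        with pytest.raises(KeyError):
            summarize_distribution(pd.DataFrame({"a": [1.0]}), "b")
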
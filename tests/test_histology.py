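"""Synthetic sections, droplet segmentation, size statistics and labelling."""

import numpy as np
import pandas as pd
import pytest

from hepatoscope.histology import (
    DEFAULT_BINS,
    SectionSpec,
    SizeHistogram,
    compare_groups,
    healthy_section_spec,
    label_from_droplets,
    nafld_section_spec,
    read_image,
    render_section,
    segment_droplets,
    size_distribution,
    two_way_anova,
    write_image,
)


def grid_spec(n=10, radius=6.0, noise=0.02):
    """n well-separated disks on a regular grid — exact count known."""
    centers = [(40.0 + 55 * (k // 4), 40.0 + 55 * (k % 4)) for k in range(n)]
    return SectionSpec(size=(256, 256), droplets=tuple((c, radius) for c in centers), noise_scale=noise)


class TestRenderSection:
    def test_same_seed_identical_image(self):
        spec = grid_spec()
        np.testing.assert_array_equal(render_section(spec, 5), render_section(spec, 5))

    def test_zero_droplets_segments_to_nothing(self):
        img = render_section(SectionSpec(droplets=()), seed=1)
        assert len(segment_droplets(img)) == 0

    def test_droplet_outside_canvas_rejected(self):
        with pytest.raises(ValueError):
            SectionSpec(droplets=((( -5.0, 10.0), 3.0),))


class TestSegmentDroplets:
    def test_exact_count_on_non_overlapping_disks(self):
        table = segment_droplets(render_section(grid_spec(10), seed=0))
        assert len(table) == 10

    def test_equivalent_diameters_within_ten_percent(self):
        radius = 6.0
        table = segment_droplets(render_section(grid_spec(8, radius=radius), seed=2))
        np.testing.assert_allclose(table["equivalent_diameter"], 2 * radius, rtol=0.10)

    def test_min_size_filter_drops_specks(self):
        img = render_section(grid_spec(5, radius=6.0, noise=0.0), seed=0)
        img[0, 0] = 1.0  # single-pixel speck
        assert len(segment_droplets(img, min_size=4)) == 5

    def test_blank_image_gives_empty_table(self):
        assert len(segment_droplets(np.zeros((50, 50)))) == 0

    def test_non_finite_pixels_rejected(self):
        img = np.zeros((10, 10))
        img[3, 3] = np.nan
        with pytest.raises(ValueError):
            segment_droplets(img)


class TestSizeDistribution:
    def test_half_open_binning_by_hand(self):
        table = pd.DataFrame({"equivalent_diameter": [2.0, 6.9, 7.0]})
        hist = size_distribution(table, bins=(2, 7, 13))
        assert hist.counts.tolist() == [2, 1]

    def test_total_conserved(self):
        table = segment_droplets(render_section(grid_spec(9), seed=1))
        hist = size_distribution(table, bins=(0.5, 7, 13, 100))
        assert hist.total == len(table)

    def test_empty_table_all_zero(self):
        hist = size_distribution(pd.DataFrame({"equivalent_diameter": []}))
        assert hist.counts.tolist() == [0, 0]

    def test_bad_bins_rejected(self):
        with pytest.raises(ValueError):
            size_distribution(pd.DataFrame({"equivalent_diameter": []}), bins=(7, 2))
        with pytest.raises(ValueError):
            size_distribution(pd.DataFrame({"equivalent_diameter": []}), bins=(2,))


def histograms_for(spec_fn, n, seed0):
    out = []
    for k in range(n):
        img = render_section(spec_fn(seed=seed0 + k), seed=seed0 + k)
        out.append(size_distribution(segment_droplets(img)))
    return out


class TestCompareGroups:
    def test_identical_groups_give_zero_f(self):
        h = SizeHistogram(counts=np.array([3, 1]))
        result = compare_groups([h, h], [h, h])
        assert (result["F"] == 0).all()
        assert (result["p"] == 1).all()

    def test_textbook_f_statistic(self):
        a = [SizeHistogram(counts=np.array([v, 0])) for v in (1, 2, 3)]
        b = [SizeHistogram(counts=np.array([v, 0])) for v in (4, 5, 6)]
        result = compare_groups(a, b)
        # between MS = 13.5, within MS = 1 -> F = 13.5 on (1, 4) df
        assert result["F"].iloc[0] == pytest.approx(13.5)
        assert result["p"].iloc[0] == pytest.approx(0.021311641128756713)

    def test_p_decreases_with_separation(self):
        a = [SizeHistogram(counts=np.array([v, 0])) for v in (1, 2, 3)]
        near = [SizeHistogram(counts=np.array([v + 2, 0])) for v in (1, 2, 3)]
        far = [SizeHistogram(counts=np.array([v + 20, 0])) for v in (1, 2, 3)]
        p_near = compare_groups(a, near)["p"].iloc[0]
        p_far = compare_groups(a, far)["p"].iloc[0]
        assert p_far < p_near

    def test_synthetic_fatty_sections_show_small_droplet_excess(self):
        healthy = histograms_for(healthy_section_spec, 6, 100)
        fatty = histograms_for(nafld_section_spec, 6, 200)
        result = compare_groups(healthy, fatty)
        small = result.iloc[0]
        assert small["mean_b"] > small["mean_a"]
        assert small["p"] < 0.001
        # every fatty section has more small droplets than every healthy one
        h_small = [h.counts[0] for h in healthy]
        f_small = [h.counts[0] for h in fatty]
        assert min(f_small) > max(h_small)

    def test_two_way_anova_finds_group_and_bin_effects(self):
        healthy = histograms_for(healthy_section_spec, 5, 300)
        fatty = histograms_for(nafld_section_spec, 5, 400)
        table = two_way_anova(healthy, fatty)
        assert set(table["effect"]) == {"group", "bin", "group:bin", "residual"}
        assert table.set_index("effect").loc["group", "p"] < 0.01

    def test_too_few_sections_rejected(self):
        h = SizeHistogram(counts=np.array([1, 1]))
        with pytest.raises(ValueError):
            compare_groups([h], [h, h])


class TestLabelFromDroplets:
    def test_all_zero_histogram_is_healthy(self):
        assert label_from_droplets(SizeHistogram(counts=np.array([0, 0]))) == "healthy"

    def test_far_above_threshold_is_nafld(self):
        assert label_from_droplets(SizeHistogram(counts=np.array([500, 3]))) == "nafld"

    def test_threshold_sweep_flips_label_exactly_once(self):
        hist = SizeHistogram(counts=np.array([37, 5]))
        labels = [label_from_droplets(hist, threshold=t) for t in range(0, 80)]
        flips = sum(a != b for a, b in zip(labels, labels[1:]))
        assert flips == 1
        assert labels[0] == "nafld" and labels[-1] == "healthy"

    def test_default_rule_recovers_generating_group(self):
        healthy = histograms_for(healthy_section_spec, 5, 500)
        fatty = histograms_for(nafld_section_spec, 5, 600)
        assert all(label_from_droplets(h) == "healthy" for h in healthy)
        assert all(label_from_droplets(h) == "nafld" for h in fatty)


class TestImageIO:
    def test_tiff_round_trip_lossless_float32(self, tmp_path):
        img = render_section(grid_spec(4), seed=3)
        write_image(tmp_path / "s.tiff", img)
        back = read_image(tmp_path / "s.tiff")
        np.testing.assert_allclose(back, img.astype(np.float32), atol=1e-7)

    def test_png_round_trip_preserves_segmentation(self, tmp_path):
        img = render_section(grid_spec(7), seed=4)
        write_image(tmp_path / "s.png", img)
        back = read_image(tmp_path / "s.png")
        assert len(segment_droplets(back)) == 7
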
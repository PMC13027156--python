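"""Nuclear segmentation pipeline and the Nuclear Enrichment Index."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmtquant import (
    DegenerateImageError,
    FieldImage,
    NoNucleiError,
    SimConfig,
    enrichment_index,
    generate_nuclei_field,
    generate_translocation_field,
    li_threshold,
    quantify_nuclear_batch,
    segment_nuclei,
)
from fmtquant.nuclear import read_records_csv, records_to_frame

from oracles import blobby_image, brute_force_li, flood_fill_label


class TestLiThreshold:
    def test_two_level_histogram_separates_classes(self):
        values = np.array([10.0] * 50 + [200.0] * 50)
        t = li_threshold(values)
        assert 10.0 < t < 200.0

    def test_constant_array_is_degenerate(self):
        with pytest.raises(DegenerateImageError, match="degenerate"):
            li_threshold(np.full((16, 16), 42.0))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_cross_entropy_minimizer(self, seed):
        img = blobby_image(np.random.default_rng(seed))
        t_iter = li_threshold(img)
        t_oracle = brute_force_li(img)
        assert np.array_equal(img >= t_iter, img >= t_oracle)

    def test_shift_equivariance_on_positive_data(self, rng):
        img = blobby_image(rng) + 5.0
        c = 37.0
        assert li_threshold(img + c) == pytest.approx(li_threshold(img) + c, abs=0.5)


class TestSegmentNuclei:
    def test_strict_small_object_exclusion_at_700(self):
        # two rectangles, 699 px and 1500 px, no smoothing so areas are exact
        img = np.zeros((128, 128))
        img[10:30, 10:45] = 200.0  # 20 x 35 = 700, minus one pixel -> 699
        img[10, 10] = 0.0
        img[60:90, 10:60] = 200.0  # 30 x 50 = 1500
        mask = segment_nuclei(img, sigma=0.0, min_area=700)
        assert mask.n_components == 1
        assert mask.component_areas.tolist() == [1500]

    def test_boundary_area_700_is_retained(self):
        img = np.zeros((64, 64))
        img[5:25, 5:40] = 200.0  # exactly 700 px
        mask = segment_nuclei(img, sigma=0.0, min_area=700)
        assert mask.n_components == 1
        assert mask.component_areas.tolist() == [700]

    def test_blank_field_raises_degenerate(self):
        with pytest.raises(DegenerateImageError):
            segment_nuclei(np.zeros((64, 64)))

    def test_recovers_simulated_nuclei_count(self):
        field, truth = generate_nuclei_field(SimConfig(n_nuclei=7, seed=11, image_shape=(320, 320)))
        mask = segment_nuclei(field)
        assert mask.n_components == truth.nuclei_count == 7

    def test_labels_match_flood_fill_oracle(self):
        field, _ = generate_nuclei_field(
            SimConfig(n_nuclei=2, seed=3, image_shape=(64, 64),
                      nucleus_radius_range=(5.0, 7.0))
        )
        mask = segment_nuclei(field, min_area=10)
        oracle = flood_fill_label(mask.labels > 0)
        # same partition into components, up to label order
        assert oracle.max() == mask.n_components
        for k in range(1, oracle.max() + 1):
            assert len(np.unique(mask.labels[oracle == k])) == 1

    def test_min_area_monotonicity(self):
        field, _ = generate_nuclei_field(SimConfig(n_nuclei=6, seed=5, image_shape=(320, 320)))
        masks = [segment_nuclei(field, min_area=a) for a in (0, 700, 1200, 10_000)]
        areas = [m.mask_area for m in masks]
        comps = [m.n_components for m in masks]
        assert areas == sorted(areas, reverse=True)
        assert comps == sorted(comps, reverse=True)


class TestEnrichmentIndex:
    def test_constant_channels_give_exact_ratio(self):
        nuclear = np.zeros((64, 64))
        nuclear[20:40, 20:40] = 50.0
        field = FieldImage(nuclear_channel=nuclear, target_channel=np.full((64, 64), 100.0))
        mask = segment_nuclei(nuclear, sigma=0.0, min_area=100)
        res = enrichment_index(field, mask)
        assert res.index == pytest.approx(2.0)

    def test_identical_channels_give_unity(self, noise_free_field):
        field, _ = noise_free_field
        field = FieldImage(nuclear_channel=field.nuclear_channel,
                           target_channel=field.nuclear_channel.copy())
        res = enrichment_index(field, segment_nuclei(field))
        assert res.index == pytest.approx(1.0, abs=1e-12)

    def test_noise_free_recovery_to_float_tolerance(self, noise_free_field):
        field, truth = noise_free_field
        res = enrichment_index(field, segment_nuclei(field))
        assert truth.true_enrichment_ratio == pytest.approx(1.5, abs=1e-12)
        assert res.index == pytest.approx(truth.true_enrichment_ratio, abs=1e-6)

    def test_empty_mask_raises(self, noise_free_field):
        field, _ = noise_free_field
        mask = segment_nuclei(field, min_area=10**6)
        with pytest.raises(NoNucleiError):
            enrichment_index(field, mask)

    def test_scale_equivariance(self, noise_free_field):
        field, _ = noise_free_field
        mask = segment_nuclei(field)
        base = enrichment_index(field, mask).index
        both = FieldImage(nuclear_channel=field.nuclear_channel * 3.7,
                          target_channel=field.target_channel * 3.7, meta=field.meta)
        assert enrichment_index(both, mask).index == pytest.approx(base, abs=1e-9)
        target_only = FieldImage(nuclear_channel=field.nuclear_channel,
                                 target_channel=field.target_channel * 2.0, meta=field.meta)
        assert enrichment_index(target_only, mask).index == pytest.approx(2 * base, rel=1e-9)

    def test_per_nucleus_diagnostic(self, noise_free_field):
        field, _ = noise_free_field
        mask = segment_nuclei(field)
        res, ratios = enrichment_index(field, mask, per_nucleus=True)
        assert len(ratios) == mask.n_components
        assert np.allclose(ratios, 1.5, atol=1e-6)


class TestBatch:
    def _fields(self, n=3):
        return [
            generate_translocation_field(SimConfig(n_nuclei=3, seed=s))[0]
            for s in range(n)
        ]

    def test_all_valid_fields_give_one_record_each(self):
        records = quantify_nuclear_batch(self._fields(3))
        assert len(records) == 3

    def test_blank_field_is_logged_not_dropped_silently(self, caplog):
        fields = self._fields(2)
        fields.append(FieldImage(nuclear_channel=np.zeros((64, 64)),
                                 target_channel=np.zeros((64, 64))))
        with caplog.at_level(logging.WARNING):
            records = quantify_nuclear_batch(fields)
        assert len(records) == 2
        assert any("failed quantification" in r.message for r in caplog.records)

    def test_all_failing_batch_raises(self):
        blank = FieldImage(nuclear_channel=np.zeros((32, 32)),
                           target_channel=np.zeros((32, 32)))
        with pytest.raises(RuntimeError, match="all .* failed"):
            quantify_nuclear_batch([blank])

    def test_records_round_trip_through_frame(self, tmp_path):
        records = quantify_nuclear_batch(self._fields(3))
        frame = records_to_frame(records)
        path = tmp_path / "records.csv"
        frame.to_csv(path, index=False)
        back = read_records_csv(path)
        assert back == records


@settings(derandomize=True, max_examples=25, deadline=None)
@given(scale=st.floats(min_value=0.1, max_value=10.0))
def test_index_scale_equivariance_property(scale):
    """Multiplying both channels by any positive constant leaves the index fixed."""
    cfg = SimConfig(n_nuclei=3, seed=42, noise_sd=0.0)
    field, _ = generate_translocation_field(cfg)
    mask = segment_nuclei(field)
    base = enrichment_index(field, mask).index
    scaled = FieldImage(nuclear_channel=field.nuclear_channel * scale,
                        target_channel=field.target_channel * scale)
    assert enrichment_index(scaled, mask).index == pytest.approx(base, abs=1e-9)
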
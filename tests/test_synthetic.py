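"""Synthetic event generator: determinism, conservation, planted truth."""

import dataclasses

import numpy as np
import pytest

from nuctrans.synthetic import (
    CellEvent,
    SyntheticPopulationSpec,
    disk_coverage,
    disk_mask,
    generate_cell_event,
    generate_population,
    generate_ss_samples,
    mixed_population,
)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"nucleus_radius_px": 25.0},  # nucleus outside cell
            {"cell_radius_px": 40.0},  # cell outside image
            {"nuclear_fraction_mean": 1.5},
            {"nuclear_fraction_sd": -0.1},
            {"noise_sd": -1.0},
            {"noise_model": "laplace"},
            {"planted_gate_category": "triplet"},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticPopulationSpec(n_events=1, **kwargs)

    def test_mismatched_channel_shapes_rejected(self):
        with pytest.raises(ValueError):
            CellEvent(
                event_id="x",
                channel_images={
                    "nuclear": np.zeros((4, 4)),
                    "reporter": np.zeros((5, 5)),
                },
                brightfield_area=1.0,
                aspect_ratio=1.0,
                livedead_intensity=0.0,
                nuclear_stain_total=0.0,
            )


class TestRasterization:
    def test_pixel_center_membership(self):
        mask = disk_mask((7, 7), (3.0, 3.0), 2.0)
        # pixel (3,5) center exactly at distance 2 -> inside (<=)
        assert mask[3, 5] and mask[3, 1]
        assert not mask[0, 0]
        assert mask.sum() == 13

    def test_coverage_matches_area(self):
        cov = disk_coverage((64, 64), (31.5, 31.5), 10.0)
        assert cov.sum() == pytest.approx(np.pi * 100, rel=0.01)
        assert cov.max() == 1.0 and cov.min() == 0.0


class TestGenerateCellEvent:
    def test_fraction_zero_leaves_nucleus_interior_empty(self, noise_free_spec):
        rng = np.random.default_rng(0)
        event = generate_cell_event(noise_free_spec, 0.0, rng)
        truth = event.truth
        interior = disk_mask(
            noise_free_spec.image_shape,
            _mask_center(truth.nucleus_mask),
            noise_free_spec.nucleus_radius_px - 1.5,
        )
        assert np.all(event.channel_images["reporter"][interior] == 0)

    def test_fraction_one_leaves_cytoplasm_interior_empty(self, noise_free_spec):
        rng = np.random.default_rng(0)
        event = generate_cell_event(noise_free_spec, 1.0, rng)
        center = _mask_center(event.truth.nucleus_mask)
        shape = noise_free_spec.image_shape
        annulus_interior = disk_mask(
            shape, center, noise_free_spec.cell_radius_px - 1.5
        ) & ~disk_mask(shape, center, noise_free_spec.nucleus_radius_px + 1.5)
        assert annulus_interior.sum() > 0
        assert np.all(event.channel_images["reporter"][annulus_interior] == 0)

    def test_invalid_fraction_rejected(self, default_spec):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            generate_cell_event(default_spec, 1.2, rng)

    def test_seeded_determinism(self, default_spec):
        a = generate_cell_event(default_spec, 0.4, np.random.default_rng(11))
        b = generate_cell_event(default_spec, 0.4, np.random.default_rng(11))
        for channel in a.channel_images:
            np.testing.assert_array_equal(
                a.channel_images[channel], b.channel_images[channel]
            )
        assert a.brightfield_area == b.brightfield_area

    def test_reporter_conservation_before_noise(self):
        # background 0 and noise 0 isolate the deposited reporter intensity
        spec = SyntheticPopulationSpec(
            n_events=1, noise_sd=0.0, background_level=0.0
        )
        event = generate_cell_event(spec, 0.37, np.random.default_rng(3))
        total = event.channel_images["reporter"].sum()
        assert total == pytest.approx(spec.reporter_total_intensity, rel=0.01)

    def test_poisson_noise_yields_integer_counts(self):
        spec = SyntheticPopulationSpec(n_events=1, noise_model="poisson")
        event = generate_cell_event(spec, 0.5, np.random.default_rng(3))
        image = event.channel_images["reporter"]
        np.testing.assert_array_equal(image, np.round(image))
        assert image.std() > 0

    def test_crosstalk_adds_nuclear_signal_to_reporter(self):
        base = SyntheticPopulationSpec(
            n_events=1, noise_sd=0.0, background_level=0.0
        )
        bled = dataclasses.replace(base, crosstalk=0.5)
        clean = generate_cell_event(base, 0.0, np.random.default_rng(5))
        dirty = generate_cell_event(bled, 0.0, np.random.default_rng(5))
        extra = (
            dirty.channel_images["reporter"] - clean.channel_images["reporter"]
        )
        np.testing.assert_allclose(
            extra, 0.5 * clean.channel_images["nuclear"], atol=1e-9
        )


class TestGeneratePopulation:
    def test_empty_population(self):
        assert generate_population(SyntheticPopulationSpec(n_events=0)) == []

    def test_degenerate_fraction_distribution(self):
        spec = SyntheticPopulationSpec(
            n_events=8, nuclear_fraction_mean=0.5, nuclear_fraction_sd=0.0
        )
        assert all(e.truth.nuclear_fraction == 0.5 for e in generate_population(spec))

    def test_fractions_clipped_to_unit_interval(self):
        spec = SyntheticPopulationSpec(
            n_events=50, nuclear_fraction_mean=0.95, nuclear_fraction_sd=0.5, seed=2
        )
        fractions = [e.truth.nuclear_fraction for e in generate_population(spec)]
        assert all(0.0 <= f <= 1.0 for f in fractions)
        assert max(fractions) == 1.0  # clipping actually engaged

    def test_population_regeneration_is_byte_identical(self, default_spec):
        first = generate_population(default_spec)
        second = generate_population(default_spec)
        for a, b in zip(first, second):
            assert a.event_id == b.event_id
            for channel in a.channel_images:
                assert (
                    a.channel_images[channel].tobytes()
                    == b.channel_images[channel].tobytes()
                )

    def test_high_fraction_population_scores_above_low(self):
        """Median downstream SS separates nuclear from cytoplasmic groups."""
        from nuctrans.scoring import score_events

        medians = {}
        for mean, seed in [(0.2, 21), (0.8, 22)]:
            spec = SyntheticPopulationSpec(
                n_events=200, nuclear_fraction_mean=mean, seed=seed,
                group_label=f"m{mean}",
            )
            scores = score_events(generate_population(spec))
            medians[mean] = np.median([s.ss for s in scores if s.valid])
        assert medians[0.8] > medians[0.2]


class TestSsSamples:
    def test_zero_variance(self):
        np.testing.assert_array_equal(
            generate_ss_samples(0.3, 0.0, 5, seed=1), np.full(5, 0.3)
        )

    def test_mean_recovery(self):
        samples = generate_ss_samples(1.0, 0.5, 1000, seed=9)
        assert abs(samples.mean() - 1.0) < 0.05

    def test_seeded_determinism(self):
        a = generate_ss_samples(0.1, 0.2, 100, seed=4)
        b = generate_ss_samples(0.1, 0.2, 100, seed=4)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("n", [0, -3])
    def test_nonpositive_n_rejected(self, n):
        with pytest.raises(ValueError):
            generate_ss_samples(0.0, 1.0, n, seed=0)


def test_mixed_population_counts_and_labels():
    base = SyntheticPopulationSpec(n_events=0, noise_sd=0.0, seed=1)
    events = mixed_population({"singlet_live_nucleated": 4, "dead": 3}, base)
    assert len(events) == 7
    categories = [e.truth.gate_category for e in events]
    assert categories.count("singlet_live_nucleated") == 4
    assert categories.count("dead") == 3


def _mask_center(mask: np.ndarray) -> tuple[float, float]:
    rows, cols = np.nonzero(mask)
    return float(rows.mean()), float(cols.mean())
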
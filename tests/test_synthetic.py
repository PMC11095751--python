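import numpy as np
import pytest

from diveresp.segmentation import segment_dives
from diveresp.synthetic import (SimulationConfig, TruthDive, WhaleSpec,
                                default_params, render_dive, sample_labels,
                                simulate_dataset)


def small_config(**kw):
    defaults = dict(
        whales=[WhaleSpec("w0"), WhaleSpec("w1", age_class="adult_male")],
        record_duration=3000.0,
        hhmm_params=default_params(),
        depth_noise_sd=0.05,
        label_coverage=0.3,
        label_bias_scale=15.0,
        seed=42,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestRenderDive:
    def test_noiseless_v_shape(self):
        rng = np.random.default_rng(0)
        samples = render_dive(20.0, 60.0, 10.0, 2.0, 0.0, rng)
        assert samples.size == 120 + 20
        dive = samples[:120]
        assert dive.max() == pytest.approx(20.0)
        assert np.all(dive > 0.5)
        assert np.all(samples[120:] <= 0.5)

    def test_u_shape_has_bottom_time(self):
        rng = np.random.default_rng(0)
        dive = render_dive(20.0, 60.0, 0.0, 2.0, 0.0, rng, shape="u")
        assert np.sum(np.isclose(dive, 20.0)) >= 58  # ~50 % bottom time

    def test_roundtrip_through_segmentation(self, rng):
        from diveresp.segmentation import DepthRecord
        for _ in range(20):
            dur = float(rng.uniform(5, 120))
            si = float(rng.uniform(2, 30))
            depth = float(rng.uniform(2, 80))
            trace = np.concatenate([
                np.zeros(4),
                render_dive(depth, dur, si, 2.0, 0.02, rng),
            ])
            dives = segment_dives(DepthRecord("w", trace, 2.0), 0.5)
            assert len(dives) == 1
            assert abs(dives[0].dive_duration - round(dur * 2) / 2) <= 0.5

    def test_below_threshold_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            render_dive(0.4, 60.0, 10.0, 2.0, 0.0, np.random.default_rng(0))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            render_dive(20.0, 0.4, 10.0, 2.0, 0.0, np.random.default_rng(0))


class TestSampleLabels:
    def _truth(self, depths):
        return [TruthDive("shallow", "travelling", d, 30.0, 5.0, 0)
                for d in depths]

    def test_zero_coverage(self, rng):
        labels = sample_labels(self._truth([5.0] * 100), 0.0, 10.0, rng)
        assert labels == [None] * 100

    def test_full_coverage_unbiased(self, rng):
        labels = sample_labels(self._truth([5.0] * 100), 1.0, np.inf, rng)
        assert all(l == "travelling" for l in labels)

    def test_shallow_bias(self, rng):
        # 5 m vs 50 m dives with a 10 m e-folding depth: shallow dives must
        # be labeled more often in at least 95 % of replicates
        truth = self._truth([5.0] * 50 + [50.0] * 50)
        wins = 0
        for _ in range(1000):
            labels = sample_labels(truth, 0.3, 10.0, rng)
            shallow = sum(l is not None for l in labels[:50])
            deep = sum(l is not None for l in labels[50:])
            wins += shallow > deep
        assert wins >= 950

    def test_labels_never_contradict_truth(self, rng):
        ds = simulate_dataset(small_config())
        for wid, labels in ds.labels.items():
            for dive, lab in zip(ds.truth_dives[wid], labels):
                assert lab is None or lab == dive.behaviour


class TestSimulateDataset:
    def test_fixed_seed_reproducibility(self):
        a = simulate_dataset(small_config())
        b = simulate_dataset(small_config())
        for ra, rb in zip(a.depth_records, b.depth_records):
            np.testing.assert_array_equal(ra.depth, rb.depth)
        assert a.truth_dives == b.truth_dives
        assert a.labels == b.labels

    def test_absorbing_resting_chain(self):
        params = default_params()
        params.pi_coarse = np.array([1.0, 0.0, 0.0])
        params.gamma_coarse = np.eye(3)
        ds = simulate_dataset(small_config(hhmm_params=params))
        for tracks in ds.truth_tracks.values():
            assert all(t.behaviour == "resting" for t in tracks)

    def test_segmentation_recovers_truth_exactly(self):
        ds = simulate_dataset(small_config())
        for rec in ds.depth_records:
            dives = segment_dives(rec, ds.config.dive_threshold)
            truth = ds.truth_dives[rec.whale_id]
            assert len(dives) == len(truth)
            for d, t in zip(dives, truth):
                assert d.dive_duration == pytest.approx(t.dive_duration)
                assert d.surface_interval == pytest.approx(t.surface_interval)
                assert abs(d.max_depth - t.max_depth) <= \
                    0.2 + 4 * ds.config.depth_noise_sd

    def test_stationary_distribution_of_track_behaviours(self):
        # empirical behaviour frequencies over many tracks approach the
        # coarse chain's stationary distribution (eigen-decomposition oracle)
        params = default_params()
        cfg = small_config(
            whales=[WhaleSpec(f"w{i}") for i in range(20)],
            record_duration=18000.0,
            track_min_duration=60.0,  # short tracks: cheap, same chain
            label_coverage=0.0,
            seed=3,
        )
        ds = simulate_dataset(cfg)
        behaviours = [t.behaviour for ts in ds.truth_tracks.values() for t in ts]
        assert len(behaviours) >= 4000
        vals, vecs = np.linalg.eig(params.gamma_coarse.T)
        stat = np.real(vecs[:, np.argmax(np.real(vals))])
        stat /= stat.sum()
        freq = np.array([behaviours.count(b) for b in params.behaviours],
                        dtype=float)
        freq /= freq.sum()
        np.testing.assert_allclose(freq, stat, atol=0.02)

    def test_emission_moments_match_generator(self):
        cfg = small_config(
            whales=[WhaleSpec(f"w{i}") for i in range(10)],
            record_duration=42000.0, depth_noise_sd=0.0, seed=9)
        ds = simulate_dataset(cfg)
        params = cfg.hhmm_params
        dives = [d for ds_ in ds.truth_dives.values() for d in ds_]
        assert len(dives) >= 10000
        for ti, tname in enumerate(params.dive_types):
            durs = np.array([d.dive_duration for d in dives if d.dive_type == tname])
            if durs.size < 100:
                continue
            a, scale = params.emissions[ti, 1]
            mean, sd = a * scale, np.sqrt(a) * scale
            se = sd / np.sqrt(durs.size)
            # quantization to the 0.5 s grid adds at most a quarter-sample bias
            assert abs(durs.mean() - mean) <= 3 * se + 0.25

    def test_incomplete_final_track_flagged(self):
        ds = simulate_dataset(small_config(record_duration=1500.0))
        for tracks in ds.truth_tracks.values():
            assert all(t.complete for t in tracks[:-1])

    def test_invalid_coverage_rejected(self):
        with pytest.raises(ValueError):
            small_config(label_coverage=1.5)

    def test_impossible_emissions_error(self):
        params = default_params()
        # shallow depths far below the dive threshold: rejection must trip
        params.emissions[0, 0] = (1.0, 0.01)
        with pytest.raises(ValueError, match="invalid emission"):
            simulate_dataset(small_config(hhmm_params=params,
                                          label_coverage=0.0))
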
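"""Determinism, noise model, and ground-truth bookkeeping of the generator."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import i0e

from zfmri.errors import DomainError, ValidationError
from zfmri.io import read_contours, read_landmarks, read_roi_spec, read_series, \
    write_contours, write_landmarks, write_roi_spec, write_series
from zfmri.relaxometry import t2_signal
from zfmri.synthetic import (Compartment, GroupDeltas, PhantomSpec,
                             make_fiber_set, make_phantom, rician,
                             simulate_cohort, simulate_morphometry_cohort,
                             simulate_series)


class TestPhantom:
    def test_identical_compartments_give_constant_t2_inside_brain(self, small_spec):
        spec = dataclasses.replace(
            small_spec, white=dataclasses.replace(small_spec.grey))
        ph = make_phantom(spec)
        t2 = ph.t2.data[ph.masks["brain"]]
        assert np.all(t2 == t2[0])

    def test_deterministic_given_spec(self, small_spec):
        a = make_phantom(small_spec)
        b = make_phantom(small_spec)
        np.testing.assert_array_equal(a.m0.data, b.m0.data)
        assert a.morpho_landmarks.points == b.morpho_landmarks.points

    def test_scaled_brain_scales_truth_ratio(self, small_spec):
        scaled = dataclasses.replace(
            small_spec, brain_length_mm=small_spec.brain_length_mm * 0.93)
        ref = make_phantom(small_spec, volumes=False).truth["normalized_length"]
        new = make_phantom(scaled, volumes=False).truth["normalized_length"]
        assert new == pytest.approx(0.93 * ref, rel=1e-12)

    def test_geometry_violations_rejected(self):
        with pytest.raises(ValidationError):
            PhantomSpec(brain_width_mm=10.0)  # wider than the skull
        with pytest.raises(ValidationError):
            PhantomSpec(shape=(8, 8, 4))
        with pytest.raises(ValidationError):
            Compartment(8000, -1, 75)

    def test_masks_partition_tissue(self, small_phantom):
        m = small_phantom.masks
        assert not (m["grey"] & m["white"]).any()
        assert ((m["grey"] | m["white"]) == m["brain"]).all()
        assert not (m["brain"] & m["skull"]).any()

    def test_generated_tables_roundtrip_through_io(self, small_phantom, tmp_path):
        write_landmarks({"morpho": small_phantom.morpho_landmarks},
                        tmp_path / "lm.tsv")
        assert read_landmarks(tmp_path / "lm.tsv")["morpho"].points == \
            small_phantom.morpho_landmarks.points
        write_roi_spec(small_phantom.roi_spec, tmp_path / "roi.yaml")
        assert read_roi_spec(tmp_path / "roi.yaml") == small_phantom.roi_spec


class TestSimulateSeries:
    def test_noiseless_equals_signal_model(self, small_phantom):
        sim = simulate_series(small_phantom, "T2", noise_sigma=0.0,
                              n_repetitions=1, motion=False)
        for vol, te in zip(sim.series.volumes, sim.series.times_ms):
            expected = t2_signal(small_phantom.m0.data, small_phantom.t2.data, te)
            np.testing.assert_allclose(vol.data, expected, rtol=1e-12)

    def test_signal_at_zero_echo_time_is_m0(self, small_phantom):
        s = t2_signal(small_phantom.m0.data, small_phantom.t2.data, 0.0)
        np.testing.assert_array_equal(s, small_phantom.m0.data)

    def test_determinism_same_seed(self, small_phantom):
        a = simulate_series(small_phantom, "T2", seed=9)
        b = simulate_series(small_phantom, "T2", seed=9)
        for va, vb in zip(a.series.volumes, b.series.volumes):
            np.testing.assert_array_equal(va.data, vb.data)

    def test_different_seed_differs(self, small_phantom):
        a = simulate_series(small_phantom, "T2", seed=9)
        b = simulate_series(small_phantom, "T2", seed=10)
        assert not np.array_equal(a.series.volumes[0].data,
                                  b.series.volumes[0].data)

    def test_default_repetition_counts_follow_acquisition(self, small_phantom):
        t1 = simulate_series(small_phantom, "T1", noise_sigma=10.0)
        t2 = simulate_series(small_phantom, "T2", noise_sigma=10.0)
        assert len(t1.series.repetitions[0]) == 4
        assert len(t2.series.repetitions[0]) == 9

    def test_negative_sigma_rejected(self, small_phantom):
        with pytest.raises(DomainError):
            simulate_series(small_phantom, "T2", noise_sigma=-1.0)

    def test_series_roundtrips_through_io(self, small_phantom, tmp_path):
        sim = simulate_series(small_phantom, "T2", noise_sigma=50.0,
                              n_repetitions=2, seed=4)
        write_series(sim.series, tmp_path / "s")
        back = read_series(tmp_path / "s")
        np.testing.assert_array_equal(back.volumes[1].data,
                                      sim.series.volumes[1].data)


def rician_mean_numint(s, sigma):
    """Numerically integrated mean of the Rician distribution (oracle)."""
    def integrand(x):
        return (x * x / sigma ** 2 * np.exp(-((x - s) ** 2) / (2 * sigma ** 2))
                * i0e(x * s / sigma ** 2))
    val, _ = quad(integrand, 0, s + 12 * sigma, limit=200)
    return val


class TestRician:
    def test_sample_mean_matches_numerical_integration(self):
        rng = np.random.default_rng(17)
        s, sigma, n = 5000.0, 500.0, 10_000
        draws = rician(np.full(n, s), sigma, rng)
        oracle = rician_mean_numint(s, sigma)
        se = draws.std(ddof=1) / np.sqrt(n)
        assert abs(draws.mean() - oracle) < 3 * se
        # high-SNR expansion agrees with the integral at this SNR
        assert np.sqrt(s ** 2 + 2 * sigma ** 2) == pytest.approx(oracle, rel=5e-3)

    def test_zero_sigma_is_identity(self):
        x = np.array([1.0, 2.0, 3.0])
        rng = np.random.default_rng(0)
        np.testing.assert_array_equal(rician(x, 0.0, rng), x)


class TestCohorts:
    def test_determinism(self):
        a = simulate_cohort(2, seed=3)
        b = simulate_cohort(2, seed=3)
        for da, db in zip(a, b):
            assert da.phantom.spec == db.phantom.spec

    def test_zero_variability_exposes_pure_group_deltas(self):
        deltas = GroupDeltas(0.85, 0.9, 0.95, 1.2)
        cohort = simulate_cohort(1, seed=0, deltas=deltas, size_cv=0.0, t2_cv=0.0)
        wt = next(d for d in cohort if d.group == "wildtype").phantom.spec
        mut = next(d for d in cohort if d.group == "mutant").phantom.spec
        assert mut.brain_length_mm == pytest.approx(wt.brain_length_mm * 0.85)
        assert mut.brain_width_mm == pytest.approx(wt.brain_width_mm * 0.9)
        assert mut.brain_height_mm == pytest.approx(wt.brain_height_mm * 0.95)
        assert mut.white.t2 == pytest.approx(wt.white.t2 * 1.2)
        assert mut.grey.t2 == wt.grey.t2

    def test_morphometry_cohort_recovers_declared_difference(self):
        wt = np.concatenate([simulate_morphometry_cohort(6, 0.85, 0.05, seed=s)[0]
                             for s in range(40)])
        mut = np.concatenate([simulate_morphometry_cohort(6, 0.85, 0.05, seed=s)[1]
                              for s in range(40)])
        assert mut.mean() / wt.mean() == pytest.approx(0.85, abs=0.02)

    def test_invalid_group_size_rejected(self):
        with pytest.raises(ValidationError):
            simulate_cohort(0)


class TestFiberSets:
    def test_same_seed_identical_table(self):
        t1, truth1 = make_fiber_set(20, 0.6, 0.05, seed=7)
        t2, truth2 = make_fiber_set(20, 0.6, 0.05, seed=7)
        np.testing.assert_array_equal(t1.fibers[3].myelin, t2.fibers[3].myelin)
        assert truth1.equals(truth2)

    def test_zero_jitter_realizes_truth_exactly(self):
        table, truth = make_fiber_set(25, 0.6, 0.08, jitter_sd=0.0, seed=2)
        from zfmri.gratio import compute_table_metrics
        for m, g in zip(compute_table_metrics(table), truth["g_true"]):
            assert m.g_ratio == pytest.approx(g, rel=1e-12)

    def test_large_sample_mean_within_three_se(self):
        n = 5000
        table, truth = make_fiber_set(n, 0.5, 0.05, seed=13)
        se = 0.05 / np.sqrt(n)
        assert abs(truth["g_true"].mean() - 0.5) < 3 * se

    def test_contours_roundtrip_through_io(self, tmp_path):
        table, _ = make_fiber_set(5, 0.6, 0.05, jitter_sd=0.01, seed=1)
        write_contours(table, tmp_path / "f.tsv")
        back = read_contours(tmp_path / "f.tsv")
        assert len(back.fibers) == 5
        np.testing.assert_allclose(back.fibers[2].axon, table.fibers[2].axon,
                                   rtol=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            make_fiber_set(5, g_mean=1.2)
        with pytest.raises(ValidationError):
            make_fiber_set(5, 0.5, n_vertices=4)
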
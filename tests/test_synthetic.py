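"""Generators: seeded determinism, planted-truth structure, zero-noise exactness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from stnpipe import locomotion as loco
from stnpipe import microarray as ma
from stnpipe import spectra as sp
from stnpipe import synthetic as syn


class TestExpressionGenerator:
    def zero_noise_truth(self, slr=-2.0):
        return syn.ExpressionTruth(
            hfs_down=[3],
            lesion_up=[3],
            counter_regulated=[3],
            hfs_slr={3: slr},
            lesion_slr={3: 1.5},
            animal_sd=0.0,
            hemisphere_noise_sd=0.0,
            probe_affinity_sd=0.0,
            seed=1,
        )

    def test_zero_noise_summarized_difference_is_exact(self):
        ds, truth = syn.gen_expression_dataset(self.zero_noise_truth(), n_probesets=10)
        stim = ds.intensities[3, :, ds.sample_index("PD1_stim")]
        non = ds.intensities[3, :, ds.sample_index("PD1_nonstim")]
        slr = ma.signal_log_ratio(non, stim)
        assert slr.slr == pytest.approx(-2.0)

    def test_same_seed_bit_identical(self):
        t1 = syn.default_expression_truth(n_probesets=50, n_hfs_only=2, n_lesion_only=2, n_counter=2, seed=5)
        t2 = syn.default_expression_truth(n_probesets=50, n_hfs_only=2, n_lesion_only=2, n_counter=2, seed=5)
        d1, _ = syn.gen_expression_dataset(t1, n_probesets=50)
        d2, _ = syn.gen_expression_dataset(t2, n_probesets=50)
        assert np.array_equal(d1.intensities, d2.intensities)

    def test_noisy_probe_log_ratio_within_three_se(self):
        truth = syn.ExpressionTruth(
            hfs_down=[0],
            lesion_up=[],
            counter_regulated=[],
            hfs_slr={0: -2.0},
            lesion_slr={},
            animal_sd=0.0,
            hemisphere_noise_sd=0.2,
            probe_affinity_sd=0.0,
            seed=9,
        )
        ds, _ = syn.gen_expression_dataset(truth, n_probesets=5, probes_per_set=11)
        diffs = []
        for animal in ("PD1", "PD2"):
            stim = np.log2(ds.intensities[0, :, ds.sample_index(f"{animal}_stim")])
            non = np.log2(ds.intensities[0, :, ds.sample_index(f"{animal}_nonstim")])
            diffs.append(stim - non)
        diffs = np.concatenate(diffs)
        se = np.sqrt(2 * 0.2**2 / diffs.size)
        assert abs(diffs.mean() - (-2.0)) <= 3 * se

    def test_planted_gene_outside_range_rejected(self):
        truth = self.zero_noise_truth()
        with pytest.raises(ValueError):
            syn.gen_expression_dataset(truth, n_probesets=3)

    def test_duplicate_sample_ids_rejected(self):
        manifest = syn.default_manifest(2)
        manifest.loc[1, "sample_id"] = manifest.loc[0, "sample_id"]
        with pytest.raises(ValueError):
            syn.gen_expression_dataset(self.zero_noise_truth(), n_probesets=10, manifest=manifest)

    def test_counter_genes_must_be_in_both_classes(self):
        with pytest.raises(ValueError):
            syn.ExpressionTruth(
                hfs_down=[1],
                lesion_up=[2],
                counter_regulated=[1],
                hfs_slr={1: -2.0},
                lesion_slr={2: 1.5},
            )


class TestTrackGenerator:
    def test_rest_only_speeds_below_noise_level(self):
        truth = syn.TrackTruth(
            schedule=[(0.0, 30.0, "rest")],
            peak_speeds_cm_s=[],
            rest_jitter_step_cm=0.05,
            seed=2,
        )
        track, _ = syn.gen_locomotion_track(truth)
        speed = loco.compute_speed(track)
        assert np.all(speed <= 4.0)

    def test_constant_bout_displacement(self):
        truth = syn.TrackTruth(
            schedule=[(0.0, 2.0, "rest"), (2.0, 5.0, "motion"), (5.0, 7.0, "rest")],
            peak_speeds_cm_s=[10.0],
            seed=3,
        )
        track, truth = syn.gen_locomotion_track(truth)
        assert truth.realized_path_cm[0] == pytest.approx(10.0 * 3.0, rel=0.03)

    def test_positions_stay_inside_arena(self):
        truth = syn.default_track_truth(n_bouts=30, seed=7)
        track, _ = syn.gen_locomotion_track(truth)
        w, h = truth.arena_cm
        assert track.x.min() >= 0 and track.x.max() <= w
        assert track.y.min() >= 0 and track.y.max() <= h

    def test_same_seed_identical(self):
        a, _ = syn.gen_locomotion_track(syn.default_track_truth(seed=4))
        b, _ = syn.gen_locomotion_track(syn.default_track_truth(seed=4))
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)

    def test_excess_jitter_rejected(self):
        truth = syn.TrackTruth(
            schedule=[(0.0, 10.0, "rest")],
            peak_speeds_cm_s=[],
            rest_jitter_step_cm=1.0,
            seed=0,
        )
        with pytest.raises(ValueError):
            syn.gen_locomotion_track(truth)

    def test_overlapping_schedule_rejected(self):
        with pytest.raises(ValueError):
            syn.TrackTruth(
                schedule=[(0.0, 5.0, "rest"), (4.0, 8.0, "motion")],
                peak_speeds_cm_s=[10.0],
            )


class TestSignalGenerator:
    def test_psd_slope_matches_one_over_f_exponent(self):
        truth = syn.SignalTruth(
            duration_s=60.0,
            one_over_f_exponent=1.0,
            oscillation_amplitude=0.0,
            line_amplitude=0.0,
            seed=6,
        )
        rec, _ = syn.gen_field_potentials(truth, n_channels=1)
        freqs, psd = sp.welch_psd(rec.channels["ch0"], rec.fs_hz, segment_s=4.0)
        sel = (freqs >= 2) & (freqs <= 100)
        slope = sps.linregress(np.log10(freqs[sel]), np.log10(psd[sel])).slope
        assert slope == pytest.approx(-1.0, abs=0.15)

    def test_pure_sinusoid_peaks_at_32hz(self):
        truth = syn.SignalTruth(
            duration_s=20.0, noise_scale=0.0, oscillation_amplitude=1.0, line_amplitude=0.0, seed=1
        )
        rec, _ = syn.gen_field_potentials(truth, n_channels=1)
        freqs, psd = sp.welch_psd(rec.channels["ch0"], rec.fs_hz)
        assert freqs[np.argmax(psd)] == pytest.approx(32.0, abs=0.5)

    def test_same_seed_identical(self):
        a, _ = syn.gen_field_potentials(syn.SignalTruth(duration_s=11.0, seed=3), n_channels=2)
        b, _ = syn.gen_field_potentials(syn.SignalTruth(duration_s=11.0, seed=3), n_channels=2)
        assert np.array_equal(a.channels["ch1"], b.channels["ch1"])

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            syn.SignalTruth(oscillation_amplitude=-1.0)

    def test_undersampled_components_rejected(self):
        with pytest.raises(ValueError):
            syn.SignalTruth(fs_hz=50.0)


class TestStereoGenerator:
    def test_zero_density_all_counts_zero(self):
        truth = syn.StereoTruth(density_per_roi={"SNc": 0.0}, seed=1)
        sample, _ = syn.gen_cell_sections(truth)
        assert (sample.table["count"] == 0).all()

    def test_poisson_total_near_expectation(self):
        truth = syn.StereoTruth(
            density_per_roi={"SNc": 2000.0}, n_sections=6, sites_per_section=100, seed=8
        )
        sample, _ = syn.gen_cell_sections(truth)
        total = sample.table["count"].sum()
        assert abs(total - 60) <= 4 * np.sqrt(60)  # mean 2000 * 5e-5 mm^3 * 600

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            syn.StereoTruth(density_per_roi={"SNc": -1.0})


class TestQpcrGenerator:
    def test_zero_noise_zero_slr(self):
        plate, _ = syn.gen_qpcr_plate({"g": 0.0}, ct_noise_sd=0.0, seed=0)
        from stnpipe import assays

        out = assays.delta_delta_ct(plate, "g", "Rpl13a", "stim", "nonstim")
        assert np.allclose(out["slr"], 0.0)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_qpcr_plate({"g": -1.0}, ct_noise_sd=-0.1)


def test_stage_rngs_are_independent():
    # regenerating one stage must not disturb another stage's stream
    a = syn.stage_rng(42, "expression").normal(size=5)
    _ = syn.stage_rng(42, "locomotion").normal(size=100)
    b = syn.stage_rng(42, "expression").normal(size=5)
    assert np.array_equal(a, b)
    c = syn.stage_rng(42, "signals").normal(size=5)
    assert not np.array_equal(a, c)


def test_truth_json_sidecar(tmp_path):
    truth = syn.default_expression_truth(n_probesets=50, n_hfs_only=2, n_lesion_only=2, n_counter=1, seed=1)
    syn.write_truth_json(truth, tmp_path / "truth.json")
    import json

    loaded = json.loads((tmp_path / "truth.json").read_text())
    assert loaded["counter_regulated"] == truth.counter_regulated
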
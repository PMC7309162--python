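import dataclasses

import numpy as np
import pytest

from patchlead import synth
from patchlead.records import STANDARD_LEADS
from patchlead.synth import (BeatMorphology, PathologySpec, SynthConfig,
                             SynthConfigError, apply_pathology,
                             default_morphology, ectopic_morphology,
                             make_dipole_trajectory, patch_leadfield,
                             project_leads, standard12_leadfield,
                             synth_paired_recording)


class TestDipoleTrajectory:
    def test_zero_amplitudes_give_zero_dipole(self):
        m = default_morphology()
        for w in synth.WAVES:
            m.amps[w] = np.zeros(3)
        d, _ = make_dipole_trajectory(m, duration=10.0, fs=250.0)
        assert np.all(d == 0.0)

    def test_60bpm_r_peaks_at_half_plus_k_seconds(self):
        _, beats = make_dipole_trajectory(default_morphology(60.0),
                                          duration=10.0, fs=250.0,
                                          rr_jitter=0.0)
        r = np.array([b.r_time for b in beats])
        np.testing.assert_allclose(r, 0.5 + np.arange(10), atol=1 / 250.0)

    def test_analytic_qrs_duration_matches_phase_arithmetic(self):
        m = default_morphology(60.0)
        # independent closed-form width-to-time conversion
        span_rad = (m.centers["S"] + 3 * m.widths["S"]) - \
            (m.centers["Q"] - 3 * m.widths["Q"])
        expected_s = span_rad / (2 * np.pi) * 1.0  # RR = 1 s at 60 bpm
        assert m.qrs_duration_s() == pytest.approx(expected_s, abs=1 / 250.0)
        _, beats = make_dipole_trajectory(m, 10.0, 250.0)
        for b in beats:
            measured = b.fiducials["qrs_off"] - b.fiducials["qrs_on"]
            assert measured == pytest.approx(expected_s, abs=1 / 250.0)

    def test_invalid_config_rejected(self):
        with pytest.raises(SynthConfigError):
            make_dipole_trajectory(default_morphology(), duration=-1.0,
                                   fs=250.0)
        with pytest.raises(SynthConfigError):
            make_dipole_trajectory(default_morphology(), duration=10.0,
                                   fs=0.0)


class TestLeadFields:
    def test_limb_lead_identities_hold_in_rows(self):
        lf = standard12_leadfield()
        row = dict(zip(lf.lead_names, lf.matrix))
        np.testing.assert_allclose(row["III"], row["II"] - row["I"])
        np.testing.assert_allclose(row["aVR"], -(row["I"] + row["II"]) / 2)
        np.testing.assert_allclose(row["aVL"], row["I"] - row["II"] / 2)
        np.testing.assert_allclose(row["aVF"], row["II"] - row["I"] / 2)

    def test_patch_rows_full_rank_for_positive_kappa(self):
        assert np.linalg.matrix_rank(patch_leadfield(1.0).matrix) == 3
        assert np.linalg.matrix_rank(patch_leadfield(0.3).matrix) == 3

    def test_zero_dipole_projects_to_zero(self):
        rec = project_leads(np.zeros((50, 3)), standard12_leadfield())
        assert np.all(rec.data == 0.0)

    def test_unit_pulse_reproduces_leadfield_column_times_gain(self):
        # dipole pulse along x: lead values = first leadfield column * gain
        lf = standard12_leadfield()
        d = np.zeros((5, 3))
        d[2, 0] = 1.0
        rec = project_leads(d, lf, nonlinearity=0.0)
        np.testing.assert_allclose(rec.data[2],
                                   lf.matrix[:, 0] * synth.GAIN_UV,
                                   atol=1e-9)

    def test_einthoven_residual_zero_without_nonlinearity(self, clean_paired):
        t = clean_paired.target
        resid = t.lead("II") - t.lead("I") - t.lead("III")
        assert np.abs(resid).max() <= 1e-9

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            project_leads(np.zeros((10, 2)), standard12_leadfield())


class TestPathology:
    def test_none_is_identity(self):
        m = default_morphology()
        out = apply_pathology(m, PathologySpec("none"))
        assert out.centers == m.centers and out.widths == m.widths
        for w in synth.WAVES:
            np.testing.assert_array_equal(out.amps[w], m.amps[w])

    def test_wide_qrs_hits_requested_duration(self):
        out = apply_pathology(default_morphology(),
                              PathologySpec("wide_qrs", 140.0))
        assert out.qrs_duration_s() * 1000 == pytest.approx(140.0, abs=4.0)

    def test_st_elevation_measured_on_clean_signal(self):
        spec = PathologySpec("st_elevation", 0.15)
        cfg = SynthConfig(pathologies=(spec,), noise_white_uv=0.0,
                          wander_uv=0.0, rr_jitter=0.0, seed=0)
        p = synth_paired_recording(cfg)
        x = p.target.lead("II")
        fs = p.fs
        devs = []
        for b in p.beats:
            j = b.fiducials["qrs_off"]
            t_on = b.fiducials["t_on"]
            lo = int((j + 0.040) * fs)
            hi = int(t_on * fs)
            base = np.mean(x[int((b.fiducials["qrs_on"] - 0.045) * fs):
                             int((b.fiducials["qrs_on"] - 0.005) * fs)])
            devs.append(np.mean(x[lo:hi]) - base)
        assert np.mean(devs) / 1000.0 == pytest.approx(0.15, abs=0.02)

    def test_t_inversion_flips_t_amplitude(self):
        m = default_morphology()
        out = apply_pathology(m, PathologySpec("t_inversion"))
        np.testing.assert_allclose(out.amps["T"], -m.amps["T"])

    def test_pathologic_q_sets_depth_fraction(self):
        m = default_morphology()
        out = apply_pathology(m, PathologySpec("pathologic_q", 0.375))
        np.testing.assert_allclose(out.amps["Q"], -0.375 * m.amps["R"])

    def test_ectopic_has_no_p_wide_qrs_inverted_t(self):
        e = ectopic_morphology()
        assert not np.any(e.amps["P"])
        assert e.qrs_duration_s() * 1000 == pytest.approx(140.0, abs=4.0)
        d = default_morphology()
        assert np.all(e.amps["T"] * d.amps["T"] <= 0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(SynthConfigError):
            PathologySpec("flutter")

    def test_magnitude_bounds_enforced(self):
        with pytest.raises(SynthConfigError):
            PathologySpec("wide_qrs", 250.0)
        with pytest.raises(SynthConfigError):
            PathologySpec("st_elevation", 0.9)


class TestPairedRecording:
    def test_sample_counts(self, clean_paired):
        assert clean_paired.patch.n_samples == 2500
        assert clean_paired.target.n_samples == 2500
        assert clean_paired.patch.n_leads == 3
        assert clean_paired.target.n_leads == 12
        assert clean_paired.target.lead_names == STANDARD_LEADS

    def test_target_exactly_affine_in_patch_when_linear(self, clean_paired):
        X = np.column_stack([clean_paired.patch.data,
                             np.ones(clean_paired.n_samples)])
        Y = clean_paired.target.data
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        assert np.sqrt(np.mean(resid ** 2)) <= 1e-6

    def test_seed_determinism(self):
        cfg = dict(nonlinearity=0.2, seed=42)
        a = synth_paired_recording(SynthConfig(**cfg))
        b = synth_paired_recording(SynthConfig(**cfg))
        np.testing.assert_array_equal(a.patch.data, b.patch.data)
        np.testing.assert_array_equal(a.target.data, b.target.data)
        assert [x.r_time for x in a.beats] == [x.r_time for x in b.beats]
        c = synth_paired_recording(SynthConfig(nonlinearity=0.2, seed=43))
        assert not np.array_equal(a.patch.data, c.patch.data)

    @pytest.mark.parametrize("rate", [45.0, 60.0, 90.0, 120.0])
    def test_beat_count_and_r_alignment(self, rate):
        cfg = SynthConfig(morphology=default_morphology(rate),
                          noise_white_uv=0.0, wander_uv=0.0, rr_jitter=0.0,
                          seed=5)
        p = synth_paired_recording(cfg)
        expected = int(10.0 * rate / 60.0)
        assert abs(len(p.beats) - expected) <= 1
        x = p.target.lead("II")
        for b in p.beats:
            r = int(round(b.r_time * p.fs))
            lo, hi = max(r - 2, 0), min(r + 3, len(x))
            # local extremum of lead II within ±2 samples of ground truth
            assert np.argmax(x[lo:hi]) + lo in range(r - 2, r + 3)

    def test_ground_truth_fiducials_ordered(self, clean_paired):
        order = synth.FIDUCIAL_KEYS
        for b in clean_paired.beats:
            times = [b.fiducials[k] for k in order
                     if b.fiducials[k] is not None]
            assert times == sorted(times)

    def test_ground_truth_json_round_trip(self, clean_paired, tmp_path):
        path = tmp_path / "gt.json"
        synth.write_ground_truth(clean_paired.beats, path)
        back = synth.read_ground_truth(path)
        assert len(back) == len(clean_paired.beats)
        assert back[0].r_time == pytest.approx(clean_paired.beats[0].r_time)
        assert back[0].fiducials["t_off"] == pytest.approx(
            clean_paired.beats[0].fiducials["t_off"])
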
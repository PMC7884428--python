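"""Semi-infinite diffusion forward model and multi-distance inversion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fddos.cohort import ArtifactSpec, inject_artifacts, synthesize_raw_frames
from fddos.diffusion import (
    ProbeGeometry,
    fit_multidistance,
    forward_semiinfinite,
    invert_slopes,
    musp_alternate,
    qc_filter,
)

GEOM = ProbeGeometry()


def _frames(mua, musp, geom=GEOM, **kwargs):
    optical = pd.DataFrame({"t_s": [0.0], "mua_785": [mua], "musp_785": [musp]})
    return synthesize_raw_frames(optical, geom, **kwargs)


class TestForwardSlopes:
    def test_slope_identities_reference_point(self):
        alpha, beta = forward_semiinfinite(0.15, 9.3, GEOM)
        assert alpha**2 - beta**2 == pytest.approx(3 * 0.15 * 9.3, rel=1e-10)
        assert alpha * beta == pytest.approx(
            3 * 9.3 * GEOM.omega / (2 * GEOM.v), rel=1e-10
        )

    @given(
        mua=st.floats(0.02, 0.5),
        musp=st.floats(2.0, 20.0),
        f_mhz=st.floats(50.0, 300.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_slope_identities_property(self, mua, musp, f_mhz):
        geom = ProbeGeometry(modulation_freq_hz=f_mhz * 1e6)
        alpha, beta = forward_semiinfinite(mua, musp, geom)
        assert alpha > beta > 0
        assert alpha**2 - beta**2 == pytest.approx(3 * mua * musp, rel=1e-10)
        assert alpha * beta == pytest.approx(
            3 * musp * geom.omega / (2 * geom.v), rel=1e-10
        )

    def test_zero_frequency_limit(self):
        geom = ProbeGeometry(modulation_freq_hz=1.0)  # ~DC
        alpha, beta = forward_semiinfinite(0.15, 9.3, geom)
        assert alpha == pytest.approx(np.sqrt(3 * 0.15 * 9.3), rel=1e-6)
        assert beta == pytest.approx(0.0, abs=1e-3)

    def test_quadratic_scaling_of_attenuation(self):
        a1, b1 = forward_semiinfinite(0.1, 8.0, GEOM)
        a2, b2 = forward_semiinfinite(0.2, 16.0, GEOM)
        assert a2**2 - b2**2 == pytest.approx(4 * (a1**2 - b1**2), rel=1e-10)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            forward_semiinfinite(-0.1, 9.0, GEOM)
        with pytest.raises(ValueError):
            forward_semiinfinite(0.1, 0.0, GEOM)


class TestGeometryValidation:
    def test_requires_three_separations(self):
        with pytest.raises(ValueError):
            ProbeGeometry(separations_cm=(1.5, 2.0))

    def test_requires_increasing_separations(self):
        with pytest.raises(ValueError):
            ProbeGeometry(separations_cm=(2.0, 1.5, 2.5))


class TestMultidistanceInversion:
    def test_round_trip_reference(self):
        rec = fit_multidistance(_frames(0.15, 9.3), GEOM)
        assert rec["mua_785"].iloc[0] == pytest.approx(0.15, rel=1e-6)
        assert rec["musp_785"].iloc[0] == pytest.approx(9.3, rel=1e-6)

    def test_round_trip_grid(self):
        for mua in np.linspace(0.05, 0.3, 4):
            for musp in np.linspace(5.0, 15.0, 4):
                rec = fit_multidistance(_frames(mua, musp), GEOM)
                assert rec["mua_785"].iloc[0] == pytest.approx(mua, rel=1e-6)
                assert rec["musp_785"].iloc[0] == pytest.approx(musp, rel=1e-6)

    def test_noise_free_linearity_r2(self):
        rec = fit_multidistance(_frames(0.12, 11.0), GEOM)
        assert rec["r2_amp_785"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert rec["r2_phase_785"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_amplitude_scale_invariance(self):
        r1 = fit_multidistance(_frames(0.15, 9.3, amplitude=1e6), GEOM)
        r2 = fit_multidistance(_frames(0.15, 9.3, amplitude=2e6), GEOM)
        assert r1["mua_785"].iloc[0] == pytest.approx(r2["mua_785"].iloc[0], rel=1e-12)
        assert r1["musp_785"].iloc[0] == pytest.approx(r2["musp_785"].iloc[0], rel=1e-12)

    def test_musp_closed_forms_agree(self):
        alpha, beta = forward_semiinfinite(0.18, 7.5, GEOM)
        mua, musp = invert_slopes(alpha, beta, GEOM)
        assert musp == pytest.approx(musp_alternate(alpha, beta, GEOM), rel=1e-8)

    def test_light_leak_biases_fit_and_drops_r2(self):
        frames = _frames(0.15, 9.3)
        leak = frames.copy()
        # r-independent floor several times the far-detector signal
        leak["ac"] = leak["ac"] + 5.0 * leak["ac"].min()
        rec = fit_multidistance(leak, GEOM)
        assert rec["r2_amp_785"].iloc[0] < 0.97
        assert rec["mua_785"].iloc[0] != pytest.approx(0.15, rel=1e-3)

    def test_amplitude_noise_bias_vanishes_with_noise(self):
        """Median |bias| of recovered mua decreases monotonically as the
        log-amplitude noise goes to zero."""
        biases = []
        for sigma in (0.02, 0.005, 0.00125):
            rng = np.random.default_rng(7)
            errs = []
            for _ in range(100):
                frames = _frames(0.15, 9.3, sigma_ln_ac=sigma, rng=rng)
                rec = fit_multidistance(frames, GEOM)
                errs.append(abs(rec["mua_785"].iloc[0] - 0.15))
            biases.append(np.median(errs))
        assert biases[0] > biases[1] > biases[2]

    def test_empty_frames_rejected(self):
        with pytest.raises(ValueError):
            fit_multidistance(pd.DataFrame(columns=["t_s"]), GEOM)


class TestQCFilter:
    def _series(self, n=100, r2=1.0):
        return pd.DataFrame(
            {
                "t_s": np.arange(n, dtype=float),
                "mua_785": 0.15,
                "musp_785": 9.3,
                "r2_amp_785": r2,
                "r2_phase_785": 1.0,
                "qc_pass": True,
            }
        )

    def test_clean_series_untouched(self):
        out, report = qc_filter(self._series(), 0.97, cpr_window=(0.0, 100.0))
        assert out["qc_pass"].all()
        assert report.n_fail == 0
        assert not report.subject_excluded

    def test_zero_threshold_flags_nothing(self):
        noisy = self._series(r2=0.5)
        out, _ = qc_filter(noisy, r2_min=0.0)
        assert out["qc_pass"].all()

    def test_window_exclusion_when_artifact_covers_epoch(self):
        s = self._series(n=700)
        s.loc[(s["t_s"] >= 540) & (s["t_s"] < 600), "r2_amp_785"] = 0.5
        out, report = qc_filter(
            s, 0.97, windows={"cpr_10min": (540.0, 600.0), "cpr_1min": (60.0, 75.0)}
        )
        assert report.window_excluded["cpr_10min"]
        assert not report.window_excluded["cpr_1min"]

    def test_qc_flags_cover_strong_artifacts(self):
        """In the strong-artifact regime every truth-masked frame fails QC."""
        optical = pd.DataFrame(
            {
                "t_s": np.arange(50, dtype=float),
                "mua_785": 0.15,
                "musp_785": 9.3,
            }
        )
        frames = synthesize_raw_frames(optical, GEOM)
        spec = ArtifactSpec(probability=1.0, duration_s=(10.0, 10.0))
        corrupted, mask = inject_artifacts(frames, spec, seed=3)
        rec = fit_multidistance(corrupted, GEOM)
        rec, _ = qc_filter(rec, 0.97)
        flagged = set(rec.loc[~rec["qc_pass"], "t_s"])
        masked = set(mask.loc[mask["artifact"], "t_s"])
        assert masked  # artifact actually injected
        assert masked <= flagged  # recall = 1


class TestArtifactInjection:
    def _frames(self):
        optical = pd.DataFrame(
            {"t_s": np.arange(30, dtype=float), "mua_785": 0.15, "musp_785": 9.3}
        )
        return synthesize_raw_frames(optical, GEOM)

    def test_zero_probability_is_identity(self):
        frames = self._frames()
        out, mask = inject_artifacts(frames, ArtifactSpec(probability=0.0), seed=1)
        pd.testing.assert_frame_equal(out, frames)
        assert not mask["artifact"].any()

    def test_seeded_mask_reproducible(self):
        frames = self._frames()
        spec = ArtifactSpec(probability=1.0, duration_s=(5.0, 15.0))
        _, m1 = inject_artifacts(frames, spec, seed=11)
        _, m2 = inject_artifacts(frames, spec, seed=11)
        pd.testing.assert_frame_equal(m1, m2)
        assert m1["artifact"].any()

    def test_overlong_artifact_rejected(self):
        frames = self._frames()
        spec = ArtifactSpec(probability=1.0, duration_s=(1000.0, 2000.0))
        with pytest.raises(ValueError):
            inject_artifacts(frames, spec, seed=0)

    def test_probe_shift_breaks_phase_fit(self):
        frames = self._frames()
        spec = ArtifactSpec(
            probability=1.0, duration_s=(25.0, 25.0), kind="probe_shift",
            shift_phase_rad=0.5,
        )
        corrupted, mask = inject_artifacts(
            frames, spec, seed=0, force_window=(0.0, 25.0)
        )
        rec = fit_multidistance(corrupted, GEOM)
        hit = rec["t_s"] < 25.0
        assert (rec.loc[hit, "r2_phase_785"] < 0.97).all()
        assert (rec.loc[~hit, "r2_phase_785"] > 0.99).all()
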
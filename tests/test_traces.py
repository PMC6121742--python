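"""TIRF trace processing: bleach detection, backgrounds, profiles, gamma."""

import numpy as np
import pytest

import fretkit as fk
from fretkit.traces import (
    GammaNotComputable,
    InsufficientPostBleachError,
    InvalidProfileError,
    Trace,
)


def _step_trace(level=1000.0, bleach=20, n=40, other=(1000.0, 1000.0)):
    """Donor channel stepping to zero at ``bleach``; flat other channels."""
    dd = np.full(n, level)
    dd[bleach:] = 0.0
    return Trace(dd, np.full(n, other[0]), np.full(n, other[1]))


class TestDetectBleaching:
    def test_noiseless_step_found_exactly(self):
        n = 40
        aa = np.full(n, 800.0)
        aa[20:] = 0.0
        trace = Trace(np.full(n, 500.0), np.full(n, 300.0), aa)
        ann = fk.detect_bleaching(trace)
        assert ann.acceptor_bleach_frame == 20

    def test_two_step_decay_flagged_invalid(self):
        """Two acceptor bleach steps indicate two acceptors."""
        aa = np.r_[np.full(15, 1000.0), np.full(15, 500.0), np.full(15, 0.0)]
        noise = np.random.default_rng(0).normal(0, 5, 45)
        trace = Trace(np.full(45, 400.0) + noise, np.full(45, 200.0), aa + noise)
        ann = fk.detect_bleaching(trace)
        assert not ann.valid

    def test_analysis_range_stops_at_earliest_bleach(self):
        n = 40
        dex_total = np.full(n, 900.0)
        dex_total[12:] = 10.0
        trace = Trace(dex_total * 0.6, dex_total * 0.4, np.full(n, 700.0))
        ann = fk.detect_bleaching(trace)
        rng = ann.analysis_range(trace)
        assert rng.stop == ann.donor_bleach_frame == 12

    def test_detection_error_small_at_good_snr(self, lab_factors):
        """Median absolute bleach-frame error <= 1 frame at SNR >= 5."""
        truth = fk.GroundTruth(
            species=[fk.SpeciesSpec("DA", E_true=0.5, brightness=500)],
            factors=lab_factors,
            seed=21,
        )
        traces, gt = fk.simulate_tirf_traces(
            truth, 150, bleach_means=(40.0, 15.0), n_frames=60
        )
        errors = []
        for tr, (_, row) in zip(traces, gt.iterrows()):
            ann = fk.detect_bleaching(tr)
            if not np.isnan(row["acceptor_bleach"]) and ann.acceptor_bleach_frame:
                errors.append(abs(ann.acceptor_bleach_frame - row["acceptor_bleach"]))
        assert len(errors) > 50
        assert np.median(errors) <= 1.0


class TestTraceBackground:
    def test_post_bleach_offset_recovered(self):
        n = 40
        dd = np.full(n, 1100.0)
        dd[10:] = 100.0
        aa = np.full(n, 900.0)
        aa[8:] = 100.0
        ad = np.full(n, 100.0)
        trace = Trace(dd, ad, aa)
        ann = fk.detect_bleaching(trace)
        bg = fk.estimate_background_trace(trace, ann)
        assert bg[0] == pytest.approx(100.0)
        assert bg[2] == pytest.approx(100.0)

    def test_insufficient_post_bleach_frames_signalled(self):
        n = 12
        dd = np.full(n, 1000.0)
        dd[n - 2 :] = 0.0
        aa = np.full(n, 800.0)
        aa[n - 2 :] = 0.0
        trace = Trace(dd, np.full(n, 100.0), aa)
        ann = fk.BleachAnnotation(n - 2, n - 2, True)
        with pytest.raises(InsufficientPostBleachError):
            fk.estimate_background_trace(trace, ann)

    def test_drifting_background_local_mask_tracks_true_mean(self):
        """With a linear drift, the local-mask estimate matches the true
        local mean while the post-bleach offset reports the late value."""
        n = 60
        drift = 50.0 + 0.5 * np.arange(n)
        dd = drift + 800.0 * (np.arange(n) < 20)
        aa = drift + 600.0 * (np.arange(n) < 25)
        trace = Trace(dd, drift.copy(), aa)
        ann = fk.BleachAnnotation(20, 25, True)
        local = fk.estimate_background_trace(
            trace, ann, method="local-mask", local_bg=drift
        )
        true_local_mean = drift[:20].mean()
        assert local[0] == pytest.approx(true_local_mean, rel=0.01)
        post = fk.estimate_background_trace(trace, ann)
        assert post[0] > local[0]  # drift makes the late offset larger

    def test_zero_background_estimates_near_zero(self, lab_factors):
        truth = fk.GroundTruth(
            species=[fk.SpeciesSpec("DA", E_true=0.5, brightness=400)],
            factors=lab_factors,
            seed=4,
        )
        traces, _ = fk.simulate_tirf_traces(
            truth, 40, bleach_means=(15.0, 10.0), n_frames=80,
            read_noise=1.0, bg_rates=(0.0, 0.0, 0.0),
        )
        estimates = []
        for tr in traces:
            ann = fk.detect_bleaching(tr)
            try:
                estimates.append(fk.estimate_background_trace(tr, ann))
            except InsufficientPostBleachError:
                continue
        assert len(estimates) > 10
        assert np.mean(estimates) == pytest.approx(0.0, abs=1.0)


class TestProfileNormalize:
    def test_equal_profiles_identity(self):
        prof = fk.ExcitationProfile(np.ones((8, 8)), np.ones((8, 8)))
        trace = Trace(np.full(5, 10.0), np.full(5, 5.0), np.full(5, 7.0), position=(3, 3))
        out = fk.profile_normalize(trace, prof)
        np.testing.assert_allclose(out.I_AemAex, trace.I_AemAex)

    def test_ratio_two_doubles_acceptor_excitation_channel(self):
        prof = fk.ExcitationProfile(np.full((8, 8), 2.0), np.ones((8, 8)))
        trace = Trace(np.full(5, 10.0), np.full(5, 5.0), np.full(5, 7.0), position=(2, 2))
        out = fk.profile_normalize(trace, prof)
        np.testing.assert_allclose(out.I_AemAex, 14.0)
        np.testing.assert_allclose(out.I_DemDex, trace.I_DemDex)

    def test_zero_profile_rejected(self):
        prof = fk.ExcitationProfile(np.ones((4, 4)), np.zeros((4, 4)))
        trace = Trace(np.ones(5), np.ones(5), np.ones(5), position=(1, 1))
        with pytest.raises(InvalidProfileError):
            fk.profile_normalize(trace, prof)

    def test_gaussian_profiles_narrow_s_population(self, lab_factors):
        """Position-specific normalization shrinks the S spread of a
        simulated dataset recorded under mismatched excitation profiles."""
        yy, xx = np.mgrid[0:64, 0:64]
        prof_d = np.exp(-((xx - 32) ** 2 + (yy - 32) ** 2) / (2 * 40.0**2))
        prof_a = np.exp(-((xx - 20) ** 2 + (yy - 40) ** 2) / (2 * 25.0**2))
        profile = fk.ExcitationProfile(prof_d, prof_a)
        truth = fk.GroundTruth(
            species=[fk.SpeciesSpec("DA", E_true=0.5, brightness=800)],
            factors=fk.CorrectionFactors(),
            seed=6,
        )
        traces, _ = fk.simulate_tirf_traces(
            truth, 150, bleach_means=(1e9, 1e9), n_frames=20,
            profile=profile, field_shape=(64, 64), bg_rates=(0, 0, 0),
        )

        def s_width(trs):
            s_vals = []
            for tr in trs:
                dex = tr.I_DemDex.mean() + tr.I_AemDex.mean()
                s_vals.append(dex / (dex + tr.I_AemAex.mean()))
            return np.std(s_vals)

        normalized = [fk.profile_normalize(tr, profile) for tr in traces]
        assert s_width(normalized) < s_width(traces)


class TestIndividualGamma:
    def test_exact_jump_ratio(self):
        """Acceptor drop 200 against donor rise 100 gives gamma = 2."""
        n = 30
        ad = np.full(n, 250.0)
        ad[15:] = 50.0
        dd = np.full(n, 300.0)
        dd[15:] = 400.0
        aa = np.full(n, 500.0)
        aa[15:] = 0.0
        trace = Trace(dd, ad, aa)
        ann = fk.BleachAnnotation(donor_bleach_frame=None, acceptor_bleach_frame=15, valid=True)
        assert fk.individual_gamma(trace, ann) == pytest.approx(2.0)

    def test_donor_first_bleach_not_computable(self):
        trace = _step_trace(bleach=10, n=30)
        ann = fk.BleachAnnotation(donor_bleach_frame=10, acceptor_bleach_frame=20, valid=True)
        with pytest.raises(GammaNotComputable):
            fk.individual_gamma(trace, ann)

    def test_parameter_recovery_over_traces(self):
        """Mean molecule-wise gamma within 5% of truth over 200 traces."""
        factors = fk.CorrectionFactors(alpha=0.02, beta=1.0, gamma=0.8, delta=0.02)
        truth = fk.GroundTruth(
            species=[fk.SpeciesSpec("DA", E_true=0.5, brightness=600)],
            factors=factors,
            seed=13,
        )
        traces, _ = fk.simulate_tirf_traces(
            truth, 200, bleach_means=(60.0, 15.0), n_frames=80
        )
        gammas = []
        for tr in traces:
            ann = fk.detect_bleaching(tr)
            if not ann.valid:
                continue
            try:
                bg = fk.estimate_background_trace(tr, ann)
            except InsufficientPostBleachError:
                bg = (2.0, 2.0, 2.0)
            try:
                gammas.append(fk.individual_gamma(tr, ann, bg=bg))
            except GammaNotComputable:
                continue
        assert len(gammas) > 50
        assert np.mean(gammas) == pytest.approx(0.8, rel=0.05)
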
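"""Cosinor estimator: exact recovery, parameter derivation, classification,
bootstrap uncertainty and conditional R²."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhythmix.cosinor import (BootstrapSettings, bootstrap_se,
                              classify_rhythmic, conditional_r2,
                              cosinor_design, derive_rhythm_params,
                              fit_cosinor_intercept, fit_cosinor_slopes,
                              fit_session, zscore_within)

from conftest import ols_cosinor

TAU = 24.0


class TestDesign:
    @pytest.mark.parametrize("t,x1,x2", [
        (0.0, 1.0, 0.0),
        (6.0, 0.0, 1.0),
        (12.0, -1.0, 0.0),
    ])
    def test_cardinal_points(self, t, x1, x2):
        d = cosinor_design([t], TAU)
        assert d.x1[0] == pytest.approx(x1, abs=1e-12)
        assert d.x2[0] == pytest.approx(x2, abs=1e-12)

    def test_periodicity(self):
        a = cosinor_design([3.0], TAU)
        b = cosinor_design([TAU + 3.0], TAU)
        assert a.x1[0] == pytest.approx(b.x1[0], abs=1e-12)
        assert a.x2[0] == pytest.approx(b.x2[0], abs=1e-12)

    def test_unit_norm_rows(self):
        d = cosinor_design(np.linspace(0, 48, 33), TAU)
        assert np.allclose(d.x1**2 + d.x2**2, 1.0, atol=1e-12)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError, match="tau"):
            cosinor_design([0.0], 0.0)


class TestZscore:
    def test_closed_form(self):
        z, deg = zscore_within(np.array([1.0, 2.0, 3.0]), ["a"] * 3)
        assert np.allclose(z, [-1.0, 0.0, 1.0])
        assert not deg.any()

    def test_constant_series_flagged_zero(self):
        z, deg = zscore_within(np.array([5.0, 5.0, 5.0]), ["a"] * 3)
        assert np.allclose(z, 0.0) and deg.all()

    def test_random_series_standardized(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=12)
        g = ["a"] * 6 + ["b"] * 6
        z, _ = zscore_within(y, g)
        for lab in ("a", "b"):
            m = np.array(g) == lab
            assert abs(z[m].mean()) < 1e-12
            assert abs(z[m].std(ddof=1) - 1.0) < 1e-12


class TestDeriveRhythmParams:
    @pytest.mark.parametrize("b1,b2,acro", [
        (1.0, 0.0, 0.0),      # pure cosine peaks at t=0
        (0.0, 1.0, 6.0),      # pure sine peaks at tau/4
        (-1.0, 0.0, 12.0),    # negated cosine
        (0.0, -1.0, 18.0),
        (1.0, 1.0, 3.0),
        (1.0, -1.0, 21.0),
        (-1.0, 1.0, 9.0),
        (-1.0, -1.0, 15.0),
    ])
    def test_quadrants_and_axes(self, b1, b2, acro):
        amp, phi, a = derive_rhythm_params(b1, b2, TAU)
        assert amp == pytest.approx(np.hypot(b1, b2))
        assert a == pytest.approx(acro, abs=1e-10)

    def test_zero_slopes_flagged_undefined(self):
        amp, phi, acro = derive_rhythm_params(0.0, 0.0, TAU)
        assert amp == 0.0 and np.isnan(phi) and np.isnan(acro)

    def test_acrophase_matches_grid_argmax(self):
        rng = np.random.default_rng(1)
        b1 = rng.normal(size=1000)
        b2 = rng.normal(size=1000)
        amp, phi, acro = derive_rhythm_params(b1, b2, TAU)
        grid = np.arange(0.0, TAU, 1.0 / 60.0)   # 1-minute grid
        curve = np.outer(b1, np.cos(2 * np.pi * grid / TAU)) + \
            np.outer(b2, np.sin(2 * np.pi * grid / TAU))
        t_best = grid[np.argmax(curve, axis=1)]
        d = np.abs((acro - t_best + TAU / 2) % TAU - TAU / 2)
        assert d.max() <= 1.0 / 120.0 + 1e-9

    def test_amplitude_identity(self):
        rng = np.random.default_rng(2)
        b1, b2 = rng.normal(size=50), rng.normal(size=50)
        amp, *_ = derive_rhythm_params(b1, b2, TAU)
        assert np.allclose(amp, np.sqrt(b1**2 + b2**2), atol=1e-10)


class TestClassifyRhythmic:
    def test_all_ones_give_nothing(self):
        r, f1, f2 = classify_rhythmic(np.ones(10), np.ones(10))
        assert not r.any() and np.allclose(f1, 1.0)

    def test_single_transcript_bh_is_identity(self):
        r, f1, _ = classify_rhythmic([0.04], [0.9])
        assert r[0] and f1[0] == pytest.approx(0.04)

    def test_bh_textbook_worked_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        _, f1, _ = classify_rhythmic(p, np.ones(5))
        assert np.allclose(f1, 0.05)

    def test_nan_pvalues_excluded_and_nonrhythmic(self):
        r, f1, _ = classify_rhythmic([0.001, np.nan], [0.5, np.nan])
        assert r[0] and not r[1] and np.isnan(f1[1])


def _session_frame(P=10, offsets_sd=0.5, rng=None):
    rng = rng or np.random.default_rng(0)
    tp = np.array([15.0, 19.0, 23.0, 27.0, 31.0, 35.0])
    offs = rng.normal(8.0, offsets_sd, P)
    t = np.concatenate([tp - o for o in offs])
    groups = np.repeat([f"P{i:02d}" for i in range(P)], 6)
    return t, groups


class TestFits:
    def test_noiseless_slopes_fit_is_exact(self):
        t, groups = _session_frame()
        d = cosinor_design(t, TAU, participants=groups)
        y = 0.6 * d.x1 + 0.8 * d.x2
        fit = fit_cosinor_slopes(y, d)
        assert np.allclose(fit.beta[0], [0.6, 0.8], atol=1e-6)
        amp, _, _ = derive_rhythm_params(*fit.beta[0], TAU)
        assert amp == pytest.approx(1.0, abs=1e-6)

    def test_noiseless_intercept_fit_recovers_mesor(self):
        t, groups = _session_frame()
        d = cosinor_design(t, TAU, participants=groups)
        y = 5.0 + 0.3 * d.x1 - 0.4 * d.x2
        fit = fit_cosinor_intercept(y, d)
        assert fit.beta[0, 0] == pytest.approx(5.0, abs=1e-6)
        assert np.allclose(fit.beta[0, 1:], [0.3, -0.4], atol=1e-6)

    def test_zero_random_variance_equals_ols(self):
        rng = np.random.default_rng(3)
        t, groups = _session_frame(rng=rng)
        d = cosinor_design(t, TAU, participants=groups)
        y = 2.0 + 0.5 * d.x1 - 0.2 * d.x2 + rng.normal(0, 0.3, len(t))
        fit = fit_cosinor_intercept(y, d)
        ref = ols_cosinor(y, t, TAU)
        assert np.allclose(fit.beta[0], ref, atol=1e-6)

    def test_participant_offsets_absorbed_by_intercept_variance(self):
        rng = np.random.default_rng(4)
        t, groups = _session_frame(rng=rng)
        d = cosinor_design(t, TAU, participants=groups)
        offs = rng.normal(0, 1.0, 10)
        codes = np.repeat(np.arange(10), 6)
        y = 3.0 + 0.5 * d.x1 + offs[codes] + rng.normal(0, 0.2, len(t))
        fit = fit_cosinor_intercept(y, d)
        clean = fit_cosinor_intercept(3.0 + 0.5 * d.x1 + rng.normal(0, 0.2, len(t)), d)
        # fixed rhythm estimates barely move; intercept variance ≈ offset var
        assert np.allclose(fit.beta[0, 1:], clean.beta[0, 1:], atol=0.1)
        assert fit.cov_re[0, 0, 0] == pytest.approx(offs.var(ddof=1), rel=0.6)

    def test_amplitude_invariant_to_time_origin(self):
        t, groups = _session_frame()
        for delta in (0.0, 3.3, 11.0):
            d0 = cosinor_design(t, TAU, participants=groups)
            d1 = cosinor_design(t + delta, TAU, participants=groups)
            y = 1.2 * d0.x1 - 0.7 * d0.x2
            f0 = fit_cosinor_slopes(y, d0)
            f1 = fit_cosinor_slopes(y, d1)
            a0, _, ac0 = derive_rhythm_params(*f0.beta[0], TAU)
            a1, _, ac1 = derive_rhythm_params(*f1.beta[0], TAU)
            assert a1 == pytest.approx(a0, abs=1e-8)
            assert (ac1 - ac0) % TAU == pytest.approx(delta % TAU, abs=1e-6)


class TestBootstrap:
    def test_zero_noise_gives_zero_se(self):
        t, groups = _session_frame()
        d = cosinor_design(t, TAU, participants=groups)
        y = 4.0 + 0.5 * d.x1 + 0.5 * d.x2
        bs = bootstrap_se(y, d, variant="intercept",
                          settings=BootstrapSettings(50, seed=1))
        assert bs["se_mes"] == pytest.approx(0.0, abs=1e-8)
        assert bs["se_amp"] == pytest.approx(0.0, abs=1e-8)
        assert bs["se_acro_circ"] == pytest.approx(0.0, abs=1e-6)

    def test_circular_se_respects_wraparound(self):
        from scipy.stats import circstd
        reps = np.array([23.9, 0.1])
        se = circstd(reps, high=TAU, low=0.0)
        assert se < 0.2           # ≈ 0.1 h, not ≈ 12 h
        assert se == pytest.approx(0.1, abs=0.05)

    def test_bootstrap_amp_se_near_delta_method(self):
        rng = np.random.default_rng(6)
        P = 40
        tp = np.array([15.0, 19.0, 23.0, 27.0, 31.0, 35.0])
        t = np.tile(tp, P)
        groups = np.repeat(np.arange(P), 6)
        d = cosinor_design(t, TAU, participants=groups)
        sigma = 0.5
        y = 2.0 + 1.0 * d.x1 + rng.normal(0, sigma, len(t))
        bs = bootstrap_se(y, d, variant="intercept",
                          settings=BootstrapSettings(200, seed=2))
        # iid noise: Var(b1)=sigma^2/(n/2); amp SE ≈ SE(b1) at b2≈0
        se_delta = sigma / np.sqrt(len(t) / 2)
        assert bs["se_amp"] == pytest.approx(se_delta, rel=0.25)


class TestConditionalR2:
    def test_degenerate_extremes(self):
        t, groups = _session_frame()
        d = cosinor_design(t, TAU, participants=groups)
        y_sig = 1.0 * d.x1
        fit = fit_cosinor_slopes(y_sig, d)
        r2 = conditional_r2(fit, d.X, d.X)
        assert r2[0] == pytest.approx(1.0, abs=1e-6)
        rng = np.random.default_rng(7)
        y_noise = rng.normal(size=len(t))
        fit0 = fit_cosinor_slopes(zscore_within(y_noise, groups)[0], d)
        r20 = conditional_r2(fit0, d.X, d.X)
        assert r20[0] < 0.3

    def test_matches_plugin_variance_ratio(self):
        rng = np.random.default_rng(8)
        P, reps = 60, 30
        t = np.tile(np.arange(6) * 4.0, P * reps // 6)[: P * reps]
        groups = np.repeat(np.arange(P), reps)
        d = cosinor_design(t[: P * reps], TAU, participants=groups)
        sig_u, sig_e = 0.4, 0.6
        y = (0.8 * d.x1 + rng.normal(0, sig_u, P)[groups]
             + rng.normal(0, sig_e, P * reps))
        fit = fit_cosinor_intercept(y, d)
        X = np.column_stack([np.ones(P * reps), d.x1, d.x2])
        r2 = conditional_r2(fit, X, np.ones((P * reps, 1)))[0]
        vf = (0.8 * d.x1).var()
        expected = (vf + sig_u**2) / (vf + sig_u**2 + sig_e**2)
        assert r2 == pytest.approx(expected, abs=0.03)


@pytest.fixture(scope="module")
def recovery_session():
    from rhythmix.synth import SimConfig, generate_cohort
    cfg = SimConfig(n_participants=20, n_transcripts=300, frac_rhythmic=0.3,
                    amp_dist=(np.log(0.7), 1e-9), noise_sd=0.35,
                    sessions=("BDC1",),
                    session_effects={"BDC1": (0.0, 1.0, 0.0)},
                    missing_rate=0.0, melatonin_undetectable_rate=0.0,
                    seed=17)
    gem, meta, mel, truth = generate_cohort(cfg)
    from rhythmix.melatonin import align_times, compute_offsets
    aligned = align_times(meta, compute_offsets(mel))
    return gem, aligned, truth


class TestFitSession:

    def test_recovery_sensitivity_and_acrophase_error(self, recovery_session):
        gem, aligned, truth = recovery_session
        res, per_part = fit_session(gem.values, aligned, variant="slopes")
        tr = truth.set_index("transcript_id").loc[res.index]
        sens = res.loc[tr["rhythmic"], "rhythmic"].mean()
        assert sens >= 0.9
        got = res.loc[tr["rhythmic"], "acrophase"]
        want = tr.loc[tr["rhythmic"], "acrophase"]
        err = np.abs((got - want + 12) % 24 - 12)
        assert np.nanmedian(err) < 0.5
        assert len(per_part) == 300 * 20

    def test_permuted_times_collapse_to_fdr_level(self, recovery_session):
        gem, aligned, _ = recovery_session
        rng = np.random.default_rng(9)
        shuffled = aligned.copy()
        shuffled["aligned_time"] = rng.permutation(
            shuffled["aligned_time"].to_numpy())
        res, _ = fit_session(gem.values, shuffled, variant="slopes")
        assert res["rhythmic"].mean() <= 0.05

    def test_variants_agree_on_zero_random_effect_data(self):
        from rhythmix.synth import SimConfig, generate_cohort
        from rhythmix.melatonin import align_times, compute_offsets
        cfg = SimConfig(n_participants=15, n_transcripts=200, frac_rhythmic=0.3,
                        re_cov=np.zeros((2, 2)), re_intercept_sd=0.0,
                        noise_sd=0.3, sessions=("BDC1",),
                        session_effects={"BDC1": (0.0, 1.0, 0.0)},
                        missing_rate=0.0, melatonin_undetectable_rate=0.0,
                        seed=23)
        gem, meta, mel, truth = generate_cohort(cfg)
        aligned = align_times(meta, compute_offsets(mel))
        r_s, _ = fit_session(gem.values, aligned, variant="slopes")
        r_i, _ = fit_session(gem.values, aligned, variant="intercept")
        # z-scoring means the variants see transformed data, so the sets
        # coincide up to borderline-FDR transcripts rather than exactly
        agree = (r_s["rhythmic"] == r_i["rhythmic"]).mean()
        assert agree >= 0.95


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(-5, 5), st.floats(-5, 5))
def test_acrophase_always_in_range(b1, b2):
    amp, phi, acro = derive_rhythm_params(b1, b2, TAU)
    if amp > 0:
        assert 0.0 <= acro < TAU
        assert 0.0 <= phi < TAU
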
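import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magest.datamodel import Modality, Session, Task
from magest.errors import ValidationError
from magest.models import (
    ModelName,
    build_all_model_priors,
    build_model_prior,
    posterior_mean,
    predict_session,
    prior_weight,
)
from magest.psychometrics import ModalityWeights, PrecisionProfile
from magest.simulate import ObserverParams, Regime, simulate_participant


def eq_subtraction_form(mu_l, sigma_l, mu_p, sigma_p):
    """Independent oracle: the subtraction form of the posterior mean."""
    return mu_l - (sigma_l**2 * (mu_l - mu_p)) / (sigma_l**2 + sigma_p**2)


class TestPosteriorMean:
    def test_equal_weights(self):
        assert posterior_mean(1.0, 2.0, 0.0, 2.0) == pytest.approx(0.5)

    def test_flat_prior_limit(self):
        s = 850.0
        assert posterior_mean(s, 60.0, 670.0, 1e12) == pytest.approx(s, rel=1e-9)

    def test_zero_likelihood_noise_returns_stimulus(self):
        assert posterior_mean(850.0, 0.0, 670.0, 104.0) == 850.0

    def test_agrees_with_subtraction_form_worked_case(self):
        ours = posterior_mean(850.0, 60.0, 670.0, 104.0)
        oracle = eq_subtraction_form(850.0, 60.0, 670.0, 104.0)
        assert ours == pytest.approx(oracle, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(
        s=st.floats(1.0, 2000.0),
        sigma_l=st.floats(0.0, 500.0),
        mu_p=st.floats(1.0, 2000.0),
        sigma_p=st.floats(1.0, 500.0),
    )
    def test_two_forms_agree(self, s, sigma_l, mu_p, sigma_p):
        ours = posterior_mean(s, sigma_l, mu_p, sigma_p)
        oracle = eq_subtraction_form(s, sigma_l, mu_p, sigma_p)
        assert ours == pytest.approx(oracle, rel=1e-12, abs=1e-12)

    def test_prediction_between_stimulus_and_prior(self):
        s, mu_p = 850.0, 670.0
        mu_r = posterior_mean(s, 60.0, mu_p, 104.0)
        assert mu_p < mu_r < s

    def test_invalid_prior_sd(self):
        with pytest.raises(ValidationError):
            posterior_mean(1.0, 1.0, 0.0, 0.0)

    def test_weight_monotonicity(self):
        sigma_ls = np.linspace(0.0, 300.0, 13)
        w = [prior_weight(sl, 104.0) for sl in sigma_ls]
        assert all(b > a for a, b in zip(w, w[1:]))
        sigma_ps = np.linspace(10.0, 500.0, 13)
        w = [prior_weight(60.0, sp) for sp in sigma_ps]
        assert all(b < a for a, b in zip(w, w[1:]))


@pytest.fixture(scope="module")
def weights():
    return ModalityWeights(omega_A=0.8, sigma2_A=1.0, sigma2_V=4.0, task=Task.TEMPORAL)


class TestBuildModelPrior:
    def test_cte_prior_mean_is_pooled_mean_805(self, cfg, weights):
        spec = build_model_prior(ModelName.CTE, cfg, Task.TEMPORAL, weights)
        assert spec.prior_mean == pytest.approx(805.0, abs=1e-6)

    def test_segregation_means(self, cfg, weights):
        sa = build_model_prior(ModelName.SEG_AUDIO, cfg, Task.TEMPORAL, weights)
        sv = build_model_prior(ModelName.SEG_VISION, cfg, Task.TEMPORAL, weights)
        assert sa.prior_mean == pytest.approx(670.0, abs=1e-6)
        assert sv.prior_mean == pytest.approx(940.0, abs=1e-6)

    def test_prior_mean_ordering(self, cfg, weights):
        specs = build_all_model_priors(cfg, Task.TEMPORAL, weights)
        assert (
            specs[ModelName.SEG_AUDIO].prior_mean
            < specs[ModelName.CTE].prior_mean
            < specs[ModelName.SEG_VISION].prior_mean
        )
        assert (
            specs[ModelName.SEG_AUDIO].prior_mean
            <= specs[ModelName.WCTE].prior_mean
            <= specs[ModelName.SEG_VISION].prior_mean
        )

    def test_wcte_degenerates_to_seg_audio_at_omega_one(self, cfg):
        w1 = ModalityWeights(omega_A=1.0, sigma2_A=0.0, sigma2_V=1.0, task=Task.TEMPORAL)
        wcte = build_model_prior(ModelName.WCTE, cfg, Task.TEMPORAL, w1)
        sa = build_model_prior(ModelName.SEG_AUDIO, cfg, Task.TEMPORAL)
        assert wcte.prior_mean == pytest.approx(sa.prior_mean, abs=1e-9)
        assert wcte.prior_sd == pytest.approx(sa.prior_sd, rel=1e-9)

    def test_wcte_midpoint_at_equal_weights(self, cfg):
        w5 = ModalityWeights(omega_A=0.5, sigma2_A=1.0, sigma2_V=1.0, task=Task.TEMPORAL)
        wcte = build_model_prior(ModelName.WCTE, cfg, Task.TEMPORAL, w5)
        sa = build_model_prior(ModelName.SEG_AUDIO, cfg, Task.TEMPORAL)
        sv = build_model_prior(ModelName.SEG_VISION, cfg, Task.TEMPORAL)
        assert wcte.prior_mean == pytest.approx(0.5 * (sa.prior_mean + sv.prior_mean))

    def test_wcte_sd_between_segregation_sds(self, cfg, weights):
        wcte = build_model_prior(ModelName.WCTE, cfg, Task.TEMPORAL, weights)
        sa = build_model_prior(ModelName.SEG_AUDIO, cfg, Task.TEMPORAL)
        sv = build_model_prior(ModelName.SEG_VISION, cfg, Task.TEMPORAL)
        lo, hi = sorted([sa.prior_sd, sv.prior_sd])
        assert lo <= wcte.prior_sd <= hi

    def test_wcte_without_weights_rejected(self, cfg):
        with pytest.raises(ValidationError):
            build_model_prior(ModelName.WCTE, cfg, Task.TEMPORAL)


def constant_profiles(cfg, task, sd_a, sd_v):
    out = {}
    for modality, sd in ((Modality.A, sd_a), (Modality.V, sd_v)):
        values = cfg.stimulus_set(task, modality).values
        out[modality] = PrecisionProfile(
            task=task,
            modality=modality,
            variances={s: sd**2 for s in values},
            counts={s: 20 for s in values},
        )
    return out


class TestPredictSession:
    def test_self_consistency_with_matching_generator(self, cfg):
        sd_a, sd_v = 50.0, 120.0
        params = ObserverParams(
            sigma_A_floor=sd_a, sigma_V_floor=sd_v,
            regime=Regime.SEG_AUDIO, sensory_noise=False, seed=0,
        )
        recs = simulate_participant(params, cfg, Task.TEMPORAL)
        inter = [t for t in recs if t.session is Session.INTERLEAVED]
        spec = build_model_prior(ModelName.SEG_AUDIO, cfg, Task.TEMPORAL)
        preds = predict_session(inter, constant_profiles(cfg, Task.TEMPORAL, sd_a, sd_v), spec)
        observed = np.array([t.response for t in inter])
        assert np.allclose(preds["predicted"].to_numpy(), observed, rtol=1e-12)

    def test_dominant_modality_shifts_less(self, cfg, temporal_participant):
        inter = [t for t in temporal_participant if t.session is Session.INTERLEAVED]
        spec = build_model_prior(ModelName.SEG_AUDIO, cfg, Task.TEMPORAL)
        preds = predict_session(inter, constant_profiles(cfg, Task.TEMPORAL, 40.0, 150.0), spec)
        shift = (preds["predicted"] - preds["stimulus"]).abs()
        # compare at the shared stimulus values so the prior distance matches
        shared = preds[preds["stimulus"].isin([760.0, 805.0, 850.0])]
        by_mod = shift[shared.index].groupby(shared["modality"]).mean()
        assert by_mod["A"] < by_mod["V"]

    def test_visual_trials_pulled_toward_auditory_mean(self, cfg, temporal_participant):
        inter = [
            t for t in temporal_participant
            if t.session is Session.INTERLEAVED and t.modality is Modality.V
        ]
        spec = build_model_prior(ModelName.SEG_AUDIO, cfg, Task.TEMPORAL)
        preds = predict_session(inter, constant_profiles(cfg, Task.TEMPORAL, 40.0, 150.0), spec)
        above = preds[preds["stimulus"] > 670.0]
        assert (above["predicted"] < above["stimulus"]).all()

    def test_missing_stimulus_in_profile_named(self, cfg, temporal_participant):
        inter = [t for t in temporal_participant if t.session is Session.INTERLEAVED]
        profiles = constant_profiles(cfg, Task.TEMPORAL, 40.0, 150.0)
        trimmed = PrecisionProfile(
            task=Task.TEMPORAL,
            modality=Modality.V,
            variances={
                s: v for s, v in profiles[Modality.V].variances.items() if s != 1120.0
            },
            counts={s: 20 for s in profiles[Modality.V].variances if s != 1120.0},
        )
        profiles[Modality.V] = trimmed
        spec = build_model_prior(ModelName.SEG_AUDIO, cfg, Task.TEMPORAL)
        with pytest.raises(ValidationError, match="1120"):
            predict_session(inter, profiles, spec)

    def test_baseline_trials_rejected(self, cfg, temporal_participant):
        audio = [t for t in temporal_participant if t.session is Session.AUDIO]
        spec = build_model_prior(ModelName.SEG_AUDIO, cfg, Task.TEMPORAL)
        with pytest.raises(ValidationError):
            predict_session(audio, constant_profiles(cfg, Task.TEMPORAL, 40.0, 150.0), spec)

    def test_wcte_converges_to_seg_audio_as_omega_to_one(self, cfg, temporal_participant):
        inter = [t for t in temporal_participant if t.session is Session.INTERLEAVED]
        profiles = constant_profiles(cfg, Task.TEMPORAL, 40.0, 150.0)
        sa_spec = build_model_prior(ModelName.SEG_AUDIO, cfg, Task.TEMPORAL)
        sa = predict_session(inter, profiles, sa_spec)["predicted"].to_numpy()
        sup_norms = []
        for omega in (0.9, 0.99, 0.999):
            w = ModalityWeights(
                omega_A=omega, sigma2_A=1.0, sigma2_V=99.0, task=Task.TEMPORAL
            )
            wcte_spec = build_model_prior(ModelName.WCTE, cfg, Task.TEMPORAL, w)
            wcte = predict_session(inter, profiles, wcte_spec)["predicted"].to_numpy()
            sup_norms.append(np.max(np.abs(wcte - sa)))
        assert sup_norms[0] > sup_norms[1] > sup_norms[2]
        assert sup_norms[2] < 1.0  # sub-ms at omega_A = 0.999
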
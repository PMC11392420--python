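"""APM matching parameters, normative Z-scores, zeta transform, Task Score."""

import numpy as np
import pytest
from scipy.special import ndtri

from proprio_disconnect import synthetic as syn
from proprio_disconnect.scoring import (
    IMPAIRMENT_THRESHOLD,
    MatchingSession,
    NormativeModel,
    compute_matching_parameters,
    mirror_match,
    normative_fit,
    task_score,
    zeta_transform,
    zeta_inverse,
    _mid_rank_percentile,
)
from proprio_disconnect.synthetic import GroundTruth, target_layout


def _session(transform=None, age=50.0, sex=0, hand=1):
    """A deterministic 54-trial session; ``transform`` maps the ideal
    mirrored match position (== robot position) to the actual one."""
    targets = target_layout()
    order = np.concatenate([np.arange(9) for _ in range(6)])
    block = np.repeat(np.arange(1, 7), 9)
    robot = targets[order]
    mirrored = robot.copy() if transform is None else transform(robot.copy())
    match = mirrored.copy()
    match[:, 0] = -match[:, 0]
    return MatchingSession(
        age=age,
        sex=sex,
        handedness=hand,
        target_index=order + 1,
        block=block,
        robot_xy=robot,
        match_xy=match,
    )


class TestMirror:
    def test_reflection(self):
        np.testing.assert_allclose(mirror_match([5.0, 10.0], 0.0), [-5.0, 10.0])

    def test_midline_point_unchanged(self):
        np.testing.assert_allclose(mirror_match([3.0, 7.0], 3.0), [3.0, 7.0])

    def test_involution(self, rng):
        pts = rng.normal(0, 100, (20, 2))
        np.testing.assert_allclose(mirror_match(mirror_match(pts, 1.5), 1.5), pts)


class TestMatchingParameters:
    def test_perfect_matching(self):
        p = compute_matching_parameters(_session())
        assert p.abs_error_xy == pytest.approx(0.0)
        assert p.variability_xy == pytest.approx(0.0)
        assert p.shift_x == p.shift_y == pytest.approx(0.0)
        assert p.ratio_x == pytest.approx(1.0)
        assert p.ratio_y == pytest.approx(1.0)

    def test_uniform_x_offset(self):
        # +20 mm x error on every trial: shift 20, pooled abs error 10
        p = compute_matching_parameters(_session(lambda m: m + [20.0, 0.0]))
        assert p.shift_x == pytest.approx(20.0)
        assert p.shift_y == pytest.approx(0.0)
        assert p.abs_error_xy == pytest.approx(10.0)  # x=20, y=0 pooled
        assert p.variability_xy == pytest.approx(0.0)
        assert p.ratio_x == pytest.approx(1.0)

    def test_contraction_about_centroid(self):
        targets = target_layout()
        c = targets.mean(axis=0)
        p = compute_matching_parameters(_session(lambda m: c + 0.5 * (m - c)))
        assert p.ratio_x == pytest.approx(0.5)
        assert p.ratio_y == pytest.approx(0.5)
        assert p.variability_xy == pytest.approx(0.0)

    def test_incomplete_session_rejected(self):
        s = _session()
        with pytest.raises(ValueError):
            MatchingSession(
                age=50,
                sex=0,
                handedness=1,
                target_index=np.ones(54, dtype=int),  # target 1 repeated
                block=s.block,
                robot_xy=s.robot_xy,
                match_xy=s.match_xy,
            )


class TestZeta:
    def test_known_values(self):
        assert zeta_transform(0.0) == pytest.approx(ndtri(0.75), abs=1e-10)
        assert zeta_transform(0.0) == pytest.approx(0.6745, abs=1e-4)
        assert zeta_transform(1.96) == pytest.approx(2.2414, abs=1e-3)
        assert zeta_transform(-8.0) == pytest.approx(0.0, abs=1e-6)

    def test_bijection_and_monotonicity(self):
        z = np.linspace(-6, 6, 101)
        zeta = zeta_transform(z)
        assert np.all(np.diff(zeta) > 0)
        assert np.all(zeta >= 0)
        np.testing.assert_allclose(zeta_inverse(zeta), z, atol=1e-10)


class TestNormativeModel:
    def test_zscore_at_prediction_and_one_sd(self, normative_model):
        fit = normative_model.fits["shift_x"]
        x = np.array([1.0, 55.0, 1.0, 1.0])  # design row
        pred = float(x @ fit.beta)
        assert normative_model.zscore("shift_x", pred, 55.0, 1, 1) == pytest.approx(0.0)
        assert normative_model.zscore(
            "shift_x", pred + fit.resid_sd, 55.0, 1, 1
        ) == pytest.approx(1.0)

    def test_fitting_cohort_z_standardized(self):
        cohort = syn.make_normative_cohort(21, n_controls=80, n_assessments=200)
        sessions = list(cohort["session"])
        model = normative_fit(sessions)
        z = np.array(
            [
                model.zscore(
                    "variability_xy",
                    compute_matching_parameters(s).variability_xy,
                    s.age,
                    s.sex,
                    s.handedness,
                )
                for s in sessions
            ]
        )
        assert abs(z.mean()) < 0.05
        assert z.std(ddof=1) == pytest.approx(1.0, abs=0.05)

    def test_age_slope_recovery_within_2_se(self):
        """The generator's age effect on variability is recovered by the fit."""
        import statsmodels.api as sm

        config = syn.NormativeConfig(age_slope=0.004)
        cohort = syn.make_normative_cohort(
            31, n_controls=300, n_assessments=600, config=config
        )
        sessions = list(cohort["session"])
        y = np.log(
            [compute_matching_parameters(s).variability_xy for s in sessions]
        )
        X = sm.add_constant(
            np.column_stack(
                [
                    [s.age for s in sessions],
                    [s.sex for s in sessions],
                    [s.handedness for s in sessions],
                ]
            )
        )
        res = sm.OLS(y, X).fit()
        # d log(variability) / d age ~= age_slope of the noise-scale model
        assert abs(res.params[1] - config.age_slope) < 2 * res.bse[1]

    def test_degenerate_design_rejected(self):
        cohort = syn.make_normative_cohort(41, n_controls=40, n_assessments=60)
        sessions = []
        for s in cohort["session"]:
            s.sex = 1  # constant covariate
            sessions.append(s)
        with pytest.raises(ValueError, match="constant sex"):
            normative_fit(sessions)

    def test_json_round_trip(self, normative_model, tmp_path):
        path = tmp_path / "model.json"
        normative_model.to_json(path)
        back = NormativeModel.from_json(path)
        np.testing.assert_allclose(back.rss_sample, normative_model.rss_sample)
        for name, fit in normative_model.fits.items():
            np.testing.assert_allclose(back.fits[name].beta, fit.beta)
            assert back.fits[name].resid_sd == pytest.approx(fit.resid_sd)


class TestTaskScore:
    def test_median_rss_maps_to_zeta_of_zero(self, normative_model):
        # the scoring chain sends the normative-median RSS to zeta(0)
        med = float(np.median(normative_model.rss_sample))
        p = _mid_rank_percentile(med, normative_model.rss_sample)[0]
        assert p == pytest.approx(0.5, abs=1e-3)
        assert zeta_transform(ndtri(p)) == pytest.approx(
            zeta_transform(0.0), abs=5e-3
        )

    def test_score_monotone_in_rss(self, normative_model):
        # any increase of a one-sided component raises the RSS, and the
        # RSS -> score map is non-decreasing
        rss = np.sort(normative_model.rss_sample)
        p = _mid_rank_percentile(rss, normative_model.rss_sample)
        scores = zeta_transform(ndtri(p))
        assert np.all(np.diff(scores) >= 0)

    def test_impairment_flag_matches_threshold(self, normative_model):
        truth = GroundTruth()
        rng = np.random.default_rng(6)
        for severity in (0.0, 1.5, 3.0):
            s = syn.generate_session(rng, 60.0, 1, 1, severity, truth)
            res = task_score(s, normative_model)
            assert res.impaired == (res.task_score > IMPAIRMENT_THRESHOLD)
            assert res.task_score >= 0

    def test_severe_impairment_scores_high(self, normative_model):
        truth = GroundTruth()
        rng = np.random.default_rng(7)
        bad = [
            task_score(
                syn.generate_session(rng, 60.0, 1, 1, 4.0, truth), normative_model
            ).task_score
            for _ in range(5)
        ]
        assert min(bad) > IMPAIRMENT_THRESHOLD

    def test_scale_consistency(self):
        """Doubling all coordinates with a refit normative model leaves
        Z-scores (hence scores) unchanged."""
        cohort = syn.make_normative_cohort(51, n_controls=60, n_assessments=120)
        sessions = list(cohort["session"])

        def scaled(s):
            return MatchingSession(
                age=s.age,
                sex=s.sex,
                handedness=s.handedness,
                target_index=s.target_index,
                block=s.block,
                robot_xy=2.0 * s.robot_xy,
                match_xy=2.0 * s.match_xy,
            )

        model = normative_fit(sessions)
        model2 = normative_fit([scaled(s) for s in sessions])
        for s in sessions[:10]:
            r1 = task_score(s, model)
            r2 = task_score(scaled(s), model2)
            assert r2.task_score == pytest.approx(r1.task_score, abs=1e-8)
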
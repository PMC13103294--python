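"""Edge-wise developmental models, group contrasts, behaviour and age
prediction."""

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

import foca
from foca.development import (
    compare_prediction,
    fit_edge_trajectories,
    group_difference,
    predict_age_svr,
    predict_behaviour,
    spline_basis,
    _penalized_fit,
)
from foca.synthgen import SubjectMeta
from foca.topography import FocaMatrix


def make_cohort(rng, n=60, k=8, age_range=(37, 44), edge_slope=None,
                noise=0.1, score_fn=None, score_name="cognitive"):
    """Random coupling matrices with an optional planted linear age effect."""
    focas, metas = [], []
    for s in range(n):
        age = float(rng.uniform(*age_range))
        v = np.clip(rng.normal(0, noise, size=(k, k)), -0.99, 0.99)
        v = (v + v.T) / 2
        if edge_slope:
            (i, j), slope = edge_slope
            v[i, j] += slope * (age - np.mean(age_range))
            v[j, i] = v[i, j]
        v = np.clip(v, -0.99, 0.99)
        np.fill_diagonal(v, 1.0)
        meta = SubjectMeta(
            subject_id=f"s{s}", group="neonate", age=age,
            sex="F" if rng.random() < 0.5 else "M",
            mean_fd=float(rng.uniform(0.02, 0.2)),
            scan_birth_interval=float(rng.uniform(0, 4)),
        )
        if score_fn is not None:
            meta.behaviour_scores[score_name] = score_fn(v, meta, rng)
        focas.append(FocaMatrix(values=v, subject_id=meta.subject_id))
        metas.append(meta)
    return focas, metas


class TestEdgeTrajectories:
    def test_planted_linear_effect_detected(self):
        rng = np.random.default_rng(0)
        focas, metas = make_cohort(rng, n=100, edge_slope=((0, 1), 0.02))
        out = fit_edge_trajectories(focas, metas)
        row = out.table[(out.table.network_i == 1) & (out.table.network_j == 2)]
        assert float(row["q"].iloc[0]) < 0.05

    def test_bh_step_up_rule(self):
        # oracle: step-up by hand on p = [.01, .02, .03, .5], m=4, q=.05:
        # largest k with p_(k) <= k/4*0.05 is k=3 -> 3 rejections
        rej, _, _, _ = multipletests([0.01, 0.02, 0.03, 0.5], alpha=0.05,
                                     method="fdr_bh")
        assert rej.sum() == 3

    def test_q_not_below_p(self):
        rng = np.random.default_rng(1)
        focas, metas = make_cohort(rng, n=40)
        out = fit_edge_trajectories(focas, metas)
        assert np.all(out.table["q"] >= out.table["p"] - 1e-12)
        assert out.family_size == len(out.table)

    def test_penalized_fit_shrinks_to_linear_on_linear_data(self):
        rng = np.random.default_rng(2)
        age = rng.uniform(37, 44, size=80)
        y = (0.05 * age + rng.normal(0, 0.01, 80))[:, None]
        x0 = np.ones((80, 1))
        b, bg, pen = spline_basis(age, None, k=5)
        beta, _ = _penalized_fit(x0, b, pen, y)
        fitted = np.column_stack([x0, b]) @ beta
        ols = np.column_stack([np.ones(80), age])
        coef, *_ = np.linalg.lstsq(ols, y, rcond=None)
        rmse = float(np.sqrt(np.mean((fitted - ols @ coef) ** 2)))
        assert rmse < 0.01

    def test_trajectory_shape_and_grid(self):
        rng = np.random.default_rng(3)
        focas, metas = make_cohort(rng, n=40, k=5)
        grid = np.linspace(38, 43, 11)
        out = fit_edge_trajectories(focas, metas, age_grid=grid)
        assert out.trajectories.shape == (10, 11)
        assert np.array_equal(out.age_grid, grid)


class TestGroupDifference:
    def test_pooled_sd_cohens_d(self):
        a = [self._make(v) for v in [1, 2, 3]]
        b = [self._make(v) for v in [4, 5, 6]]
        eff = group_difference(a, b)
        assert eff.d[0, 1] == pytest.approx(-3.0)
        assert np.sign(eff.t[0, 1]) == np.sign(eff.d[0, 1])

    @staticmethod
    def _make(v):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = v / 10.0  # keep in [-1, 1]
        m[0, 2] = m[2, 0] = 0.1 * v + 0.01 * (v % 2)
        m[1, 2] = m[2, 1] = -0.05 * v
        np.fill_diagonal(m, 1.0)
        return FocaMatrix(values=m)

    def test_swapping_groups_flips_signs(self):
        rng = np.random.default_rng(4)
        a = [self._make(v) for v in rng.uniform(-2, 2, 5)]
        b = [self._make(v) for v in rng.uniform(-2, 2, 5)]
        ab = group_difference(a, b)
        ba = group_difference(b, a)
        assert np.allclose(ab.d, -ba.d)
        assert np.allclose(ab.t, -ba.t)


class TestBehaviourPrediction:
    def test_planted_network_profile_detected(self):
        rng = np.random.default_rng(5)

        def score(v, meta, r):
            profile = np.delete(v[4], 4)  # network 5's couplings
            return float(profile.sum() * 3.0) + 0.05 * r.standard_normal()

        focas, metas = make_cohort(rng, n=200, k=8, score_fn=score)
        rep = predict_behaviour(focas, metas, "cognitive")
        row = rep.table[rep.table.network == 5]
        assert float(row["q"].iloc[0]) < 0.05

    def test_score_equal_to_covariate_is_explained_away(self):
        rng = np.random.default_rng(6)

        def score(v, meta, r):
            return meta.mean_fd * 10.0 + 0.01 * r.standard_normal()

        focas, metas = make_cohort(rng, n=120, k=6, score_fn=score)
        rep = predict_behaviour(focas, metas, "cognitive")
        assert (rep.table["q"] < 0.05).sum() == 0

    def test_family_is_network_count(self):
        rng = np.random.default_rng(7)
        focas, metas = make_cohort(
            rng, n=60, k=6, score_fn=lambda v, m, r: r.standard_normal()
        )
        rep = predict_behaviour(focas, metas, "cognitive")
        assert rep.family_size == 6
        assert len(rep.table) == 6


class TestAgePrediction:
    def _age_features(self, rng, n=120, p=30, n_signal=10, slope=0.03, noise=0.05):
        ages = rng.uniform(37, 44, n)
        metas = [
            SubjectMeta(subject_id=f"s{i}", group="neonate", age=float(a),
                        sex="F" if rng.random() < 0.5 else "M",
                        mean_fd=float(rng.uniform(0.02, 0.2)),
                        scan_birth_interval=float(rng.uniform(0, 4)))
            for i, a in enumerate(ages)
        ]
        x = rng.normal(0, noise, size=(n, p))
        x[:, :n_signal] += slope * (ages - 40.5)[:, None]
        return x, metas, ages

    def test_planted_age_signal_predicted(self):
        rng = np.random.default_rng(8)
        x, metas, _ = self._age_features(rng, n=200)
        rep = predict_age_svr(x, metas, n_repeats=5, seed=1)
        assert rep.accuracy_r >= 0.8

    def test_permuted_ages_not_predicted(self):
        rng = np.random.default_rng(9)
        x, metas, ages = self._age_features(rng, n=80)
        perm = rng.permutation(ages)
        for m, a in zip(metas, perm):
            m.age = float(a)
        rep = predict_age_svr(x, metas, n_repeats=5, n_perms=20, seed=2)
        assert abs(rep.accuracy_r) < 0.25
        assert rep.perm_p > 0.05

    def test_confound_only_signal_removed(self):
        # age signal rides entirely on a confound (mean FD proportional to
        # age): residualization must remove it
        rng = np.random.default_rng(10)
        n = 100
        ages = rng.uniform(37, 44, n)
        metas = [
            SubjectMeta(subject_id=f"s{i}", group="neonate", age=float(a),
                        sex="F",
                        mean_fd=float(max(0.005, (a - 37) / 50 + 0.02 + rng.normal(0, 0.02))),
                        scan_birth_interval=float(rng.uniform(0, 4)))
            for i, a in enumerate(ages)
        ]
        # features carry age information only through mean FD
        x = rng.normal(0, 0.05, size=(n, 20))
        x += np.array([m.mean_fd for m in metas])[:, None] * 3.0
        rep = predict_age_svr(x, metas, n_repeats=5, seed=3)
        assert abs(rep.accuracy_r) < 0.3

    def test_paired_comparison_report(self):
        rng = np.random.default_rng(11)
        x, metas, _ = self._age_features(rng, n=100)
        good = predict_age_svr(x, metas, n_repeats=5, seed=4)
        bad = predict_age_svr(rng.normal(size=x.shape), metas, n_repeats=5, seed=4)
        out = compare_prediction(good, bad)
        assert out["mean_a"] > out["mean_b"]
        assert out["t"] > 0
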
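"""Topography maps, the FOCA matrix, consistency, MAD, duration reliability."""

import numpy as np
import pytest

import foca
from foca.benchmarks import block_coupling
from foca.individualize import Parcellation
from foca.synthgen import EffectSpec, SubjectMeta
from foca.topography import (
    FocaMatrix,
    TopographySet,
    compute_foca,
    compute_topography,
    consistency,
    duration_reliability,
    matrix_similarity,
    variability_mad,
)


def toy_scan(data):
    t = data.shape[0]
    return foca.Scan(data=data, tr=1.0, fd=np.full(t, 0.1),
                     censor_mask=np.ones(t, bool),
                     meta=SubjectMeta(subject_id="toy"))


class TestComputeTopography:
    def test_fisher_z_values(self):
        # vertex identical to the seed clips at arctanh(1 - 1e-7); r = 0.5
        # maps to arctanh(0.5) ~ 0.5493
        rng = np.random.default_rng(0)
        seed_sig = rng.standard_normal(20000)
        other = 0.5 * seed_sig + np.sqrt(1 - 0.25) * rng.standard_normal(20000)
        ortho = rng.standard_normal(20000)
        data = np.column_stack([seed_sig, seed_sig, other, ortho])
        parc = Parcellation(labels=np.array([1, 1, 2, 2]), n_networks=2)
        topo = compute_topography(toy_scan(data), parc)
        # seeds are means of two vertices; vertex 0 correlates ~1 with seed 1
        assert topo.maps[0, 0] >= np.arctanh(1 - 1e-6)
        assert topo.maps[0, 2] == pytest.approx(np.arctanh(0.5), abs=0.05)
        assert abs(topo.maps[0, 3]) <= 0.05  # r ~ 0 -> z ~ 0

    def test_nuisance_map_regression_contract(self, noisy_cohort):
        scan = noisy_cohort[0]
        parc = Parcellation(labels=scan.true_labels, n_networks=5, level="individual")
        topo = compute_topography(scan, parc)
        nuis = topo.maps[2]
        resid = compute_topography(scan, parc, nuisance_map=nuis)
        # regressing a map on itself leaves (numerically) nothing
        assert np.abs(resid.maps[2]).max() < 1e-10
        for i in (0, 1, 3, 4):
            r = np.corrcoef(resid.maps[i], nuis)[0, 1]
            assert abs(r) < 1e-8

    def test_zero_variance_seed_rejected(self):
        data = np.column_stack([np.ones(60), np.random.default_rng(0).standard_normal(60)])
        parc = Parcellation(labels=np.array([1, 2]), n_networks=2)
        with pytest.raises(ValueError, match="zero-variance seed"):
            compute_topography(toy_scan(data), parc)


class TestComputeFoca:
    def test_sign_contracts(self):
        rng = np.random.default_rng(1)
        m = rng.standard_normal(100)
        maps = np.vstack([m, m + 1e-9, -m])
        f = compute_foca(TopographySet(maps=maps))
        assert f.values[0, 1] == pytest.approx(1.0)
        assert f.values[0, 2] == pytest.approx(-1.0)

    def test_affine_rescaling_invariance(self, noisy_focas, noisy_cohort):
        scan = noisy_cohort[0]
        parc = Parcellation(labels=scan.true_labels, n_networks=5, level="individual")
        topo = compute_topography(scan, parc)
        scaled = TopographySet(maps=3.7 * topo.maps + 0.4)
        a = compute_foca(topo).values
        b = compute_foca(scaled).values
        assert np.abs(a - b).max() < 0.02

    def test_constant_map_rejected(self):
        maps = np.vstack([np.ones(50), np.random.default_rng(0).standard_normal(50)])
        with pytest.raises(ValueError, match="constant"):
            compute_foca(TopographySet(maps=maps))


class TestConsistencyAndMad:
    def test_identical_matrices_fully_consistent(self, noisy_focas):
        same = [noisy_focas[0]] * 4
        rep = consistency(same)
        assert np.allclose(rep["values"], 1.0)
        assert len(rep["values"]) == 6  # 4*3/2 pairs

    def test_hand_pearson_on_opposite_triangles(self):
        a = np.array([[1, 1, 0], [1, 1, -1], [0, -1, 1.0]])
        b = np.array([[1, -1, 0], [-1, 1, 1], [0, 1, 1.0]])
        # upper triangles [1, 0, -1] vs [-1, 0, 1]
        assert matrix_similarity(a, b) == pytest.approx(-1.0)

    def test_mad_of_known_edge_values(self):
        # edge values [1,2,3,4,100]: median 3, |dev| {2,1,0,1,97} -> MAD = 1
        mats = []
        for v in [1, 2, 3, 4, 100]:
            m = np.eye(3)
            m[0, 1] = m[1, 0] = np.tanh(v)  # keep inside [-1,1]
            mats.append(FocaMatrix(values=m))
        stack = np.stack([m.values for m in mats])
        med = np.median(stack, axis=0)
        expected = np.median(np.abs(stack - med), axis=0)[0, 1]
        out = variability_mad(mats)
        assert out[0, 1] == pytest.approx(expected)
        assert np.allclose(out, out.T)
        assert np.all(np.diag(out) == 0)

    def test_mad_zero_for_identical_subjects(self, noisy_focas):
        out = variability_mad([noisy_focas[0]] * 3)
        assert np.abs(out).max() == 0.0

    def test_mad_requires_three_subjects(self, noisy_focas):
        with pytest.raises(ValueError):
            variability_mad(noisy_focas[:2])


@pytest.fixture(scope="module")
def long_scan(geometry):
    model = foca.sample_latent_model(
        5, geometry, block_coupling(5),
        EffectSpec(noise_sd=4.0), seed=0,
    )
    return model, foca.simulate_scan(
        model, SubjectMeta(subject_id="long"), n_frames=6000, tr=2.0, seed=9
    )


class TestDurationReliability:
    def test_rep_bookkeeping(self, long_scan):
        model, scan = long_scan
        parc = Parcellation(labels=model.group_labels, n_networks=5, level="individual")
        out = duration_reliability(scan, parc, [5.0], reference_min=70.0,
                                   n_reps=7, seed=1)
        assert len(out["values"][5.0]) == 7

    def test_similarity_increases_with_duration(self, long_scan):
        model, scan = long_scan
        parc = Parcellation(labels=model.group_labels, n_networks=5, level="individual")
        out = duration_reliability(scan, parc, [2.0, 20.0], reference_min=70.0,
                                   n_reps=30, seed=2)
        assert out["mean"][1] >= out["mean"][0]

    def test_split_half_of_low_noise_scan(self, geometry):
        model = foca.sample_latent_model(
            5, geometry, block_coupling(5),
            EffectSpec(noise_sd=0.5), seed=0,
        )
        scan = foca.simulate_scan(model, SubjectMeta(subject_id="sh"),
                                  n_frames=2000, seed=11)
        parc = Parcellation(labels=model.group_labels, n_networks=5, level="individual")
        half = scan.n_frames // 2
        a = compute_foca(compute_topography(toy_scan(scan.data[:half]), parc)).values
        b = compute_foca(compute_topography(toy_scan(scan.data[half:]), parc)).values
        assert matrix_similarity(a, b) > 0.9

    def test_insufficient_frames_rejected(self, long_scan):
        model, scan = long_scan
        parc = Parcellation(labels=model.group_labels, n_networks=5, level="individual")
        with pytest.raises(ValueError):
            duration_reliability(scan, parc, [500.0], reference_min=70.0,
                                 n_reps=2, seed=0)
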
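"""Template matching: eta-squared, template construction, label recovery,
within-network homogeneity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import foca
from foca.benchmarks import block_coupling
from foca.individualize import (
    Parcellation,
    TemplateSet,
    build_group_templates,
    compare_homogeneity,
    eta_squared,
    match_templates,
    parcel_homogeneity,
)
from foca.synthgen import EffectSpec, SubjectMeta


class TestEtaSquared:
    def test_identical_maps_give_one(self):
        a = np.array([0.2, -1.0, 3.0, 0.5])
        assert eta_squared(a, a) == pytest.approx(1.0)

    def test_hand_computed_orthogonal_case(self):
        # a=[1,0], b=[0,1]: m=[0.5,0.5], grand=0.5, SSW = SST = 1 -> eta2 = 0
        assert eta_squared([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_both_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            eta_squared([1.0, 1.0], [1.0, 1.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(-5, 5), min_size=3, max_size=12),
        st.integers(0, 2**31 - 1),
    )
    def test_symmetric_and_bounded(self, a, seed):
        rng = np.random.default_rng(seed)
        a = np.asarray(a)
        b = a + rng.normal(0, 1.0, size=a.shape)
        if np.var(a + b) < 1e-12 and np.var(a - b) < 1e-12:
            return
        v1 = eta_squared(a, b)
        v2 = eta_squared(b, a)
        assert v1 == pytest.approx(v2)
        assert -1e-12 <= v1 <= 1 + 1e-12


class TestTemplates:
    def test_z_threshold_retains_normal_tail_fraction(self):
        # a z-scored standard-normal map thresholded at 1 keeps the upper
        # ~15.9% tail
        rng = np.random.default_rng(0)
        m = rng.standard_normal(200_000)
        z = (m - m.mean()) / m.std()
        assert np.mean(z > 1) == pytest.approx(0.1587, abs=0.005)

    def test_templates_overlap_planted_networks(self, geometry):
        model = foca.sample_latent_model(
            5, geometry, block_coupling(5),
            EffectSpec(noise_sd=0.1), seed=0,
        )
        scans = foca.simulate_cohort(model, 6, n_frames=400, seed=3)
        parc = Parcellation(labels=model.group_labels, n_networks=5)
        templates = build_group_templates(scans, parc, 1.0)
        for i in range(5):
            mask = templates.masks[i]
            planted = model.group_labels == i + 1
            dice = 2 * np.sum(mask & planted) / (mask.sum() + planted.sum())
            assert dice >= 0.8

    def test_infinite_threshold_rejected(self, noisy_cohort, group_parcellation):
        with pytest.raises(ValueError):
            build_group_templates(noisy_cohort[:2], group_parcellation, np.inf)

    def test_rebuilt_templates_replicate_across_cohorts(self, geometry):
        model = foca.sample_latent_model(
            5, geometry, block_coupling(5), EffectSpec(noise_sd=0.5), seed=0
        )
        parc = Parcellation(labels=model.group_labels, n_networks=5)
        t1 = build_group_templates(
            foca.simulate_cohort(model, 5, n_frames=300, seed=10), parc
        )
        t2 = build_group_templates(
            foca.simulate_cohort(model, 5, n_frames=300, seed=20), parc
        )
        for i in range(5):
            inter = np.sum(t1.masks[i] & t2.masks[i])
            dice = 2 * inter / (t1.masks[i].sum() + t2.masks[i].sum())
            assert dice > 0.7


class TestMatchTemplates:
    def test_recovers_planted_labels(self, geometry):
        model = foca.sample_latent_model(
            5, geometry, block_coupling(5), EffectSpec(noise_sd=0.1), seed=0
        )
        scans = foca.simulate_cohort(model, 4, n_frames=400, seed=5)
        parc = Parcellation(labels=model.group_labels, n_networks=5)
        templates = build_group_templates(scans[:3], parc)
        out = match_templates(scans[3], templates, geometry=geometry)
        assert np.mean(out.labels == model.group_labels) >= 0.9

    def test_every_vertex_labelled(self, noisy_cohort, group_parcellation, geometry):
        templates = build_group_templates(noisy_cohort[:4], group_parcellation)
        out = match_templates(noisy_cohort[4], templates, geometry=geometry)
        assert out.labels.min() >= 1 and out.labels.max() <= 5

    def test_exact_tie_breaks_to_lower_index(self):
        # five templates; templates 3 and 5 identical, so their eta-squared
        # values tie exactly and the lower index must win
        v = 40
        masks = np.zeros((5, v), dtype=bool)
        for i in range(5):
            masks[i, 8 * i : 8 * (i + 1)] = True
        masks[4] = masks[2]
        templates = TemplateSet(masks=masks, z_threshold=1.0)
        rng = np.random.default_rng(0)
        base = rng.standard_normal((100, 5))
        data = np.repeat(base, 8, axis=1) + 0.01 * rng.standard_normal((100, v))
        scan = foca.Scan(data=data, tr=1.0, fd=np.full(100, 0.1),
                         censor_mask=np.ones(100, bool),
                         meta=SubjectMeta(subject_id="tie"))
        out = match_templates(scan, templates)
        block3 = out.labels[16:24]
        assert np.all(block3 != 5)  # never the duplicated higher index


class TestHomogeneity:
    def test_identical_series_are_fully_homogeneous(self):
        base = np.random.default_rng(0).standard_normal(120)
        data = np.tile(base[:, None], (1, 6))
        scan = foca.Scan(data=data, tr=1.0, fd=np.full(120, 0.1),
                         censor_mask=np.ones(120, bool),
                         meta=SubjectMeta(subject_id="h"))
        parc = Parcellation(labels=np.ones(6, dtype=int), n_networks=1)
        per, mean = parcel_homogeneity(scan, parc)
        assert per[1] == pytest.approx(1.0)

    def test_white_noise_near_zero(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((500, 20))
        scan = foca.Scan(data=data, tr=1.0, fd=np.full(500, 0.1),
                         censor_mask=np.ones(500, bool),
                         meta=SubjectMeta(subject_id="n"))
        parc = Parcellation(labels=np.ones(20, dtype=int), n_networks=1)
        _, mean = parcel_homogeneity(scan, parc)
        assert abs(mean) <= 0.1

    def test_individualized_beats_group_parcellation(self, geometry):
        model = foca.sample_latent_model(
            5, geometry, block_coupling(5),
            EffectSpec(noise_sd=0.5, boundary_shift_rate=0.2), seed=0,
        )
        scans = foca.simulate_cohort(model, 20, n_frames=300, seed=6)
        group = Parcellation(labels=model.group_labels, n_networks=5)
        indiv = [
            Parcellation(labels=s.true_labels, n_networks=5, level="individual")
            for s in scans
        ]
        rep = compare_homogeneity(scans, indiv, group)
        assert rep["fraction_improved"] >= 0.9
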
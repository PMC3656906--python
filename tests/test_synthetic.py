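import numpy as np
import pytest

import dmnconn as dc
from dmnconn.synthetic import random_support, ring_support


class TestMakePrecisionMatrix:
    def test_empty_support_identity(self):
        p = dc.make_precision_matrix(dc.PrecisionSpec(n_regions=5, support=()))
        assert np.allclose(p, np.eye(5))
        assert np.allclose(dc.theoretical_partial_correlation(p), np.eye(5))

    def test_single_edge_strength(self):
        spec = dc.PrecisionSpec(n_regions=4, support=((0, 1),), strength=0.5)
        p = dc.make_precision_matrix(spec)
        # independent check: invert the constructed precision and rescale
        r = dc.partial_correlation_from_covariance(np.linalg.inv(p))
        assert r[0, 1] == pytest.approx(0.5, abs=1e-12)
        off = r - np.eye(4)
        off[0, 1] = off[1, 0] = 0.0
        assert np.allclose(off, 0.0, atol=1e-12)

    def test_analytic_strength_exact(self):
        spec = dc.PrecisionSpec(
            n_regions=6, support=((0, 1), (2, 3)),
            strength={(0, 1): 0.3, (2, 3): -0.45})
        p = dc.make_precision_matrix(spec)
        r = dc.theoretical_partial_correlation(p)
        assert abs(r[0, 1] - 0.3) < 1e-12
        assert abs(r[2, 3] + 0.45) < 1e-12

    def test_spd(self):
        p = dc.make_precision_matrix(dc.PrecisionSpec(
            n_regions=16, support=ring_support(16), strength=0.4))
        assert np.linalg.eigvalsh(p)[0] > 0

    def test_infeasible_spec_rejected(self):
        spec = dc.PrecisionSpec(
            n_regions=5,
            support=((0, 1), (0, 2), (0, 3), (0, 4)), strength=0.6)
        with pytest.raises(ValueError, match="infeasible"):
            dc.make_precision_matrix(spec)

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError, match="self-pair"):
            dc.make_precision_matrix(dc.PrecisionSpec(
                n_regions=3, support=((1, 1),)))


class TestSimulateTimeseries:
    def test_independent_channels(self):
        ts = dc.simulate_timeseries(np.eye(4), 40000, seed=0)
        c = np.corrcoef(ts.data)
        off = c[~np.eye(4, dtype=bool)]
        # 4 SE bound: the max over six null correlations
        assert np.all(np.abs(off) < 4 / np.sqrt(40000))

    def test_planted_partial_correlation_recovered(self):
        spec = dc.PrecisionSpec(n_regions=4, support=((0, 1),), strength=0.5)
        p = dc.make_precision_matrix(spec)
        ts = dc.simulate_timeseries(p, 50000, band="alpha", seed=11)
        est = dc.partial_correlation_matrix(ts)
        assert est[0, 1] == pytest.approx(0.5, abs=0.05)

    def test_same_seed_bit_identical(self):
        p = dc.make_precision_matrix(dc.PrecisionSpec(
            n_regions=3, support=((0, 2),), strength=0.3))
        a = dc.simulate_timeseries(p, 2000, band="beta", seed=5)
        b = dc.simulate_timeseries(p, 2000, band="beta", seed=5)
        assert np.array_equal(a.data, b.data)

    def test_non_spd_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive-definite"):
            dc.simulate_timeseries(bad, 100)

    def test_estimator_consistency_over_T(self):
        """MAE of estimated vs theoretical partial correlation shrinks with T."""
        spec = dc.PrecisionSpec(n_regions=4, support=((0, 1), (2, 3)),
                                strength=0.4)
        p = dc.make_precision_matrix(spec)
        theo = dc.theoretical_partial_correlation(p)
        mask = ~np.eye(4, dtype=bool)
        maes = []
        for T in (1000, 10000, 50000):
            errs = []
            for seed in range(10):
                est = dc.partial_correlation_matrix(
                    dc.simulate_timeseries(p, T, seed=seed))
                errs.append(np.abs(est - theo)[mask].mean())
            maes.append(np.mean(errs))
        assert maes[0] > maes[1] > maes[2]


class TestGroupStudy:
    def small_design(self, **kw):
        kw.setdefault("n_per_group", 2)
        kw.setdefault("duration_s", 2.0)
        return dc.StudyDesign(**kw)

    def test_layout_and_determinism(self):
        design = self.small_design(seed=3)
        base = dc.PrecisionSpec(n_regions=16, support=())
        bundle = dc.simulate_group_study(design, base)
        assert len(bundle.recordings) == 2 * 2 * 2
        again = dc.simulate_group_study(design, base)
        for a, b in zip(bundle.recordings, again.recordings):
            assert np.array_equal(a.timeseries.data, b.timeseries.data)

    def test_null_study_rest_post_differ_only_by_noise(self):
        design = self.small_design(seed=1)
        bundle = dc.simulate_group_study(
            design, dc.PrecisionSpec(n_regions=16, support=()))
        rest = bundle.select(condition="rest")[0].timeseries
        post = bundle.select(condition="post")[0].timeseries
        assert not np.array_equal(rest.data, post.data)
        assert bundle.ledger["effects"] == {}

    def test_ledger_records_planted_change(self):
        design = self.small_design(
            seed=2,
            bands_with_effects={"delta": {("PCC_L", "STG_L"): 0.3}})
        base = dc.PrecisionSpec(n_regions=16, support=())
        bundle = dc.simulate_group_study(design, base)
        assert bundle.ledger["effects"] == {
            "delta": {"PCC_L-STG_L": 0.3}}

    def test_infeasible_effect_rejected(self):
        design = self.small_design(
            bands_with_effects={"theta": {(0, 1): 0.9}})
        base = dc.PrecisionSpec(n_regions=16, support=((0, 1),), strength=0.4)
        with pytest.raises(ValueError, match="outside"):
            dc.simulate_group_study(design, base)

    def test_effects_confined_to_effect_group(self):
        design = self.small_design(
            seed=4, bands_with_effects={"gamma": {(0, 1): 0.5}})
        base = dc.PrecisionSpec(n_regions=16, support=())
        bundle = dc.simulate_group_study(design, base)
        # sham rest and post come from the same distribution: the per-band
        # components share seeds keyed only by (group, subject, cond, band)
        assert {r.group for r in bundle.recordings} == {"verum", "sham"}


class TestSyntheticMaps:
    def spec(self, **kw):
        kw.setdefault("grid_shape", (20, 24, 20))
        kw.setdefault("voxel_size_mm", 4.0)
        kw.setdefault("template_regions",
                      (((0.0, 0.0, 0.0), 6.0), ((-20.0, 10.0, 8.0), 6.0)))
        return dc.SyntheticMapSpec(**kw)

    def test_noiseless_pattern(self):
        maps, affine, idx = dc.make_synthetic_spatial_maps(
            self.spec(noise_sd=0.0, in_template_z=2.0, n_components=3))
        patterned = maps[idx]
        assert set(np.unique(patterned)) == {0.0, 2.0}
        for i, m in enumerate(maps):
            if i != idx:
                assert np.all(m == 0.0)

    def test_patterned_map_scores_highest(self):
        spec = self.spec(noise_sd=0.5, in_template_z=2.0, n_components=5,
                         seed=9)
        maps, affine, idx = dc.make_synthetic_spatial_maps(spec)
        template = dc.SphericalTemplate(spec.template_regions)
        scores = [dc.template_fit_score(dc.SpatialMap(m, affine), template)
                  for m in maps]
        assert int(np.argmax(scores)) == idx

    def test_single_component(self):
        maps, affine, idx = dc.make_synthetic_spatial_maps(
            self.spec(n_components=1))
        assert idx == 0 and len(maps) == 1

    def test_center_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            dc.make_synthetic_spatial_maps(self.spec(
                template_regions=(((500.0, 0.0, 0.0), 5.0),)))


def test_random_support_respects_degree_cap():
    sup = random_support(16, 12, seed=0, max_degree=2)
    assert len(sup) == 12
    deg = np.zeros(16, int)
    for a, b in sup:
        deg[a] += 1
        deg[b] += 1
    assert deg.max() <= 2
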
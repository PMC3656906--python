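import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dmnconn as dc
from dmnconn.connectivity import collapse_subject_values, edge_list

from conftest import schur_partial_correlation


class TestSampleCovariance:
    def test_identical_channels_correlate_fully(self):
        x = np.random.default_rng(0).standard_normal(500)
        cov = dc.sample_covariance(np.vstack([x, x]))
        r = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
        assert r == pytest.approx(1.0)

    def test_zero_channel_gives_zero_row(self):
        data = np.vstack([np.zeros(100),
                          np.random.default_rng(1).standard_normal(100)])
        cov = dc.sample_covariance(data)
        assert np.allclose(cov[0], 0.0)

    def test_divisor_is_T(self):
        data = np.array([[0.0, 2.0]])
        assert dc.sample_covariance(data)[0, 0] == pytest.approx(1.0)

    def test_monte_carlo_recovery(self, rng):
        pop = np.array([[2.0, 0.8], [0.8, 1.0]])
        chol = np.linalg.cholesky(pop)
        data = chol @ rng.standard_normal((2, 50000))
        cov = dc.sample_covariance(data)
        # entries within 3 standard errors of the population values
        assert np.all(np.abs(cov - pop) < 3 * 3.0 / np.sqrt(50000))


class TestPartialCorrelation:
    def test_identity_covariance(self):
        r = dc.partial_correlation_from_covariance(np.eye(4))
        assert np.allclose(r - np.eye(4), 0.0)

    def test_two_variable_reduction(self):
        cov = np.array([[1.0, 0.6], [0.6, 1.0]])
        r = dc.partial_correlation_from_covariance(cov)
        assert r[0, 1] == pytest.approx(0.6)

    def test_equicorrelation_closed_form(self):
        cov = np.full((3, 3), 0.5) + 0.5 * np.eye(3)
        r = dc.partial_correlation_from_covariance(cov)
        off = r[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0 / 3.0)

    def test_matches_schur_oracle(self, random_spd_covariances):
        """Precision rescaling equals the regression-residual definition."""
        for cov in random_spd_covariances:
            r = dc.partial_correlation_from_covariance(cov)
            assert np.allclose(r, schur_partial_correlation(cov), atol=1e-8)

    def test_singular_covariance_rejected(self):
        x = np.random.default_rng(0).standard_normal(100)
        cov = dc.sample_covariance(np.vstack([x, x, -x]))
        with pytest.warns(RuntimeWarning, match="ill-conditioned"):
            r = dc.partial_correlation_from_covariance(cov)
        assert np.all(np.abs(r) <= 1.0)

    def test_estimator_sklearn_interface(self, rng):
        est = dc.PartialCorrelation()
        X = rng.standard_normal((5000, 4))
        est.fit(X)
        assert est.partial_correlation_.shape == (4, 4)
        assert np.allclose(est.partial_correlation_,
                           est.partial_correlation_.T)
        assert est.get_params()["ridge"] == pytest.approx(1e-6)
        cloned = dc.PartialCorrelation(**est.get_params())
        assert cloned.get_params() == est.get_params()


class TestFisher:
    def test_closed_form(self):
        assert dc.fisher_r_to_z(0.0) == 0.0
        assert dc.fisher_r_to_z(0.5) == pytest.approx(0.5 * np.log(3.0))
        assert dc.fisher_r_to_z(-0.5) == pytest.approx(-0.5 * np.log(3.0))

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            dc.fisher_r_to_z(1.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(-0.999, 0.999), st.floats(-0.999, 0.999))
    def test_odd_and_increasing(self, r1, r2):
        assert dc.fisher_r_to_z(-r1) == pytest.approx(-dc.fisher_r_to_z(r1))
        if r1 < r2:
            assert dc.fisher_r_to_z(r1) < dc.fisher_r_to_z(r2)


class TestEdgeTests:
    def test_symmetric_sample(self):
        t, p = dc.one_sample_edge_ttest([-1.0, 0.0, 1.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_closed_form_t(self):
        t, p = dc.one_sample_edge_ttest([1.0, 2.0, 3.0])
        assert t == pytest.approx(2 * np.sqrt(3), rel=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            dc.one_sample_edge_ttest([5.0, 5.0, 5.0])

    def test_paired_identical(self):
        t, p = dc.paired_edge_comparison([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert t == 0.0 and p == 1.0

    def test_paired_closed_form(self):
        t, _ = dc.paired_edge_comparison([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(2 * np.sqrt(3), rel=1e-6)

    def test_paired_mismatched_lengths(self):
        with pytest.raises(ValueError):
            dc.paired_edge_comparison([1.0, 2.0], [1.0, 2.0, 3.0])


class TestFdr:
    def test_step_up_by_hand(self):
        flags = dc.fdr_mask([0.001, 0.01, 0.02, 0.04, 0.2], q=0.05)
        assert flags.tolist() == [True, True, True, True, False]

    def test_all_half(self):
        assert not dc.fdr_mask([0.5] * 10).any()

    def test_single_p(self):
        assert dc.fdr_mask([0.04], q=0.05).tolist() == [True]

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_rejections_monotone_in_p(self, ps):
        flags = dc.fdr_mask(ps)
        if flags.any():
            thr = max(p for p, f in zip(ps, flags) if f)
            assert all(f for p, f in zip(ps, flags) if p <= thr)


class TestGroupMeanNetwork:
    def make_mats(self, vals):
        mats = []
        for v in vals:
            m = np.eye(3)
            m[0, 1] = m[1, 0] = v
            mats.append(m)
        return mats

    def test_mean_of_significant_edge(self):
        mats = self.make_mats([0.2, 0.4, 0.3, 0.25])
        stats = dc.group_mean_network(mats)
        i = stats.edges.index((0, 1))
        assert stats.significant[i]
        assert stats.mean_r[i] == pytest.approx(0.2875)

    def test_nonsignificant_edge_zeroed(self, rng):
        mats = [np.eye(3) + 0.0 for _ in range(10)]
        for m in mats:
            v = rng.normal(0, 0.05)
            m[0, 1] = m[0, 1] = v
            m[1, 0] = v
        stats = dc.group_mean_network(mats)
        assert np.all(stats.mean_r[~stats.significant] == 0.0)

    def test_single_subject_degenerate(self):
        stats = dc.group_mean_network(self.make_mats([0.3]))
        i = stats.edges.index((0, 1))
        assert stats.degenerate
        assert np.isnan(stats.t[i])
        assert stats.mean_r[i] == 0.0  # nothing significant without a test

    def test_mixed_cohorts_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            dc.group_mean_network([np.eye(3), np.eye(4)])


class TestCollapse:
    def build16(self, entries, labels):
        m = np.zeros((16, 16))
        idx = {lab: i for i, lab in enumerate(labels)}
        for (a, b), v in entries.items():
            m[idx[a], idx[b]] = m[idx[b], idx[a]] = v
        return m

    def test_max_of_four(self, labels16):
        m = self.build16({("PCC_L", "STG_L"): 0.1, ("PCC_L", "STG_R"): 0.0,
                          ("PCC_R", "STG_L"): 0.3, ("PCC_R", "STG_R"): 0.2},
                         labels16)
        net = dc.collapse_bilateral_max(m, labels16, dc.ROI_ORDER)
        assert net.value("PCC", "STG") == pytest.approx(0.3)
        assert net.provenance[("PCC", "STG")] == ("PCC_R", "STG_L")

    def test_all_zero(self, labels16):
        net = dc.collapse_bilateral_max(np.zeros((16, 16)), labels16,
                                        dc.ROI_ORDER)
        assert np.all(net.values == 0.0)
        assert net.provenance[("PCC", "STG")] is None

    def test_absolute_ordering_preserves_sign(self, labels16):
        m = self.build16({("MFG_L", "AG_L"): -0.4, ("MFG_L", "AG_R"): 0.1},
                         labels16)
        with pytest.warns(RuntimeWarning, match="sign-sensitive"):
            net = dc.collapse_bilateral_max(m, labels16, dc.ROI_ORDER)
        assert net.value("MFG", "AG") == pytest.approx(-0.4)
        assert ("MFG", "AG") in net.sign_sensitive

    def test_provenance_names_achieving_pair(self, rng, labels16):
        m = rng.normal(size=(16, 16))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        with pytest.warns(RuntimeWarning, match="sign-sensitive"):
            net = dc.collapse_bilateral_max(m, labels16, dc.ROI_ORDER)
        idx = {lab: i for i, lab in enumerate(labels16)}
        for (a, b), pair in net.provenance.items():
            v = net.value(a, b)
            if pair is not None:
                assert m[idx[pair[0]], idx[pair[1]]] == pytest.approx(v)

    def test_unpaired_node_rejected(self):
        labels = ["A_L", "A_R", "B_L"]
        with pytest.raises(ValueError, match="exactly two"):
            dc.collapse_bilateral_max(np.zeros((3, 3)), labels)

    def test_subject_values_follow_group_pairs(self, labels16):
        m = self.build16({("PCC_R", "STG_L"): 0.3}, labels16)
        net = dc.collapse_bilateral_max(m, labels16, dc.ROI_ORDER)
        subj = self.build16({("PCC_R", "STG_L"): 0.7,
                             ("PCC_L", "STG_L"): 0.9}, labels16)
        vals = collapse_subject_values(subj, labels16, net.provenance,
                                       dc.ROI_ORDER)
        a, b = dc.ROI_ORDER.index("PCC"), dc.ROI_ORDER.index("STG")
        assert vals[a, b] == pytest.approx(0.7)  # group pair, not subject max


class TestClassifyChanges:
    def net(self, vals):
        m = np.zeros((8, 8))
        names = dc.ROI_ORDER
        for (a, b), v in vals.items():
            i, j = names.index(a), names.index(b)
            m[i, j] = m[j, i] = v
        return dc.CollapsedNetwork(list(names), m)

    def test_emerged_and_suspended(self):
        rest = self.net({("STG", "IPL"): 0.05})
        post = self.net({("SFG", "AG"): 0.0475})
        df = dc.classify_edge_changes(rest, post)
        d = {(r.roi_a, r.roi_b): r.category for r in df.itertuples()}
        assert d[("SFG", "AG")] == "emerged"
        assert d[("STG", "IPL")] == "suspended"

    def test_increase_requires_paired_significance(self):
        rest = self.net({("PCC", "STG"): 0.05})
        post = self.net({("PCC", "STG"): 0.07})
        df = dc.classify_edge_changes(rest, post,
                                      {("PCC", "STG"): (0.5, 0.5)})
        assert df[(df.roi_a == "PCC") & (df.roi_b == "STG")
                  ].category.item() == "unchanged"
        df2 = dc.classify_edge_changes(rest, post,
                                       {("PCC", "STG"): (2.9, 0.019)})
        assert df2[(df2.roi_a == "PCC") & (df2.roi_b == "STG")
                   ].category.item() == "increased"

    def test_absent_in_both_is_unchanged(self):
        df = dc.classify_edge_changes(self.net({}), self.net({}))
        assert (df.category == "unchanged").all()


def test_edge_list_counts():
    assert len(edge_list(16)) == 120
    assert len(edge_list(8)) == 28
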
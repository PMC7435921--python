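import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import vfegm as v
from oracles import tally_entropy_bits, tally_joint_entropy_bits

H_GAUSS = 0.5 * np.log2(2 * np.pi * np.e)  # 2.0471 bits


def gaussian_xy(n, rho=0.5, seed=0):
    cov = np.array([[1.0, rho], [rho, 1.0]])
    return v.generate_bivariate_gaussian(v.GaussianConfig(n_samples=n, covariance=cov, seed=seed))


class TestMarginalEntropy:
    def test_gaussian_closed_form(self):
        x, _ = gaussian_xy(10**5, seed=1)
        est = v.estimate_entropy(x, 0.05)
        assert abs(est.value - H_GAUSS) < 0.05

    def test_uniform_closed_form_is_zero(self):
        x = np.random.default_rng(2).uniform(0.0, 1.0, 10**5)
        est = v.estimate_entropy(x, 0.1)
        assert abs(est.value) < 0.01
        assert est.n_occupied_bins == 10

    def test_small_sample_saturation_bias(self):
        # with N bins all distinct the plug-in estimate collapses to
        # log2(N) + log2(bin_width), far below the true differential entropy
        x, _ = gaussian_xy(100, seed=3)
        est = v.estimate_entropy(x, 1e-3)
        assert abs(est.value - (np.log2(100) + np.log2(1e-3))) < 1e-9
        assert est.n_occupied_bins == 100

    def test_constant_sequence_flagged_degenerate(self):
        est = v.estimate_entropy(np.full(50, 3.7), 0.25)
        assert est.degenerate
        assert est.value == np.log2(0.25)

    def test_matches_per_sample_tally_oracle(self):
        x = np.random.default_rng(4).standard_normal(1000)
        for db in (0.05, 0.4833, 2.0):
            assert abs(v.estimate_entropy(x, db).value - tally_entropy_bits(x, db)) < 1e-12

    def test_plugin_bound_invariant(self):
        x = np.random.default_rng(5).standard_normal(500)
        est = v.estimate_entropy(x, 0.01)
        assert est.value <= np.log2(est.n_samples) + np.log2(est.bin_width) + 1e-9


class TestJointEntropy:
    def test_independent_gaussians_additive(self):
        x, y = gaussian_xy(2 * 10**5, rho=0.0, seed=6)
        est = v.estimate_joint_entropy(x, y, 0.25)
        assert abs(est.value - 2 * H_GAUSS) < 0.05

    def test_identical_sequences_occupy_the_diagonal(self):
        x = np.random.default_rng(7).standard_normal(5000)
        hj = v.estimate_joint_entropy(x, x, 0.2)
        hx = v.estimate_entropy(x, 0.2)
        assert abs(hj.value - (hx.value + np.log2(0.2))) < 1e-9

    def test_correlated_gaussian_closed_form(self):
        x, y = gaussian_xy(2 * 10**5, rho=0.5, seed=8)
        est = v.estimate_joint_entropy(x, y, 0.25)
        assert abs(est.value - (2 * H_GAUSS + 0.5 * np.log2(0.75))) < 0.05

    def test_matches_tally_oracle(self):
        rng = np.random.default_rng(9)
        x, y = rng.standard_normal((2, 800))
        assert abs(
            v.estimate_joint_entropy(x, y, 0.3).value - tally_joint_entropy_bits(x, y, 0.3)
        ) < 1e-12


class TestMutualInformation:
    def test_independent_near_zero(self):
        x, y = gaussian_xy(2 * 10**5, rho=0.0, seed=10)
        assert abs(v.estimate_mi(x, y, 0.25).mi) < 0.02

    def test_correlated_closed_form(self):
        x, y = gaussian_xy(2 * 10**5, rho=0.5, seed=11)
        assert abs(v.estimate_mi(x, y, 0.25).mi - (-0.5 * np.log2(0.75))) < 0.03

    def test_self_information_equals_discrete_entropy(self):
        x = np.random.default_rng(12).standard_normal(2000)
        m = v.estimate_mi(x, x, 0.25)
        hx = v.estimate_entropy(x, 0.25)
        assert hx.n_occupied_bins >= 10
        assert abs(m.mi - (hx.value - np.log2(0.25))) < 1e-9

    def test_identity_and_symmetry(self):
        x, y = gaussian_xy(10**4, seed=13)
        m = v.estimate_mi(x, y, 0.4833)
        assert abs(m.mi - (m.h_lv + m.h_rv - m.h_joint)) < 1e-9
        m_swapped = v.estimate_mi(y, x, 0.4833)
        assert m.mi == m_swapped.mi

    def test_correction_convention_cancels_in_mi(self):
        x, y = gaussian_xy(10**4, seed=14)
        db = 0.3
        m = v.estimate_mi(x, y, db)
        raw = (
            (v.estimate_entropy(x, db).value - np.log2(db))
            + (v.estimate_entropy(y, db).value - np.log2(db))
            - (v.estimate_joint_entropy(x, y, db).value - 2 * np.log2(db))
        )
        assert abs(m.mi - raw) < 1e-9

    def test_shift_invariance(self):
        x, y = gaussian_xy(10**4, seed=15)
        db = 0.25
        base = v.estimate_mi(x, y, db).mi
        assert v.estimate_mi(x + 4 * db, y, db).mi == base  # exact on-grid shift
        assert abs(v.estimate_mi(x + 0.1234, y, db).mi - base) < 0.02

    @given(st.integers(min_value=0, max_value=50))
    def test_mi_nonnegative_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 400))
        x = rng.normal(scale=rng.uniform(0.1, 3.0), size=n)
        y = x * rng.uniform(-1, 1) + rng.normal(size=n)
        m = v.estimate_mi(x, y, float(rng.uniform(0.05, 1.5)))
        assert m.mi >= -1e-9
        assert abs(m.mi - (m.h_lv + m.h_rv - m.h_joint)) < 1e-9


class TestSweeps:
    def test_gaussian_sweep_populates_full_grid(self):
        template = v.GaussianConfig(n_samples=2, seed=0)
        res = v.sweep_n_and_binwidth(template, [100, 1000, 10000], [0.01, 0.1, 0.25, 0.5, 1.0])
        frame = res.to_frame()
        assert len(frame) == 15
        assert set(res.seeds) == {100, 1000, 10000}
        assert frame["n_occupied_bins"].gt(0).all()

    def test_small_n_small_bin_is_biased_large_n_is_not(self):
        template = v.GaussianConfig(n_samples=2, seed=1)
        res = v.sweep_n_and_binwidth(template, [100, 10**5], [1e-3, 0.25])
        small = res.estimates[(100, 1e-3)]
        large = res.estimates[(10**5, 0.25)]
        assert abs(small.h_lv - H_GAUSS) > 3.0
        assert abs(large.h_lv - H_GAUSS) < 0.05

    def test_cardiac_sweep_rows_and_plateau_report(self, default_pair):
        res = v.sweep_binwidth_cardiac(default_pair)
        frame = res.to_frame()
        assert len(frame) == 4
        assert sorted(frame["bin_width"]) == sorted(v.CANDIDATE_BIN_WIDTHS)
        report = res.stability_report()
        assert set(report.columns) >= {"N", "plateau_reached", "max_rel_change"}

    def test_fully_coupled_pair_maximizes_mi_at_every_binwidth(self):
        frames = {}
        for c in (0.0, 0.5, 1.0):
            pair = v.generate_vf_pair(v.VFSignalConfig(coupling=c, seed=16))
            frames[c] = v.sweep_binwidth_cardiac(pair).to_frame().set_index("bin_width")["MI"]
        for db in v.CANDIDATE_BIN_WIDTHS:
            assert frames[1.0][db] >= frames[0.5][db]
            assert frames[1.0][db] >= frames[0.0][db]

    def test_uncoupled_pair_mi_is_small_plugin_bias_decreasing_in_binwidth(self):
        cfg = v.VFSignalConfig(envelope_lv=(0.0,), envelope_rv=(0.0,),
                               noise_sd_lv=1.0, noise_sd_rv=1.0, coupling=0.0, seed=17)
        res = v.sweep_binwidth_cardiac(v.generate_vf_pair(cfg))
        frame = res.to_frame().sort_values("bin_width")
        mi = frame["MI"].to_numpy()
        assert np.all(mi > 0)
        assert np.all(mi < 0.5)
        assert mi[-1] < mi[0]  # coarser bins, fewer occupied cells, less bias
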
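import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

import corhythm as cr
from corhythm.errors import AnalysisError, ValidationError


def model(t, mesor, amp, peak, period=24.0):
    return mesor + amp * np.cos(2 * np.pi * (t - peak) / period)


class TestFitCosinor:
    def test_noise_free_recovery_is_exact(self, mouse_grid):
        y = model(mouse_grid, 5.0, 2.0, 14.5)
        fit = cr.fit_cosinor(y, mouse_grid)
        assert fit.mesor == pytest.approx(5.0, abs=1e-9)
        assert fit.amplitude == pytest.approx(2.0, abs=1e-9)
        assert fit.peak_time_h == pytest.approx(14.5, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_input_is_null(self, mouse_grid):
        fit = cr.fit_cosinor(np.full_like(mouse_grid, 7.0), mouse_grid)
        assert fit.amplitude == pytest.approx(0.0, abs=1e-9)
        assert fit.f_stat == 0.0
        assert fit.p_value == 1.0

    def test_matches_brute_force_rss_minimizer(self, mouse_grid):
        """OLS solution agrees with direct RSS minimization over
        (mesor, amplitude, peak) — grid scan refined by Nelder-Mead."""
        rng = np.random.default_rng(17)
        y = model(mouse_grid, 4.0, 1.2, 9.3) + rng.normal(0, 0.6, mouse_grid.size)

        def rss(params):
            m, a, ph = params
            return float(np.sum((y - model(mouse_grid, m, a, ph)) ** 2))

        best = None
        for ph0 in np.arange(0, 24, 1.0):
            res = minimize(rss, x0=[y.mean(), y.std(), ph0], method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
            if best is None or res.fun < best.fun:
                best = res
        m, a, ph = best.x
        if a < 0:  # canonical form: positive amplitude, peak shifted half period
            a, ph = -a, ph + 12.0
        ph %= 24.0
        fit = cr.fit_cosinor(y, mouse_grid)
        assert fit.mesor == pytest.approx(m, abs=1e-6)
        assert fit.amplitude == pytest.approx(a, abs=1e-6)
        d = (fit.peak_time_h - ph) % 24.0
        assert min(d, 24.0 - d) == pytest.approx(0.0, abs=1e-5)

    def test_f_test_matches_permutation_null(self, mouse_grid):
        """Parametric F-test p agrees with a permutation p within MC error."""
        rng = np.random.default_rng(3)
        y = model(mouse_grid, 2.0, 0.45, 5.0) + rng.normal(0, 1.0, mouse_grid.size)
        fit = cr.fit_cosinor(y, mouse_grid)
        n_perm = 10_000
        hits = 0
        for _ in range(n_perm):
            t_perm = rng.permutation(mouse_grid)
            hits += cr.fit_cosinor(y, t_perm).f_stat >= fit.f_stat
        p_perm = (hits + 1) / (n_perm + 1)
        mc_sd = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(fit.p_value - p_perm) < 4 * mc_sd + 0.005

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(shift=st.floats(0.0, 24.0), seed=st.integers(0, 10_000))
    def test_phase_equivariance_under_time_shift(self, mouse_grid, shift, seed):
        rng = np.random.default_rng(seed)
        y = model(mouse_grid, 3.0, 1.0, 6.0) + rng.normal(0, 0.4, mouse_grid.size)
        f0 = cr.fit_cosinor(y, mouse_grid)
        f1 = cr.fit_cosinor(y, (mouse_grid + shift) % 24.0)
        assert f1.amplitude == pytest.approx(f0.amplitude, abs=1e-8)
        assert f1.r2 == pytest.approx(f0.r2, abs=1e-8)
        assert f1.p_value == pytest.approx(f0.p_value, rel=1e-6)
        d = (f1.peak_time_h - f0.peak_time_h - shift) % 24.0
        assert min(d, 24.0 - d) == pytest.approx(0.0, abs=1e-6)

    def test_peak_recovery_at_stated_noise(self, mouse_grid):
        """Median |peak error| <= 1 h: amplitude 1.0, residual SD 0.5."""
        rng = np.random.default_rng(99)
        n_genes = 500
        peaks = rng.uniform(0, 24, n_genes)
        Y = np.stack(
            [model(mouse_grid, 5.0, 1.0, p) + rng.normal(0, 0.5, mouse_grid.size)
             for p in peaks],
            axis=1,
        )
        est = cr.CosinorRhythmometer().fit(Y, mouse_grid)
        err = np.abs((est.peak_time_h_ - peaks + 12.0) % 24.0 - 12.0)
        assert np.median(err) <= 1.0

    @pytest.mark.parametrize(
        "times,err",
        [
            (np.array([1.0, 1.0, 1.0, 1.0]), "distinct time"),
            (np.array([1.0, 2.0]), "at least 4"),
        ],
    )
    def test_degenerate_designs_rejected(self, times, err):
        with pytest.raises((ValidationError, AnalysisError), match=err):
            cr.fit_cosinor(np.ones_like(times), times)


class TestFitGroup:
    def test_null_genes_have_large_q(self, mouse_grid):
        rng = np.random.default_rng(12)
        n_genes = 100
        Y = rng.normal(5, 1, size=(mouse_grid.size, n_genes))
        est = cr.CosinorRhythmometer().fit(Y, mouse_grid)
        assert est.q_value_.min() > 0.2
        assert (est.q_value_ >= est.p_value_ - 1e-12).all()

    def test_gene_order_permutation_permutes_results(self, small_study):
        expr, samples, _ = small_study
        ms = samples.select(species="mouse")
        sub = expr.subset_samples(ms.sample_ids)
        norm = cr.normalize_log2(sub, cr.median_of_ratios(sub))
        res = cr.fit_group(norm, ms, "mouse_M_mPFC")
        perm = list(np.random.default_rng(0).permutation(norm.gene_ids))
        res_p = cr.fit_group(norm.subset_genes(perm), ms, "mouse_M_mPFC")
        a = res.frame.drop(columns="q_value").loc[perm]
        b = res_p.frame.drop(columns="q_value")
        pd.testing.assert_frame_equal(a, b)

    def test_single_timepoint_group_rejected(self):
        meta = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(6)],
                "species": "mouse",
                "sex": "M",
                "region": "mPFC",
                "time_h": 8.0,
            }
        )
        samples = cr.SampleTable(meta)
        em = cr.ExpressionMatrix(
            pd.DataFrame(
                np.ones((3, 6), dtype=int),
                index=["a", "b", "c"],
                columns=meta["sample_id"],
            )
        )
        with pytest.raises((ValidationError, AnalysisError), match="mouse_M_mPFC"):
            cr.fit_group(em, samples, "mouse_M_mPFC")


class TestBhFdr:
    def test_step_up_worked_example(self):
        q = cr.bh_fdr([0.01, 0.02, 0.03, 0.5])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_single_p_is_its_own_q(self):
        assert cr.bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_all_ones_capped(self):
        assert (cr.bh_fdr([1.0, 1.0, 1.0]) == 1.0).all()

    @pytest.mark.parametrize("bad", [[0.0], [1.2], [-0.1], [float("nan")]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValidationError):
            cr.bh_fdr(bad)
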
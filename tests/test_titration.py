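"""Equilibrium forward model, stability-constant and DNA-binding estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coordchar import (
    DNATitration,
    TitrationSeries,
    beer_lambert_concentration,
    chromism_percent,
    equilibrium_absorbance,
    gen_dna_titration,
    gen_metal_titration,
    gibbs_free_energy,
    molar_ratio_breakpoint,
    stability_constant,
    wolfe_shimer_fit,
)
from coordchar.titration import (
    DegenerateSeriesError,
    InconsistentChromismError,
    UnphysicalAbsorbanceError,
)


class TestEquilibriumAbsorbance:
    def test_zero_kf_gives_zero(self):
        assert equilibrium_absorbance(0.0, 2e-5, 4e-5, 1e4) == 0.0

    def test_saturation_limit_all_metal_bound(self):
        # huge Kf with excess ligand: A -> eps*b*C_M
        a = equilibrium_absorbance(1e12, 0.36e-4, 1.25e-4, 1e4, 1.0)
        assert a == pytest.approx(0.36, rel=1e-3)

    def test_known_root(self):
        # x = 1e-5 satisfies Kf = x/((C_M-x)(C_L-2x)^2) at Kf = 2.5e9:
        # 1e-5 / (1e-5 * (2e-5)^2) = 2.5e9, so A/eps must invert to 1e-5
        a = equilibrium_absorbance(2.5e9, 2e-5, 4e-5, 1e4, 1.0)
        assert a / 1e4 == pytest.approx(1e-5, rel=1e-10)

    @given(st.floats(min_value=2.0, max_value=9.0), st.floats(min_value=2.0, max_value=9.0))
    @settings(max_examples=40, deadline=None)
    def test_strictly_increasing_in_kf(self, la, lb):
        if abs(la - lb) < 1e-9:
            return
        lo, hi = sorted([10**la, 10**lb])
        a_lo = equilibrium_absorbance(lo, 2e-5, 4e-5, 1e4)
        a_hi = equilibrium_absorbance(hi, 2e-5, 4e-5, 1e4)
        assert a_hi > a_lo

    @given(st.floats(min_value=1e-5, max_value=9e-5), st.floats(min_value=1e-5, max_value=9e-5))
    @settings(max_examples=40, deadline=None)
    def test_strictly_increasing_in_ligand(self, ca, cb):
        if abs(ca - cb) < 1e-12:
            return
        lo, hi = sorted([ca, cb])
        a_lo = equilibrium_absorbance(1e8, 2e-5, lo, 1e4)
        a_hi = equilibrium_absorbance(1e8, 2e-5, hi, 1e4)
        assert a_hi > a_lo


class TestStabilityConstant:
    def test_pointwise_mass_action_value(self):
        # direct substitution oracle: x=1e-5 -> Kf = 1e-5/((1e-5)(2e-5)^2)
        series = TitrationSeries(
            metal_conc=2e-5,
            ligand_concs=(4e-5, 4.5e-5, 5e-5),
            absorbances=(0.1, 0.1, 0.1),
            epsilon=1e4,
        )
        fit = stability_constant(series)
        assert fit.kf_pointwise[0] == pytest.approx(2.5e9, rel=1e-9)
        assert fit.complex_conc[0] == pytest.approx(1e-5)

    @pytest.mark.parametrize("kf_true", [1e3, 1e4, 1.47e5, 1e6, 1e7, 1e8])
    def test_roundtrip_noise_free(self, kf_true):
        series, _ = gen_metal_titration(kf_true)
        fit = stability_constant(series)
        assert fit.kf == pytest.approx(kf_true, rel=1e-3)

    def test_zero_absorbance_flagged_as_zero_kf(self):
        series = TitrationSeries(
            metal_conc=2e-5,
            ligand_concs=(4e-5, 5e-5, 6e-5),
            absorbances=(0.0, 0.0, 0.0),
            epsilon=1e4,
        )
        fit = stability_constant(series)
        assert all(k == 0.0 for k in fit.kf_pointwise)

    def test_unphysical_absorbance_rejected(self):
        series = TitrationSeries(
            metal_conc=2e-5,
            ligand_concs=(4e-5, 5e-5, 6e-5),
            absorbances=(0.5, 0.5, 0.5),  # A/eps = 5e-5 > C_M
            epsilon=1e4,
        )
        with pytest.raises(UnphysicalAbsorbanceError):
            stability_constant(series)


class TestMolarRatioBreakpoint:
    @staticmethod
    def _two_line(break_at, n=11, slope=3.0, noise=0.0, rng=None):
        x = np.linspace(0.05, 0.95, n)
        y = np.where(x < break_at, slope * x, slope * break_at)
        if noise:
            y = y + rng.normal(0.0, noise, n)
        return x, y

    def test_exact_one_to_two(self):
        x, y = self._two_line(1 / 3)
        res = molar_ratio_breakpoint(x, y)
        assert res.ratio == pytest.approx(1 / 3, abs=1e-6)
        assert res.stoichiometry == "1:2"

    def test_exact_one_to_one(self):
        x, y = self._two_line(0.5)
        res = molar_ratio_breakpoint(x, y)
        assert res.ratio == pytest.approx(0.5, abs=1e-6)
        assert res.stoichiometry == "1:1"

    def test_noisy_monte_carlo(self):
        rng = np.random.default_rng(42)
        ratios = []
        for _ in range(200):
            x, y = self._two_line(1 / 3, n=15, noise=0.005, rng=rng)
            ratios.append(molar_ratio_breakpoint(x, y).ratio)
        assert float(np.median(ratios)) == pytest.approx(1 / 3, abs=0.02)

    def test_flat_series_degenerate(self):
        x = np.linspace(0.1, 0.9, 9)
        with pytest.raises(DegenerateSeriesError):
            molar_ratio_breakpoint(x, np.full(9, 2.0))


class TestWolfeShimer:
    @pytest.mark.parametrize("kb_true", [1e4, 1e5, 9e5, 1e6, 1e7])
    def test_exact_recovery_from_hyperbolic_model(self, kb_true):
        t, _ = gen_dna_titration(kb_true)
        fit = wolfe_shimer_fit(t)
        assert fit.kb == pytest.approx(kb_true, rel=1e-3)
        assert fit.epsilon_bound == pytest.approx(5e3, rel=1e-3)

    def test_hypochromic_sign(self):
        t, _ = gen_dna_titration(9e5, epsilon_free=1e4, epsilon_bound=5e3)
        fit = wolfe_shimer_fit(t)
        assert fit.chromism < 0

    def test_noise_median_error(self):
        rng = np.random.default_rng(7)
        errs = []
        for _ in range(200):
            t, _ = gen_dna_titration(9e5, n_points=6)
            eps = np.asarray(t.epsilon_apparent)
            noisy = DNATitration(
                dna_concs=t.dna_concs,
                epsilon_apparent=tuple(eps * (1 + 0.01 * rng.standard_normal(6))),
                epsilon_free=t.epsilon_free,
            )
            try:
                errs.append(abs(wolfe_shimer_fit(noisy).kb - 9e5) / 9e5)
            except (InconsistentChromismError, ValueError):
                continue
        assert float(np.median(errs)) <= 0.10

    def test_constant_epsilon_rejected(self):
        t = DNATitration(
            dna_concs=(1e-6, 2e-6, 3e-6),
            epsilon_apparent=(1e4, 1e4, 1e4),
            epsilon_free=1e4,
        )
        with pytest.raises(InconsistentChromismError):
            wolfe_shimer_fit(t)


class TestGibbsAndChromism:
    def test_unit_cases(self):
        assert gibbs_free_energy(1.0, 298.0) == 0.0
        assert gibbs_free_energy(math.e, 1.0) == pytest.approx(-8.314)

    def test_dna_binding_value(self):
        assert gibbs_free_energy(9e5, 298.0) == pytest.approx(-33.97e3, abs=10)

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            gibbs_free_energy(0.0)

    @given(st.floats(min_value=-3, max_value=8), st.floats(min_value=-3, max_value=8))
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_negative_iff_k_above_1(self, la, lb):
        ka, kb = 10**la, 10**lb
        ga, gb = gibbs_free_energy(ka), gibbs_free_energy(kb)
        if ka < kb:
            assert ga > gb
        assert (ga < 0) == (ka > 1)

    @pytest.mark.parametrize(
        "free, bound, expected", [(1.0, 0.8, -20.0), (1.0, 1.2, 20.0), (1.0, 1.0, 0.0)]
    )
    def test_chromism(self, free, bound, expected):
        assert chromism_percent(free, bound) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "a, eps, expected", [(0.0, 6600, 0.0), (0.7986, 6600, 1.21e-4), (6600, 6600, 1.0)]
    )
    def test_beer_lambert(self, a, eps, expected):
        assert beer_lambert_concentration(a, eps) == pytest.approx(expected, rel=1e-3)
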
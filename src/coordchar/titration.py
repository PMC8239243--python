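"""Equilibrium binding models and estimators for spectrophotometric titrations.

Two experiments are covered:

* **Metal-ligand titration** (molar-ratio method). A metal ion M at fixed
  concentration C_M is titrated with ligand L, forming ML2:
  M + 2L <=> ML2 with formation constant
  Kf = [ML2] / ([M][L]^2) = x / ((C_M - x)(C_L - 2x)^2),
  where x = [ML2]. Absorbance reads out x through Beer's law, A = eps*b*x.
  The breakpoint of A versus the metal mole fraction [M]/([M]+[L]) gives
  the stoichiometry (1:2 binding breaks near 1/3).

* **DNA titration** (two-state binding isotherm). The apparent extinction
  coefficient eps_a of a compound moves from its free value eps_f toward a
  bound value eps_b as DNA is added. The linearized isotherm

      [DNA]/(eps_a - eps_f) = [DNA]/(eps_b - eps_f) + 1/(Kb (eps_b - eps_f))

  yields Kb as slope/intercept of [DNA]/(eps_a - eps_f) versus [DNA]
  (Wolfe-Shimer plot), and eps_b from the slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import linregress

__all__ = [
    "TitrationSeries",
    "StabilityFit",
    "DNATitration",
    "BindingFit",
    "BreakpointResult",
    "UnphysicalAbsorbanceError",
    "DegenerateSeriesError",
    "InconsistentChromismError",
    "UnboundedKbError",
    "GAS_CONSTANT",
    "equilibrium_absorbance",
    "stability_constant",
    "molar_ratio_breakpoint",
    "wolfe_shimer_fit",
    "gibbs_free_energy",
    "chromism_percent",
    "beer_lambert_concentration",
]

GAS_CONSTANT = 8.314  # J K^-1 mol^-1


class UnphysicalAbsorbanceError(ValueError):
    """Absorbance implies more complex than the mass balance allows."""


class DegenerateSeriesError(ValueError):
    """Titration series carries no detectable breakpoint."""


class InconsistentChromismError(ValueError):
    """eps_a - eps_f changes sign (or vanishes) across the DNA series."""


class UnboundedKbError(ValueError):
    """Wolfe-Shimer intercept is indistinguishable from zero."""


@dataclass(frozen=True)
class TitrationSeries:
    """Fixed-metal titration: C_M constant, ligand concentration swept."""

    metal_conc: float
    ligand_concs: tuple[float, ...]
    absorbances: tuple[float, ...]
    path_length: float = 1.0
    epsilon: float | None = None

    def __post_init__(self) -> None:
        cl = tuple(float(c) for c in self.ligand_concs)
        a = tuple(float(x) for x in self.absorbances)
        if len(cl) != len(a) or len(cl) < 3:
            raise ValueError("need matched ligand/absorbance lists of length >= 3")
        if self.metal_conc <= 0 or any(c <= 0 for c in cl):
            raise ValueError("all concentrations must be positive")
        if any(x < 0 for x in a):
            raise ValueError("absorbances must be non-negative")
        if self.path_length <= 0:
            raise ValueError("path length must be positive")
        object.__setattr__(self, "ligand_concs", cl)
        object.__setattr__(self, "absorbances", a)


@dataclass(frozen=True)
class StabilityFit:
    kf: float                      # headline Kf, M^-2 (forward-model fit)
    kf_pointwise: tuple[float, ...]  # per-point Kf from the mass-action form
    kf_pointwise_mean: float
    complex_conc: tuple[float, ...]  # [ML2] per point, mol/L
    epsilon: float
    stoichiometry_ratio: float = 0.5  # ligand:metal = 2 -> ratio 1:2


@dataclass(frozen=True)
class DNATitration:
    dna_concs: tuple[float, ...]       # base-pair molarity
    epsilon_apparent: tuple[float, ...]
    epsilon_free: float
    compound_conc: float | None = None

    def __post_init__(self) -> None:
        d = tuple(float(c) for c in self.dna_concs)
        e = tuple(float(x) for x in self.epsilon_apparent)
        if len(d) != len(e) or len(d) < 3:
            raise ValueError("need matched DNA/extinction lists of length >= 3")
        if any(c <= 0 for c in d):
            raise ValueError("DNA concentrations must be positive")
        object.__setattr__(self, "dna_concs", d)
        object.__setattr__(self, "epsilon_apparent", e)


@dataclass(frozen=True)
class BindingFit:
    kb: float              # M^-1
    epsilon_bound: float   # L mol^-1 cm^-1
    delta_g: float         # J/mol at temperature
    temperature: float     # K
    chromism: float        # signed percent; negative = hypochromic
    r_squared: float


@dataclass(frozen=True)
class BreakpointResult:
    ratio: float                  # mole-fraction abscissa of the intersection
    stoichiometry: str            # "1:2", "1:1", or "indeterminate"
    split_index: int
    r_squared_left: float
    r_squared_right: float


def equilibrium_absorbance(
    kf: float, c_m: float, c_l: float, epsilon: float, b: float = 1.0
) -> float:
    """Forward model: absorbance of the ML2 complex at equilibrium.

    Solves Kf = x/((C_M - x)(C_L - 2x)^2) for the unique root x in
    [0, min(C_M, C_L/2)) and returns eps*b*x. The left side of the
    bracket gives f(0) <= Kf and the upper end diverges, so bisection
    (Brent) bracketing is guaranteed.
    """
    if c_m <= 0 or c_l <= 0 or epsilon <= 0 or b <= 0:
        raise ValueError("concentrations, epsilon and path length must be positive")
    if kf < 0:
        raise ValueError("Kf must be non-negative")
    if kf == 0.0:
        return 0.0
    x_max = min(c_m, c_l / 2.0)

    def g(x: float) -> float:
        # log-free residual: Kf*(C_M-x)*(C_L-2x)^2 - x, strictly decreasing
        return kf * (c_m - x) * (c_l - 2.0 * x) ** 2 - x

    hi = x_max * (1.0 - 1e-12)
    if g(hi) >= 0.0:  # numerically saturated: all limiting species consumed
        x = x_max
    else:
        x = brentq(g, 0.0, hi, xtol=1e-300, rtol=1e-14)
    return epsilon * b * x


def stability_constant(series: TitrationSeries) -> StabilityFit:
    """Estimate the ML2 formation constant from a fixed-metal titration.

    Two estimates are produced. The per-point values apply the mass-action
    expression Kf = x/((C_M-x)(C_L-2x)^2) with x = A/(eps*b) at each point
    (noise-amplifying near saturation, reported for transparency). The
    headline ``kf`` is a one-parameter least-squares fit of the forward
    model in log10(Kf), which weights every point through the model.

    When ``series.epsilon`` is not supplied it is estimated from the
    saturation plateau as max(A)/(b*C_M) — i.e. the plateau is assumed to
    correspond to fully complexed metal.
    """
    b = series.path_length
    c_m = series.metal_conc
    a = np.asarray(series.absorbances)
    c_l = np.asarray(series.ligand_concs)

    eps = series.epsilon
    if eps is None:
        eps = float(a.max() / (b * c_m))
        if eps <= 0:
            raise ValueError("cannot estimate epsilon from an all-zero series")

    x = a / (eps * b)
    limit = np.minimum(c_m, c_l / 2.0)
    if np.any(x >= limit):
        i = int(np.argmax(x >= limit))
        raise UnphysicalAbsorbanceError(
            f"point {i}: A/eps = {x[i]:.3e} M is >= the stoichiometric limit "
            f"{limit[i]:.3e} M (C_M = {c_m:.3e}, C_L = {c_l[i]:.3e})"
        )

    with np.errstate(divide="ignore"):
        kf_point = np.where(x > 0, x / ((c_m - x) * (c_l - 2.0 * x) ** 2), 0.0)

    def sse(log10_kf: float) -> float:
        kf = 10.0 ** log10_kf
        model = np.array([equilibrium_absorbance(kf, c_m, cl, eps, b) for cl in c_l])
        return float(np.sum((model - a) ** 2))

    res = minimize_scalar(sse, bounds=(-2.0, 16.0), method="bounded",
                          options={"xatol": 1e-10})
    kf_fit = 10.0 ** float(res.x)

    return StabilityFit(
        kf=kf_fit,
        kf_pointwise=tuple(float(k) for k in kf_point),
        kf_pointwise_mean=float(kf_point[kf_point > 0].mean()) if np.any(kf_point > 0) else 0.0,
        complex_conc=tuple(float(v) for v in x),
        epsilon=float(eps),
    )


def molar_ratio_breakpoint(
    mole_fractions: Sequence[float], absorbances: Sequence[float]
) -> BreakpointResult:
    """Locate the breakpoint of an absorbance-versus-mole-fraction plot.

    Fits two least-squares lines (an ascending branch and a plateau
    branch) with the split chosen to minimize the total squared residual;
    ties break toward the smaller abscissa. The intersection abscissa of
    the two lines is the stoichiometric ratio: values in [0.28, 0.38]
    are read as 1:2 metal:ligand binding, values in [0.45, 0.55] as 1:1.
    """
    xs = np.asarray(mole_fractions, dtype=float)
    ys = np.asarray(absorbances, dtype=float)
    if xs.shape != ys.shape or xs.size < 5:
        raise ValueError("need >= 5 matched points")
    order = np.argsort(xs)[::-1] if xs[0] > xs[-1] else np.argsort(xs)
    xs, ys = xs[order], ys[order]

    best = None
    for split in range(2, xs.size - 1):
        xl, yl = xs[:split], ys[:split]
        xr, yr = xs[split:], ys[split:]
        (sl, il), rl = _lsq_line(xl, yl)
        (sr, ir), rr = _lsq_line(xr, yr)
        tot = rl + rr
        if best is None or tot < best[0] - 1e-15:
            best = (tot, split, sl, il, sr, ir)
    assert best is not None
    _, split, sl, il, sr, ir = best

    if abs(sl - sr) < 1e-12 * max(1.0, abs(sl), abs(sr)):
        raise DegenerateSeriesError("no detectable slope change in the series")
    ratio = (ir - il) / (sl - sr)

    if 0.28 <= ratio <= 0.38:
        stoich = "1:2"
    elif 0.45 <= ratio <= 0.55:
        stoich = "1:1"
    else:
        stoich = "indeterminate"
    return BreakpointResult(
        ratio=float(ratio),
        stoichiometry=stoich,
        split_index=split,
        r_squared_left=_r2(xs[:split], ys[:split], sl, il),
        r_squared_right=_r2(xs[split:], ys[split:], sr, ir),
    )


def _lsq_line(x: np.ndarray, y: np.ndarray) -> tuple[tuple[float, float], float]:
    A = np.vstack([x, np.ones_like(x)]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = float(np.sum((y - A @ coef) ** 2))
    return (float(coef[0]), float(coef[1])), resid


def _r2(x: np.ndarray, y: np.ndarray, slope: float, intercept: float) -> float:
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot


def wolfe_shimer_fit(
    t: DNATitration, temperature: float = 298.0, intercept_rtol: float = 1e-12
) -> BindingFit:
    """Fit the linearized two-state DNA-binding isotherm.

    Regresses y = [DNA]/(eps_a - eps_f) on [DNA]; then
    Kb = slope/intercept, eps_b = eps_f + 1/slope, and
    delta_g = -R*T*ln(Kb) at *temperature*. The linearization is
    algebraically exact for noise-free hyperbolic data.
    """
    dna = np.asarray(t.dna_concs)
    de = np.asarray(t.epsilon_apparent) - t.epsilon_free
    if np.any(de == 0) or (np.any(de > 0) and np.any(de < 0)):
        raise InconsistentChromismError(
            "eps_a - eps_f must be nonzero and of one sign at every point"
        )
    y = dna / de
    fit = linregress(dna, y)
    slope, intercept = float(fit.slope), float(fit.intercept)
    if abs(intercept) <= intercept_rtol * max(abs(slope) * dna.max(), 1e-300):
        raise UnboundedKbError("intercept within tolerance of zero; Kb unbounded")
    kb = slope / intercept
    if kb <= 0:
        raise UnboundedKbError(f"slope/intercept gave non-positive Kb = {kb:.3e}")
    eps_b = t.epsilon_free + 1.0 / slope
    chrom = chromism_percent(t.epsilon_free, eps_b)
    return BindingFit(
        kb=kb,
        epsilon_bound=eps_b,
        delta_g=gibbs_free_energy(kb, temperature),
        temperature=temperature,
        chromism=chrom,
        r_squared=float(fit.rvalue) ** 2,
    )


def gibbs_free_energy(k: float, temperature: float = 298.0) -> float:
    """Standard free energy -R*T*ln(K) in J/mol (R = 8.314 J K^-1 mol^-1)."""
    if k <= 0:
        raise ValueError(f"equilibrium constant must be positive, got {k}")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return -GAS_CONSTANT * temperature * math.log(k)


def chromism_percent(a_free: float, a_bound: float) -> float:
    """Signed percent absorbance change on binding.

    Negative = hypochromic (absorbance drops), positive = hyperchromic.
    """
    if a_free <= 0:
        raise ValueError("free-compound absorbance must be positive")
    return 100.0 * (a_bound - a_free) / a_free


def beer_lambert_concentration(a: float, epsilon: float, b: float = 1.0) -> float:
    """Concentration from Beer's law, c = A/(eps*b)."""
    if epsilon <= 0 or b <= 0:
        raise ValueError("epsilon and path length must be positive")
    return a / (epsilon * b)
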
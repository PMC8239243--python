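"""Synthetic raw-data generators with known ground truth.

Every raw input the characterization pipeline consumes can be emulated
here: metal-ligand titrations (two-state ML2 equilibrium with
Beer-Lambert readout), DNA titrations (hyperbolic two-state binding of
the apparent extinction coefficient), non-isothermal TGA traces
(first-order Arrhenius steps integrated under a constant heating rate),
MTT dose-response plates (Hill survival mapped to optical densities),
and d-d band pairs consistent with given ligand-field parameters.

Default grids mirror the titration protocols these estimators are built
for: metal held at 3.6e-5 M with ligand swept 1.8e-5 to 1.25e-4 M, DNA
swept 1.69e-6 to 5.55e-6 M (base pairs), a 10 K/min TGA ramp from 25 to
800 C, and twofold plate dilutions. Noise is additive Gaussian on the
measured channel; a seed fully determines the output.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .cytotox import PlateReadings
from .ligand_field import BandSet
from .thermal import R, TGACurve
from .titration import DNATitration, TitrationSeries, equilibrium_absorbance

__all__ = [
    "gen_metal_titration",
    "gen_dna_titration",
    "gen_tga_curve",
    "gen_mtt_plate",
    "gen_bandset",
    "DEFAULT_METAL_CONC",
    "DEFAULT_LIGAND_RANGE",
    "DEFAULT_DNA_RANGE",
]

DEFAULT_METAL_CONC = 0.36e-4          # mol/L
DEFAULT_LIGAND_RANGE = (0.18e-4, 1.25e-4)  # mol/L
DEFAULT_DNA_RANGE = (1.69e-6, 5.55e-6)     # mol/L base pairs


def gen_metal_titration(
    kf: float,
    epsilon: float = 1.0e4,
    metal_conc: float = DEFAULT_METAL_CONC,
    ligand_range: tuple[float, float] = DEFAULT_LIGAND_RANGE,
    n_points: int = 12,
    path_length: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> tuple[TitrationSeries, dict]:
    """Fixed-metal titration series from the ML2 equilibrium forward model.

    Returns the series and a ground-truth dict (kf, epsilon, grid).
    """
    rng = np.random.default_rng(seed)
    c_l = np.linspace(*ligand_range, n_points)
    a = np.array(
        [equilibrium_absorbance(kf, metal_conc, cl, epsilon, path_length) for cl in c_l]
    )
    if noise_sigma > 0:
        a = np.clip(a + rng.normal(0.0, noise_sigma, a.shape), 0.0, None)
    series = TitrationSeries(
        metal_conc=metal_conc,
        ligand_concs=tuple(c_l),
        absorbances=tuple(a),
        path_length=path_length,
        epsilon=epsilon,
    )
    truth = {"kf": kf, "epsilon": epsilon, "metal_conc": metal_conc,
             "noise_sigma": noise_sigma, "seed": seed}
    return series, truth


def gen_dna_titration(
    kb: float,
    epsilon_free: float = 1.0e4,
    epsilon_bound: float = 5.0e3,
    dna_range: tuple[float, float] = DEFAULT_DNA_RANGE,
    n_points: int = 6,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> tuple[DNATitration, dict]:
    """DNA titration from the two-state hyperbolic binding model.

    eps_a([DNA]) = eps_f + (eps_b - eps_f) * Kb [DNA] / (1 + Kb [DNA]),
    plus additive Gaussian noise on eps_a. eps_b < eps_f produces a
    hypochromic series.
    """
    rng = np.random.default_rng(seed)
    dna = np.linspace(*dna_range, n_points)
    frac = kb * dna / (1.0 + kb * dna) if kb > 0 else np.zeros_like(dna)
    eps_a = epsilon_free + (epsilon_bound - epsilon_free) * frac
    if noise_sigma > 0:
        eps_a = eps_a + rng.normal(0.0, noise_sigma, eps_a.shape)
    t = DNATitration(
        dna_concs=tuple(dna),
        epsilon_apparent=tuple(eps_a),
        epsilon_free=epsilon_free,
    )
    truth = {"kb": kb, "epsilon_free": epsilon_free, "epsilon_bound": epsilon_bound,
             "noise_sigma": noise_sigma, "seed": seed}
    return t, truth


def _integrate_alpha(
    temps_k: np.ndarray, ea: float, a: float, beta_k_per_s: float
) -> np.ndarray:
    """RK4 integration of dalpha/dT = (A/beta) exp(-Ea/RT) (1 - alpha)."""

    def rate(t_k: float, alpha: float) -> float:
        return (a / beta_k_per_s) * math.exp(-ea / (R * t_k)) * (1.0 - alpha)

    alphas = np.empty_like(temps_k)
    alphas[0] = 0.0
    y = 0.0
    for i in range(1, temps_k.size):
        t0, t1 = temps_k[i - 1], temps_k[i]
        h = t1 - t0
        k1 = rate(t0, y)
        k2 = rate(t0 + h / 2, y + h * k1 / 2)
        k3 = rate(t0 + h / 2, y + h * k2 / 2)
        k4 = rate(t1, y + h * k3)
        y = min(y + (h / 6) * (k1 + 2 * k2 + 2 * k3 + k4), 1.0)
        alphas[i] = y
    return alphas


def gen_tga_curve(
    steps: Sequence[tuple[float, float, float]],
    heating_rate: float = 10.0,
    t_start_c: float = 25.0,
    t_end_c: float = 800.0,
    resolution_k: float = 0.5,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> tuple[TGACurve, dict]:
    """Non-isothermal TGA trace composed of first-order Arrhenius steps.

    ``steps`` is a sequence of (Ea [J/mol], A [s^-1], mass fraction lost);
    fractions must sum to <= 1. Each step's extent alpha_i(T) is RK4-
    integrated at ``resolution_k`` kelvin; the trace is
    100 * (1 - sum_i f_i alpha_i(T)), monotone non-increasing before
    noise. Returns the curve and the ground-truth step list.
    """
    fracs = [f for *_ignored, f in steps]
    if any(f <= 0 for f in fracs) or sum(fracs) > 1.0 + 1e-12:
        raise ValueError("step mass fractions must be positive and sum to <= 1")
    rng = np.random.default_rng(seed)
    n = int(round((t_end_c - t_start_c) / resolution_k)) + 1
    temps_c = np.linspace(t_start_c, t_end_c, n)
    temps_k = temps_c + 273.15
    mass = np.full(n, 100.0)
    beta_s = heating_rate / 60.0
    for ea, a, frac in steps:
        mass -= 100.0 * frac * _integrate_alpha(temps_k, ea, a, beta_s)
    if noise_sigma > 0:
        mass = np.clip(mass + rng.normal(0.0, noise_sigma, n), 0.0, 100.0)
    curve = TGACurve(
        temperature_c=tuple(temps_c),
        mass_percent=tuple(mass),
        heating_rate=heating_rate,
    )
    truth = {"steps": [{"ea": e, "a": a, "fraction": f} for e, a, f in steps],
             "heating_rate": heating_rate, "noise_sigma": noise_sigma, "seed": seed}
    return curve, truth


def gen_mtt_plate(
    ic50: float,
    hill: float = 1.0,
    doses: Sequence[float] | None = None,
    control_od: float = 1.0,
    background_od: float = 0.05,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> tuple[PlateReadings, dict]:
    """MTT plate with Hill-model survival 100/(1 + (dose/IC50)^hill).

    Survival maps to OD as bg + survival/100 * (control - bg); additive
    Gaussian noise is applied to the treated ODs. Default doses are
    twofold dilutions 3.125 to 400 ug/ml.
    """
    if ic50 <= 0 or hill <= 0:
        raise ValueError("IC50 and Hill slope must be positive")
    rng = np.random.default_rng(seed)
    if doses is None:
        doses = [400.0 / 2**k for k in range(7, -1, -1)]
    d = np.asarray(doses, dtype=float)
    surv = 100.0 / (1.0 + (d / ic50) ** hill)
    span = control_od - background_od
    od = background_od + (surv / 100.0) * span
    if noise_sigma > 0:
        od = np.clip(od + rng.normal(0.0, noise_sigma, od.shape), background_od, None)
    plate = PlateReadings(
        doses=tuple(d),
        od560_treated=tuple(od),
        od560_control=control_od,
        od620_background=background_od,
    )
    truth = {"ic50": ic50, "hill": hill, "noise_sigma": noise_sigma, "seed": seed}
    return plate, truth


def gen_bandset(config: str, dq: float, b: float) -> BandSet:
    """Band pair (V2, V3) consistent with given ligand-field parameters.

    For d8 (Ni-type) the two spin-allowed transitions are

        v_{2,3} = 15 Dq + 7.5 B -/+ 0.5 sqrt(225 B^2 + 100 Dq^2 - 180 Dq B)

    so V2 + V3 = 30 Dq + 15 B and the linear B relation round-trips
    exactly. For d7 (Co-type) the pair is reconstructed by inverting the
    two closed forms used by :func:`~coordchar.ligand_field.cobalt_ligand_field`.
    B = 0 collapses the d8 pair toward degeneracy and raises a warning
    via the returned labels instead.
    """
    if dq <= 0 or b < 0:
        raise ValueError("Dq must be positive and B non-negative")
    if config == "d8_Ni":
        radicand = 225.0 * b * b + 100.0 * dq * dq - 180.0 * dq * b
        if radicand < 0:
            raise ValueError(f"negative radicand {radicand:.4g} for (Dq, B)")
        half = 0.5 * math.sqrt(radicand)
        centre = 15.0 * dq + 7.5 * b
        v2, v3 = centre - half, centre + half
        labels = ("", "") if b > 0 else ("degenerate: B=0", "degenerate: B=0")
        return BandSet(v2=v2, v3=v3, labels=labels)
    if config == "d7_Co":
        d = 15.0 * b - 30.0 * dq        # V3 - 2 V2
        s = 340.0 * dq + 9.0 * d        # = sqrt(85 V3^2 - 4 d^2)
        if s < 0:
            raise ValueError("no d7 band pair exists for this (Dq, B)")
        v3 = math.sqrt((s * s + 4.0 * d * d) / 85.0)
        v2 = (v3 - d) / 2.0
        if v2 <= 0:
            raise ValueError("d7 inversion gave a non-positive V2")
        return BandSet(v2=v2, v3=v3)
    raise ValueError(f"config must be 'd7_Co' or 'd8_Ni', got {config!r}")
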
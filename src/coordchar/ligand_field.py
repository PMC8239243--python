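"""Ligand-field and EPR parameter arithmetic for octahedral d7/d8 ions.

From two observed d-d transition energies (wavenumbers V2 < V3) the
ligand-field splitting Dq and the Racah interelectronic-repulsion
parameter B are obtained through closed forms specific to the electron
configuration; the nephelauxetic ratio beta = B/B0 compares B to the
free-ion value B0 (971 cm^-1 for Co(II), 1030 cm^-1 for Ni(II)) and
drops below 1 as metal-ligand covalency delocalizes the d electrons.

For an axially distorted Cu(II) centre the powder EPR spectrum yields
g_parallel and g_perpendicular; the isotropic average
g_av = (g_par + 2 g_perp)/3 below 2.3 is the conventional marker of a
covalent metal-ligand bond.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BandSet",
    "LigandFieldResult",
    "EPRResult",
    "InconsistentBandError",
    "FREE_ION_B0",
    "to_wavenumber",
    "cobalt_ligand_field",
    "nickel_ligand_field",
    "g_average",
    "spin_only_moment",
]

#: Free-ion Racah B values (cm^-1) used for the nephelauxetic ratio.
FREE_ION_B0 = {"d7_Co": 971.0, "d8_Ni": 1030.0}

#: g_av at or above this value is read as an ionic metal-ligand bond.
COVALENCY_THRESHOLD = 2.3


class InconsistentBandError(ValueError):
    """Band pair incompatible with the closed-form Dq expression."""


@dataclass(frozen=True)
class BandSet:
    """A pair of d-d transition energies, lowest first."""

    v2: float  # cm^-1
    v3: float  # cm^-1
    labels: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        if self.v2 <= 0 or self.v3 <= 0:
            raise ValueError("band energies must be positive")


@dataclass(frozen=True)
class LigandFieldResult:
    dq: float            # cm^-1
    ten_dq: float        # cm^-1, always 10*dq
    b: float             # Racah B, cm^-1
    beta: float          # B/B0
    b0: float            # free-ion B, cm^-1
    config: str          # "d7_Co" | "d8_Ni"
    dq_source: str = "closed_form"   # or "user_supplied"
    notes: str = ""


@dataclass(frozen=True)
class EPRResult:
    g_parallel: float
    g_perpendicular: float
    g_average: float
    covalency: str  # "covalent" | "ionic"


def to_wavenumber(wavelength_nm: float) -> float:
    """Convert a wavelength in nm to a wavenumber in cm^-1 (1e7/lambda)."""
    if wavelength_nm <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength_nm}")
    return 1e7 / wavelength_nm


def cobalt_ligand_field(v2: float, v3: float) -> LigandFieldResult:
    """Dq, B, beta for an octahedral d7 Co(II) ion from its V2, V3 bands.

        Dq = [ (85 V3^2 - 4 (V3 - 2 V2)^2)^1/2 - 9 (V3 - 2 V2) ] / 340
        B  = (V3 - 2 V2 + 30 Dq) / 15,   beta = B / 971
    """
    if v2 <= 0 or v3 <= 0:
        raise ValueError("band energies must be positive")
    d = v3 - 2.0 * v2
    radicand = 85.0 * v3 * v3 - 4.0 * d * d
    if radicand < 0:
        raise InconsistentBandError(
            f"negative radicand {radicand:.4g} in the d7 Dq closed form"
        )
    dq = (math.sqrt(radicand) - 9.0 * d) / 340.0
    b = (d + 30.0 * dq) / 15.0
    b0 = FREE_ION_B0["d7_Co"]
    return LigandFieldResult(
        dq=dq, ten_dq=10.0 * dq, b=b, beta=b / b0, b0=b0, config="d7_Co"
    )


def nickel_ligand_field(
    v2: float, v3: float, ten_dq: float | None = None
) -> LigandFieldResult:
    """Dq, B, beta for an octahedral d8 Ni(II) ion.

    The closed form

        Dq = [ (9 V2 + V3) - (85 (V2 - V3)^2 - 4 (V2 + V3)^2)^1/2 ] / 340

    has a radicand that goes negative whenever the two bands are close
    (it requires |V2 - V3| > ~0.217 (V2 + V3)); in that case a
    user-supplied ``ten_dq`` is required and the result records that the
    closed form failed. B always comes from the linear relation
    B = (V2 + V3 - 30 Dq)/15 and beta = B/1030.
    """
    if v2 <= 0 or v3 <= 0:
        raise ValueError("band energies must be positive")
    b0 = FREE_ION_B0["d8_Ni"]
    radicand = 85.0 * (v2 - v3) ** 2 - 4.0 * (v2 + v3) ** 2
    notes = ""
    if radicand >= 0:
        dq = ((9.0 * v2 + v3) - math.sqrt(radicand)) / 340.0
        source = "closed_form"
        if ten_dq is not None:
            dq = ten_dq / 10.0
            source = "user_supplied"
    else:
        if ten_dq is None:
            raise InconsistentBandError(
                f"d8 Dq closed form fails on these bands (radicand = "
                f"{radicand:.4g} < 0); supply ten_dq explicitly"
            )
        dq = ten_dq / 10.0
        source = "user_supplied"
        notes = f"closed-form Dq unavailable (radicand {radicand:.4g} < 0)"
    b = (v2 + v3 - 30.0 * dq) / 15.0
    return LigandFieldResult(
        dq=dq, ten_dq=10.0 * dq, b=b, beta=b / b0, b0=b0,
        config="d8_Ni", dq_source=source, notes=notes,
    )


def g_average(
    g_parallel: float, g_perpendicular: float,
    covalency_threshold: float = COVALENCY_THRESHOLD,
) -> EPRResult:
    """Isotropic g average (g_par + 2 g_perp)/3 with a covalency call.

    g_av below the threshold (default 2.3) marks a covalent metal-ligand
    bond; at or above it, ionic.
    """
    if g_parallel <= 0 or g_perpendicular <= 0:
        raise ValueError("g values must be positive")
    g_av = (g_parallel + 2.0 * g_perpendicular) / 3.0
    return EPRResult(
        g_parallel=g_parallel,
        g_perpendicular=g_perpendicular,
        g_average=g_av,
        covalency="covalent" if g_av < covalency_threshold else "ionic",
    )


def spin_only_moment(n_unpaired: int) -> float:
    """Spin-only magnetic moment sqrt(n(n+2)) in Bohr magnetons."""
    if not isinstance(n_unpaired, int) or n_unpaired < 0:
        raise ValueError("number of unpaired electrons must be a non-negative integer")
    return math.sqrt(n_unpaired * (n_unpaired + 2))
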
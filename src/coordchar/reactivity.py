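"""Conceptual-DFT global reactivity descriptors from frontier-orbital energies.

Within Koopmans' approximation the ionization energy and electron
affinity are -E_HOMO and -E_LUMO, giving

    Eg    = E_LUMO - E_HOMO          (gap, eV)
    mu    = (E_HOMO + E_LUMO) / 2    (chemical potential, eV)
    eta   = (E_LUMO - E_HOMO) / 2    (global hardness, eV)
    S     = 1 / (2 eta)              (softness, eV^-1)
    omega = mu^2 / (2 eta)           (electrophilicity index, eV)

A small gap (low eta, high S) marks a soft, polarizable, reactive
molecule; a negative mu marks spontaneous electron acceptance.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "FMOEnergies",
    "ReactivityDescriptors",
    "DegenerateGapError",
    "InvertedOrbitalError",
    "global_descriptors",
]


class DegenerateGapError(ValueError):
    """E_HOMO == E_LUMO: hardness vanishes and softness diverges."""


class InvertedOrbitalError(ValueError):
    """E_HOMO above E_LUMO: the two energies are almost certainly swapped."""


@dataclass(frozen=True)
class FMOEnergies:
    e_homo: float  # eV
    e_lumo: float  # eV
    label: str = ""

    def __post_init__(self) -> None:
        if self.e_lumo < self.e_homo:
            raise InvertedOrbitalError(
                f"E_LUMO ({self.e_lumo} eV) is below E_HOMO ({self.e_homo} eV); "
                "if these came from a table, swap them"
            )


@dataclass(frozen=True)
class ReactivityDescriptors:
    eg: float       # eV
    mu: float       # eV
    eta: float      # eV
    softness: float  # eV^-1
    omega: float    # eV
    label: str = ""


def global_descriptors(e: FMOEnergies) -> ReactivityDescriptors:
    """Compute the descriptor set (Eg, mu, eta, S, omega) from HOMO/LUMO."""
    if e.e_lumo == e.e_homo:
        raise DegenerateGapError("degenerate gap: softness is infinite")
    eg = e.e_lumo - e.e_homo
    mu = (e.e_homo + e.e_lumo) / 2.0
    eta = eg / 2.0
    return ReactivityDescriptors(
        eg=eg, mu=mu, eta=eta, softness=1.0 / (2.0 * eta),
        omega=mu * mu / (2.0 * eta), label=e.label,
    )
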
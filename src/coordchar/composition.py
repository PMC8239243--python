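"""Molecular-formula arithmetic.

Parsing of condensed molecular formulas, molar mass, elemental percent
composition (the CHN/metal analysis table of a synthesis paper), mass
accounting for thermogravimetric fragments and residues, and electrolyte
classification from molar conductance.

Hydrated solids are first-class: a formula may carry an ``·nH2O`` (or
``.nH2O``) suffix, and every mass operation takes an explicit *basis*
(``"anhydrous"`` or ``"hydrate"``) because published TGA tables routinely
quote water-loss steps on the hydrate mass and the residue on the
anhydrous mass.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .periodic import ATOMIC_WEIGHTS, WATER_MASS, atomic_weight

__all__ = [
    "Formula",
    "CompositionReport",
    "ConductanceClass",
    "FormulaError",
    "MassBalanceError",
    "parse_formula",
    "molecular_weight",
    "percent_composition",
    "fragment_loss_percent",
    "classify_electrolyte",
    "DEFAULT_CONDUCTANCE_CUTOFFS",
]

BASES = ("anhydrous", "hydrate")


class FormulaError(ValueError):
    """Malformed or chemically impossible formula string."""


class MassBalanceError(ValueError):
    """Fragment masses exceed what the parent formula can supply."""


@dataclass(frozen=True)
class Formula:
    """An element->count composition plus optional waters of crystallization.

    ``composition`` never contains the hydrate waters; they are carried
    separately in ``hydrate_waters`` so that either mass basis can be
    formed on demand.
    """

    composition: Mapping[str, int]
    hydrate_waters: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        comp = dict(self.composition)
        if not comp or all(n == 0 for n in comp.values()):
            raise FormulaError("formula must contain at least one atom")
        for sym, n in comp.items():
            if sym not in ATOMIC_WEIGHTS:
                raise FormulaError(f"unknown element symbol: {sym!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"count for {sym} must be a non-negative integer")
        if self.hydrate_waters < 0:
            raise FormulaError("hydrate_waters must be non-negative")
        object.__setattr__(self, "composition", dict(comp))

    def counts(self, basis: str = "anhydrous") -> dict[str, int]:
        """Element counts on the given basis (hydrate folds the waters in)."""
        _check_basis(basis)
        out = dict(self.composition)
        if basis == "hydrate" and self.hydrate_waters:
            out["H"] = out.get("H", 0) + 2 * self.hydrate_waters
            out["O"] = out.get("O", 0) + self.hydrate_waters
        return out

    def to_string(self) -> str:
        """Canonical Hill-order rendering (C, H, then alphabetical)."""
        comp = dict(self.composition)
        parts: list[str] = []
        order = [s for s in ("C", "H") if s in comp]
        order += sorted(s for s in comp if s not in ("C", "H"))
        for sym in order:
            n = comp[sym]
            if n == 0:
                continue
            parts.append(sym if n == 1 else f"{sym}{n}")
        s = "".join(parts)
        if self.hydrate_waters:
            s += f"·{self.hydrate_waters}H2O"
        return s

    def __mul__(self, k: int) -> "Formula":
        if not isinstance(k, int) or k <= 0:
            raise FormulaError("formula multiplier must be a positive integer")
        return Formula(
            {s: n * k for s, n in self.composition.items()},
            hydrate_waters=self.hydrate_waters * k,
            label=self.label,
        )

    __rmul__ = __mul__


@dataclass(frozen=True)
class CompositionReport:
    molecular_weight: float
    percent_by_element: Mapping[str, float]
    basis: str


@dataclass(frozen=True)
class ConductanceClass:
    lambda_m: float
    category: str


# Molar conductance cut-offs for ~1e-3 M solutions in DMF, in S cm^2 mol^-1.
# Bands between the electrolyte classes are reported as ambiguous rather
# than forced into a class.
DEFAULT_CONDUCTANCE_CUTOFFS = {
    "non_electrolyte_max": 20.0,
    "one_one_range": (60.0, 95.0),
    "two_one_min": 120.0,
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)|(\()|(\))|(\[)|(\])|(\d+)")
_HYDRATE = re.compile(r"[.··]\s*(\d*)\s*H2O\s*$")
_MAX_DEPTH = 3


def parse_formula(text: str, label: str = "") -> Formula:
    """Parse a condensed formula string into a :class:`Formula`.

    Accepts element symbols with optional integer multipliers, groups in
    ``()`` or ``[]`` nested to depth 3, and a trailing hydrate suffix
    written with either a middle dot or a period (``·2H2O`` / ``.2H2O``).

    >>> parse_formula("Cu(C10H9ClN4O2S)2Cl2").composition["C"]
    20
    """
    s = text.strip()
    if not s:
        raise FormulaError("empty formula string")

    hydrate_waters = 0
    m = _HYDRATE.search(s)
    if m:
        hydrate_waters = int(m.group(1) or 1)
        s = s[: m.start()].rstrip()
        if not s:
            raise FormulaError("formula consists only of a hydrate suffix")

    stack: list[dict[str, int]] = [{}]
    i = 0
    while i < len(s):
        ch = s[i]
        if ch in "([":
            if len(stack) > _MAX_DEPTH:
                raise FormulaError(f"groups nested deeper than {_MAX_DEPTH}: {text!r}")
            stack.append({})
            i += 1
        elif ch in ")]":
            if len(stack) == 1:
                raise FormulaError(f"unbalanced closing bracket in {text!r}")
            group = stack.pop()
            i += 1
            j = i
            while j < len(s) and s[j].isdigit():
                j += 1
            mult = int(s[i:j]) if j > i else 1
            if mult <= 0:
                raise FormulaError(f"non-positive group multiplier in {text!r}")
            i = j
            for sym, n in group.items():
                stack[-1][sym] = stack[-1].get(sym, 0) + n * mult
        else:
            m = re.match(r"([A-Z][a-z]?)(\d*)", s[i:])
            if not m:
                raise FormulaError(f"unexpected character {ch!r} at position {i} in {text!r}")
            sym, digits = m.group(1), m.group(2)
            if sym not in ATOMIC_WEIGHTS:
                # A two-letter match like "Cl" may shadow a valid one-letter
                # element followed by a lowercase typo; report the symbol seen.
                raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
            n = int(digits) if digits else 1
            if n <= 0:
                raise FormulaError(f"non-positive count for {sym} in {text!r}")
            stack[-1][sym] = stack[-1].get(sym, 0) + n
            i += m.end()
    if len(stack) != 1:
        raise FormulaError(f"unbalanced opening bracket in {text!r}")
    return Formula(stack[0], hydrate_waters=hydrate_waters, label=label or text.strip())


def _check_basis(basis: str) -> None:
    if basis not in BASES:
        raise ValueError(f"basis must be one of {BASES}, got {basis!r}")


def molecular_weight(f: Formula, basis: str = "anhydrous") -> float:
    """Molar mass in g/mol on the requested basis.

    The hydrate basis adds one water mass (18.015 g/mol with the embedded
    table) per water of crystallization.
    """
    _check_basis(basis)
    mw = sum(n * atomic_weight(sym) for sym, n in f.composition.items())
    if basis == "hydrate":
        mw += WATER_MASS * f.hydrate_waters
    return mw


def percent_composition(f: Formula, basis: str = "anhydrous") -> CompositionReport:
    """Mass percent of every element, on the requested basis.

    Percents are exact mass fractions times 100 and sum to 100 to within
    floating-point rounding.
    """
    _check_basis(basis)
    counts = f.counts(basis)
    mw = molecular_weight(f, basis)
    pct = {sym: 100.0 * n * atomic_weight(sym) / mw for sym, n in counts.items() if n > 0}
    return CompositionReport(molecular_weight=mw, percent_by_element=pct, basis=basis)


def fragment_loss_percent(
    parent: Formula, fragments: Iterable[Formula], basis: str = "anhydrous",
    strict: bool = True,
) -> float:
    """Percent of the parent mass carried away by *fragments*.

    This is the "calc" column of a TGA step table: 100 x (summed fragment
    mass) / (parent mass on *basis*). With ``strict`` (the default) the
    fragments' joint element counts must not exceed the parent's counts on
    that basis; ``strict=False`` skips that gate so published fragment
    assignments that do not balance atomically can still be priced.
    """
    _check_basis(basis)
    frags = list(fragments)
    if strict:
        total: dict[str, int] = {}
        for fr in frags:
            for sym, n in fr.counts("hydrate").items():
                total[sym] = total.get(sym, 0) + n
        parent_counts = parent.counts(basis)
        for sym, n in total.items():
            if n > parent_counts.get(sym, 0):
                raise MassBalanceError(
                    f"fragments need {n} x {sym} but parent supplies "
                    f"{parent_counts.get(sym, 0)} on {basis} basis"
                )
    frag_mass = sum(molecular_weight(fr, "hydrate") for fr in frags)
    return 100.0 * frag_mass / molecular_weight(parent, basis)


def classify_electrolyte(
    lambda_m: float, cutoffs: Mapping[str, object] | None = None
) -> ConductanceClass:
    """Classify a molar conductance value (S cm^2 mol^-1, ~1e-3 M in DMF).

    Values between the configured bands come back as ``"ambiguous"``
    rather than being forced into the nearer class.
    """
    if lambda_m < 0:
        raise ValueError(f"molar conductance must be non-negative, got {lambda_m}")
    c = dict(DEFAULT_CONDUCTANCE_CUTOFFS)
    if cutoffs:
        c.update(cutoffs)
    lo_11, hi_11 = c["one_one_range"]  # type: ignore[misc]
    if lambda_m < c["non_electrolyte_max"]:
        cat = "non-electrolyte"
    elif lo_11 <= lambda_m <= hi_11:
        cat = "1:1 electrolyte"
    elif lambda_m > c["two_one_min"]:
        cat = "2:1 electrolyte"
    else:
        cat = "ambiguous"
    return ConductanceClass(lambda_m=lambda_m, category=cat)
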
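"""MTT-plate reduction, IC50 interpolation, and potency classification.

An MTT viability plate reads formazan optical density at 560 nm with a
620 nm background well; survival at each dose is the background-corrected
treated OD as a percent of the control OD. The half-inhibitory
concentration IC50 is interpolated on log10(dose) between the two doses
bracketing 50% survival, then classified into the conventional potency
bands (ug/ml): 1-10 very strong, 11-20 strong, 21-50 moderate,
51-100 weak, >100 non-cytotoxic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PlateReadings",
    "DoseResponse",
    "IC50Result",
    "POTENCY_BANDS",
    "survival_fractions",
    "ic50_interpolate",
    "potency_class",
]

#: Upper edges (inclusive) of the IC50 potency bands, in ug/ml.
POTENCY_BANDS = (
    (10.0, "very strong"),
    (20.0, "strong"),
    (50.0, "moderate"),
    (100.0, "weak"),
    (math.inf, "non-cytotoxic"),
)


@dataclass(frozen=True)
class PlateReadings:
    doses: tuple[float, ...]          # ug/ml, strictly increasing
    od560_treated: tuple[float, ...]  # replicate-averaged, per dose
    od560_control: float
    od620_background: float = 0.0     # per-plate scalar background

    def __post_init__(self) -> None:
        d = tuple(float(v) for v in self.doses)
        od = tuple(float(v) for v in self.od560_treated)
        if len(d) != len(od) or len(d) < 2:
            raise ValueError("need matched dose/OD lists of length >= 2")
        if any(x <= 0 for x in d) or any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("doses must be positive and strictly increasing")
        if self.od560_control - self.od620_background <= 0:
            raise ValueError("background-corrected control OD must be positive")
        object.__setattr__(self, "doses", d)
        object.__setattr__(self, "od560_treated", od)


@dataclass(frozen=True)
class DoseResponse:
    doses: tuple[float, ...]
    survival: tuple[float, ...]  # percent; 100 = untreated control


@dataclass(frozen=True)
class IC50Result:
    ic50: float | None            # ug/ml; None when censored
    potency: str
    censored: str | None = None   # None | "> max dose" | "< min dose"
    bracket: tuple[float, float] | None = None


def survival_fractions(p: PlateReadings) -> DoseResponse:
    """Survival percent per dose: 100 x corrected treated OD / control OD."""
    ctrl = p.od560_control - p.od620_background
    surv = tuple(
        100.0 * max(od - p.od620_background, 0.0) / ctrl for od in p.od560_treated
    )
    return DoseResponse(doses=p.doses, survival=surv)


def ic50_interpolate(d: DoseResponse) -> IC50Result:
    """IC50 by log-dose linear interpolation at the first 50% crossing.

    If survival never crosses 50% the result is censored ("> max dose"
    when everything survives above 50%, "< min dose" otherwise) instead
    of raising. A non-monotone survival profile triggers a warning and
    the first crossing is used.
    """
    doses = np.asarray(d.doses, dtype=float)
    surv = np.asarray(d.survival, dtype=float)
    if np.any(np.diff(surv) > 0):
        warnings.warn("non-monotone survival profile; using first 50% crossing",
                      stacklevel=2)

    exact = np.isclose(surv, 50.0)
    for i in range(doses.size):
        if exact[i]:
            return IC50Result(
                ic50=float(doses[i]), potency=potency_class(float(doses[i])).potency,
                bracket=(float(doses[i]), float(doses[i])),
            )
        if i > 0 and (surv[i - 1] - 50.0) * (surv[i] - 50.0) < 0:
            lo_d, hi_d = doses[i - 1], doses[i]
            lo_s, hi_s = surv[i - 1], surv[i]
            frac = (lo_s - 50.0) / (lo_s - hi_s)
            log_ic50 = math.log10(lo_d) + frac * (math.log10(hi_d) - math.log10(lo_d))
            ic50 = 10.0 ** log_ic50
            return IC50Result(
                ic50=float(ic50), potency=potency_class(float(ic50)).potency,
                bracket=(float(lo_d), float(hi_d)),
            )
    if surv.min() > 50.0:
        pot = "non-cytotoxic" if doses.max() >= 100.0 else "indeterminate"
        return IC50Result(ic50=None, potency=pot, censored="> max dose")
    return IC50Result(ic50=None, potency="indeterminate", censored="< min dose")


def potency_class(ic50: float) -> IC50Result:
    """Classify a (finite, positive) IC50 into the standard potency bands."""
    if ic50 <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50}")
    for upper, name in POTENCY_BANDS:
        if ic50 <= upper:
            return IC50Result(ic50=ic50, potency=name)
    raise AssertionError("unreachable")
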
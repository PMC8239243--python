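"""CSV/JSON readers and writers for the characterization pipeline.

All tabular interchange is plain UTF-8 CSV with a header row; parameters
and fit results travel as JSON. Readers validate eagerly and report the
offending row number and column name.

Schemas
-------
titration.csv      metal_conc_M, ligand_conc_M, absorbance
dna_titration.csv  dna_conc_M, epsilon_apparent  (or absorbance + compound_conc_M)
tga.csv            temp_C, mass_pct
plate.csv          dose_ug_ml, od560 [, od620_bg]
bands.json         {config, v2_cm | bands_nm: [..], v3_cm, ten_Dq?}
fmo.json           {label, E_HOMO_eV, E_LUMO_eV}
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd

from .cytotox import PlateReadings
from .ligand_field import to_wavenumber
from .thermal import TGACurve
from .titration import DNATitration, TitrationSeries

__all__ = [
    "SchemaError",
    "read_titration_csv",
    "read_dna_csv",
    "read_tga_csv",
    "read_plate_csv",
    "read_bands_json",
    "read_fmo_json",
    "write_json",
]


class SchemaError(ValueError):
    """Input file does not match its documented schema."""


def _require_columns(df: pd.DataFrame, cols: list[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _check_positive(df: pd.DataFrame, col: str, path: str | Path) -> None:
    bad = df.index[df[col] <= 0]
    if len(bad):
        # +2: one for the header line, one for 0- vs 1-based indexing
        raise SchemaError(
            f"{path}: non-positive {col} at line {int(bad[0]) + 2}"
        )


def _read_csv(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # surface pandas' message with the path attached
        raise SchemaError(f"{path}: {exc}") from exc
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    return df


def read_titration_csv(path: str | Path) -> TitrationSeries:
    df = _read_csv(path)
    _require_columns(df, ["metal_conc_M", "ligand_conc_M", "absorbance"], path)
    _check_positive(df, "metal_conc_M", path)
    _check_positive(df, "ligand_conc_M", path)
    c_m = df["metal_conc_M"].unique()
    if len(c_m) != 1:
        raise SchemaError(f"{path}: metal_conc_M must be constant across the series")
    return TitrationSeries(
        metal_conc=float(c_m[0]),
        ligand_concs=tuple(df["ligand_conc_M"]),
        absorbances=tuple(df["absorbance"]),
    )


def read_dna_csv(
    path: str | Path, epsilon_free: float, compound_conc: float | None = None
) -> DNATitration:
    df = _read_csv(path)
    _require_columns(df, ["dna_conc_M"], path)
    _check_positive(df, "dna_conc_M", path)
    if "epsilon_apparent" in df.columns:
        eps_a = df["epsilon_apparent"]
    elif "absorbance" in df.columns:
        if not compound_conc or compound_conc <= 0:
            raise SchemaError(
                f"{path}: absorbance column requires a positive compound_conc_M"
            )
        eps_a = df["absorbance"] / compound_conc
    else:
        raise SchemaError(f"{path}: need an epsilon_apparent or absorbance column")
    return DNATitration(
        dna_concs=tuple(df["dna_conc_M"]),
        epsilon_apparent=tuple(eps_a),
        epsilon_free=epsilon_free,
        compound_conc=compound_conc,
    )


def read_tga_csv(path: str | Path, heating_rate: float = 10.0) -> TGACurve:
    df = _read_csv(path)
    _require_columns(df, ["temp_C", "mass_pct"], path)
    t = df["temp_C"].to_numpy()
    dup = (t[1:] <= t[:-1]).nonzero()[0]
    if len(dup):
        raise SchemaError(
            f"{path}: temp_C not strictly increasing at line {int(dup[0]) + 3}"
        )
    return TGACurve(
        temperature_c=tuple(t),
        mass_percent=tuple(df["mass_pct"]),
        heating_rate=heating_rate,
    )


def read_plate_csv(path: str | Path, control_od: float | None = None) -> PlateReadings:
    """Read an MTT plate table.

    Control OD comes either from a ``dose_ug_ml == 0`` row or from the
    ``control_od`` argument; od620_bg, when present, must be a per-plate
    constant and is applied as the scalar background.
    """
    df = _read_csv(path)
    _require_columns(df, ["dose_ug_ml", "od560"], path)
    bg = 0.0
    if "od620_bg" in df.columns:
        vals = df["od620_bg"].unique()
        if len(vals) != 1:
            raise SchemaError(f"{path}: od620_bg must be a per-plate constant")
        bg = float(vals[0])
    ctrl_rows = df[df["dose_ug_ml"] == 0]
    if len(ctrl_rows):
        control_od = float(ctrl_rows["od560"].mean())
        df = df[df["dose_ug_ml"] > 0]
    if control_od is None:
        raise SchemaError(f"{path}: no dose-0 control row and no control_od given")
    if "replicate" in df.columns:
        df = df.groupby("dose_ug_ml", as_index=False)["od560"].mean()
    df = df.sort_values("dose_ug_ml")
    return PlateReadings(
        doses=tuple(df["dose_ug_ml"]),
        od560_treated=tuple(df["od560"]),
        od560_control=control_od,
        od620_background=bg,
    )


def read_bands_json(path: str | Path) -> dict[str, Any]:
    """Read a band-set parameter file into wavenumbers.

    Accepts either ``v2_cm``/``v3_cm`` directly or ``bands_nm`` (two
    wavelengths, converted and sorted so v2 < v3), plus ``config`` and an
    optional ``ten_Dq``.
    """
    with open(path) as fh:
        raw = json.load(fh)
    if "config" not in raw:
        raise SchemaError(f"{path}: missing 'config'")
    if "bands_nm" in raw:
        wn = sorted(to_wavenumber(w) for w in raw["bands_nm"])
        if len(wn) != 2:
            raise SchemaError(f"{path}: bands_nm must list exactly two wavelengths")
        v2, v3 = wn
    elif "v2_cm" in raw and "v3_cm" in raw:
        v2, v3 = float(raw["v2_cm"]), float(raw["v3_cm"])
    else:
        raise SchemaError(f"{path}: need bands_nm or v2_cm/v3_cm")
    return {"config": raw["config"], "v2": v2, "v3": v3,
            "ten_dq": raw.get("ten_Dq")}


def read_fmo_json(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        raw = json.load(fh)
    for key in ("E_HOMO_eV", "E_LUMO_eV"):
        if key not in raw:
            raise SchemaError(f"{path}: missing '{key}'")
    return {"label": raw.get("label", ""), "e_homo": float(raw["E_HOMO_eV"]),
            "e_lumo": float(raw["E_LUMO_eV"])}


def write_json(obj: Any, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
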
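"""Raw instrument readouts -> functional quantities.

Three conversions:

* MicroResp-style CO2 indicator plates: the change in absorbance at 572 nm
  (after subtracting a negative control exposed only to atmospheric CO2)
  maps to the mass of CO2 respired through a log-linear calibration,
  ``mg CO2 = exp((ln dA + 0.305414) / 0.282164)``.
* Per-capita respiration: the daily CO2 rate divided by the total cell
  count (flow cytometry density x culture volume), reported in
  pg CO2 cell^-1 day^-1.
* Fluorogenic enzyme assays: raw 4-methylumbelliferone (MUB) fluorescence
  is normalized across the data set so each enzyme's dataset-wide mean
  equals the grand mean (value x grand_mean / enzyme_mean), removing
  enzyme-specific fluorescence yield before conversion to nM MUB h^-1.
  The normalization redistributes signal between enzymes; it preserves
  the grand mean exactly.

Records that cannot be converted (non-positive corrected absorbance, zero
cells, missing controls) are flagged and kept as missing values rather
than dropped, so downstream joins stay aligned.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

UG_PER_MG = 1_000.0
PG_PER_UG = 1_000_000.0

#: assay labels used in the long measurement table
ASSAY_DLAMBDA = "dlambda572"
ASSAY_CELLS = "cells_per_ml"
FLUOR_PREFIX = "fluor:"
TRF_PREFIX = "trf:"

CONTROL_ID = "NEG_CONTROL"


class AssayError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationModel:
    """Log-linear absorbance->CO2 mass calibration.

    ``mass_mg = exp((ln(dlambda) + intercept) / slope)``; the default
    constants are the MicroResp indicator calibration (R^2 = 0.936).
    """

    intercept: float = 0.305414
    slope: float = 0.282164
    note: str = "MicroResp indicator calibration, R^2=0.936"

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise AssayError("calibration slope must be nonzero")

    def co2_mass_mg(self, dlambda: float | np.ndarray) -> float | np.ndarray:
        """mg CO2 from a (control-corrected) absorbance change."""
        return np.exp((np.log(dlambda) + self.intercept) / self.slope)

    def dlambda_from_mass(self, mass_mg: float | np.ndarray) -> float | np.ndarray:
        """Inverse mapping; used by the simulator's observation model."""
        return np.exp(self.slope * np.log(mass_mg) - self.intercept)


def co2_from_absorbance(
    dlambda: float,
    control_dlambda: float,
    interval_days: float,
    calibration: CalibrationModel | None = None,
) -> tuple[float, float, bool]:
    """Return (mass_mg, rate_ug_per_day, flagged).

    The negative-control absorbance change is subtracted first; if the
    corrected value is not positive the record is flagged and both outputs
    are NaN (never a silent zero or negative mass).
    """
    if interval_days <= 0:
        raise AssayError("interval_days must be positive")
    cal = calibration or CalibrationModel()
    corrected = dlambda - control_dlambda
    if not np.isfinite(corrected) or corrected <= 0:
        return float("nan"), float("nan"), True
    mass = float(cal.co2_mass_mg(corrected))
    return mass, mass * UG_PER_MG / interval_days, False


def per_capita_respiration(
    co2_rate_ug_day: float, cells_per_ml: float, volume_ml: float
) -> tuple[float, bool]:
    """pg CO2 cell^-1 day^-1; flagged (NaN) when no cells were counted."""
    total_cells = cells_per_ml * volume_ml
    if not np.isfinite(total_cells) or total_cells <= 0:
        return float("nan"), True
    return co2_rate_ug_day * PG_PER_UG / total_cells, False


def normalize_fluorescence(
    raw: pd.DataFrame,
    value_col: str = "value",
    enzyme_col: str = "enzyme",
    nm_mub_per_unit: float = 1.0,
) -> pd.DataFrame:
    """Equalize enzyme-specific fluorescence scales across the data set.

    Each reading is multiplied by grand_mean / enzyme_mean, then by a
    configurable linear factor to nM MUB h^-1 (default 1.0: no standard
    curve supplied).  After normalization every enzyme's dataset-wide mean
    equals the raw grand mean.
    """
    if raw.empty:
        raise AssayError("no fluorescence records to normalize")
    counts = raw.groupby(enzyme_col)[value_col].count()
    empty = counts[counts == 0]
    if not empty.empty:
        raise AssayError(f"enzyme group(s) with no values: {list(empty.index)}")
    grand = raw[value_col].mean()
    if grand == 0:
        raise AssayError("grand mean of fluorescence is zero")
    means = raw.groupby(enzyme_col)[value_col].transform("mean")
    if (means == 0).any():
        bad = sorted(raw.loc[means == 0, enzyme_col].unique())
        raise AssayError(f"enzyme group(s) with zero mean: {bad}")
    out = raw.copy()
    out[value_col] = raw[value_col] * grand / means * nm_mub_per_unit
    return out


def functioning_table(
    measurements: pd.DataFrame,
    sample_days: list[int] | None = None,
    calibration: CalibrationModel | None = None,
    volume_ml: float = 0.88,
    control_id: str = CONTROL_ID,
    nm_mub_per_unit: float = 1.0,
) -> pd.DataFrame:
    """Build the per-microcosm functioning table from long measurements.

    Input columns: microcosm_id, day, assay, value.  Sampling intervals are
    day minus the previous sample day (the first interval starts at
    inoculation, day 0).  Output: one row per microcosm x day with CO2
    mass/rate, cell counts, per-capita respiration and normalized enzyme
    activities, plus a ``flag`` column naming any conversion problem.
    """
    cal = calibration or CalibrationModel()
    days = sorted(sample_days or measurements["day"].unique())
    prev = {d: p for d, p in zip(days, [0] + days[:-1])}

    ctrl = measurements[
        (measurements["microcosm_id"] == control_id)
        & (measurements["assay"] == ASSAY_DLAMBDA)
    ]
    control_by_day = ctrl.groupby("day")["value"].mean().to_dict()

    samples = measurements[measurements["microcosm_id"] != control_id]
    fluor = samples[samples["assay"].str.startswith(FLUOR_PREFIX)].copy()
    if not fluor.empty:
        fluor["enzyme"] = fluor["assay"].str.removeprefix(FLUOR_PREFIX)
        fluor = normalize_fluorescence(
            fluor, nm_mub_per_unit=nm_mub_per_unit
        )
    rows = []
    wide = samples[samples["assay"].isin([ASSAY_DLAMBDA, ASSAY_CELLS])]
    for (mid, day), grp in wide.groupby(["microcosm_id", "day"], sort=True):
        vals = dict(zip(grp["assay"], grp["value"]))
        flags: list[str] = []
        if day not in control_by_day:
            flags.append("missing_control")
            mass, rate = float("nan"), float("nan")
        else:
            mass, rate, bad = co2_from_absorbance(
                vals.get(ASSAY_DLAMBDA, float("nan")),
                control_by_day[day],
                interval_days=day - prev.get(day, 0),
                calibration=cal,
            )
            if bad:
                flags.append("nonpositive_corrected_dlambda")
        cells = vals.get(ASSAY_CELLS, float("nan"))
        percap, bad_cells = per_capita_respiration(rate, cells, volume_ml)
        if bad_cells:
            flags.append("no_cells")
        row = {
            "microcosm_id": mid,
            "day": day,
            "co2_mass_mg": mass,
            "co2_rate_ug_day": rate,
            "cells_per_ml": cells,
            "per_capita_pg_cell_day": percap,
            "flag": ";".join(flags),
        }
        rows.append(row)
    out = pd.DataFrame(rows)
    if not fluor.empty:
        act = (
            fluor.pivot_table(
                index=["microcosm_id", "day"],
                columns="enzyme",
                values="value",
            )
            .add_prefix("activity_")
            .reset_index()
        )
        out = out.merge(act, on=["microcosm_id", "day"], how="left")
    return out
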
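"""Cell-viability endpoints, well exclusions, and the overall viability BMC.

Two well-level endpoints are computed from cell-level viability data:

* normalized cell count — valid nuclei divided by the per-plate median of
  vehicle-control valid nuclei, x 100;
* percent PI-positive — PI-positive cells over valid nuclei, x 100.

Vehicle wells below 50% normalized count and treated wells with fewer than 50
valid nuclei are excluded (single pass; the vehicle median is not
recomputed).  Per chemical, the centered count response (count - 100) is fit
with {constant, hill} and the EC50 (the fitted gain AC50) is its BMC; the
centered cytotoxicity response is fit with {constant, hill, gain-loss} at a
benchmark response of 3 x the vehicle nMAD.  The overall viability BMC is the
lower of the two, the LOEC is the lowest tested concentration strictly above
it, and only concentrations at or below the LOEC are retained for phenotypic
profiling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .curvefit import (
    NOT_CALCULABLE,
    BMCResult,
    BMCStatus,
    CRFit,
    CV_COUNT_MODELS,
    CV_CYTO_MODELS,
    fit_family,
    invert_bmc,
    nmad,
    select_model,
)
from .design import PlateLayout, Role

MIN_VALID_NUCLEI = 50
MIN_VEHICLE_NORMALIZED = 50.0


class PlateQCError(RuntimeError):
    """A plate cannot be analyzed (e.g. every vehicle well failed QC)."""


def well_endpoints(cells: pd.DataFrame, layout: PlateLayout) -> pd.DataFrame:
    """Per-well viability endpoints for one plate.

    The layout defines the well universe, so wells whose cells were entirely
    lost still appear (with zero counts and a no-valid-nuclei exclusion).
    Normalization uses the median vehicle valid-nucleus count of this plate.
    """
    cells = cells[cells["plate_id"] == layout.plate_id]
    valid = cells[cells["valid"]]
    n_valid = valid.groupby("well").size()
    n_pi = valid.groupby("well")["pi_positive"].sum()

    rows = []
    for well, a in layout.assignments.items():
        v = int(n_valid.get(well, 0))
        p = int(n_pi.get(well, 0))
        rows.append({
            "plate_id": layout.plate_id, "well": well,
            "chemical_id": a.chemical_id, "concentration_uM": a.concentration_uM,
            "role": a.role.value, "valid_nuclei": v, "pi_positive": p,
        })
    df = pd.DataFrame(rows)
    veh = df[df["role"] == Role.VEHICLE.value]
    if veh.empty:
        raise PlateQCError(f"plate {layout.plate_id}: no vehicle wells in layout")
    veh_median = float(veh["valid_nuclei"].median())
    if veh_median <= 0:
        raise PlateQCError(f"plate {layout.plate_id}: vehicle wells have no valid nuclei")
    df["normalized_cell_count"] = 100.0 * df["valid_nuclei"] / veh_median
    with np.errstate(divide="ignore", invalid="ignore"):
        df["pct_pi_positive"] = np.where(
            df["valid_nuclei"] > 0, 100.0 * df["pi_positive"] / df["valid_nuclei"], np.nan
        )
    df["excluded"] = df["valid_nuclei"] == 0
    df["exclusion_reason"] = np.where(df["excluded"], "no-valid-nuclei", "")
    return df


def apply_exclusions(wells: pd.DataFrame) -> pd.DataFrame:
    """Flag QC-failing wells: vehicle < 50% normalized count, treated < 50 nuclei.

    Single pass — the vehicle median used for normalization is deliberately
    not recomputed after exclusion.  Raises ``PlateQCError`` if a plate loses
    every vehicle well.
    """
    df = wells.copy()
    is_vehicle = df["role"] == Role.VEHICLE.value
    low_vehicle = is_vehicle & (df["normalized_cell_count"] < MIN_VEHICLE_NORMALIZED)
    low_treated = ~is_vehicle & (df["valid_nuclei"] < MIN_VALID_NUCLEI)
    for mask, reason in ((low_vehicle, "vehicle-count-below-50pct"),
                         (low_treated, "fewer-than-50-valid-nuclei")):
        fresh = mask & ~df["excluded"]
        df.loc[fresh, "exclusion_reason"] = reason
        df.loc[fresh, "excluded"] = True
    for plate, sub in df[is_vehicle].groupby("plate_id"):
        if sub["excluded"].all():
            raise PlateQCError(f"plate {plate}: all vehicle wells excluded")
    return df


def viability_table(cells: pd.DataFrame, layouts: Sequence[PlateLayout]) -> pd.DataFrame:
    """Endpoints plus exclusions for every plate of a study."""
    parts = [well_endpoints(cells, lay) for lay in layouts]
    return apply_exclusions(pd.concat(parts, ignore_index=True))


@dataclass
class ViabilitySummary:
    """Per-chemical viability outcome."""

    chemical_id: str
    count_fit: CRFit | None
    cyto_fit: CRFit | None
    count_bmc: BMCResult
    cyto_bmc: BMCResult
    overall_cv_bmc: BMCResult
    loec_uM: float | None
    tested_concentrations: tuple[float, ...]
    retained_concentrations: tuple[float, ...]

    @property
    def top_tested(self) -> float:
        return max(self.tested_concentrations)

    def to_dict(self) -> dict:
        return {
            "chemical_id": self.chemical_id,
            "count_fit": self.count_fit.to_dict() if self.count_fit else None,
            "cyto_fit": self.cyto_fit.to_dict() if self.cyto_fit else None,
            "count_bmc": self.count_bmc.to_dict(),
            "cyto_bmc": self.cyto_bmc.to_dict(),
            "overall_cv_bmc": self.overall_cv_bmc.to_dict(),
            "loec_uM": self.loec_uM,
            "tested_concentrations": list(self.tested_concentrations),
            "retained_concentrations": list(self.retained_concentrations),
        }


def _count_bmc(fit: CRFit, top: float, min_tested: float, loss_gate: float) -> BMCResult:
    """EC50-as-BMC for the normalized cell count: the fitted gain AC50.

    The EC50 is only reported as a viability BMC when the selected hill
    describes a cell-count *loss* whose asymptote exceeds ``loss_gate``
    (3 x the vehicle normalized-count nMAD): an AIC-preferred hill whose
    top sits inside vehicle noise, or points upward, is not evidence of
    reduced viability and is censored.
    """
    if fit.model != "hill":
        return BMCResult(None, np.nan, BMCStatus.ABOVE_TOP_CENSORED, "down")
    ga, tp = fit.params["ga"], fit.params["tp"]
    direction = "up" if tp > 0 else "down"
    if ga > top or tp >= 0 or abs(tp) < loss_gate:
        return BMCResult(None, tp / 2, BMCStatus.ABOVE_TOP_CENSORED, direction)
    return BMCResult(float(ga), tp / 2, BMCStatus.ESTIMATED, direction, bool(ga < min_tested))


def cv_concentration_response(
    chemical_wells: pd.DataFrame,
    vehicle_wells: pd.DataFrame,
    chemical_id: str | None = None,
) -> ViabilitySummary:
    """Fit viability endpoints for one chemical and derive BMC, LOEC, retained set.

    ``chemical_wells`` are that chemical's rows of the study viability table
    (all plates; wells are the fitting units); ``vehicle_wells`` are the
    study's vehicle rows, pooled across plates for the cytotoxicity baseline
    and benchmark response.  When the overall BMC is censored the LOEC is
    undefined and every tested concentration is retained.
    """
    if chemical_id is None:
        chemical_id = str(chemical_wells["chemical_id"].iloc[0])
    tested = tuple(sorted(chemical_wells["concentration_uM"].unique()))
    top = max(tested)
    lo = min(tested)

    cw = chemical_wells[~chemical_wells["excluded"]]
    veh = vehicle_wells[~vehicle_wells["excluded"]]
    if cw["concentration_uM"].nunique() < 2:
        return ViabilitySummary(chemical_id, None, None, NOT_CALCULABLE, NOT_CALCULABLE,
                                NOT_CALCULABLE, None, tested, tested)

    conc = cw["concentration_uM"].to_numpy(float)
    count_resp = cw["normalized_cell_count"].to_numpy(float) - 100.0
    count_fit = select_model(fit_family(conc, count_resp, CV_COUNT_MODELS))
    count_gate = 3.0 * float(nmad(veh["normalized_cell_count"].to_numpy(float)))
    count_bmc = _count_bmc(count_fit, top, lo, count_gate)

    pi_base = float(veh["pct_pi_positive"].median())
    pi_bmr = 3.0 * float(nmad(veh["pct_pi_positive"].to_numpy(float)))
    has_pi = cw["pct_pi_positive"].notna()
    cyto_fit = None
    cyto_bmc = NOT_CALCULABLE
    if has_pi.sum() >= 2 and cw.loc[has_pi, "concentration_uM"].nunique() >= 2 and pi_bmr > 0:
        cyto_resp = cw.loc[has_pi, "pct_pi_positive"].to_numpy(float) - pi_base
        cyto_conc = cw.loc[has_pi, "concentration_uM"].to_numpy(float)
        cyto_fit = select_model(fit_family(cyto_conc, cyto_resp, CV_CYTO_MODELS))
        cyto_bmc = invert_bmc(cyto_fit, pi_bmr, top, min_tested=lo)

    candidates = [r for r in (count_bmc, cyto_bmc) if r.is_estimated]
    if candidates:
        overall = min(candidates, key=lambda r: r.bmc_uM)
    elif count_bmc.status is BMCStatus.NOT_CALCULABLE and cyto_bmc.status is BMCStatus.NOT_CALCULABLE:
        overall = NOT_CALCULABLE
    else:
        overall = BMCResult(None, np.nan, BMCStatus.ABOVE_TOP_CENSORED, "down")

    loec = None
    if overall.is_estimated:
        above = [c for c in tested if c > overall.bmc_uM]
        loec = min(above) if above else None
    retained = tuple(c for c in tested if c <= loec) if loec is not None else tested
    return ViabilitySummary(chemical_id, count_fit, cyto_fit, count_bmc, cyto_bmc,
                            overall, loec, tested, retained)
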
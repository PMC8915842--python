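"""Per-chemical assembly: viability-to-profiling BMC ratios and reference selection.

The viability:profiling BMC ratio measures how far below the cytotoxic range
a chemical's phenotype emerges — a large ratio means the phenotypic response
is unlikely to be an artifact of dying cells.  The ratio is defined only
when both BMCs were estimated; a censored (">top") or not-calculable input
propagates as "—".  Reference-chemical selection requires an estimated
phenotypic BMC together with either a large ratio or no cytotoxicity in the
tested range.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import pandas as pd

from .curvefit import BMCResult, BMCStatus


def bmc_ratio(cv: BMCResult, pp: BMCResult) -> float | None:
    """Cell-viability BMC over phenotypic-profiling BMC; None when not calculable."""
    if not (cv.is_estimated and pp.is_estimated):
        return None
    if pp.bmc_uM == 0:
        raise ValueError("phenotypic BMC of zero is not a valid concentration")
    return cv.bmc_uM / pp.bmc_uM


def format_ratio(ratio: float | None) -> str:
    """Display convention: one decimal with thousands separators, or an em dash."""
    return "—" if ratio is None else f"{ratio:,.1f}"


@dataclass
class ChemicalReport:
    """Final per-chemical verdict."""

    chemical_id: str
    cv_bmc: BMCResult
    pp_bmc: BMCResult
    ratio: float | None
    loec_uM: float | None
    top_tested: float
    selected: bool = False
    rationale: str = ""

    def row(self) -> dict:
        return {
            "chemical_id": self.chemical_id,
            "cv_bmc": self.cv_bmc.display(self.top_tested),
            "pp_bmc": self.pp_bmc.display(self.top_tested),
            "ratio": format_ratio(self.ratio),
            "loec_uM": self.loec_uM,
            "selected": self.selected,
            "rationale": self.rationale,
        }


def build_report(
    chemical_id: str,
    cv_bmc: BMCResult,
    pp_bmc: BMCResult,
    top_tested: float,
    loec_uM: float | None = None,
) -> ChemicalReport:
    return ChemicalReport(chemical_id, cv_bmc, pp_bmc, bmc_ratio(cv_bmc, pp_bmc),
                          loec_uM, top_tested)


def select_references(
    reports: list[ChemicalReport],
    min_ratio: float = 5.0,
    require_estimated_pp: bool = True,
) -> list[ChemicalReport]:
    """Apply the reference-chemical criteria, annotating each verdict in place.

    A chemical qualifies when its phenotypic BMC was estimated and either the
    viability:profiling ratio reaches ``min_ratio`` or viability was censored
    (no cytotoxicity within the tested range).  Returns the selected subset.
    """
    selected = []
    for r in reports:
        pp_ok = r.pp_bmc.is_estimated or not require_estimated_pp
        if not pp_ok:
            r.selected = False
            r.rationale = ("no phenotypic response below the cytotoxic range"
                           if r.pp_bmc.status is BMCStatus.NOT_CALCULABLE
                           else "no phenotypic response within tested range")
            continue
        if r.cv_bmc.status is BMCStatus.ABOVE_TOP_CENSORED:
            r.selected = True
            r.rationale = "phenotype altered with no cytotoxicity in tested range"
        elif r.ratio is not None and r.ratio >= min_ratio:
            r.selected = True
            r.rationale = (f"viability:profiling BMC ratio {r.ratio:,.1f} "
                           f">= {min_ratio:g}")
        else:
            r.selected = False
            r.rationale = ("phenotype emerges too close to cytotoxicity "
                           f"(ratio {format_ratio(r.ratio)} < {min_ratio:g})")
        if r.selected:
            selected.append(r)
    return selected


def report_table(reports: list[ChemicalReport]) -> pd.DataFrame:
    return pd.DataFrame([r.row() for r in reports])


# ---------------------------------------------------------------------------
# published reference ledgers (shipped as package data; used for regression
# checks of the dose-series and ratio conventions)

def _read_data(name: str) -> pd.DataFrame:
    with importlib.resources.files("htpp.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def reference_chemicals() -> pd.DataFrame:
    """Published screening roster: chemical, group, tested min/max (µM)."""
    return _read_data("reference_chemicals.csv")


def reference_bmcs() -> pd.DataFrame:
    """Published benchmark concentrations and ratios (as printed, incl. censoring)."""
    return _read_data("reference_bmcs.csv")


def parse_printed_bmc(text: str) -> BMCResult:
    """Parse a printed BMC cell: a number, '>top', or an em dash."""
    s = str(text).strip()
    if s in ("—", "-", ""):
        return BMCResult(None, float("nan"), BMCStatus.NOT_CALCULABLE, "up")
    if s.startswith(">"):
        return BMCResult(None, float("nan"), BMCStatus.ABOVE_TOP_CENSORED, "up")
    return BMCResult(float(s.replace(" ", "")), float("nan"), BMCStatus.ESTIMATED, "up")
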
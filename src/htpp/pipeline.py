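"""End-to-end screen analysis: cells in, per-chemical reports out.

Ties the stages together in the order the assay design dictates: well-level
viability endpoints and QC exclusions, per-chemical viability
concentration-response (overall BMC, LOEC, retained concentrations),
two-stage feature normalization and well aggregation, the study-level
Mahalanobis profiler, and finally the viability:profiling ratio and
reference-selection verdicts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .curvefit import BMCResult, nmad
from .design import PlateLayout, Role, small_screen_layout
from .profiling import (
    GlobalProfiler,
    GlobalProfileResult,
    aggregate_wells,
    feature_level_cr,
    normalize_cells,
)
from .report import ChemicalReport, build_report, report_table, select_references
from .simulate import ChemicalTruth, FeatureTaxonomy, SimConfig, generate_study, pick_affected_features
from .viability import ViabilitySummary, cv_concentration_response, viability_table


@dataclass
class ScreenResult:
    """Everything the analysis computed for one study."""

    wells: pd.DataFrame  # viability endpoints + exclusion flags
    viability: dict[str, ViabilitySummary]
    profiles: pd.DataFrame  # well-level scaled feature table
    dropped_features: list[str]
    profiler: GlobalProfiler
    global_results: dict[str, GlobalProfileResult]
    feature_results: dict[str, dict[str, BMCResult]]
    reports: list[ChemicalReport]
    selected: list[ChemicalReport]

    @property
    def table(self) -> pd.DataFrame:
        return report_table(self.reports)


def run_screen(
    cells: pd.DataFrame,
    layouts: Sequence[PlateLayout],
    min_ratio: float = 5.0,
    feature_level: bool = False,
    var_explained: float = 0.95,
) -> ScreenResult:
    """Analyze a full study from the cell level up.

    ``feature_level`` additionally fits all 9 models per feature per chemical
    (the slowest stage; off by default — the global Mahalanobis BMC is what
    drives reporting).
    """
    wells = viability_table(cells, layouts)
    chemicals = sorted(
        c for c in wells.loc[wells["role"] != Role.VEHICLE.value, "chemical_id"].unique())
    vehicle_wells = wells[wells["role"] == Role.VEHICLE.value]
    viability: dict[str, ViabilitySummary] = {}
    for chem in chemicals:
        cw = wells[wells["chemical_id"] == chem]
        viability[chem] = cv_concentration_response(cw, vehicle_wells, chem)

    normalized, dropped1 = normalize_cells(cells)
    excluded = [tuple(t) for t in wells.loc[wells["excluded"], ["plate_id", "well"]]
                .itertuples(index=False)]
    profiles, dropped2 = aggregate_wells(normalized, excluded)

    # keep vehicle wells plus each chemical's viability-retained concentrations
    keep = profiles["role"] == Role.VEHICLE.value
    for chem, summ in viability.items():
        keep |= (profiles["chemical_id"] == chem) & \
            profiles["concentration_uM"].isin(summ.retained_concentrations)
    retained_profiles = profiles[keep].reset_index(drop=True)

    profiler = GlobalProfiler(var_explained=var_explained).fit(retained_profiles)
    global_results = {
        chem: profiler.chemical_result(chem, viability[chem].retained_concentrations)
        for chem in chemicals
    }
    feature_results = {}
    if feature_level:
        feature_results = {
            chem: feature_level_cr(retained_profiles, chem,
                                   viability[chem].retained_concentrations)
            for chem in chemicals
        }

    reports = [
        build_report(chem, viability[chem].overall_cv_bmc, global_results[chem].pp_bmc,
                     viability[chem].top_tested, viability[chem].loec_uM)
        for chem in chemicals
    ]
    selected = select_references(reports, min_ratio=min_ratio)
    return ScreenResult(wells, viability, profiles, dropped1 + dropped2, profiler,
                        global_results, feature_results, reports, selected)


# ---------------------------------------------------------------------------
# a compact simulated screen exercising the full analysis path

def demo_roster(
    n_features: int = 200,
    affected_per_chemical: int = 20,
    seed: int = 11,
) -> tuple[list[tuple[str, str, float]], dict[str, ChemicalTruth]]:
    """Reduced reference-like roster: 5 test chemicals spanning the archetypes
    (profile-only, profile + cytotoxicity at various potencies, weak profile),
    2 negative controls, and 1 cytotoxic viability control.
    """
    tax = FeatureTaxonomy.default(n_features)
    pick = lambda ch, k: pick_affected_features(tax, ch, affected_per_chemical, seed + k)
    roster = [
        ("dna_blocker", "test", 10.0),
        ("mito_toxicant", "test", 100.0),
        ("er_stressor", "test", 10.0),
        ("weak_modulator", "test", 100.0),
        ("rna_toxicant", "test", 10.0),
        ("negative_a", "negative", 100.0),
        ("negative_b", "negative", 100.0),
        ("viability_positive", "viability_control", 10.0),
    ]
    truths = {
        "dna_blocker": ChemicalTruth(
            "dna_blocker", pick("DNA", 0), effect_size=3.0, true_bmc_uM=0.05),
        "mito_toxicant": ChemicalTruth(
            "mito_toxicant", pick("Mito", 1), effect_size=2.5, true_bmc_uM=1.0,
            cytotox_ec50_uM=40.0, pi_gain_ec50_uM=40.0),
        "er_stressor": ChemicalTruth(
            "er_stressor", pick("ER", 2), effect_size=2.0, true_bmc_uM=0.3,
            cytotox_ec50_uM=6.0, pi_gain_ec50_uM=6.0),
        "weak_modulator": ChemicalTruth(
            "weak_modulator", pick("AGP", 3), effect_size=1.0, true_bmc_uM=1.0),
        "rna_toxicant": ChemicalTruth(
            "rna_toxicant", pick("RNA", 4), effect_size=2.5, true_bmc_uM=0.2,
            cytotox_ec50_uM=3.0, pi_gain_ec50_uM=3.0),
        "negative_a": ChemicalTruth("negative_a"),
        "negative_b": ChemicalTruth("negative_b"),
        "viability_positive": ChemicalTruth(
            "viability_positive", cytotox_ec50_uM=0.2, cytotox_slope=1.5,
            pi_gain_ec50_uM=0.2, pi_gain_slope=1.5),
    }
    return roster, truths


def simulate_demo_screen(
    seed: int,
    n_plates: int = 3,
    n_features: int = 200,
    cells_per_well: float = 200.0,
    n_vehicle: int = 24,
) -> tuple[pd.DataFrame, dict[str, ChemicalTruth], list[PlateLayout], SimConfig]:
    """Simulate the compact screen: uniquely randomized plates, one per replicate."""
    roster, truths = demo_roster(n_features=n_features)
    layouts = [
        small_screen_layout(roster, f"SIM{p + 1:02d}", seed=seed * 1000 + p, n_vehicle=n_vehicle)
        for p in range(n_plates)
    ]
    config = SimConfig(n_features=n_features, cells_per_well_mean=cells_per_well)
    cells, _truth_table = generate_study(layouts, truths, config, seed=seed)
    return cells, truths, layouts, config
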
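"""Cell-Painting feature normalization, well aggregation, and phenotype BMCs.

Normalization is two-stage and per plate: cell-level feature values are
robust-z-scored against vehicle-control cells (median / nMAD), well medians
of those z-scores are then centered on the vehicle well median and scaled by
the vehicle well nMAD.  A well-level value of +2 therefore reads "two robust
standard deviations above the vehicle median" for that feature.

Potency is estimated two ways.  Feature-level: each feature's well values are
fit with the nine-model family at a benchmark response of 1 (one vehicle
nMAD, direction of the fitted top).  Global: well profiles are projected
onto principal axes, a covariance matrix is estimated from vehicle wells in
component space, and each well's Mahalanobis distance from the vehicle mean
is fit with the same family, again at a benchmark response of one vehicle
nMAD of the distance.  The global BMC is the phenotype-altering
concentration ("phenotypic profiling BMC").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .curvefit import (
    NOT_CALCULABLE,
    BMCResult,
    CRFit,
    PROFILING_MODELS,
    fit_family,
    invert_bmc,
    nmad,
    select_model,
)
from .design import Role
from .simulate import feature_columns
from .viability import PlateQCError

WELL_META = ("plate_id", "well", "chemical_id", "concentration_uM", "role", "n_cells_used")


def normalize_cells(
    cells: pd.DataFrame,
    min_vehicle_cells: int = 20,
) -> tuple[pd.DataFrame, list[str]]:
    """Robust z-score cell-level features against vehicle cells, per plate.

    Only valid cells are used.  Features whose vehicle cell-level nMAD is zero
    on any plate carry no usable spread and are dropped study-wide; the
    dropped names are returned alongside the normalized table.
    """
    fcols = feature_columns(cells)
    valid = cells["valid"].to_numpy(bool)
    X = cells[fcols].to_numpy(float)[valid]
    plates = cells["plate_id"].to_numpy()[valid]
    roles = cells["role"].to_numpy()[valid]
    Z = np.empty_like(X)
    dropped_mask = np.zeros(len(fcols), dtype=bool)
    for plate in pd.unique(plates):
        pm = plates == plate
        vm = pm & (roles == Role.VEHICLE.value)
        if int(vm.sum()) < min_vehicle_cells:
            raise PlateQCError(
                f"plate {plate}: {int(vm.sum())} vehicle cells < required {min_vehicle_cells}")
        v = X[vm]
        med = np.median(v, axis=0)
        spread = 1.4826 * np.median(np.abs(v - med), axis=0)
        zero = spread == 0
        dropped_mask |= zero
        spread[zero] = np.nan
        Z[pm] = (X[pm] - med) / spread
    dropped = sorted(np.asarray(fcols)[dropped_mask])
    keep_cols = [f for f, d in zip(fcols, dropped_mask) if not d]
    meta = cells.loc[valid, list(WELL_META[:5])].reset_index(drop=True)
    normalized = pd.concat(
        [meta, pd.DataFrame(Z[:, ~dropped_mask], columns=keep_cols, copy=False)],
        axis=1, copy=False)
    return normalized, dropped


def aggregate_wells(
    normalized: pd.DataFrame,
    excluded_wells: Iterable[tuple[str, str]] = (),
) -> tuple[pd.DataFrame, list[str]]:
    """Median-aggregate normalized cells to wells and scale to vehicle well spread.

    ``excluded_wells`` are (plate_id, well) pairs failing viability QC; they
    are omitted before the vehicle well statistics are computed.  Features
    whose vehicle well-level nMAD is zero on any plate are dropped study-wide.
    Raises ``PlateQCError`` if a plate retains fewer than 2 vehicle wells.
    """
    excluded = set(excluded_wells)
    if excluded:
        keep = ~normalized.set_index(["plate_id", "well"]).index.isin(excluded)
        normalized = normalized[keep]
    fcols = feature_columns(normalized)

    grouped = normalized.groupby(["plate_id", "well"], sort=False)
    med = grouped[fcols].median()
    meta = grouped[["chemical_id", "concentration_uM", "role"]].first()
    meta["n_cells_used"] = grouped.size()

    out_blocks = []
    dropped: set[str] = set()
    for plate in med.index.get_level_values(0).unique():
        m = med.loc[plate]
        veh_mask = meta.loc[plate, "role"] == Role.VEHICLE.value
        if int(veh_mask.sum()) < 2:
            raise PlateQCError(f"plate {plate}: fewer than 2 vehicle wells after exclusions")
        v = m[veh_mask].to_numpy(float)
        center = np.median(v, axis=0)
        spread = 1.4826 * np.median(np.abs(v - center), axis=0)
        zero = spread == 0
        dropped.update(np.asarray(fcols)[zero])
        spread[zero] = np.nan
        scaled = (m.to_numpy(float) - center) / spread
        block = meta.loc[plate].reset_index().copy()
        block.insert(0, "plate_id", plate)
        out_blocks.append(pd.concat(
            [block.reset_index(drop=True), pd.DataFrame(scaled, columns=fcols)], axis=1))
    wells = pd.concat(out_blocks, ignore_index=True)
    if dropped:
        wells = wells.drop(columns=sorted(dropped))
    wells = wells[[c for c in WELL_META if c in wells.columns]
                  + [c for c in wells.columns if c not in WELL_META]]
    return wells, sorted(dropped)


def feature_level_cr(
    profiles: pd.DataFrame,
    chemical_id: str,
    retained_concentrations: Sequence[float],
    models: Sequence[str] = PROFILING_MODELS,
) -> dict[str, BMCResult]:
    """Nine-model fit and BMC (BMR = 1 nMAD) for every feature of one chemical."""
    fcols = feature_columns(profiles)
    retained = sorted(retained_concentrations)
    sub = profiles[(profiles["chemical_id"] == chemical_id)
                   & profiles["concentration_uM"].isin(retained)]
    if not retained or sub["concentration_uM"].nunique() < 2:
        return {f: NOT_CALCULABLE for f in fcols}
    conc = sub["concentration_uM"].to_numpy(float)
    top, lo = max(retained), min(retained)
    out = {}
    for f in fcols:
        fit = select_model(fit_family(conc, sub[f].to_numpy(float), models))
        out[f] = invert_bmc(fit, 1.0, top, min_tested=lo)
    return out


def ledoit_wolf_covariance(X: np.ndarray) -> tuple[np.ndarray, float]:
    """Shrinkage covariance estimate of the rows of ``X`` (already centered).

    The sample covariance is shrunk toward a scaled identity with the
    Ledoit-Wolf optimal intensity, keeping the estimate well conditioned when
    the number of samples barely exceeds the dimension — the regime vehicle
    wells are in once the component count approaches the vehicle-well count.
    Returns the estimate and the shrinkage intensity used.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    S = X.T @ X / n
    m = np.trace(S) / p
    d2 = np.sum((S - m * np.eye(p)) ** 2) / p
    if d2 <= 0:
        return S, 0.0
    b2_bar = (np.sum(np.sum(X**2, axis=1) ** 2) / n**2 - np.sum(S**2) / n) / p
    b2 = min(max(b2_bar, 0.0), d2)
    rho = b2 / d2
    return (1.0 - rho) * S + rho * m * np.eye(p), float(rho)


def mahalanobis_distances(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Mahalanobis distance of each row of X from ``mean`` under ``cov``.

    Solved through a Cholesky factorization — the covariance inverse is never
    formed explicitly.
    """
    c, low = linalg.cho_factor(cov)
    d = np.atleast_2d(X) - mean
    y = linalg.cho_solve((c, low), d.T)
    return np.sqrt(np.sum(d.T * y, axis=0))


@dataclass
class GlobalProfileResult:
    """Global (Mahalanobis) concentration-response outcome for one chemical."""

    chemical_id: str
    distances: pd.DataFrame  # per-well: plate_id, well, concentration_uM, distance, response
    n_components: int
    fit: CRFit | None
    pp_bmc: BMCResult
    bmr: float


class GlobalProfiler:
    """Study-level PCA + vehicle covariance model for Mahalanobis profiling.

    Principal axes are estimated from all wells handed to :meth:`fit`
    (vehicle plus every chemical's viability-retained wells), centered but
    not re-scaled since features are already in common nMAD units.  The
    number of components is the smallest explaining >= ``var_explained`` of
    the variance, capped at one less than the number of vehicle wells; if the
    vehicle covariance in component space is ill-conditioned the count is
    reduced further until it is invertible.
    """

    def __init__(self, var_explained: float = 0.95, max_condition: float = 1e10):
        self.var_explained = var_explained
        self.max_condition = max_condition

    def fit(self, profiles: pd.DataFrame) -> "GlobalProfiler":
        fcols = feature_columns(profiles)
        X = profiles[fcols].to_numpy(float)
        veh_mask = (profiles["role"] == Role.VEHICLE.value).to_numpy()
        plates = profiles["plate_id"].to_numpy()
        n_vehicle = int(veh_mask.sum())
        if n_vehicle < 3:
            raise PlateQCError("global profiling needs at least 3 vehicle wells")

        # Vehicle wells are cross-calibrated before they define the null.
        # Stage-two scaling makes vehicle profiles exactly self-calibrated
        # (median 0, nMAD 1 in-sample) while treated wells carry the vehicle
        # statistics' estimation noise as shared per-plate offsets; measuring
        # treated wells against a null of pristine vehicle profiles therefore
        # overcalls hits.  Splitting each plate's vehicle wells in half and
        # re-scaling each half against the other (an exact affine map in
        # scaled space) gives the null the same class of calibration noise.
        # Half-plate statistics over-cover the treated noise (12- vs 24-well
        # estimates), which biases the benchmark response upward: hit calls
        # are conservative by design.
        Xn = X.copy()
        for plate in np.unique(plates):
            vi = np.nonzero(veh_mask & (plates == plate))[0]
            if len(vi) < 4:
                continue
            for g, other in ((vi[0::2], vi[1::2]), (vi[1::2], vi[0::2])):
                c = np.median(X[other], axis=0)
                s = 1.4826 * np.median(np.abs(X[other] - c), axis=0)
                s[s == 0] = np.nan
                Xn[g] = np.nan_to_num((X[g] - c) / s, nan=0.0, posinf=0.0, neginf=0.0)

        # principal axes from treated profiles plus the cross-calibrated
        # vehicle profiles, so null calibration-noise directions are
        # representable (economy SVD, deterministic)
        self._mean = Xn.mean(axis=0)
        Xc = Xn - self._mean
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        var = s**2
        cum = np.cumsum(var) / var.sum()
        k = int(np.searchsorted(cum, self.var_explained) + 1)
        k = min(k, n_vehicle - 1, len(s))
        while k > 1:
            veh_c = (Xc @ Vt[:k].T)[veh_mask]
            cov, self.shrinkage = ledoit_wolf_covariance(veh_c - veh_c.mean(axis=0))
            if np.linalg.cond(cov) < self.max_condition:
                break
            k -= 1  # singular vehicle covariance: shed components
        self.n_components = k
        self._axes = Vt[:k]
        null_comps = Xc @ self._axes.T  # cross-calibrated vehicle + treated
        comps = (X - self._mean) @ self._axes.T  # as-reported profiles
        veh_c = null_comps[veh_mask]
        self._veh_mean = veh_c.mean(axis=0)
        self._veh_cov, self.shrinkage = ledoit_wolf_covariance(veh_c - self._veh_mean)
        self._veh_cov = np.atleast_2d(self._veh_cov)
        dist = mahalanobis_distances(comps, self._veh_mean, self._veh_cov)
        # vehicle null distances: cross-calibrated profile, leave-one-out model
        for j, i in enumerate(np.nonzero(veh_mask)[0]):
            others = np.delete(veh_c, j, axis=0)
            mu = others.mean(axis=0)
            cov, _ = ledoit_wolf_covariance(others - mu)
            dist[i] = mahalanobis_distances(null_comps[i:i + 1], mu, np.atleast_2d(cov))[0]
        self._table = profiles[["plate_id", "well", "chemical_id", "concentration_uM", "role"]].copy()
        self._table["distance"] = dist
        veh_d = dist[veh_mask]
        self.vehicle_median_distance = float(np.median(veh_d))
        self.bmr = float(nmad(veh_d))
        self._table["response"] = dist - self.vehicle_median_distance
        return self

    def distances(self) -> pd.DataFrame:
        return self._table.copy()

    def transform_distance(self, profile_rows: pd.DataFrame) -> np.ndarray:
        """Mahalanobis distance for new well profiles under the fitted model."""
        fcols = feature_columns(profile_rows)
        comps = (profile_rows[fcols].to_numpy(float) - self._mean) @ self._axes.T
        return mahalanobis_distances(comps, self._veh_mean, self._veh_cov)

    def chemical_result(
        self,
        chemical_id: str,
        retained_concentrations: Sequence[float],
        models: Sequence[str] = PROFILING_MODELS,
    ) -> GlobalProfileResult:
        retained = sorted(retained_concentrations)
        sub = self._table[(self._table["chemical_id"] == chemical_id)
                          & self._table["concentration_uM"].isin(retained)]
        if not retained or sub["concentration_uM"].nunique() < 2 or self.bmr <= 0:
            return GlobalProfileResult(chemical_id, sub.copy(), self.n_components,
                                       None, NOT_CALCULABLE, self.bmr)
        conc = sub["concentration_uM"].to_numpy(float)
        resp = sub["response"].to_numpy(float)
        fit = select_model(fit_family(conc, resp, models))
        top, lo = max(retained), min(retained)
        # a distance response is one-sided: only wells moving AWAY from the
        # vehicle null indicate an altered phenotype
        bmc = invert_bmc(fit, self.bmr, top, min_tested=lo, require_direction="up")
        return GlobalProfileResult(chemical_id, sub.copy(), self.n_components, fit, bmc, self.bmr)


def global_cr(
    profiles: pd.DataFrame,
    chemical_id: str,
    retained_concentrations: Sequence[float],
    var_explained: float = 0.95,
) -> GlobalProfileResult:
    """One-shot global Mahalanobis concentration-response for a single chemical."""
    profiler = GlobalProfiler(var_explained=var_explained).fit(profiles)
    return profiler.chemical_result(chemical_id, retained_concentrations)
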
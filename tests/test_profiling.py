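import numpy as np
import pandas as pd
import pytest

from htpp.curvefit import BMCStatus, nmad
from htpp.profiling import (
    GlobalProfiler,
    aggregate_wells,
    feature_level_cr,
    global_cr,
    ledoit_wolf_covariance,
    mahalanobis_distances,
    normalize_cells,
)
from htpp.simulate import feature_columns
from htpp.viability import PlateQCError


def toy_cell_table(plates=("P1",), wells_per_plate=6, cells_per_well=40,
                   n_features=5, seed=0, constant_feature=False):
    rng = np.random.default_rng(seed)
    rows = []
    for p in plates:
        for w in range(wells_per_plate):
            role = "vehicle" if w < wells_per_plate // 2 else "test"
            for i in range(cells_per_well):
                feats = rng.normal(10, 2, n_features)
                if constant_feature:
                    feats[0] = 7.0
                rows.append({
                    "plate_id": p, "well": f"W{w}",
                    "chemical_id": "DMSO" if role == "vehicle" else "x",
                    "concentration_uM": 0.0 if role == "vehicle" else float(w),
                    "role": role, "valid": True,
                    **{f"F_{j}": feats[j] for j in range(n_features)},
                })
    return pd.DataFrame(rows)


class TestNormalizeCells:
    def test_vehicle_cell_at_median_maps_to_zero(self):
        cells = toy_cell_table()
        norm, dropped = normalize_cells(cells, min_vehicle_cells=10)
        fcols = feature_columns(norm)
        veh = norm[norm["role"] == "vehicle"]
        med = veh[fcols].median()
        assert np.allclose(med, 0.0, atol=1e-12)
        spread = 1.4826 * (veh[fcols] - med).abs().median()
        assert np.allclose(spread, 1.0, atol=1e-12)
        assert dropped == []

    def test_zero_spread_feature_dropped_and_reported(self):
        cells = toy_cell_table(constant_feature=True)
        norm, dropped = normalize_cells(cells, min_vehicle_cells=10)
        assert dropped == ["F_0"]
        assert "F_0" not in norm.columns

    def test_known_shift_recovered_in_z_units(self):
        cells = toy_cell_table(cells_per_well=400, seed=3)
        delta, sigma = 2.5, 2.0
        treated = cells["role"] == "test"
        cells.loc[treated, "F_1"] += delta * sigma  # shift in true-spread units
        norm, _ = normalize_cells(cells, min_vehicle_cells=10)
        z_gap = norm.loc[norm["role"] == "test", "F_1"].mean() \
            - norm.loc[norm["role"] == "vehicle", "F_1"].mean()
        assert z_gap == pytest.approx(delta, rel=0.1)

    def test_no_vehicle_cells_is_plate_failure(self):
        cells = toy_cell_table()
        cells = cells[cells["role"] != "vehicle"]
        with pytest.raises(PlateQCError):
            normalize_cells(cells, min_vehicle_cells=10)


class TestAggregateWells:
    def test_vehicle_wells_exactly_calibrated_per_plate(self, small_study):
        norm, _ = normalize_cells(small_study["cells"])
        wells, _ = aggregate_wells(norm)
        fcols = feature_columns(wells)
        for _, sub in wells.groupby("plate_id"):
            v = sub[sub["role"] == "vehicle"][fcols].to_numpy()
            med = np.median(v, axis=0)
            assert np.max(np.abs(med)) < 1e-9
            spread = 1.4826 * np.median(np.abs(v - med), axis=0)
            assert np.max(np.abs(spread - 1.0)) < 1e-9

    def test_two_stage_matches_straight_line_recomputation(self):
        # independent brute-force recomputation on a 5-well toy table
        cells = toy_cell_table(wells_per_plate=5, cells_per_well=30, seed=9)
        norm, _ = normalize_cells(cells, min_vehicle_cells=10)
        wells, _ = aggregate_wells(norm)
        fcols = feature_columns(wells)
        veh_cells = cells[cells["role"] == "vehicle"]
        for f in fcols:
            cm = veh_cells[f].median()
            cs = 1.4826 * (veh_cells[f] - cm).abs().median()
            z = cells.groupby("well", sort=False)[f].apply(
                lambda x: ((x - cm) / cs).median())
            veh_wells = [f"W{i}" for i in range(2)]
            wm = z[veh_wells].median()
            ws = 1.4826 * (z[veh_wells] - wm).abs().median()
            expected = (z - wm) / ws
            got = wells.set_index("well")[f]
            assert np.allclose(got[expected.index], expected, atol=1e-10)

    def test_excluded_wells_omitted(self):
        cells = toy_cell_table(wells_per_plate=8)
        norm, _ = normalize_cells(cells, min_vehicle_cells=10)
        wells, _ = aggregate_wells(norm, excluded_wells=[("P1", "W7")])
        assert "W7" not in set(wells["well"])

    def test_single_vehicle_well_is_plate_failure(self):
        cells = toy_cell_table(wells_per_plate=4)
        norm, _ = normalize_cells(cells, min_vehicle_cells=10)
        with pytest.raises(PlateQCError):
            aggregate_wells(norm, excluded_wells=[("P1", "W0")])

    def test_well_of_identical_cells_aggregates_to_scaled_median(self):
        cells = toy_cell_table(wells_per_plate=6, cells_per_well=20, seed=4)
        norm, _ = normalize_cells(cells, min_vehicle_cells=10)
        fcols = feature_columns(norm)
        # force one treated well's cells all to z = 3
        mask = norm["well"] == "W5"
        norm.loc[mask, fcols] = 3.0
        wells, _ = aggregate_wells(norm)
        veh = wells[wells["role"] == "vehicle"]
        z = norm[norm["role"] == "vehicle"].groupby("well")[fcols[0]].median()
        wm = z.median()
        ws = 1.4826 * (z - wm).abs().median()
        got = wells.set_index("well").loc["W5", fcols[0]]
        assert got == pytest.approx((3.0 - wm) / ws, rel=1e-9)


class TestMahalanobis:
    def test_distance_zero_at_the_mean(self, rng):
        X = rng.normal(size=(10, 4))
        mu = X.mean(axis=0)
        cov = np.cov(X, rowvar=False)
        assert mahalanobis_distances(mu[None, :], mu, cov)[0] == pytest.approx(0.0, abs=1e-12)

    def test_identity_covariance_reduces_to_euclidean(self, rng):
        v = rng.normal(size=(5, 1))
        mu = np.array([0.5])
        d = mahalanobis_distances(v, mu, np.eye(1))
        assert np.allclose(d, np.abs(v[:, 0] - 0.5))

    def test_matches_linear_solve_oracle_to_1e8(self, rng):
        X = rng.normal(size=(6, 3)) * [1.0, 5.0, 0.2]
        mu = rng.normal(size=3)
        A = rng.normal(size=(3, 3))
        cov = A @ A.T + 0.5 * np.eye(3)
        d = mahalanobis_distances(X, mu, cov)
        oracle = np.array([
            np.sqrt((x - mu) @ np.linalg.solve(cov, x - mu)) for x in X])
        assert np.max(np.abs(d - oracle)) < 1e-8

    def test_invariant_under_linear_reparameterization(self, rng):
        X = rng.normal(size=(20, 5))
        mu = X.mean(axis=0)
        cov = np.cov(X, rowvar=False)
        T = rng.normal(size=(5, 5)) + np.eye(5) * 2  # invertible w.h.p.
        d1 = mahalanobis_distances(X, mu, cov)
        d2 = mahalanobis_distances(X @ T, mu @ T, T.T @ cov @ T)
        assert np.allclose(d1, d2, atol=1e-8)

    def test_ledoit_wolf_keeps_sample_structure_when_well_conditioned(self, rng):
        X = rng.normal(size=(500, 4)) * [1, 2, 3, 4.0]
        Xc = X - X.mean(axis=0)
        cov, intensity = ledoit_wolf_covariance(Xc)
        assert intensity < 0.1
        assert np.allclose(np.sqrt(np.diag(cov)), [1, 2, 3, 4], rtol=0.2)


class TestGlobalProfiling:
    def test_distance_monotone_in_injected_effect_size(self, small_study):
        # wells with a larger multivariate shift sit farther from the null
        norm, _ = normalize_cells(small_study["cells"])
        profiles, _ = aggregate_wells(norm)
        gp = GlobalProfiler().fit(profiles)
        fcols = feature_columns(profiles)
        base = profiles[profiles["role"] == "vehicle"].head(1).copy()
        dists = []
        for scale in (0.0, 1.0, 2.0, 4.0):
            shifted = base.copy()
            shifted[fcols[:10]] = shifted[fcols[:10]].to_numpy() + scale
            dists.append(float(gp.transform_distance(shifted)[0]))
        assert all(a < b for a, b in zip(dists, dists[1:]))

    def test_component_cap_respects_vehicle_count(self, small_screen_result):
        gp = small_screen_result.profiler
        n_vehicle = int((small_screen_result.profiles["role"] == "vehicle").sum())
        assert 1 <= gp.n_components <= n_vehicle - 1

    def test_pp_bmc_within_retained_range_when_estimated(self, small_screen_result):
        for chem, res in small_screen_result.global_results.items():
            if res.pp_bmc.is_estimated:
                top = max(small_screen_result.viability[chem].retained_concentrations)
                assert 0 < res.pp_bmc.bmc_uM <= top

    def test_strong_effect_detected_and_negative_censored(self, small_screen_result):
        assert small_screen_result.global_results["dna_blocker"].pp_bmc.is_estimated
        assert not small_screen_result.global_results["negative_a"].pp_bmc.is_estimated

    def test_global_cr_single_shot_matches_profiler(self, small_study, small_screen_result):
        profiles = small_screen_result.profiles
        keep = (profiles["role"] == "vehicle") | (profiles["chemical_id"] == "dna_blocker")
        retained = small_screen_result.viability["dna_blocker"].retained_concentrations
        res = global_cr(profiles[keep].reset_index(drop=True), "dna_blocker", retained)
        assert res.pp_bmc.is_estimated


class TestFeatureLevel:
    def test_no_retained_concentrations_gives_not_calculable(self, small_screen_result):
        out = feature_level_cr(small_screen_result.profiles, "dna_blocker", [])
        assert all(r.status is BMCStatus.NOT_CALCULABLE for r in out.values())

    def test_affected_features_recover_potency(self, small_study, small_screen_result):
        truths = small_study["truths"]["dna_blocker"]
        profiles = small_screen_result.profiles
        fcols = feature_columns(profiles)
        retained = small_screen_result.viability["dna_blocker"].retained_concentrations
        sub_cols = [fcols[j] for j in truths.affected[:4] if fcols and j < len(fcols)]
        small = profiles[["plate_id", "well", "chemical_id", "concentration_uM",
                          "role", "n_cells_used"] + sub_cols]
        out = feature_level_cr(small, "dna_blocker", retained)
        est = [r for r in out.values() if r.is_estimated]
        assert len(est) >= len(sub_cols) - 1
        for r in est:
            assert abs(np.log10(r.bmc_uM / truths.true_bmc_uM)) < 1.0
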
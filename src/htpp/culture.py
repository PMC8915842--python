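"""Culture-optimization endpoints and nonparametric group comparisons.

These endpoints drive plating-density, substrate-titer, and media decisions:
analyzed cells per well, percent confluence (cell-body area over imaged
area), average nearest-neighbor nucleus distance, and a percent contact-area
proxy for how tightly neighboring cell bodies pack.  Group comparisons
report normality (Shapiro-Wilk) and variance homogeneity (Levene) checks,
then a Kruskal-Wallis test with Dunn's post-hoc comparisons against a
reference group under Bonferroni correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class CultureEndpoints:
    """Well-level culture metrics."""

    plate_id: str
    well: str
    analyzed_cells: int
    pct_confluence: float
    avg_distance_um: float | None  # undefined (< 2 cells) -> None
    pct_contact_area: float | None


def _disc_overlap(r1: np.ndarray, r2: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Intersection area of discs with radii r1, r2 at center distance d."""
    area = np.zeros_like(d)
    rmin = np.minimum(r1, r2)
    contained = d <= np.abs(r1 - r2)
    area[contained] = np.pi * rmin[contained] ** 2
    mask = (~contained) & (d < r1 + r2)
    if np.any(mask):
        a, b, dd = r1[mask], r2[mask], d[mask]
        alpha = np.arccos(np.clip((dd**2 + a**2 - b**2) / (2 * dd * a), -1, 1))
        beta = np.arccos(np.clip((dd**2 + b**2 - a**2) / (2 * dd * b), -1, 1))
        area[mask] = (a**2 * (alpha - np.sin(2 * alpha) / 2)
                      + b**2 * (beta - np.sin(2 * beta) / 2))
    return area


def compute_endpoints(well_cells: pd.DataFrame, imaged_area_um2: float) -> CultureEndpoints:
    """Culture endpoints for the cells of a single well.

    Confluence is total cell-body area over imaged area (capped at 100%).
    Average distance is the well mean of each valid cell's nearest-neighbor
    nucleus centroid distance.  Contact area is approximated by the overlap
    of equivalent-area discs placed at nucleus centroids — a proxy for the
    segmented-mask contact of neighboring cell bodies — expressed as percent
    of the cell's own footprint.
    """
    if imaged_area_um2 <= 0:
        raise ValueError("imaged area must be positive")
    cells = well_cells[well_cells["valid"]]
    plate = str(well_cells["plate_id"].iloc[0]) if len(well_cells) else ""
    well = str(well_cells["well"].iloc[0]) if len(well_cells) else ""
    n = len(cells)
    confluence = min(100.0, 100.0 * float(cells["cell_area"].sum()) / imaged_area_um2)
    if n < 2:
        return CultureEndpoints(plate, well, n, confluence, None, None)
    xy = cells[["nucleus_x", "nucleus_y"]].to_numpy(float)
    dist, idx = cKDTree(xy).query(xy, k=2)
    nn_dist, nn_idx = dist[:, 1], idx[:, 1]
    radius = np.sqrt(cells["cell_area"].to_numpy(float) / np.pi)
    overlap = _disc_overlap(radius, radius[nn_idx], nn_dist)
    pct_contact = 100.0 * float(np.mean(overlap / (np.pi * radius**2)))
    return CultureEndpoints(plate, well, n, confluence, float(np.mean(nn_dist)), pct_contact)


def endpoints_table(cells: pd.DataFrame, imaged_area_um2: float) -> pd.DataFrame:
    """Per-well culture endpoints for a whole cell table."""
    rows = []
    for (plate, well), sub in cells.groupby(["plate_id", "well"], sort=False):
        e = compute_endpoints(sub, imaged_area_um2)
        rows.append(vars(e))
    return pd.DataFrame(rows)


def dunn_test(
    groups: Mapping[str, Sequence[float]],
    reference: str,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Dunn's rank-based post-hoc comparisons of each group against a reference.

    Uses pooled mid-ranks with tie correction; two-sided normal p-values are
    Bonferroni-multiplied by the number of comparisons (capped at 1).
    """
    if reference not in groups:
        raise KeyError(f"reference group {reference!r} not among groups")
    labels = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in labels]
    pooled = np.concatenate(values)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g, v in zip(labels, values):
        mean_ranks[g] = float(np.mean(ranks[start:start + len(v)]))
        sizes[g] = len(v)
        start += len(v)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (N - 1))
    var_unit = N * (N + 1) / 12.0 - tie_term
    others = [g for g in labels if g != reference]
    m = len(others)
    rows = []
    for g in others:
        se = math.sqrt(var_unit * (1.0 / sizes[g] + 1.0 / sizes[reference]))
        z = (mean_ranks[g] - mean_ranks[reference]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p * m) if adjust == "bonferroni" else p
        rows.append({"group": g, "reference": reference, "z": z,
                     "p_value": p, "p_adjusted": p_adj, "significant": p_adj < 0.05})
    return pd.DataFrame(rows)


def compare_conditions(
    groups: Mapping[str, Sequence[float]],
    reference: str,
    alpha: float = 0.05,
) -> dict:
    """Full comparison harness: assumption checks, omnibus test, post-hoc.

    Shapiro-Wilk and Levene are reported as context for why the nonparametric
    route is taken; inference rests on Kruskal-Wallis plus Dunn-Bonferroni
    against the reference, flagged at adjusted p < ``alpha``.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, v in groups.items():
        if len(v) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 values")
    shapiro = {}
    for g, v in groups.items():
        v = np.asarray(v, dtype=float)
        if np.ptp(v) == 0:
            shapiro[g] = {"statistic": None, "p_value": None, "note": "constant group"}
        else:
            res = stats.shapiro(v)
            shapiro[g] = {"statistic": float(res.statistic), "p_value": float(res.pvalue)}
    lev = stats.levene(*[np.asarray(v, float) for v in groups.values()])
    kw = stats.kruskal(*[np.asarray(v, float) for v in groups.values()])
    dunn = dunn_test(groups, reference)
    return {
        "shapiro": shapiro,
        "levene": {"statistic": float(lev.statistic), "p_value": float(lev.pvalue)},
        "kruskal": {"statistic": float(kw.statistic), "p_value": float(kw.pvalue)},
        "dunn": dunn,
        "significant_groups": sorted(dunn.loc[dunn["significant"], "group"]),
        "alpha": alpha,
    }
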
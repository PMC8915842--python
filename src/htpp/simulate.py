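"""Synthetic cell-level Cell-Painting and viability data with known ground truth.

The generator emulates the per-cell export of a high-content imaging pipeline
for a neural-progenitor screen: each well yields a few hundred segmented
cells, each carrying geometry, Hoechst and propidium-iodide (PI) intensities,
a validity flag, and a wide morphology-feature vector spanning five organelle
channels (DNA, RNA, ER, AGP, Mito) and four categories (intensity, texture,
shape, position).

Treatment effects are injected on a configurable subset of features as
Hill-shaped shifts expressed in units of the vehicle-control nMAD, so the
analysis pipeline's benchmark-concentration estimates can be compared to the
recorded truth.  Cytotoxicity thins the per-well cell count by a Hill
survival factor and raises the PI-positive conversion probability.  Wells and
plates carry random intercepts emulating culture-to-culture variability, and
cell positions follow a clustered parent-offspring point process because
neural progenitors grow in dense clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import PlateLayout, Role, TreatmentAssignment

CHANNELS = ("DNA", "RNA", "ER", "AGP", "Mito")
CATEGORIES = ("intensity", "texture", "shape", "position")
#: per-channel category mix (sums to 260 for the default 1300-feature set)
_CATEGORY_WEIGHTS = {"intensity": 60, "texture": 100, "shape": 60, "position": 40}

META_COLUMNS = (
    "plate_id", "well", "cell_index", "chemical_id", "concentration_uM", "role",
    "nucleus_x", "nucleus_y", "nucleus_area", "cell_area",
    "hoechst_intensity", "pi_intensity", "pi_positive", "valid",
    "n_cells_used",  # well-level tables
)


@dataclass(frozen=True)
class FeatureTaxonomy:
    """Assignment of every feature to a (channel, category) cell."""

    channels: tuple[str, ...]
    categories: tuple[str, ...]
    names: tuple[str, ...]
    channel_index: np.ndarray  # feature -> channel id
    category_index: np.ndarray

    @classmethod
    @lru_cache(maxsize=8)
    def default(cls, n_features: int = 1300) -> "FeatureTaxonomy":
        """Split ``n_features`` evenly over channels, categories in a 60:100:60:40 mix."""
        if n_features < len(CHANNELS) * len(CATEGORIES):
            raise ValueError("need at least one feature per channel x category")
        per_channel = np.full(len(CHANNELS), n_features // len(CHANNELS))
        per_channel[: n_features % len(CHANNELS)] += 1
        names, ch_idx, cat_idx = [], [], []
        wsum = sum(_CATEGORY_WEIGHTS.values())
        for ci, (ch, nch) in enumerate(zip(CHANNELS, per_channel)):
            # largest-remainder apportionment of this channel's features
            exact = {cat: nch * w / wsum for cat, w in _CATEGORY_WEIGHTS.items()}
            counts = {cat: max(1, int(v)) for cat, v in exact.items()}
            while sum(counts.values()) < nch:
                cat = max(exact, key=lambda c: exact[c] - counts[c])
                counts[cat] += 1
            while sum(counts.values()) > nch:
                cat = min(exact, key=lambda c: exact[c] - counts[c])
                counts[cat] -= 1
            for cat in CATEGORIES:
                for k in range(counts[cat]):
                    names.append(f"{ch}_{cat}_{k}")
                    ch_idx.append(ci)
                    cat_idx.append(CATEGORIES.index(cat))
        return cls(CHANNELS, CATEGORIES, tuple(names),
                   np.asarray(ch_idx), np.asarray(cat_idx))

    @property
    def n_features(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class ChemicalTruth:
    """Ground truth for one chemical's simulated activity.

    ``effect_size`` is the asymptotic per-feature shift in vehicle nMAD units;
    the Hill midpoint of the shift sits at ``true_bmc_uM`` with slope
    ``hill_slope`` (steep by default, so the concentration at which well-level
    responses emerge tracks the recorded potency).
    """

    chemical_id: str
    affected: tuple[int, ...] = ()
    effect_size: float = 0.0
    true_bmc_uM: float | None = None
    hill_slope: float = 4.0
    cytotox_ec50_uM: float | None = None
    cytotox_slope: float = 3.0
    pi_gain_ec50_uM: float | None = None
    pi_gain_slope: float = 3.0

    def __post_init__(self) -> None:
        if self.affected and self.true_bmc_uM is None:
            raise ValueError("affected features require a true_bmc_uM")
        if self.true_bmc_uM is not None and self.true_bmc_uM <= 0:
            raise ValueError("true_bmc_uM must be positive")

    def feature_shift(self, conc: float) -> float:
        """Expected affected-feature shift (nMAD units) at a concentration."""
        if not self.affected or conc <= 0:
            return 0.0
        return self.effect_size / (1.0 + (self.true_bmc_uM / conc) ** self.hill_slope)

    def survival(self, conc: float) -> float:
        """Hill survival factor thinning the expected cell count."""
        if self.cytotox_ec50_uM is None or conc <= 0:
            return 1.0
        return 1.0 / (1.0 + (conc / self.cytotox_ec50_uM) ** self.cytotox_slope)

    def pi_conversion(self, conc: float, base: float, top: float) -> float:
        """PI-positive probability, rising from ``base`` toward ``top`` with dose."""
        if self.pi_gain_ec50_uM is None or conc <= 0:
            return base
        frac = 1.0 / (1.0 + (self.pi_gain_ec50_uM / conc) ** self.pi_gain_slope)
        return base + (top - base) * frac


VEHICLE_TRUTH = ChemicalTruth("DMSO")


@dataclass
class SimConfig:
    """Study-level simulation settings.

    Defaults reflect the screen being emulated: ~800 analyzed cells per well
    at the chosen plating density, five-field imaging area, and modest
    well/plate culture variability on top of correlated cell-level baselines.
    """

    n_features: int = 1300
    cells_per_well_mean: float = 800.0
    count_cv: float = 0.08  # lognormal well-to-well count variability
    rho: float = 0.3  # within-channel single-factor correlation
    noise_scale: float = 0.05  # extra measurement noise, nMAD units
    well_effect_sd: float = 0.25  # well random intercept, nMAD units
    plate_effect_sd: float = 0.10  # plate random intercept, nMAD units
    pi_base_rate: float = 0.02
    pi_max_rate: float = 0.70
    pi_threshold: float = 200.0
    hoechst_floor: float = 300.0
    nucleus_area_gate: tuple[float, float] = (40.0, 400.0)
    imaged_area_um2: float = 2.09e6  # five 20X fields
    cluster_size: float = 8.0  # mean cells per growth cluster
    cluster_sd_um: float = 30.0
    baseline_seed: int = 7

    def __post_init__(self) -> None:
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")
        if self.cells_per_well_mean <= 0:
            raise ValueError("cells_per_well_mean must be positive")


def _lognormal_nmad(mu: float, sigma: float) -> float:
    """nMAD of a lognormal(mu, sigma) variate, solved from its CDF."""
    m = np.exp(mu)
    def half_mass(t):
        lo = stats.norm.cdf((np.log(m - t) - mu) / sigma) if t < m else 0.0
        return stats.norm.cdf((np.log(m + t) - mu) / sigma) - lo - 0.5
    mad = optimize.brentq(half_mass, 1e-12 * m, m * np.expm1(6 * sigma) + m)
    return 1.4826 * mad


@lru_cache(maxsize=8)
def _cached_baselines(n_features: int, seed: int) -> "FeatureBaselines":
    return FeatureBaselines(FeatureTaxonomy.default(n_features), seed)


class FeatureBaselines:
    """Deterministic per-feature baseline distributions.

    Intensity- and texture-category features are log-normal (strictly
    positive, right-skewed); shape and position features are normal.  Each
    feature's theoretical nMAD is precomputed so treatment shifts, well and
    plate intercepts, and measurement noise can be expressed in nMAD units.
    """

    def __init__(self, taxonomy: FeatureTaxonomy, seed: int):
        self.taxonomy = taxonomy
        rng = np.random.default_rng(np.random.SeedSequence([seed, taxonomy.n_features]))
        F = taxonomy.n_features
        cat = taxonomy.category_index
        self.lognormal = np.isin(cat, [0, 1])  # intensity, texture
        self.mu = np.where(self.lognormal, rng.uniform(np.log(200), np.log(2000), F), 0.0)
        self.sigma = np.where(self.lognormal, rng.uniform(0.2, 0.5, F), 1.0)
        loc = np.where(cat == 2, rng.uniform(20, 200, F), rng.uniform(0.2, 0.8, F))
        scale = np.where(cat == 2, loc * rng.uniform(0.1, 0.3, F), rng.uniform(0.05, 0.15, F))
        self.loc = np.where(self.lognormal, 0.0, loc)
        self.scale = np.where(self.lognormal, 1.0, scale)
        self.nmad = np.empty(F)
        for j in range(F):
            if self.lognormal[j]:
                self.nmad[j] = _lognormal_nmad(self.mu[j], self.sigma[j])
            else:
                self.nmad[j] = self.scale[j]  # nMAD of N(loc, scale) is scale

    def sample(self, z: np.ndarray) -> np.ndarray:
        """Map standard-normal latents (cells x features) to feature space."""
        x = np.where(self.lognormal, np.exp(self.mu + self.sigma * z),
                     self.loc + self.scale * z)
        return x


@dataclass(frozen=True)
class CellRecord:
    """One segmented cell (a typed view of a row of the cell table)."""

    plate_id: str
    well: str
    cell_index: int
    nucleus_x: float
    nucleus_y: float
    nucleus_area: float
    cell_area: float
    hoechst_intensity: float
    pi_intensity: float
    pi_positive: bool
    valid: bool
    features: np.ndarray

    def __post_init__(self) -> None:
        if self.nucleus_area <= 0 or self.cell_area <= 0:
            raise ValueError("areas must be positive")


def feature_columns(df: pd.DataFrame) -> list[str]:
    """Feature column names of a cell-level or well-level table."""
    return [c for c in df.columns if c not in META_COLUMNS]


def records(df: pd.DataFrame) -> list[CellRecord]:
    """View a cell table as typed records (small inputs only)."""
    fcols = feature_columns(df)
    out = []
    for _, r in df.iterrows():
        out.append(CellRecord(
            r["plate_id"], r["well"], int(r["cell_index"]),
            float(r["nucleus_x"]), float(r["nucleus_y"]), float(r["nucleus_area"]),
            float(r["cell_area"]), float(r["hoechst_intensity"]),
            float(r["pi_intensity"]), bool(r["pi_positive"]), bool(r["valid"]),
            r[fcols].to_numpy(dtype=float),
        ))
    return out


def _cluster_positions(n: int, config: SimConfig, rng: np.random.Generator):
    """Thomas-process cell positions in the (square-equivalent) imaged area."""
    L = np.sqrt(config.imaged_area_um2)
    if n == 0:
        return np.empty(0), np.empty(0)
    n_parents = max(1, rng.poisson(n / config.cluster_size))
    parents = rng.uniform(0, L, size=(n_parents, 2))
    assign = rng.integers(0, n_parents, size=n)
    xy = parents[assign] + rng.normal(0, config.cluster_sd_um, size=(n, 2))
    xy = np.clip(xy, 0, L)
    return xy[:, 0], xy[:, 1]


def _generate_well_arrays(
    assignment: TreatmentAssignment,
    truth: ChemicalTruth | None,
    config: SimConfig,
    rng: np.random.Generator,
    plate_id: str,
    well: str,
    baselines: FeatureBaselines,
    plate_offsets: np.ndarray | None,
) -> tuple[dict, np.ndarray]:
    if assignment.role is not Role.VEHICLE and truth is None:
        raise ValueError(f"no ground truth configured for chemical {assignment.chemical_id!r}")
    truth = truth if truth is not None else VEHICLE_TRUTH
    taxonomy = FeatureTaxonomy.default(config.n_features)
    F = taxonomy.n_features
    conc = assignment.concentration_uM

    mean_n = config.cells_per_well_mean * truth.survival(conc)
    mean_n *= rng.lognormal(-0.5 * config.count_cv**2, config.count_cv)
    n = int(rng.poisson(mean_n))

    # correlated cell-level latents: one factor per channel
    g = rng.standard_normal((n, len(CHANNELS)))
    eps = rng.standard_normal((n, F))
    z = np.sqrt(config.rho) * g[:, taxonomy.channel_index] + np.sqrt(1 - config.rho) * eps
    x = baselines.sample(z)

    offsets = rng.normal(0.0, config.well_effect_sd, F)  # well random intercept
    if plate_offsets is not None:
        offsets = offsets + plate_offsets
    shift = truth.feature_shift(conc)
    if shift != 0.0:
        eff = np.zeros(F)
        eff[list(truth.affected)] = shift
        offsets = offsets + eff
    x = x + offsets * baselines.nmad
    if config.noise_scale > 0:
        x = x + rng.standard_normal((n, F)) * (config.noise_scale * baselines.nmad)

    nucleus_x, nucleus_y = _cluster_positions(n, config, rng)
    nucleus_area = rng.lognormal(np.log(150.0), 0.25, n)
    cell_area = rng.lognormal(np.log(1400.0), 0.35, n)
    hoechst = rng.lognormal(np.log(1000.0), 0.35, n)
    p_pos = truth.pi_conversion(conc, config.pi_base_rate, config.pi_max_rate)
    pi_positive = rng.uniform(size=n) < p_pos
    mag = 0.3 + 0.5 * np.abs(rng.standard_normal(n))
    pi_intensity = config.pi_threshold * np.exp(np.where(pi_positive, mag, -mag))
    valid = (
        (hoechst > config.hoechst_floor)
        & (nucleus_area > config.nucleus_area_gate[0])
        & (nucleus_area < config.nucleus_area_gate[1])
    )

    meta = {
        "plate_id": np.full(n, plate_id, dtype=object),
        "well": np.full(n, well, dtype=object),
        "cell_index": np.arange(n),
        "chemical_id": np.full(n, assignment.chemical_id, dtype=object),
        "concentration_uM": np.full(n, conc),
        "role": np.full(n, assignment.role.value, dtype=object),
        "nucleus_x": nucleus_x, "nucleus_y": nucleus_y,
        "nucleus_area": nucleus_area, "cell_area": cell_area,
        "hoechst_intensity": hoechst, "pi_intensity": pi_intensity,
        "pi_positive": pi_positive, "valid": valid,
    }
    return meta, x


def _assemble(metas: list[dict], xs: list[np.ndarray], names: Sequence[str]) -> pd.DataFrame:
    cols = {k: np.concatenate([m[k] for m in metas]) for k in metas[0]}
    df = pd.DataFrame(cols, copy=False)
    feats = pd.DataFrame(np.vstack(xs), columns=list(names), copy=False)
    out = pd.concat([df, feats], axis=1, copy=False)
    return out


def generate_well(
    assignment: TreatmentAssignment,
    truth: ChemicalTruth | None,
    config: SimConfig,
    seed,
    *,
    plate_id: str = "PLATE1",
    well: str = "A1",
    baselines: FeatureBaselines | None = None,
    plate_offsets: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate the cell-level export of a single well.

    ``seed`` may be an integer or a ``numpy`` SeedSequence/Generator.
    ``plate_offsets`` (per-feature, nMAD units) lets a study superimpose a
    shared plate random intercept.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if baselines is None:
        baselines = _cached_baselines(config.n_features, config.baseline_seed)
    meta, x = _generate_well_arrays(
        assignment, truth, config, rng, plate_id, well, baselines, plate_offsets)
    return _assemble([meta], [x], FeatureTaxonomy.default(config.n_features).names)


def generate_study(
    layouts: Sequence[PlateLayout],
    truths: Mapping[str, ChemicalTruth],
    config: SimConfig,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a multi-plate study (one layout per biological replicate).

    Returns the concatenated cell-level table and a sidecar ground-truth
    table.  Plate-level random intercepts on the baseline features emulate
    culture-to-culture variability; the per-plate normalization downstream is
    what removes them.
    """
    ids = [lay.plate_id for lay in layouts]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate plate_id in layouts: {ids}")
    taxonomy = FeatureTaxonomy.default(config.n_features)
    baselines = _cached_baselines(config.n_features, config.baseline_seed)
    master = np.random.SeedSequence([int(seed)])
    plate_seeds = master.spawn(len(layouts))
    metas, xs = [], []
    for lay, pss in zip(layouts, plate_seeds):
        prng = np.random.default_rng(pss)
        plate_offsets = prng.normal(0.0, config.plate_effect_sd, taxonomy.n_features)
        well_seeds = pss.spawn(len(lay.assignments))
        for (well, a), wss in zip(lay.assignments.items(), well_seeds):
            truth = truths.get(a.chemical_id) if a.role is not Role.VEHICLE else None
            m, x = _generate_well_arrays(
                a, truth, config, np.random.default_rng(wss),
                lay.plate_id, well, baselines, plate_offsets)
            metas.append(m)
            xs.append(x)
    cells = _assemble(metas, xs, taxonomy.names)
    truth_rows = [{
        "chemical_id": t.chemical_id,
        "n_affected": len(t.affected),
        "affected": ";".join(map(str, t.affected)),
        "effect_size": t.effect_size,
        "true_bmc_uM": t.true_bmc_uM,
        "hill_slope": t.hill_slope,
        "cytotox_ec50_uM": t.cytotox_ec50_uM,
        "pi_gain_ec50_uM": t.pi_gain_ec50_uM,
    } for t in truths.values()]
    return cells, pd.DataFrame(truth_rows)


def pick_affected_features(
    taxonomy: FeatureTaxonomy,
    channel: str,
    n: int,
    seed: int,
) -> tuple[int, ...]:
    """Deterministically choose ``n`` affected features within one channel."""
    pool = np.nonzero(taxonomy.channel_index == list(taxonomy.channels).index(channel))[0]
    rng = np.random.default_rng(np.random.SeedSequence([seed, len(pool)]))
    return tuple(int(i) for i in rng.choice(pool, size=min(n, len(pool)), replace=False))
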
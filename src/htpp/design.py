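"""Concentration series and randomized 384-well plate layouts.

A screening plate carries test chemicals at 8 half-log-spaced concentrations
with two technical replicates, negative controls under the same scheme, one
cell-viability positive control at 6 log-spaced concentrations (with the 1 µM
point in triplicate), and 24 DMSO vehicle wells.  Treatments are assigned to
well coordinates by a seeded uniform permutation, so every plate is uniquely
randomized with respect to treatment while replicate plates share the same
concentration sets.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ROWS = "ABCDEFGHIJKLMNOP"
N_COLS = 24
PLATE_WELLS = len(ROWS) * N_COLS  # 384

#: wells per chemical under the screen's replicate rules
WELLS_PER_TEST = 16  # 8 concentrations x 2 technical replicates
WELLS_PER_VIABILITY_CONTROL = 8  # 5 conc x 1 + 1 conc x 3
N_VEHICLE_WELLS = 24


class Role(str, Enum):
    TEST = "test"
    NEGATIVE = "negative"
    VIABILITY_CONTROL = "viability_control"
    VEHICLE = "vehicle"


class Spacing(str, Enum):
    HALF_LOG = "half_log"
    LOG = "log"


def round_sig(x: float, sig: int = 3) -> float:
    """Round to `sig` significant figures (reporting precision of the dose ledger)."""
    if x == 0:
        return 0.0
    return float(f"{x:.{sig - 1}E}")


@dataclass(frozen=True)
class DoseSeries:
    """A descending concentration series for one chemical."""

    chemical_id: str
    concentrations_uM: tuple[float, ...]
    spacing: Spacing

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_uM, dtype=float)
        if c.ndim != 1 or c.size < 1:
            raise ValueError("concentration series must be a non-empty vector")
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(np.diff(c) >= 0):
            raise ValueError("concentrations must be strictly decreasing")

    @property
    def n_points(self) -> int:
        return len(self.concentrations_uM)

    @property
    def rounded(self) -> tuple[float, ...]:
        """Series at 3-significant-figure reporting precision."""
        return tuple(round_sig(c) for c in self.concentrations_uM)


def halflog_series(top_uM: float, n_points: int = 8, chemical_id: str = "") -> DoseSeries:
    """Half-log dilution series realized as the rounded {1, 3.33} x 10^k ladder.

    Starting from the top concentration, steps alternate dividing by 3 and by
    10/3, so consecutive points are one half-decade apart and every second
    point is exactly ``top / 10**k``.  For the default 8 points the minimum is
    ``top / 3000``.
    """
    if not (top_uM > 0):
        raise ValueError(f"top concentration must be positive, got {top_uM}")
    if n_points < 2:
        raise ValueError(f"need at least 2 points, got {n_points}")
    conc = [float(top_uM)]
    for i in range(n_points - 1):
        conc.append(conc[-1] / (3.0 if i % 2 == 0 else 10.0 / 3.0))
    return DoseSeries(chemical_id, tuple(conc), Spacing.HALF_LOG)


def log_series(top_uM: float, n_points: int = 6, chemical_id: str = "") -> DoseSeries:
    """Full-decade dilution series: top x 10^{0, -1, ..., -(n-1)}."""
    if not (top_uM > 0):
        raise ValueError(f"top concentration must be positive, got {top_uM}")
    if n_points < 2:
        raise ValueError(f"need at least 2 points, got {n_points}")
    conc = tuple(float(top_uM) * 10.0 ** (-k) for k in range(n_points))
    return DoseSeries(chemical_id, conc, Spacing.LOG)


@dataclass(frozen=True)
class TreatmentAssignment:
    """What goes into one well: chemical, concentration, and its role on the plate."""

    chemical_id: str
    concentration_uM: float
    role: Role

    def __post_init__(self) -> None:
        if (self.role is Role.VEHICLE) != (self.concentration_uM == 0):
            raise ValueError("vehicle role if and only if concentration is 0")
        if self.concentration_uM < 0:
            raise ValueError("concentration must be non-negative")


VEHICLE = TreatmentAssignment("DMSO", 0.0, Role.VEHICLE)


class LayoutInfeasibleError(ValueError):
    """Roster does not tile the plate exactly."""


@dataclass
class PlateLayout:
    """Mapping of well coordinates (A1..P24) to treatment assignments."""

    plate_id: str
    assignments: dict[str, TreatmentAssignment]
    seed: int | None = None

    def __iter__(self):
        return iter(self.assignments.items())

    @property
    def wells(self) -> list[str]:
        return list(self.assignments)

    def wells_for(self, chemical_id: str) -> list[str]:
        return [w for w, a in self.assignments.items() if a.chemical_id == chemical_id]

    @property
    def vehicle_wells(self) -> list[str]:
        return [w for w, a in self.assignments.items() if a.role is Role.VEHICLE]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "plate_id": self.plate_id,
                "well": w,
                "row": w[0],
                "col": int(w[1:]),
                "chemical_id": a.chemical_id,
                "concentration_uM": a.concentration_uM,
                "role": a.role.value,
            }
            for w, a in self.assignments.items()
        ]
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "plate_id": self.plate_id,
                "seed": self.seed,
                "assignments": {
                    w: {
                        "chemical_id": a.chemical_id,
                        "concentration_uM": a.concentration_uM,
                        "role": a.role.value,
                    }
                    for w, a in self.assignments.items()
                },
            },
            indent=2,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, plate_id: str | None = None) -> "PlateLayout":
        if plate_id is not None:
            df = df[df["plate_id"] == plate_id]
        elif df["plate_id"].nunique() != 1:
            raise ValueError("frame holds multiple plates; pass plate_id")
        assignments = {
            r.well: TreatmentAssignment(r.chemical_id, float(r.concentration_uM), Role(r.role))
            for r in df.itertuples()
        }
        return cls(str(df["plate_id"].iloc[0]), assignments)


def all_wells() -> list[str]:
    return [f"{r}{c}" for r in ROWS for c in range(1, N_COLS + 1)]


def _interior_wells() -> list[str]:
    return [f"{r}{c}" for r in ROWS[1:-1] for c in range(2, N_COLS)]


def treatment_slots(
    chemicals: Sequence[tuple[str, Role | str, float]],
    n_vehicle: int = N_VEHICLE_WELLS,
    viability_triplicate_uM: float = 1.0,
) -> list[TreatmentAssignment]:
    """Expand a chemical roster into the per-well treatment list (unplaced).

    Test and negative-control chemicals get 8 half-log concentrations x 2
    replicates; the viability control gets 6 log concentrations with the point
    nearest ``viability_triplicate_uM`` (1 µM by default) in triplicate.
    """
    slots: list[TreatmentAssignment] = []
    for chem_id, role, top in chemicals:
        role = Role(role)
        if role in (Role.TEST, Role.NEGATIVE):
            series = halflog_series(top, 8, chem_id)
            for c in series.concentrations_uM:
                slots.extend([TreatmentAssignment(chem_id, c, role)] * 2)
        elif role is Role.VIABILITY_CONTROL:
            series = log_series(top, 6, chem_id)
            conc = np.asarray(series.concentrations_uM)
            trip = int(np.argmin(np.abs(np.log10(conc) - np.log10(viability_triplicate_uM))))
            for i, c in enumerate(conc):
                n_rep = 3 if i == trip else 1
                slots.extend([TreatmentAssignment(chem_id, float(c), role)] * n_rep)
        else:
            raise ValueError(f"roster may not contain role {role}")
    slots.extend([VEHICLE] * n_vehicle)
    return slots


def _plate_rng(seed: int, plate_id: str) -> np.random.Generator:
    # distinct plate_ids spawn distinct streams under the same master seed
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(plate_id.encode())]))


def build_layout(
    chemicals: Sequence[tuple[str, Role | str, float]],
    plate_id: str,
    seed: int,
    no_edge_vehicle: bool = False,
) -> PlateLayout:
    """Fully randomized 384-well layout for a chemical roster.

    The roster must tile the plate exactly (e.g. 20 test + 2 negative chemicals
    at 16 wells each, 1 viability control at 8 wells, 24 vehicle wells = 384).
    With ``no_edge_vehicle`` the vehicle wells are restricted to interior
    coordinates; by default randomization is unrestricted.
    """
    slots = treatment_slots(chemicals)
    if len(slots) != PLATE_WELLS:
        raise LayoutInfeasibleError(
            f"roster fills {len(slots)} wells, plate has {PLATE_WELLS} "
            f"({'deficit' if len(slots) < PLATE_WELLS else 'excess'} of "
            f"{abs(PLATE_WELLS - len(slots))})"
        )
    rng = _plate_rng(seed, plate_id)
    wells = all_wells()
    if no_edge_vehicle:
        interior = _interior_wells()
        veh_wells = [wells[i] for i in rng.choice(
            [wells.index(w) for w in interior], size=N_VEHICLE_WELLS, replace=False)]
        rest = [w for w in wells if w not in set(veh_wells)]
        treated = [s for s in slots if s.role is not Role.VEHICLE]
        order = rng.permutation(len(treated))
        assignments = {w: VEHICLE for w in veh_wells}
        assignments.update({rest[i]: treated[j] for i, j in enumerate(order)})
    else:
        order = rng.permutation(len(slots))
        assignments = {wells[i]: slots[j] for i, j in enumerate(order)}
    assignments = {w: assignments[w] for w in wells}  # canonical A1..P24 order
    return PlateLayout(plate_id, assignments, seed)


def small_screen_layout(
    chemicals: Sequence[tuple[str, Role | str, float]],
    plate_id: str,
    seed: int,
    n_vehicle: int = N_VEHICLE_WELLS,
) -> PlateLayout:
    """Randomized layout for a reduced roster, occupying a subset of the plate.

    Intended for simulation studies that exercise the full analysis path at a
    fraction of full-screen cost; treatments are placed on a seeded random
    subset of well coordinates.
    """
    slots = treatment_slots(chemicals, n_vehicle=n_vehicle)
    if len(slots) > PLATE_WELLS:
        raise LayoutInfeasibleError(f"roster fills {len(slots)} wells > {PLATE_WELLS}")
    rng = _plate_rng(seed, plate_id)
    wells = all_wells()
    chosen = sorted(rng.choice(PLATE_WELLS, size=len(slots), replace=False))
    order = rng.permutation(len(slots))
    assignments = {wells[i]: slots[j] for i, j in zip(chosen, order)}
    return PlateLayout(plate_id, assignments, seed)
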
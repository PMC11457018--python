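"""Projection of restorable reef area from habitat-suitability maps.

Suitability models classify broad areas of an estuary as high / medium /
low suitability for oyster reef, but reefs are patchy: only a fraction of
a suitable area will actually carry reef.  That fraction is estimated per
suitability class by fitting, across grid cells where historical mapping
recorded oysters, the proportion p minimizing Σ(mapped_i − p·area_i)² —
a regression through the origin — and the restorable footprint of every
cell is then projected as p_high·area_high + p_medium·area_medium.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "SuitabilityCell",
    "RestorationFootprint",
    "fit_restorable_proportion",
    "project_restorable_area",
    "read_suitability_table",
    "write_suitability_table",
    "footprints_frame",
]


@dataclass(frozen=True)
class SuitabilityCell:
    """Per-cell suitability areas (m²) and optional mapped historical reef (m²)."""

    cell_id: str
    area_high: float = 0.0
    area_medium: float = 0.0
    mapped_oyster_area_high: Optional[float] = None
    mapped_oyster_area_medium: Optional[float] = None

    def __post_init__(self) -> None:
        if self.area_high < 0 or self.area_medium < 0:
            raise ValueError("suitability areas must be >= 0")
        for mapped, area, cls in (
            (self.mapped_oyster_area_high, self.area_high, "high"),
            (self.mapped_oyster_area_medium, self.area_medium, "medium"),
        ):
            if mapped is not None:
                if mapped < 0:
                    raise ValueError("mapped oyster areas must be >= 0")
                if mapped > area * (1 + 1e-9):
                    raise ValueError(
                        f"mapped oyster area exceeds {cls}-suitability area "
                        f"in cell {self.cell_id}"
                    )


@dataclass(frozen=True)
class RestorationFootprint:
    """Projected restored reef area (m²) in one grid cell."""

    cell_id: str
    reef_area: float

    def __post_init__(self) -> None:
        if self.reef_area < 0:
            raise ValueError("reef_area must be >= 0")


def fit_restorable_proportion(
    observations: Sequence[tuple[float, float]],
    method: str = "origin",
) -> float:
    """Fit the proportion of a suitability class actually covered by reef.

    ``observations`` pairs (suitability_area, mapped_oyster_area) per cell;
    cells where the historical mapping recorded no oysters should be
    excluded by the caller before fitting.

    method="origin" (default) is the least-squares slope through the
    origin, p = Σ(area·mapped)/Σ(area²); method="ratio-mean" averages the
    per-cell ratios mapped/area.  The result is clamped to [0, 1].
    """
    obs = np.asarray(observations, dtype=float)
    if obs.size == 0:
        raise ValueError("at least one observation is required")
    area, mapped = obs[:, 0], obs[:, 1]
    if np.any(area < 0) or np.any(mapped < 0):
        raise ValueError("areas must be >= 0")
    if not np.any(area > 0):
        raise ValueError("all suitability areas are zero; nothing to fit")
    if method == "origin":
        p = float(np.sum(area * mapped) / np.sum(area**2))
    elif method == "ratio-mean":
        pos = area > 0
        p = float(np.mean(mapped[pos] / area[pos]))
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(np.clip(p, 0.0, 1.0))


def project_restorable_area(
    cells: Iterable[SuitabilityCell],
    p_high: float,
    p_medium: float,
) -> list[RestorationFootprint]:
    """Project restorable reef area per cell: p_high·A_high + p_medium·A_medium.

    Cells whose projection is zero are retained with reef_area 0 so the
    candidate set stays aligned with the suitability table.
    """
    for name, p in (("p_high", p_high), ("p_medium", p_medium)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    return [
        RestorationFootprint(
            cell_id=c.cell_id,
            reef_area=p_high * c.area_high + p_medium * c.area_medium,
        )
        for c in cells
    ]


_SUIT_COLUMNS = ["cell_id", "area_high_m2", "area_medium_m2"]
_MAPPED_COLUMNS = ["mapped_high_m2", "mapped_medium_m2"]


def read_suitability_table(source: Union[str, Path]) -> list[SuitabilityCell]:
    """Read a suitability table (CSV: cell_id, area_high_m2, area_medium_m2
    and optionally mapped_high_m2, mapped_medium_m2)."""
    df = pd.read_csv(source)
    missing = [c for c in _SUIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"suitability table missing columns {missing}")
    has_mapped = all(c in df.columns for c in _MAPPED_COLUMNS)
    cells = []
    for r in df.itertuples():
        kwargs = {}
        if has_mapped:
            mh, mm = float(r.mapped_high_m2), float(r.mapped_medium_m2)
            kwargs = dict(
                mapped_oyster_area_high=None if np.isnan(mh) else mh,
                mapped_oyster_area_medium=None if np.isnan(mm) else mm,
            )
        cells.append(
            SuitabilityCell(
                cell_id=str(r.cell_id),
                area_high=float(r.area_high_m2),
                area_medium=float(r.area_medium_m2),
                **kwargs,
            )
        )
    return cells


def write_suitability_table(
    cells: Sequence[SuitabilityCell], dest: Union[str, Path]
) -> None:
    """Write a suitability table as CSV (mapped columns included when any present)."""
    data = {
        "cell_id": [c.cell_id for c in cells],
        "area_high_m2": [c.area_high for c in cells],
        "area_medium_m2": [c.area_medium for c in cells],
    }
    if any(
        c.mapped_oyster_area_high is not None
        or c.mapped_oyster_area_medium is not None
        for c in cells
    ):
        data["mapped_high_m2"] = [c.mapped_oyster_area_high for c in cells]
        data["mapped_medium_m2"] = [c.mapped_oyster_area_medium for c in cells]
    pd.DataFrame(data).to_csv(dest, index=False)


def footprints_frame(footprints: Sequence[RestorationFootprint]) -> pd.DataFrame:
    """Footprints as a DataFrame (cell_id, reef_area_m2)."""
    return pd.DataFrame(
        {
            "cell_id": [f.cell_id for f in footprints],
            "reef_area_m2": [f.reef_area for f in footprints],
        }
    )
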
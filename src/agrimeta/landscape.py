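"""Randomized transect sampling of categorical land-cover maps.

Maps are synthetic planar rasters (metric coordinates, no geodesy) carrying
a habitat label per cell and, for arable cells, a field-parcel id.  A study
region is sampled with five randomly placed 1-km line transects (no buffer)
that are not allowed to cross; three metrics are read off each transect:

- pct_arable: percent of transect length over arable field cells
- n_habitats: number of distinct habitat labels intersected
- avg_field_size: mean area (ha) of the distinct arable parcels intersected

and averaged over the transects of a region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely.geometry import LineString

from .io import StudyRecord

__all__ = [
    "HABITATS",
    "LandCoverMap",
    "StudyRegion",
    "Transect",
    "place_transects",
    "transect_metrics",
    "study_landscape_metrics",
    "impute_country_means",
    "write_map",
    "read_map",
]

HABITATS = (
    "field", "pasture", "forest", "wetland", "water", "rural", "urban", "line_element",
)
HABITAT_CODE = {name: i for i, name in enumerate(HABITATS)}
FIELD_CODE = HABITAT_CODE["field"]

TRANSECT_LENGTH = 1000.0  # metres
HALF_LENGTH = TRANSECT_LENGTH / 2.0
ORIENTATIONS = (0.0, 45.0, 90.0, 180.0)


@dataclass
class LandCoverMap:
    """Categorical raster with a parcel-id layer for arable cells.

    ``grid[row, col]`` holds a habitat code (see :data:`HABITAT_CODE`);
    ``parcels`` holds a positive parcel id wherever ``grid`` is arable and
    0 elsewhere.  Row 0 is the southern edge: world coordinates map as
    x = origin_x + col * cell_size, y = origin_y + row * cell_size.
    """

    grid: np.ndarray
    parcels: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int16)
        self.parcels = np.asarray(self.parcels, dtype=np.int32)
        if self.grid.shape != self.parcels.shape:
            raise ValueError("grid and parcel layers must have the same shape")
        if self.cell_size <= 0:
            raise ValueError("cell size must be > 0")
        field_mask = self.grid == FIELD_CODE
        if np.any(field_mask & (self.parcels <= 0)):
            raise ValueError("every arable cell must carry a parcel id")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        x0, y0 = self.origin
        h, w = self.grid.shape
        return (x0, y0, x0 + w * self.cell_size, y0 + h * self.cell_size)

    def parcel_areas_ha(self) -> dict[int, float]:
        ids, counts = np.unique(self.parcels[self.parcels > 0], return_counts=True)
        cell_ha = self.cell_size**2 / 1e4
        return {int(i): float(c) * cell_ha for i, c in zip(ids, counts)}

    def lookup(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Habitat codes and parcel ids at world coordinates; errors outside."""
        x0, y0 = self.origin
        col = np.floor((np.asarray(x) - x0) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y) - y0) / self.cell_size).astype(int)
        h, w = self.grid.shape
        if np.any((col < 0) | (col >= w) | (row < 0) | (row >= h)):
            raise ValueError("coordinates fall outside the map extent")
        return self.grid[row, col], self.parcels[row, col]


@dataclass
class StudyRegion:
    centre: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("region radius must be > 0")


@dataclass
class Transect:
    """A 1-km line: start point plus one of four drawn orientations."""

    start: tuple[float, float]
    orientation_deg: float

    def __post_init__(self) -> None:
        if self.orientation_deg not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")

    @property
    def endpoints(self) -> tuple[tuple[float, float], tuple[float, float]]:
        th = math.radians(self.orientation_deg)
        dx, dy = math.cos(th), math.sin(th)
        x, y = self.start
        return (
            (x - HALF_LENGTH * dx, y - HALF_LENGTH * dy),
            (x + HALF_LENGTH * dx, y + HALF_LENGTH * dy),
        )

    @property
    def line(self) -> LineString:
        return LineString(self.endpoints)


def place_transects(
    region: StudyRegion,
    k: int = 5,
    seed: int | np.random.Generator = 0,
    *,
    max_attempts: int = 10_000,
) -> list[Transect]:
    """Draw k non-crossing transects in a study region, deterministically.

    Each candidate is defined by three random numbers: a distance from the
    region centre (uniform on [0, radius]), a bearing (uniform on [0, 360)
    degrees) placing the start point, and an orientation drawn uniformly
    from {0, 45, 90, 180} degrees.  Candidates whose full 1-km segment
    intersects an accepted transect (shared endpoints count as crossing)
    are rejected and redrawn.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cx, cy = region.centre
    accepted: list[Transect] = []
    attempts = 0
    while len(accepted) < k:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {k} non-crossing transects in {max_attempts} "
                "attempts; try a larger region radius"
            )
        attempts += 1
        d = rng.uniform(0.0, region.radius)
        bearing = math.radians(rng.uniform(0.0, 360.0))
        orientation = float(ORIENTATIONS[rng.integers(0, len(ORIENTATIONS))])
        cand = Transect(
            start=(cx + d * math.cos(bearing), cy + d * math.sin(bearing)),
            orientation_deg=orientation,
        )
        line = cand.line
        if any(line.intersects(t.line) for t in accepted):
            continue
        accepted.append(cand)
    return accepted


def transect_metrics(
    transect: Transect, lc_map: LandCoverMap, *, step: float = 1.0
) -> dict:
    """Metrics for one transect, by discretising the line at ``step``-metre
    intervals (midpoint sampling, so segment lengths sum to exactly 1 km)."""
    (x1, y1), (x2, y2) = transect.endpoints
    n_steps = int(round(TRANSECT_LENGTH / step))
    t = (np.arange(n_steps) + 0.5) / n_steps
    xs = x1 + (x2 - x1) * t
    ys = y1 + (y2 - y1) * t
    try:
        codes, parcel_ids = lc_map.lookup(xs, ys)
    except ValueError as exc:
        raise ValueError("transect exits the map extent") from exc

    lengths = {
        HABITATS[code]: float(cnt) * step
        for code, cnt in zip(*np.unique(codes, return_counts=True))
    }
    field_len = lengths.get("field", 0.0)
    pct_arable = 100.0 * field_len / TRANSECT_LENGTH

    hit_parcels = set(int(pid) for pid in parcel_ids[codes == FIELD_CODE])
    if hit_parcels:
        areas = lc_map.parcel_areas_ha()
        avg_field_size = float(np.mean([areas[p] for p in hit_parcels]))
    else:
        avg_field_size = math.nan

    return {
        "pct_arable": pct_arable,
        "n_habitats": len(lengths),
        "avg_field_size": avg_field_size,
        "segment_lengths": lengths,
    }


def study_landscape_metrics(
    region: StudyRegion,
    lc_map: LandCoverMap,
    k: int = 5,
    seed: int | np.random.Generator = 0,
    *,
    step: float = 1.0,
) -> dict:
    """Arithmetic mean of the three metrics over k random transects."""
    transects = place_transects(region, k=k, seed=seed)
    per = [transect_metrics(t, lc_map, step=step) for t in transects]
    sizes = [m["avg_field_size"] for m in per if not math.isnan(m["avg_field_size"])]
    return {
        "pct_arable": float(np.mean([m["pct_arable"] for m in per])),
        "n_habitats": float(np.mean([m["n_habitats"] for m in per])),
        "avg_field_size": float(np.mean(sizes)) if sizes else math.nan,
        "transects": transects,
        "per_transect": per,
    }


def impute_country_means(records: Sequence[StudyRecord]) -> list[StudyRecord]:
    """Fill missing landscape covariates with per-country donor means.

    Records that already carry the full covariate triple are returned
    unchanged; incomplete ones receive the mean of all complete records
    from the same country and are flagged as imputed.
    """
    donors: dict[str, list[StudyRecord]] = {}
    for rec in records:
        if rec.has_landscape():
            donors.setdefault(rec.country, []).append(rec)
    out: list[StudyRecord] = []
    for rec in records:
        if rec.has_landscape():
            out.append(rec)
            continue
        pool = donors.get(rec.country)
        if not pool:
            raise ValueError(
                f"no donor records with landscape covariates in country {rec.country!r}"
            )
        out.append(
            replace(
                rec,
                pct_arable=float(np.mean([d.pct_arable for d in pool])),
                n_habitats=float(np.mean([d.n_habitats for d in pool])),
                avg_field_size=float(np.mean([d.avg_field_size for d in pool])),
                landscape_imputed=True,
            )
        )
    return out


def write_map(lc_map: LandCoverMap, path: str | Path) -> None:
    """Serialise a map as plain text: a header line then two integer grids."""
    h, w = lc_map.grid.shape
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(
            f"landcover {h} {w} {lc_map.cell_size} "
            f"{lc_map.origin[0]} {lc_map.origin[1]}\n"
        )
        for layer in (lc_map.grid, lc_map.parcels):
            for row in layer:
                fh.write(" ".join(str(int(x)) for x in row) + "\n")


def read_map(path: str | Path) -> LandCoverMap:
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline().split()
        if not header or header[0] != "landcover":
            raise ValueError("not a landcover map file")
        h, w = int(header[1]), int(header[2])
        cell = float(header[3])
        origin = (float(header[4]), float(header[5]))
        data = np.loadtxt(fh, dtype=int, max_rows=2 * h)
    if data.shape != (2 * h, w):
        raise ValueError("map payload does not match header dimensions")
    return LandCoverMap(grid=data[:h], parcels=data[h:], cell_size=cell, origin=origin)
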
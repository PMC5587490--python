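"""Pentad-grid conventions, spherical geometry, and tabular/geographic I/O.

The atlas sampling unit is the *pentad*: a grid cell spanning 5 minutes of
latitude by 5 minutes of longitude.  A pentad is named by its north-west
corner, written as degrees and minutes of south latitude followed by degrees
and minutes of east longitude, e.g. ``"3355_1825"`` for the cell whose NW
corner sits at 33°55'S, 18°25'E.  Coordinates throughout the package are
decimal degrees with south and west negative; cells are half-open toward the
south-east, i.e. a cell contains its NW corner and extends 5' south and 5'
east of it.  The cell midpoint is the corner shifted 2.5' south and 2.5'
east.

Distances are great-circle distances on a sphere of radius 6371.0 km.  No
ellipsoid correction is applied: distances enter the downstream models only
through a log transform, so the sub-0.3% spherical error is immaterial.

Roads are consumed as densified polyline vertex lists (the caller is expected
to supply vertices spaced <= 1 km apart); point-to-segment projection is
deliberately not implemented, bounding the distance error by half the vertex
spacing.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

#: arc-minutes per cell edge
CELL_MINUTES = 5
#: cells per degree along each axis
CELLS_PER_DEGREE = 60 // CELL_MINUTES

_CODE_RE = re.compile(r"^(\d{2})(\d{2})_(\d{2,3})(\d{2})$")

CLIMATE_COLUMNS = ("precip", "t_summer", "t_winter")
COVER_COLUMNS = ("protected", "urban", "cultivated")
DISTANCE_COLUMNS = ("dist_hub_km", "dist_road_km")
BIOME_PREFIX = "biome_"


class PentadFormatError(ValueError):
    """A pentad code does not follow the ddmm_dddmm convention."""


@dataclass(frozen=True)
class PentadCode:
    """A resolved pentad: its code and NW-corner / midpoint coordinates."""

    code: str
    lat_min: float  # NW corner latitude, decimal degrees (negative = south)
    lon_min: float  # NW corner longitude, decimal degrees (positive = east)

    @property
    def midpoint_lat(self) -> float:
        return self.lat_min - 2.5 / 60.0

    @property
    def midpoint_lon(self) -> float:
        return self.lon_min + 2.5 / 60.0

    @property
    def row(self) -> int:
        """Grid row index: number of 5' steps south of the equator."""
        return int(round(-self.lat_min * CELLS_PER_DEGREE))

    @property
    def col(self) -> int:
        """Grid column index: number of 5' steps east of the prime meridian."""
        return int(round(self.lon_min * CELLS_PER_DEGREE))


def decode_pentad(code: str) -> PentadCode:
    """Resolve a pentad code to its NW corner and midpoint.

    The latitude field is ``ddmm`` of south latitude; the longitude field is
    ``ddmm`` (or ``dddmm`` east of 100°E) of east longitude.

    Raises
    ------
    PentadFormatError
        If the code does not match the pattern or a minutes field is not a
        multiple of 5 below 60.
    """
    if not isinstance(code, str):
        raise PentadFormatError(f"pentad code must be a string, got {type(code)!r}")
    m = _CODE_RE.match(code)
    if m is None:
        raise PentadFormatError(
            f"pentad code {code!r} does not match the ddmm_dddmm pattern"
        )
    lat_deg, lat_min_, lon_deg, lon_min_ = (int(g) for g in m.groups())
    for name, minutes in (("latitude", lat_min_), ("longitude", lon_min_)):
        if minutes >= 60 or minutes % CELL_MINUTES != 0:
            raise PentadFormatError(
                f"pentad code {code!r}: {name} minutes field {minutes:02d} is not "
                f"a multiple of {CELL_MINUTES} below 60"
            )
    if lat_deg >= 90:
        raise PentadFormatError(f"pentad code {code!r}: latitude degrees >= 90")
    lat = -(lat_deg + lat_min_ / 60.0)
    lon = lon_deg + lon_min_ / 60.0
    return PentadCode(code=encode_code_string(lat, lon), lat_min=lat, lon_min=lon)


def encode_code_string(lat: float, lon: float) -> str:
    """Canonical code string for the cell containing (lat, lon).

    ``lat`` must be <= 0 (southern hemisphere or equator), ``lon`` >= 0.
    Cells are half-open toward the south-east, so a cell's NW corner maps to
    that cell.
    """
    if lat > 0 or lon < 0:
        raise PentadFormatError(
            f"coordinates ({lat}, {lon}) fall outside the south-east quadrant "
            "grid (need lat <= 0 and lon >= 0)"
        )
    # guard against representation error exactly at cell corners
    i = int(np.floor(-lat * CELLS_PER_DEGREE + 1e-9))
    j = int(np.floor(lon * CELLS_PER_DEGREE + 1e-9))
    lat_deg, lat_cells = divmod(i, CELLS_PER_DEGREE)
    lon_deg, lon_cells = divmod(j, CELLS_PER_DEGREE)
    lon_fmt = f"{lon_deg:03d}" if lon_deg >= 100 else f"{lon_deg:02d}"
    return f"{lat_deg:02d}{lat_cells * CELL_MINUTES:02d}_{lon_fmt}{lon_cells * CELL_MINUTES:02d}"


def encode_pentad(lat: float, lon: float) -> PentadCode:
    """Return the pentad containing the point (lat, lon)."""
    return decode_pentad(encode_code_string(lat, lon))


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km (sphere of radius 6371.0 km); vectorized."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    if np.ndim(d) == 0:
        return float(d)
    return d


def min_distance_km(pentad: PentadCode, landmarks: Sequence[tuple[float, float]]) -> float:
    """Minimum great-circle distance from the pentad midpoint to any landmark.

    ``landmarks`` is a non-empty sequence of (lat, lon) pairs; for roads these
    are densified polyline vertices.
    """
    pts = np.asarray(landmarks, dtype=float)
    if pts.size == 0:
        raise ValueError("landmark set is empty")
    pts = pts.reshape(-1, 2)
    d = haversine_km(pentad.midpoint_lat, pentad.midpoint_lon, pts[:, 0], pts[:, 1])
    return float(np.min(d))


# ---------------------------------------------------------------------------
# checklist table
# ---------------------------------------------------------------------------


class ChecklistTable:
    """Visit-level species lists keyed by pentad code.

    One row per visit: ``(pentad, visit_id, species)`` with ``species`` a
    non-empty frozenset of species identifiers.  Visit ids are unique across
    the table.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.reset_index(drop=True)
        expected = ["pentad", "visit_id", "species"]
        if list(frame.columns) != expected and set(frame.columns) >= set(expected):
            frame = frame[expected]
        elif list(frame.columns) != expected:
            raise ValueError(f"checklist frame must have columns {expected}")
        if frame["visit_id"].duplicated().any():
            dupes = frame.loc[frame["visit_id"].duplicated(), "visit_id"].unique()
            raise ValueError(f"duplicate visit_id values: {list(dupes[:5])}")
        for i, sp in enumerate(frame["species"]):
            if not isinstance(sp, frozenset):
                frame.at[i, "species"] = frozenset(sp)
            if len(frame.at[i, "species"]) == 0:
                raise ValueError(f"row {i}: species set is empty")
        for i, code in enumerate(frame["pentad"]):
            try:
                decode_pentad(code)
            except PentadFormatError as exc:
                raise PentadFormatError(f"row {i}: {exc}") from exc
        self.frame = frame

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, Iterable[str]]]
    ) -> "ChecklistTable":
        rows = [(p, v, frozenset(s)) for p, v, s in records]
        return cls(pd.DataFrame(rows, columns=["pentad", "visit_id", "species"]))

    def __len__(self) -> int:
        return len(self.frame)

    def lists_per_pentad(self) -> pd.Series:
        """Number of contributed lists (visits) per pentad."""
        return self.frame.groupby("pentad").size()

    def species_by_pentad(self) -> dict[str, frozenset]:
        """Union of species recorded across all of a pentad's lists."""
        out: dict[str, frozenset] = {}
        for pentad, grp in self.frame.groupby("pentad"):
            out[pentad] = frozenset().union(*grp["species"])
        return out


def read_checklists(path) -> ChecklistTable:
    """Read a checklist CSV: header ``pentad,visit_id,species``, species
    ``;``-joined."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = ["pentad", "visit_id", "species"]
    if list(df.columns) != expected:
        raise ValueError(
            f"{path}: expected header {','.join(expected)}, got {','.join(df.columns)}"
        )
    rows = []
    for i, rec in enumerate(df.itertuples(index=False)):
        species = frozenset(s for s in rec.species.split(";") if s)
        if not species:
            raise ValueError(f"{path}: row {i + 2}: empty species field")
        try:
            decode_pentad(rec.pentad)
        except PentadFormatError as exc:
            raise PentadFormatError(f"{path}: row {i + 2}: {exc}") from exc
        rows.append((rec.pentad, rec.visit_id, species))
    return ChecklistTable.from_records(rows)


def write_checklists(table: ChecklistTable, path) -> None:
    """Write a checklist CSV with deterministic (pentad, visit_id) row order."""
    df = table.frame.copy()
    df["species"] = df["species"].map(lambda s: ";".join(sorted(s)))
    df = df.sort_values(["pentad", "visit_id"], kind="mergesort")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# covariate table
# ---------------------------------------------------------------------------


class PentadCovariates:
    """Per-pentad climate, cover, distance and biome-fraction attributes.

    Wraps a DataFrame indexed by pentad code with columns
    ``precip`` (mm/yr), ``t_summer``/``t_winter`` (°C),
    ``protected``/``urban``/``cultivated`` (fractions in [0, 1]),
    ``biome_<label>`` fraction columns, and optionally ``dist_hub_km`` /
    ``dist_road_km``.  Missing distance columns set :attr:`needs_distances`.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if frame.index.name != "pentad":
            if "pentad" in frame.columns:
                frame = frame.set_index("pentad")
            else:
                raise ValueError("covariate frame needs a 'pentad' index or column")
        if frame.index.duplicated().any():
            dupes = frame.index[frame.index.duplicated()].unique()
            raise ValueError(f"duplicated pentad rows: {list(dupes[:5])}")
        for code in frame.index:
            decode_pentad(code)
        missing = [c for c in CLIMATE_COLUMNS + COVER_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"covariate table missing columns: {missing}")
        for col in COVER_COLUMNS:
            vals = frame[col].to_numpy(dtype=float)
            if np.any((vals < 0) | (vals > 1)):
                bad = frame.index[(vals < 0) | (vals > 1)][0]
                raise ValueError(f"{col} outside [0, 1] at pentad {bad}")
        biome_cols = self.biome_columns(frame)
        if biome_cols:
            fr = frame[biome_cols].to_numpy(dtype=float)
            if np.any((fr < 0) | (fr > 1)):
                raise ValueError("biome fractions outside [0, 1]")
            if np.any(fr.sum(axis=1) > 1 + 1e-6):
                bad = frame.index[fr.sum(axis=1) > 1 + 1e-6][0]
                raise ValueError(f"biome fractions sum above 1 at pentad {bad}")
        for col in DISTANCE_COLUMNS:
            if col in frame.columns and (frame[col].to_numpy(dtype=float) < 0).any():
                raise ValueError(f"{col} contains negative distances")
        self.frame = frame

    @staticmethod
    def biome_columns(frame: pd.DataFrame) -> list[str]:
        return [c for c in frame.columns if c.startswith(BIOME_PREFIX)]

    @property
    def needs_distances(self) -> bool:
        """True if hub/road distance columns must still be derived."""
        return any(c not in self.frame.columns for c in DISTANCE_COLUMNS)

    @property
    def biome_fractions(self) -> pd.DataFrame:
        cols = self.biome_columns(self.frame)
        out = self.frame[cols].copy()
        out.columns = [c[len(BIOME_PREFIX):] for c in cols]
        return out

    def pentads(self) -> list[PentadCode]:
        return [decode_pentad(c) for c in self.frame.index]

    def midpoints(self) -> np.ndarray:
        """(n, 2) array of midpoint (lat, lon) in pentad order."""
        return np.array(
            [(p.midpoint_lat, p.midpoint_lon) for p in self.pentads()], dtype=float
        )

    def with_distances(
        self,
        hubs: Sequence[tuple[float, float]],
        road_vertices: Sequence[tuple[float, float]],
    ) -> "PentadCovariates":
        """Return a copy with hub/road midpoint distances filled in."""
        mids = self.midpoints()
        frame = self.frame.copy()
        for col, pts in (("dist_hub_km", hubs), ("dist_road_km", road_vertices)):
            pts_arr = np.asarray(pts, dtype=float).reshape(-1, 2)
            if pts_arr.size == 0:
                raise ValueError(f"no landmarks supplied for {col}")
            d = np.empty(len(mids))
            for k in range(len(mids)):
                d[k] = np.min(
                    haversine_km(mids[k, 0], mids[k, 1], pts_arr[:, 0], pts_arr[:, 1])
                )
            frame[col] = d
        return PentadCovariates(frame)

    def __len__(self) -> int:
        return len(self.frame)


def read_covariates(path) -> PentadCovariates:
    df = pd.read_csv(path)
    if "pentad" not in df.columns:
        raise ValueError(f"{path}: missing 'pentad' column")
    return PentadCovariates(df)


def write_covariates(cov: PentadCovariates, path) -> None:
    cov.frame.sort_index().to_csv(path, index_label="pentad")


# ---------------------------------------------------------------------------
# GeoJSON export
# ---------------------------------------------------------------------------


def pentads_to_geojson(
    codes: Sequence[str], properties: Mapping[str, Mapping[str, object]] | pd.DataFrame | None = None
) -> dict:
    """Build an RFC 7946 FeatureCollection of pentad polygons (lon-lat order).

    ``properties`` maps pentad code -> property dict (or a DataFrame indexed
    by pentad).
    """
    if isinstance(properties, pd.DataFrame):
        properties = properties.to_dict(orient="index")
    features = []
    step = CELL_MINUTES / 60.0
    for code in codes:
        p = decode_pentad(code)
        lat0, lon0 = p.lat_min, p.lon_min
        ring = [
            [lon0, lat0],
            [lon0 + step, lat0],
            [lon0 + step, lat0 - step],
            [lon0, lat0 - step],
            [lon0, lat0],
        ]
        props = {"pentad": code}
        if properties and code in properties:
            props.update(properties[code])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_geojson(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj))


def read_landmarks_geojson(path) -> dict:
    """Read hub/road landmarks from a GeoJSON FeatureCollection.

    Returns ``{"hubs": [(lat, lon), ...], "roads": [(lat, lon), ...]}`` where
    Point features with ``kind == "hub"`` (or no kind) are hubs and
    LineString features are road polylines (vertices pooled).
    """
    data = json.loads(Path(path).read_text())
    hubs: list[tuple[float, float]] = []
    roads: list[tuple[float, float]] = []
    for feat in data.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") == "Point":
            lon, lat = geom["coordinates"]
            hubs.append((lat, lon))
        elif geom.get("type") == "LineString":
            roads.extend((lat, lon) for lon, lat in geom["coordinates"])
    return {"hubs": hubs, "roads": roads}
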
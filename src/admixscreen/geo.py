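"""Geographic optimality metrics for qpAdm model tables on real maps.

Applies the source-target distance / source-target-source angle framework
to models whose groups carry latitude/longitude coordinates: great-circle
distances between group centroids, angles between initial bearings at the
target, and the same downstream classification and binning layer used on
simulated landscapes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import OptimalityMetrics

EARTH_RADIUS_KM = 6371.0
#: source-target distances at or below this are treated as zero, with the
#: corresponding angles undefined
NEGLIGIBLE_KM = 50.0


def mean_center(points) -> tuple[float, float]:
    """Planar mean of (lat, lon) points (arithmetic per coordinate)."""
    pts = list(points)
    if not pts:
        raise ValueError("empty coordinate list")
    lats = [p[0] for p in pts]
    lons = [p[1] for p in pts]
    return float(np.mean(lats)), float(np.mean(lons))


def great_circle_distance(a, b) -> float:
    """Haversine distance in km (Earth radius 6371 km)."""
    lat1, lon1, lat2, lon2 = map(math.radians, (*a, *b))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = (
        math.sin(dlat / 2) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def initial_bearing(a, b) -> float:
    """Initial bearing from a to b in degrees clockwise from north."""
    lat1, lon1, lat2, lon2 = map(math.radians, (*a, *b))
    dlon = lon2 - lon1
    x = math.sin(dlon) * math.cos(lat2)
    y = math.cos(lat1) * math.sin(lat2) - math.sin(lat1) * math.cos(
        lat2
    ) * math.cos(dlon)
    return math.degrees(math.atan2(x, y)) % 360.0


@dataclass
class GeoModelRecord:
    """One qpAdm model with per-group coordinates (real-data table row)."""

    target: str
    target_coords: list  # [(lat, lon), ...] per individual
    sources: list[str]
    source_coords: list  # list of per-source coordinate lists
    eaf: list[float]
    se: list[float]
    p_value: float

    @property
    def n_way(self) -> int:
        return len(self.sources)

    def __post_init__(self):
        for lat, lon in self.target_coords + [
            c for sc in self.source_coords for c in sc
        ]:
            if not (-90 <= lat <= 90 and -180 <= lon <= 180):
                raise ValueError(f"coordinate out of range: {(lat, lon)}")
        if not 2 <= self.n_way <= 4:
            raise ValueError("model complexity must be 2-4")


def geo_model_metrics(record: GeoModelRecord) -> OptimalityMetrics:
    """Spatial metrics of one model in km / degrees.

    Distances at or below 50 km count as 0 and exclude the source from the
    angle computation; a model containing such a source has an undefined
    minimal angle.
    """
    t_cent = mean_center(record.target_coords)
    cents = [mean_center(sc) for sc in record.source_coords]
    dists = [great_circle_distance(t_cent, c) for c in cents]
    dists = [0.0 if d <= NEGLIGIBLE_KM else d for d in dists]
    if any(d == 0.0 for d in dists):
        angle = None
    else:
        bearings = [initial_bearing(t_cent, c) for c in cents]
        angle = 180.0
        for i in range(len(bearings)):
            for j in range(i + 1, len(bearings)):
                diff = abs(bearings[i] - bearings[j]) % 360.0
                angle = min(angle, 360.0 - diff if diff > 180.0 else diff)
    return OptimalityMetrics(
        n_way=record.n_way,
        max_st=max(dists),
        avg_st=float(np.mean(dists)),
        min_angle=angle,
    )


# ---------------------------------------------------------------------------
# model table I/O and synthetic fixtures
# ---------------------------------------------------------------------------

TABLE_COLUMNS = [
    "target",
    "target_coords",
    "sources",
    "source_coords",
    "eaf",
    "se",
    "p_value",
]


def read_model_table(path) -> list[GeoModelRecord]:
    """Read a TSV of model records (coordinate lists JSON-encoded)."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        records.append(
            GeoModelRecord(
                target=row["target"],
                target_coords=[tuple(c) for c in json.loads(row["target_coords"])],
                sources=json.loads(row["sources"]),
                source_coords=[
                    [tuple(c) for c in sc] for sc in json.loads(row["source_coords"])
                ],
                eaf=json.loads(row["eaf"]),
                se=json.loads(row["se"]),
                p_value=float(row["p_value"]),
            )
        )
    return records


def write_model_table(records, path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "target": r.target,
                "target_coords": json.dumps([list(c) for c in r.target_coords]),
                "sources": json.dumps(list(r.sources)),
                "source_coords": json.dumps(
                    [[list(c) for c in sc] for sc in r.source_coords]
                ),
                "eaf": json.dumps(list(r.eaf)),
                "se": json.dumps(list(r.se)),
                "p_value": r.p_value,
            }
        )
    pd.DataFrame(rows, columns=TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def synthetic_model_table(
    n_models: int = 50,
    seed: int = 0,
    region=(35.0, 60.0, -10.0, 60.0),
    n_way: int = 2,
) -> list[GeoModelRecord]:
    """Generate a synthetic table of geographically located models.

    Emulates the structure of published high-throughput screen tables
    (groups scattered over a bounded region, a few individuals per group)
    with controllable geometry; the genetics columns are random placeholders.
    """
    rng = np.random.default_rng(seed)
    lat0, lat1, lon0, lon1 = region
    records = []
    for k in range(n_models):
        def cluster():
            lat = rng.uniform(lat0, lat1)
            lon = rng.uniform(lon0, lon1)
            n = int(rng.integers(1, 5))
            return [
                (
                    float(np.clip(lat + rng.normal(0, 0.3), -90, 90)),
                    float(np.clip(lon + rng.normal(0, 0.3), -180, 180)),
                )
                for _ in range(n)
            ]
        w = rng.dirichlet(np.ones(n_way))
        records.append(
            GeoModelRecord(
                target=f"T{k}",
                target_coords=cluster(),
                sources=[f"S{k}_{i}" for i in range(n_way)],
                source_coords=[cluster() for _ in range(n_way)],
                eaf=[float(x) for x in w],
                se=[float(abs(rng.normal(0, 0.05))) for _ in range(n_way)],
                p_value=float(rng.uniform()),
            )
        )
    return records
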
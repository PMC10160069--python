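"""Spherical geometry helpers shared across the pipeline.

Distances between observations and grid cells are great-circle arcs; the
neighbourhood radius of the kriging step ("0.5 degrees spherical distance")
is interpreted as a great-circle arc of 0.5 degrees.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius
KM_PER_ARC_DEG = EARTH_RADIUS_KM * np.pi / 180.0


def arc_deg(lon1, lat1, lon2, lat2):
    """Great-circle central angle between points, in degrees (haversine)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return np.degrees(2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0))))


def arc_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km."""
    return arc_deg(lon1, lat1, lon2, lat2) * KM_PER_ARC_DEG


def unit_vectors(lon, lat):
    """(n, 3) Cartesian unit vectors for lon/lat in degrees."""
    lon = np.radians(np.atleast_1d(np.asarray(lon, dtype=float)))
    lat = np.radians(np.atleast_1d(np.asarray(lat, dtype=float)))
    return np.column_stack(
        (np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat))
    )


def chord_length(angle_deg: float) -> float:
    """Chord length on the unit sphere subtending a central angle (degrees)."""
    return 2.0 * np.sin(np.radians(angle_deg) / 2.0)


def densify_polyline(vertices: np.ndarray, step_deg: float = 0.02) -> np.ndarray:
    """Insert points along polyline segments so no gap exceeds ``step_deg``."""
    vertices = np.asarray(vertices, dtype=float)
    pts = []
    for (lon0, lat0), (lon1, lat1) in zip(vertices[:-1], vertices[1:]):
        seg_len = max(abs(lon1 - lon0), abs(lat1 - lat0))
        n = max(int(np.ceil(seg_len / step_deg)), 1)
        t = np.linspace(0.0, 1.0, n, endpoint=False)
        pts.append(np.column_stack((lon0 + t * (lon1 - lon0), lat0 + t * (lat1 - lat0))))
    pts.append(vertices[-1:])
    return np.vstack(pts)


def dist_to_coast_km(lon, lat, coastline) -> np.ndarray:
    """Great-circle distance (km) to the nearest point on the coastline polyline.

    The polyline is densified before the nearest-vertex search, so segment
    interiors are represented to ~2 km.
    """
    coastline = np.asarray(coastline, dtype=float)
    if coastline.ndim != 2 or coastline.shape[0] < 2:
        raise ValueError("coastline must be a polyline with at least 2 vertices")
    dense = densify_polyline(coastline)
    v_pts = unit_vectors(lon, lat)
    v_coast = unit_vectors(dense[:, 0], dense[:, 1])
    # chord distance is monotone in arc; min chord == min arc
    cos_angle = np.clip(v_pts @ v_coast.T, -1.0, 1.0)
    best = np.max(cos_angle, axis=1)
    d = np.degrees(np.arccos(best)) * KM_PER_ARC_DEG
    return d if np.ndim(lon) else float(d[0])
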
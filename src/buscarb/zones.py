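"""Offshore boundary of the upwelling zone from cross-shelf pCO2 variability.

Upwelling systems show the highest and most variable pCO2 nearshore, where
carbon-rich water reaches the surface, and a declining trend offshore. A
drop in pCO2 variability therefore marks the waning influence of upwelling:
the zone's offshore boundary is taken as the distance from shore where the
per-bin standard deviation of pCO2 falls persistently below a threshold
(default +-30 uatm), evaluated on a fixed-width (10 km) binning of coastal
distance. The upwelling area follows as

    area = |lat_max - lat_min| * 111.0 km/deg * boundary_km
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

KM_PER_DEG_LAT = 111.0  # exactly; reproduces the reference subsystem areas


def cross_shelf_profile(records: pd.DataFrame, bin_km: float = 10.0, value_col: str = "pco2") -> pd.DataFrame:
    """Bin records by distance to coast; arithmetic mean and sample s.d. per
    bin. Empty bins are omitted; s.d. is NaN where n < 2.

    Returns a DataFrame with columns dist_center_km, mean, sd, n, ordered by
    distance.
    """
    d = records["dist_coast_km"].to_numpy(dtype=float)
    v = records[value_col].to_numpy(dtype=float)
    finite = np.isfinite(d) & np.isfinite(v)
    if not np.any(finite):
        raise ValueError("no records with finite coastal distance")
    d, v = d[finite], v[finite]
    idx = (d / bin_km).astype(int)
    rows = []
    for b in np.unique(idx):
        vals = v[idx == b]
        rows.append(
            {
                "dist_center_km": (b + 0.5) * bin_km,
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if vals.size >= 2 else np.nan,
                "n": int(vals.size),
            }
        )
    prof = pd.DataFrame(rows).sort_values("dist_center_km", ignore_index=True)
    prof.attrs["bin_km"] = bin_km
    return prof


@dataclass
class BoundaryResult:
    boundary_km: float  # outer edge of the first persistently-quiet bin
    converged: bool  # False when no bin satisfies the persistence rule


def detect_offshore_boundary(profile: pd.DataFrame, sd_threshold: float = 30.0) -> BoundaryResult:
    """First bin from which the s.d. stays below the threshold.

    "Persistently" means: this bin and every subsequent bin with a defined
    s.d. are below ``sd_threshold`` (a trailing data-free bin does not break
    persistence). The boundary is reported at the bin's outer edge. When no
    bin qualifies, the outermost bin edge is returned, flagged not
    converged.
    """
    bin_km = profile.attrs.get("bin_km", 10.0)
    sd = profile["sd"].to_numpy(dtype=float)
    dist = profile["dist_center_km"].to_numpy(dtype=float)
    defined = np.isfinite(sd)
    if defined.sum() < 3:
        raise ValueError("at least 3 bins with defined s.d. required")
    below = sd < sd_threshold
    ok = np.ones(len(sd), dtype=bool)
    # suffix-and over defined bins: quiet from here on out
    acc = True
    for i in range(len(sd) - 1, -1, -1):
        if defined[i]:
            acc = acc and below[i]
        ok[i] = acc
    candidates = np.nonzero(ok & defined)[0]
    if candidates.size == 0:
        return BoundaryResult(float(dist[-1] + bin_km / 2.0), False)
    edge = dist[candidates[0]] + bin_km / 2.0
    return BoundaryResult(float(edge), True)


def compute_area(lat_min: float, lat_max: float, boundary_km: float, km_per_deg: float = KM_PER_DEG_LAT) -> float:
    """Upwelling area (km^2) of a latitude band extending ``boundary_km``
    offshore."""
    if lat_max < lat_min:
        raise ValueError("lat_max must not be below lat_min")
    if boundary_km <= 0:
        raise ValueError("boundary_km must be > 0")
    return abs(lat_max - lat_min) * km_per_deg * boundary_km


@dataclass
class UpwellingZone:
    """A subsystem's upwelling zone: latitude band x offshore extent."""

    name: str
    lat_min: float
    lat_max: float
    boundary_km: float
    sd_threshold: float = 30.0

    @property
    def area_km2(self) -> float:
        return compute_area(self.lat_min, self.lat_max, self.boundary_km)

    def contains(self, lat, dist_coast_km):
        """Boolean mask of points inside the zone."""
        lat = np.asarray(lat, dtype=float)
        d = np.asarray(dist_coast_km, dtype=float)
        return (lat >= self.lat_min) & (lat < self.lat_max) & (d <= self.boundary_km)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "lat_min": self.lat_min,
            "lat_max": self.lat_max,
            "boundary_km": self.boundary_km,
            "sd_threshold_uatm": self.sd_threshold,
            "area_km2": self.area_km2,
        }
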
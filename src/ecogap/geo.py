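"""Great-circle geometry helpers on a spherical Earth.

All coordinates are decimal degrees WGS84; longitudes are normalised to
[-180, 180]. Distances use the haversine formula with R = 6371 km; "arc-minute"
buffers and tolerances throughout the package are angular distances, i.e. the
central angle of the great circle between two points, expressed in minutes.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0
#: Length of one degree of a great circle (meridian degree), km.
KM_PER_DEGREE = EARTH_RADIUS_KM * np.pi / 180.0


def normalize_lon(lon):
    """Wrap longitudes into [-180, 180]."""
    lon = np.asarray(lon, dtype=float)
    out = ((lon + 180.0) % 360.0) - 180.0
    # keep +180 as +180 rather than -180
    out = np.where((lon == 180.0) | (out == -180.0) & (lon > 0), 180.0, out)
    return out if out.ndim else float(out)


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km; accepts scalars or broadcastable arrays."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if np.ndim(d) else float(d)


def angular_arcmin(lat1, lon1, lat2, lon2):
    """Great-circle central angle between two points, in arc-minutes."""
    km = haversine_km(lat1, lon1, lat2, lon2)
    return np.asarray(km) / KM_PER_DEGREE * 60.0 if np.ndim(km) else km / KM_PER_DEGREE * 60.0


def km_to_degrees(km: float, mean_lat: float) -> float:
    """Convert a great-circle distance to E-W degrees at ``mean_lat``.

    One degree of longitude spans ``KM_PER_DEGREE * cos(lat)`` km; this is the
    conversion used for thinning-grid cell sizes and hull buffers.
    """
    c = np.cos(np.radians(mean_lat))
    if c <= 0:
        raise ValueError("mean latitude too close to the pole for a degree conversion")
    return float(km / (KM_PER_DEGREE * c))
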
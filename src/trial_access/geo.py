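"""Spherical access metrics: haversine distances, nearest-facility search and
excess-distance decomposition.

All coordinates are WGS84 decimal degrees (lon, lat).  Distances are
great-circle kilometres on a sphere of radius :data:`EARTH_RADIUS_KM` (the
IUGG mean Earth radius).  Travel times come from a pluggable provider; the
default is a constant-speed model over the great-circle distance and its
output is labelled as such in summaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Protocol

import numpy as np
import pandas as pd

#: IUGG mean Earth radius in kilometres.
EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable arrays.  Symmetric, non-negative, and
    clamped so antipodal rounding noise cannot produce NaN.

    Raises
    ------
    ValueError
        If any input coordinate is non-finite.
    """
    lon1, lat1, lon2, lat2 = (np.asarray(c, dtype=float) for c in (lon1, lat1, lon2, lat2))
    for c in (lon1, lat1, lon2, lat2):
        if not np.all(np.isfinite(c)):
            raise ValueError("non-finite coordinate passed to haversine_km")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    if d.ndim == 0:
        return float(d)
    return d


class TravelTimeProvider(Protocol):
    """Contract for travel-time backends (routing APIs, speed models...)."""

    label: str

    def travel_time_min(self, lon1, lat1, lon2, lat2): ...


@dataclass(frozen=True)
class SpeedModelProvider:
    """Travel time as great-circle distance over a constant speed.

    A deliberately simple stand-in for road routing: minutes =
    ``haversine_km / speed_kmh * 60``.  Monotone in distance by construction.
    """

    speed_kmh: float = 50.0

    @property
    def label(self) -> str:
        return f"haversine-constant-speed-{self.speed_kmh:g}kmh"

    def travel_time_min(self, lon1, lat1, lon2, lat2):
        if self.speed_kmh <= 0:
            raise ValueError("speed_kmh must be positive")
        return haversine_km(lon1, lat1, lon2, lat2) / self.speed_kmh * 60.0


def travel_time_min(provider: TravelTimeProvider, lon1, lat1, lon2, lat2):
    """Travel time in minutes via ``provider``, with context on failure."""
    try:
        return provider.travel_time_min(lon1, lat1, lon2, lat2)
    except Exception as exc:  # re-raise with the route endpoints attached
        raise RuntimeError(
            f"travel-time provider {getattr(provider, 'label', provider)!r} failed for "
            f"({lon1}, {lat1}) -> ({lon2}, {lat2}): {exc}"
        ) from exc


def _facility_frame(facilities: pd.DataFrame) -> pd.DataFrame:
    """Sorted copy so that argmin tie-breaks lexicographically on facility_id."""
    fac = facilities.reset_index(drop=True)
    missing = {"facility_id", "lon", "lat"} - set(fac.columns)
    if missing:
        raise ValueError(f"facility table missing columns: {sorted(missing)}")
    return fac.sort_values("facility_id", kind="mergesort").reset_index(drop=True)


def _nearest_block(lons: np.ndarray, lats: np.ndarray, fac: pd.DataFrame):
    """Vectorised nearest facility for many query points.

    ``fac`` must already be sorted by facility_id; np.argmin returns the first
    minimum, which is then the lexicographically smallest id among exact ties.
    """
    dmat = haversine_km(
        np.asarray(lons, dtype=float)[:, None],
        np.asarray(lats, dtype=float)[:, None],
        fac["lon"].to_numpy(dtype=float)[None, :],
        fac["lat"].to_numpy(dtype=float)[None, :],
    )
    idx = np.argmin(dmat, axis=1)
    return fac["facility_id"].to_numpy()[idx], dmat[np.arange(len(idx)), idx]


def nearest_facility(lon: float, lat: float, facilities: pd.DataFrame, predicate=None):
    """Nearest facility to one point; returns ``(facility_id, distance_km)``.

    ``predicate`` filters the facility table (row-wise boolean function or a
    boolean mask).  Exact distance ties break to the lexicographically
    smallest facility_id.
    """
    fac = facilities
    if predicate is not None:
        mask = predicate(fac) if callable(predicate) else np.asarray(predicate, dtype=bool)
        fac = fac.loc[mask]
    if len(fac) == 0:
        raise ValueError("no eligible facility")
    fac = _facility_frame(fac)
    ids, dists = _nearest_block(np.array([lon]), np.array([lat]), fac)
    return str(ids[0]), float(dists[0])


def access_table(
    areas: pd.DataFrame,
    facilities: pd.DataFrame,
    active_ids: Iterable[str],
    provider: TravelTimeProvider | None = None,
):
    """Per-area access to the nearest care and nearest research-active facility.

    Parameters
    ----------
    areas : DataFrame with area_id, lon, lat.
    facilities : DataFrame with facility_id, lon, lat and optionally a
        boolean ``provides_care`` column (missing means all provide care).
    active_ids : ids of research-active facilities (must be care providers
        with rows in ``facilities``).
    provider : optional travel-time backend applied to the nearest active
        facility of each area.

    Returns
    -------
    (DataFrame, dict)
        One row per area: ``area_id, nearest_care_id, d_care, nearest_active_id,
        d_active, excess`` and ``t_active`` when a provider is given.  The dict
        summarises d_active (and t_active): median, q1, q3, max, plus
        ``frac_nearest_inactive`` — the fraction of areas whose nearest care
        facility is not research active.
    """
    care = facilities
    if "provides_care" in care.columns:
        care = care.loc[care["provides_care"].astype(bool)]
    if len(care) == 0:
        raise ValueError("no eligible facility (no care providers)")
    active_ids = set(map(str, active_ids))
    active = care.loc[care["facility_id"].astype(str).isin(active_ids)]
    if len(active) == 0:
        raise ValueError("no eligible facility (active set empty)")

    care = _facility_frame(care)
    active = _facility_frame(active)
    lons = areas["lon"].to_numpy(dtype=float)
    lats = areas["lat"].to_numpy(dtype=float)
    care_id, d_care = _nearest_block(lons, lats, care)
    active_id, d_active = _nearest_block(lons, lats, active)

    nearest_inactive = ~np.isin(care_id, list(active_ids))
    excess = np.where(nearest_inactive, d_active - d_care, 0.0)
    out = pd.DataFrame(
        {
            "area_id": areas["area_id"].to_numpy(),
            "nearest_care_id": care_id,
            "d_care": d_care,
            "nearest_active_id": active_id,
            "d_active": d_active,
            "excess": excess,
        }
    )

    summary = {
        "d_active_median": float(np.median(d_active)),
        "d_active_q1": float(np.quantile(d_active, 0.25)),
        "d_active_q3": float(np.quantile(d_active, 0.75)),
        "d_active_max": float(np.max(d_active)),
        "frac_nearest_inactive": float(np.mean(nearest_inactive)),
    }
    if provider is not None:
        act_lookup = active.set_index("facility_id")
        t = travel_time_min(
            provider,
            lons,
            lats,
            act_lookup.loc[active_id, "lon"].to_numpy(dtype=float),
            act_lookup.loc[active_id, "lat"].to_numpy(dtype=float),
        )
        out["t_active"] = t
        summary.update(
            {
                "t_active_median": float(np.median(t)),
                "t_active_q1": float(np.quantile(t, 0.25)),
                "t_active_q3": float(np.quantile(t, 0.75)),
                "t_active_max": float(np.max(t)),
                "travel_time_source": provider.label,
            }
        )
    return out, summary


def write_access_geojson(access: pd.DataFrame, areas: pd.DataFrame, path) -> None:
    """Write the access table as a GeoJSON FeatureCollection of area points."""
    coords = areas.set_index("area_id")[["lon", "lat"]]
    features = []
    for rec in access.to_dict("records"):
        lon, lat = coords.loc[rec["area_id"]]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(lon), float(lat)]},
                "properties": {k: (v if not isinstance(v, np.generic) else v.item()) for k, v in rec.items()},
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
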
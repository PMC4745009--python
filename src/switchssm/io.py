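"""Track table I/O, coordinate handling and run manifests.

Track CSV format (one row per observed location)::

    id,time,x_km,y_km,lc

``time`` is either an ISO-8601 timestamp or a numeric value in hours from
track start; ``lc`` is the Argos location-quality class and may be empty.
Longitude/latitude input uses columns ``lon,lat`` instead of ``x_km,y_km``
and is converted to local planar km via an equirectangular projection about
the track centroid (origin recorded on the Track).  Coordinates are never
silently coerced between the two systems.

Internally times are hours from the first observation of each individual
(float); step indices in persisted posterior files are 0-based.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import lonlat_to_km

__all__ = ["Track", "read_tracks", "write_tracks", "write_truth", "RunManifest"]

logger = logging.getLogger("switchssm")


@dataclass
class Track:
    """Observed locations for one individual, in planar km.

    ``times`` are hours from the first observation (strictly increasing),
    ``y`` the (n, 2) observed coordinates, ``lc`` optional quality classes.
    """

    ident: str
    times: np.ndarray
    y: np.ndarray
    lc: np.ndarray | None = None
    origin: tuple[float, float] | None = None  # lon/lat projection origin

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 2 or self.y.shape[1] != 2:
            raise ValueError("y must have shape (n, 2)")
        if self.times.shape != (self.y.shape[0],):
            raise ValueError("times and y lengths differ")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.lc is not None:
            self.lc = np.asarray(self.lc, dtype=object)
            if self.lc.shape != self.times.shape:
                raise ValueError("lc length differs from times")

    def __len__(self) -> int:
        return len(self.times)


def _parse_times(raw: pd.Series, ident: str) -> np.ndarray:
    """Times in hours from the first observation; accepts numbers or ISO-8601."""
    numeric = pd.to_numeric(raw, errors="coerce")
    if numeric.notna().all():
        return numeric.to_numpy(dtype=float)
    parsed = pd.to_datetime(raw, errors="coerce", utc=True, format="ISO8601")
    bad = parsed.isna() & numeric.isna()
    if bad.any():
        rows = [int(i) for i in raw.index[bad]]
        raise ValueError(
            f"individual {ident!r}: unparseable time(s) at input row(s) {rows}: "
            f"{[str(raw.loc[i]) for i in rows[:5]]}"
        )
    t0 = parsed.iloc[0]
    return ((parsed - t0).dt.total_seconds() / 3600.0).to_numpy(dtype=float)


def read_tracks(path) -> list[Track]:
    """Read and validate a track CSV, grouped by individual.

    Rows are sorted by time within individual (with a logged notice if the
    input was unsorted); duplicate timestamps are a validation error naming
    the offending rows.
    """
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    planar = {"x_km", "y_km"}.issubset(df.columns)
    lonlat = {"lon", "lat"}.issubset(df.columns)
    required = {"id", "time"}
    missing = required - set(df.columns)
    if missing or not (planar or lonlat):
        coords = "" if (planar or lonlat) else " and x_km/y_km (or lon/lat)"
        raise ValueError(f"missing required column(s): {sorted(missing)}{coords}")
    if planar and lonlat:
        raise ValueError(
            "both planar (x_km/y_km) and lon/lat columns present; "
            "supply exactly one coordinate system"
        )
    tracks = []
    for ident, grp in df.groupby("id", sort=True):
        times = _parse_times(grp["time"], str(ident))
        order = np.argsort(times, kind="stable")
        if not np.all(order == np.arange(len(order))):
            logger.info("individual %s: input rows were unsorted; sorted by time", ident)
            grp = grp.iloc[order]
            times = times[order]
        dup = np.flatnonzero(np.diff(times) == 0)
        if dup.size:
            rows = [int(grp.index[i + 1]) for i in dup]
            raise ValueError(
                f"individual {ident!r}: duplicate timestamp(s) at input row(s) {rows}"
            )
        times = times - times[0]
        origin = None
        if planar:
            y = grp[["x_km", "y_km"]].to_numpy(dtype=float)
        else:
            y, origin = lonlat_to_km(
                grp["lon"].to_numpy(dtype=float), grp["lat"].to_numpy(dtype=float)
            )
        lc = None
        if "lc" in grp.columns:
            vals = grp["lc"]
            if vals.notna().any():
                lc = np.array(
                    [str(v) if pd.notna(v) else None for v in vals], dtype=object
                )
        tracks.append(Track(ident=str(ident), times=times, y=y, lc=lc, origin=origin))
    return tracks


def write_tracks(tracks, path) -> None:
    """Write tracks to the CSV format read by :func:`read_tracks`."""
    frames = []
    for tr in tracks:
        frames.append(
            pd.DataFrame(
                {
                    "id": tr.ident,
                    "time": tr.times,
                    "x_km": tr.y[:, 0],
                    "y_km": tr.y[:, 1],
                    "lc": tr.lc if tr.lc is not None else "",
                }
            )
        )
    # %.17g guarantees float64 round-trips bit-exactly through the CSV
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def write_truth(simulated_tracks, path) -> None:
    """Write simulated ground truth (id, step, x_true, y_true, b_true) CSV."""
    frames = []
    for tr in simulated_tracks:
        frames.append(
            pd.DataFrame(
                {
                    "id": tr.track_id,
                    "step": np.arange(len(tr.truth)),
                    "x_true": tr.truth.x[:, 0],
                    "y_true": tr.truth.x[:, 1],
                    "b_true": tr.truth.b,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written by every CLI run.

    Captures the stage, resolved configuration, root seed, software version
    and input checksums -- enough to re-run the stage bit-exactly (seeded
    stochastic stages reproduce draw-exactly).
    """

    stage: str
    config: dict
    seed: int
    version: str
    inputs: dict[str, str] = field(default_factory=dict)
    stage_seeds: dict[str, int] = field(default_factory=dict)

    def add_input(self, path) -> None:
        self.inputs[str(path)] = sha256_of(path)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
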
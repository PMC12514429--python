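"""Track-table post-processing: velocity maps and trajectory overlays.

Mirrors the image-analysis workflow used with tracked fluorescent tracer
beads: particle tracks (e.g. TrackMate spot exports) are converted to
physical units, each consecutive displacement contributes an instantaneous
speed sample assigned to the bin containing the segment midpoint, and the
per-bin mean speed forms a gridded velocity-magnitude map.  Overlaying all
track polylines into one raster reveals vortex structure the same way
superposing video frames does.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ConfigError
from .stokesflow import FlowField
from .tracing import BilinearSampler

__all__ = [
    "TrackTable",
    "VelocityMap",
    "load_tracks",
    "write_tracks",
    "velocity_map",
    "overlay",
    "write_pgm",
    "make_synthetic_tracks",
]

logger = logging.getLogger("aceodep")

#: canonical CSV dialect column names
_CANONICAL = ("track_id", "t_s", "x_um", "y_um")

#: TrackMate spot-export column names and their meaning
_TRACKMATE = {
    "track_id": "TRACK_ID",
    "x": "POSITION_X",
    "y": "POSITION_Y",
    "t": "POSITION_T",
    "frame": "FRAME",
}


@dataclass(frozen=True)
class TrackTable:
    """Particle tracks in SI units: columns track_id, t (s), x (m), y (m)."""

    data: pd.DataFrame
    pixel_size: float | None = None
    frame_interval: float | None = None
    source: str = ""

    @property
    def n_tracks(self) -> int:
        return self.data["track_id"].nunique()


@dataclass(frozen=True)
class VelocityMap:
    """Binned mean speed over the field of view; empty bins are NaN."""

    bin_x: np.ndarray  # bin centers (m)
    bin_y: np.ndarray
    mean_speed: np.ndarray  # (ny, nx), NaN where no samples
    counts: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        gx, gy = np.meshgrid(self.bin_x, self.bin_y, indexing="xy")
        return pd.DataFrame(
            {
                "bin_x_um": gx.ravel() * 1e6,
                "bin_y_um": gy.ravel() * 1e6,
                "mean_speed_um_s": self.mean_speed.ravel() * 1e6,
                "n": self.counts.ravel().astype(int),
            }
        )


def _read_csv_tolerant(path_or_buf) -> pd.DataFrame:
    """Read a track CSV, tolerating TrackMate's extra non-numeric header rows."""
    df = pd.read_csv(path_or_buf)
    if df.empty:
        return df
    # TrackMate spot tables repeat the header as human-readable name/units rows
    first = df.iloc[:, 0].astype(str)
    numericish = pd.to_numeric(df.iloc[:, 0], errors="coerce").notna()
    keep = numericish | ~first.str.match(r"^[A-Za-z]")
    dropped = (~keep).sum()
    if dropped:
        df = df.loc[keep].reset_index(drop=True)
        logger.info("dropped %d non-numeric header row(s)", dropped)
    return df


def load_tracks(
    path,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
    column_map: dict[str, str] | None = None,
) -> TrackTable:
    """Load a track CSV in the canonical or TrackMate-spot dialect.

    ``pixel_size`` (m/px) and ``frame_interval`` (s) convert image
    coordinates to physical units; canonical files (already in um and s)
    need neither.  Tracks with fewer than two points are dropped.
    """
    df = _read_csv_tolerant(path)
    if df.empty:
        raise ConfigError(f"tracks: file {path!r} contains no data rows")
    cols = set(df.columns)

    if column_map:
        missing = [c for c in column_map.values() if c not in cols]
        if missing:
            raise ConfigError(
                f"tracks: mapped column(s) {missing} not found; file has {sorted(cols)}"
            )
        tid = df[column_map["track_id"]]
        xs = df[column_map["x"]].astype(float)
        ys = df[column_map["y"]].astype(float)
        ts = df[column_map["t"]].astype(float)
    elif set(_CANONICAL) <= cols:
        tid = df["track_id"]
        ts = df["t_s"].astype(float)
        xs = df["x_um"].astype(float) * 1e-6
        ys = df["y_um"].astype(float) * 1e-6
        out = pd.DataFrame({"track_id": tid.astype(int), "t": ts, "x": xs, "y": ys})
        return _finalize(out, pixel_size, frame_interval, str(path))
    elif _TRACKMATE["track_id"] in cols:
        tid = df[_TRACKMATE["track_id"]]
        xs = df[_TRACKMATE["x"]].astype(float)
        ys = df[_TRACKMATE["y"]].astype(float)
        if _TRACKMATE["t"] in cols:
            ts = df[_TRACKMATE["t"]].astype(float)
        elif _TRACKMATE["frame"] in cols:
            if frame_interval is None:
                raise ConfigError(
                    "tracks: file has FRAME but no POSITION_T; provide frame_interval"
                )
            ts = df[_TRACKMATE["frame"]].astype(float)
        else:
            raise ConfigError(
                f"tracks: need POSITION_T or FRAME; file has {sorted(cols)}"
            )
    else:
        raise ConfigError(
            f"tracks: required columns {list(_CANONICAL)} (canonical) or "
            f"TrackMate TRACK_ID/POSITION_X/POSITION_Y/POSITION_T not found; "
            f"file has {sorted(cols)}"
        )

    xs = xs * (pixel_size if pixel_size is not None else 1.0)
    ys = ys * (pixel_size if pixel_size is not None else 1.0)
    ts = ts * (frame_interval if frame_interval is not None else 1.0)
    out = pd.DataFrame(
        {"track_id": tid.astype(float).astype(int), "t": ts, "x": xs, "y": ys}
    )
    return _finalize(out, pixel_size, frame_interval, str(path))


def _finalize(
    df: pd.DataFrame, pixel_size, frame_interval, source: str
) -> TrackTable:
    # keep file order within each track: monotone time is a contract, not
    # something to repair silently
    df = df.sort_values("track_id", kind="stable").reset_index(drop=True)
    for tid, grp in df.groupby("track_id"):
        dts = np.diff(grp["t"].to_numpy())
        if (dts <= 0).any():
            raise ConfigError(f"tracks: non-monotone time within track {tid}")
    sizes = df.groupby("track_id")["t"].transform("size")
    short = int((sizes < 2).sum())
    if short:
        logger.warning("dropping %d single-point track row(s)", short)
    df = df.loc[sizes >= 2].reset_index(drop=True)
    return TrackTable(df, pixel_size, frame_interval, source)


def write_tracks(table: TrackTable, path) -> None:
    """Write the canonical dialect: track_id, t_s, x_um, y_um."""
    out = pd.DataFrame(
        {
            "track_id": table.data["track_id"].astype(int),
            "t_s": table.data["t"],
            "x_um": table.data["x"] * 1e6,
            "y_um": table.data["y"] * 1e6,
        }
    )
    out.to_csv(path, index=False, float_format="%.10g")


def velocity_map(
    tracks: TrackTable, bin_size: float, extent: tuple[float, float, float, float] | None = None
) -> VelocityMap:
    """Gridded mean of per-step displacement speeds.

    Each consecutive pair within a track contributes |dx|/dt at the segment
    midpoint; speeds are averaged per bin.  ``extent`` is (x0, x1, y0, y1)
    in meters; by default the bounding box of the data.
    """
    df = tracks.data
    if df.empty:
        raise ConfigError("tracks: no retained tracks")
    mids, speeds = [], []
    for _, grp in df.groupby("track_id"):
        t = grp["t"].to_numpy()
        xy = grp[["x", "y"]].to_numpy()
        dt = np.diff(t)
        seg = np.diff(xy, axis=0)
        speeds.append(np.hypot(seg[:, 0], seg[:, 1]) / dt)
        mids.append((xy[1:] + xy[:-1]) / 2.0)
    mids_arr = np.concatenate(mids)
    speeds_arr = np.concatenate(speeds)

    if extent is None:
        x0, x1 = mids_arr[:, 0].min(), mids_arr[:, 0].max()
        y0, y1 = mids_arr[:, 1].min(), mids_arr[:, 1].max()
    else:
        x0, x1, y0, y1 = extent
    span_x = max(x1 - x0, 1e-30)
    span_y = max(y1 - y0, 1e-30)
    if bin_size > max(span_x, span_y):
        raise ConfigError(
            f"bin_size {bin_size!r} m exceeds the field of view "
            f"({span_x:g} x {span_y:g} m)"
        )
    nx = max(1, int(np.ceil(span_x / bin_size)))
    ny = max(1, int(np.ceil(span_y / bin_size)))
    ex = np.linspace(x0, x0 + nx * bin_size, nx + 1)
    ey = np.linspace(y0, y0 + ny * bin_size, ny + 1)
    counts, _, _ = np.histogram2d(mids_arr[:, 1], mids_arr[:, 0], bins=(ey, ex))
    sums, _, _ = np.histogram2d(
        mids_arr[:, 1], mids_arr[:, 0], bins=(ey, ex), weights=speeds_arr
    )
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return VelocityMap(
        bin_x=(ex[:-1] + ex[1:]) / 2.0,
        bin_y=(ey[:-1] + ey[1:]) / 2.0,
        mean_speed=mean,
        counts=counts,
    )


def overlay(
    tracks: TrackTable,
    extent: tuple[float, float, float, float],
    shape: tuple[int, int] = (200, 200),
) -> np.ndarray:
    """Deterministic raster of all track polylines (hit counts per pixel).

    Segments are sampled at half-pixel spacing; returns an (ny, nx) array of
    visit counts, analogous to superposing all video frames of the tracers.
    """
    df = tracks.data
    if df.empty:
        raise ConfigError("tracks: no retained tracks")
    x0, x1, y0, y1 = extent
    ny, nx = shape
    img = np.zeros((ny, nx), dtype=np.int64)
    px = (x1 - x0) / nx
    py = (y1 - y0) / ny
    step = min(px, py) / 2.0
    for _, grp in df.groupby("track_id"):
        xy = grp[["x", "y"]].to_numpy()
        for a, b in zip(xy[:-1], xy[1:]):
            npts = max(2, int(np.ceil(np.hypot(*(b - a)) / step)) + 1)
            ts = np.linspace(0.0, 1.0, npts)
            pts = a[None, :] + ts[:, None] * (b - a)[None, :]
            i = np.clip(((pts[:, 0] - x0) / px).astype(int), 0, nx - 1)
            j = np.clip(((pts[:, 1] - y0) / py).astype(int), 0, ny - 1)
            keep = np.ones(npts, dtype=bool)
            keep[1:] = (i[1:] != i[:-1]) | (j[1:] != j[:-1])
            np.add.at(img, (j[keep], i[keep]), 1)
    return img


def write_pgm(img: np.ndarray, path) -> None:
    """Write a raster as plain-text PGM (P2), a portable grayscale format."""
    arr = np.asarray(img)
    maxv = int(max(1, arr.max()))
    with open(path, "w", encoding="ascii") as fh:
        fh.write(f"P2\n{arr.shape[1]} {arr.shape[0]}\n{maxv}\n")
        for row in arr:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def make_synthetic_tracks(
    pattern: str,
    params: dict | None = None,
    seed: int = 0,
) -> TrackTable:
    """Deterministic synthetic track generator (fixture factory).

    Patterns:

    * ``constant`` -- straight tracks at uniform speed.  params: speed (m/s),
      direction (rad), n_tracks, n_frames, fps, origin_spread (m), jitter (m).
    * ``rotation`` -- solid-body rotation at angular rate omega (rad/s).
      params: omega, center (x, y), radii (list of m), n_frames, fps, jitter.
    * ``from_flowfield`` -- seeds advected through a simulated
      :class:`~aceodep.stokesflow.FlowField`.  params: flow, seeds ((n,2) m),
      n_frames, fps.

    Jitter (positional noise) is the only randomness and is governed by
    ``seed``; the mean motion is seed-independent.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    rows = []
    if pattern == "constant":
        speed = params.get("speed", 100e-6)
        theta = params.get("direction", 0.0)
        n_tracks = int(params.get("n_tracks", 5))
        n_frames = int(params.get("n_frames", 10))
        fps = params.get("fps", 60.0)
        spread = params.get("origin_spread", 50e-6)
        jitter = params.get("jitter", 0.0)
        vel = speed * np.array([np.cos(theta), np.sin(theta)])
        for k in range(n_tracks):
            origin = np.array([0.0, k * spread / max(1, n_tracks - 1) if n_tracks > 1 else 0.0])
            for f in range(n_frames):
                t = f / fps
                p = origin + vel * t + jitter * rng.standard_normal(2)
                rows.append((k, t, p[0], p[1]))
    elif pattern == "rotation":
        omega = params.get("omega", 1.0)
        cx, cy = params.get("center", (0.0, 0.0))
        radii = params.get("radii", [50e-6, 100e-6])
        n_frames = int(params.get("n_frames", 32))
        fps = params.get("fps", 60.0)
        jitter = params.get("jitter", 0.0)
        for k, rad in enumerate(radii):
            for f in range(n_frames):
                t = f / fps
                a = omega * t
                p = np.array([cx + rad * np.cos(a), cy + rad * np.sin(a)])
                p = p + jitter * rng.standard_normal(2)
                rows.append((k, t, p[0], p[1]))
    elif pattern == "from_flowfield":
        flow: FlowField = params["flow"]
        seeds = np.asarray(params["seeds"], dtype=float)
        n_frames = int(params.get("n_frames", 60))
        fps = params.get("fps", 60.0)
        sampler = BilinearSampler(flow.x, flow.y, flow.u, flow.v)
        dt = 1.0 / fps
        pos = seeds.copy()
        for f in range(n_frames):
            t = f / fps
            for k in range(pos.shape[0]):
                rows.append((k, t, pos[k, 0], pos[k, 1]))
            k1 = np.column_stack(sampler(pos))
            k2 = np.column_stack(sampler(pos + 0.5 * dt * k1))
            k3 = np.column_stack(sampler(pos + 0.5 * dt * k2))
            k4 = np.column_stack(sampler(pos + dt * k3))
            pos = pos + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    else:
        raise ConfigError(f"pattern: unknown synthetic pattern {pattern!r}")

    df = pd.DataFrame(rows, columns=["track_id", "t", "x", "y"])
    return _finalize(df, None, None, f"synthetic:{pattern}")


def tracks_roundtrip_buffer(table: TrackTable) -> TrackTable:
    """Write to the canonical dialect and read back (identity check helper)."""
    buf = io.StringIO()
    write_tracks(table, buf)
    buf.seek(0)
    return load_tracks(buf)
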
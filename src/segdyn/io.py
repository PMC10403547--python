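"""File formats and run configuration.

Canonical interchange: plain multi-page TIFF for image stacks with a JSON
sidecar declaring voxel spacing (µm), channel names and timestamp (the
spacing is never silently assumed — a stack without declared spacing is
an error); tidy CSV with unit-bearing column names for curves, series and
DPA records; JSON for fits and ground truths.  Page order within a stack
file is channel-major: all z planes of channel 0, then channel 1, …
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from segdyn.correlation import ClusterSizeSeries, CorrelationCurve
from segdyn.doublet_mechanics import DoubletGeometry, DPARecord
from segdyn.morphometry import SpheroidTrace
from segdyn.stack import VoxelStack


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: VoxelStack, path: str | Path) -> Path:
    """Write a stack as channel-major multi-page TIFF + JSON sidecar."""
    path = Path(path)
    pages = np.concatenate([np.asarray(stack.channels[c]) for c in stack.channel_names])
    # Explicit photometric: a 3-page stack must not be guessed as RGB.
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "spacing_um": list(stack.spacing),
        "channel_names": stack.channel_names,
        "timestamp_h": stack.timestamp,
        "n_z": stack.shape[0],
        "page_order": "channel-major (c, z, y, x)",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def load_stack(
    path: str | Path,
    sidecar: str | Path | None = None,
    spacing: tuple[float, float, float] | None = None,
    channel_names: list[str] | None = None,
) -> VoxelStack:
    """Read a multi-page TIFF stack; spacing must be declared somewhere.

    Metadata comes from the sidecar JSON when present, else from the
    explicit arguments; a stack with no spacing from either source is an
    error.  The page count must equal n_channels × n_z.
    """
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    sidecar = Path(sidecar) if sidecar else _sidecar_path(path)
    meta = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    spacing = spacing or meta.get("spacing_um")
    if spacing is None:
        raise ValueError(
            f"{path}: no voxel spacing declared (sidecar or argument required)"
        )
    channel_names = channel_names or meta.get("channel_names")
    if channel_names is None:
        channel_names = ["ch0"]
    n_c = len(channel_names)
    n_pages = pages.shape[0]
    if n_pages % n_c != 0:
        raise ValueError(
            f"{path}: {n_pages} pages do not divide into {n_c} channels "
            f"(expected layout c x z with equal z per channel)"
        )
    n_z = n_pages // n_c
    channels = {
        name: pages[i * n_z : (i + 1) * n_z] for i, name in enumerate(channel_names)
    }
    return VoxelStack(
        channels=channels,
        spacing=tuple(spacing),
        timestamp=float(meta.get("timestamp_h", 0.0)),
    )


def write_correlation_csv(
    curve: CorrelationCurve, path: str | Path, channel: str = "", time_h: float = 0.0
) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_h": time_h,
            "channel": channel,
            "r_um": curve.r_centers,
            "C": curve.C,
            "pair_count": curve.pair_counts,
        }
    )
    df.to_csv(path, index=False)
    return path


def write_series_csv(series: ClusterSizeSeries, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for c, vals in series.R0.items():
        sems = series.sem[c] if series.sem else np.full_like(vals, np.nan)
        for t, v, s in zip(series.times, vals, sems):
            rows.append(
                {
                    "time_h": t,
                    "channel": c,
                    "R0_um": v,
                    "sem_um": s,
                    "n": series.replicate_count,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_series_csv(path: str | Path) -> ClusterSizeSeries:
    df = pd.read_csv(path)
    times = np.sort(df["time_h"].unique())
    R0: dict[str, np.ndarray] = {}
    sem: dict[str, np.ndarray] = {}
    has_sem = df["sem_um"].notna().any()
    n = int(df["n"].iloc[0]) if "n" in df else 1
    for c, sub in df.groupby("channel"):
        sub = sub.sort_values("time_h")
        R0[str(c)] = sub["R0_um"].to_numpy()
        if has_sem:
            sem[str(c)] = sub["sem_um"].to_numpy()
    return ClusterSizeSeries(
        times=times, R0=R0, sem=sem if has_sem else None, replicate_count=n
    )


def write_trace_csv(trace: SpheroidTrace, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "time_h": trace.times,
            "perimeter_um": trace.perimeter_um,
            "perimeter_pct": trace.perimeter_pct,
            "status": np.where(np.isfinite(trace.perimeter_um), "ok", "missing"),
        }
    ).to_csv(path, index=False)
    return path


def write_dpa_csv(record: DPARecord, path: str | Path) -> Path:
    """DPA record as CSV; the pipette radius rides in a comment header."""
    path = Path(path)
    sep = np.zeros(len(record.pressures_pa), dtype=int)
    if record.separated_at is not None:
        sep[record.separated_at] = 1
    body = pd.DataFrame(
        {
            "step_index": np.arange(len(record.pressures_pa)),
            "pressure_pa": record.pressures_pa,
            "separated_flag": sep,
        }
    ).to_csv(index=False)
    path.write_text(f"# pipette_radius_um: {record.pipette_radius_um}\n{body}")
    return path


def read_dpa_csv(path: str | Path) -> DPARecord:
    path = Path(path)
    radius = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "pipette_radius_um" in first:
        radius = float(first.split(":")[1])
    if radius is None:
        raise ValueError(f"{path}: missing '# pipette_radius_um:' header")
    df = pd.read_csv(path, comment="#")
    sep_rows = np.flatnonzero(df["separated_flag"].to_numpy())
    separated_at = int(sep_rows[0]) if sep_rows.size else None
    return DPARecord(
        pipette_radius_um=radius,
        pressures_pa=df["pressure_pa"].to_numpy(),
        separated_at=separated_at,
    )


def write_geometry_json(geom: DoubletGeometry, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "circle1_center_um": list(geom.circle1[0]),
        "circle1_radius_um": geom.circle1[1],
        "circle2_center_um": list(geom.circle2[0]),
        "circle2_radius_um": geom.circle2[1],
        "d1_um": geom.d1,
        "d2_um": geom.d2,
        "theta1_deg": geom.theta1,
        "theta2_deg": geom.theta2,
        "theta_mean_deg": geom.theta_mean,
        "theta_vertex_deg": geom.theta_vertex,
        "angle_convention": "per-cell tangent-to-contact-line angle; "
        "theta_mean averages the two cells",
        "fit_residual_um": geom.fit_residual,
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


@dataclasses.dataclass
class RunConfig:
    """Effective parameters of a pipeline run (defaults follow the
    standard protocol: 0–200 µm correlation range, σ = 5 px blur,
    1000 px hole limit, 10 µm z step)."""

    input: str = ""
    out_dir: str = "segdyn_out"
    seed: int = 0
    pixel_size_um: float = 1.0
    spacing_um: tuple[float, float, float] = (10.0, 1.0, 1.0)
    channels: list[str] = dataclasses.field(default_factory=list)
    r_max_um: float = 200.0
    bin_width_um: float | None = None
    threshold: str = "otsu"
    blur_sigma_px: float = 5.0
    hole_limit_px: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.spacing_um, list):
            cfg.spacing_um = tuple(cfg.spacing_um)
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class RunLog:
    """Collects structured run records and module warnings (each once)."""

    def __init__(self) -> None:
        self.records: list[dict] = []

    def add(self, kind: str, **fields) -> None:
        rec = {"kind": kind, **fields}
        if rec not in self.records:
            self.records.append(rec)

    def capture_warnings(self, caught: list[warnings.WarningMessage]) -> None:
        for w in caught:
            self.add("warning", message=str(w.message))

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.records, indent=1, default=str))
        return path
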
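"""Readers and writers for the pipeline's file formats.

Image stacks and movies travel as multi-page TIFF with voxel/pixel-size
metadata (ImageJ-style tags); cluster tables, size distributions, traces
and idealized records as CSV with documented column schemas; configs and
manifests as JSON.  Every writer produces files its paired reader parses
back to an equal object.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import (
    CLUSTER_COLUMNS_2D,
    CLUSTER_COLUMNS_3D,
    ClusterPopulation,
    ImageStack,
    Movie,
    SizeDistribution,
    SparkletTrace,
)
from .ephys import StepRecording
from .sparklets import IdealizedRecord


class FormatError(ValueError):
    """A file did not match its documented schema."""


# ---------------------------------------------------------------------------
# TIFF stacks and movies


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a 3D stack as ImageJ TIFF with voxel-size metadata (μm)."""
    vx, vy, vz = stack.voxel_size
    tifffile.imwrite(
        str(path),
        stack.data.astype(np.float32),
        imagej=True,
        resolution=(1.0 / vx, 1.0 / vy),
        metadata={"spacing": vz, "unit": "um", "axes": "ZYX"},
    )


def read_stack(path: str | Path) -> ImageStack:
    """Read a 3D TIFF stack; refuses files lacking voxel metadata."""
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        meta = tif.imagej_metadata or {}
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
    if xres is None or yres is None or "spacing" not in meta:
        raise FormatError(
            f"{path}: TIFF lacks voxel-size metadata (XResolution/YResolution "
            "tags and ImageJ 'spacing'); re-export with physical calibration"
        )
    vx = xres.value[1] / xres.value[0]
    vy = yres.value[1] / yres.value[0]
    vz = float(meta["spacing"])
    if data.ndim == 2:
        data = data[None]
    return ImageStack(data.astype(float), (float(vx), float(vy), vz))


def write_movie(path: str | Path, movie: Movie) -> None:
    """Write a 2D time series as ImageJ TIFF; pixel size stored in nm."""
    px_um = movie.pixel_size_nm / 1e3
    tifffile.imwrite(
        str(path),
        movie.frames.astype(np.float32),
        imagej=True,
        resolution=(1.0 / px_um, 1.0 / px_um),
        metadata={"unit": "um", "axes": "TYX"},
    )


def read_movie(path: str | Path) -> Movie:
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
    if xres is None:
        raise FormatError(f"{path}: TIFF lacks pixel-size metadata")
    px_um = xres.value[1] / xres.value[0]
    if data.ndim == 2:
        data = data[None]
    return Movie(data.astype(float), pixel_size_nm=float(px_um * 1e3))


# ---------------------------------------------------------------------------
# Cluster tables


def write_clusters(path: str | Path, pop: ClusterPopulation) -> None:
    """Cluster table as CSV; cell metadata in a JSON sidecar column-free header."""
    pop.table.to_csv(path, index=False)
    meta = {k: v for k, v in pop.meta.items() if _json_safe(v)}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def read_clusters(path: str | Path) -> ClusterPopulation:
    table = pd.read_csv(path)
    required = CLUSTER_COLUMNS_3D if "volume_um3" in table.columns else CLUSTER_COLUMNS_2D
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: cluster table is missing column(s) {missing}")
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return ClusterPopulation(table, meta)


# ---------------------------------------------------------------------------
# Size distributions


def write_distribution(path: str | Path, dist: SizeDistribution) -> None:
    df = pd.DataFrame(
        {"size": dist.sizes, "count": dist.counts, "relative_frequency": dist.relative_frequency}
    )
    df.to_csv(path, index=False)


def read_distribution(path: str | Path) -> SizeDistribution:
    df = pd.read_csv(path)
    for col in ("size", "count"):
        if col not in df.columns:
            raise FormatError(f"{path}: distribution CSV is missing column '{col}'")
    return SizeDistribution(df["size"].to_numpy(float), df["count"].to_numpy(float))


# ---------------------------------------------------------------------------
# Traces and idealized records


def write_trace(path: str | Path, trace: SparkletTrace) -> None:
    """Trace CSV: a commented header line with the sampling rate, then frame,signal."""
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={trace.sampling_rate}\n")
        fh.write(f"# site_id={trace.site_id}\n")
        fh.write(f"# cell_id={trace.cell_id}\n")
        pd.DataFrame(
            {"frame": np.arange(len(trace.samples)), "signal": trace.samples}
        ).to_csv(fh, index=False)


def read_trace(path: str | Path) -> SparkletTrace:
    header: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            header[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    if "signal" not in df.columns:
        raise FormatError(f"{path}: trace CSV is missing column 'signal'")
    if "frame" in df.columns:
        frames = df["frame"].to_numpy()
        if len(frames) > 1 and not np.all(np.diff(frames) == 1):
            raise FormatError(f"{path}: frames are not uniformly sampled")
    rate = float(header.get("sampling_rate_hz", 100.0))
    return SparkletTrace(
        df["signal"].to_numpy(float),
        sampling_rate=rate,
        site_id=header.get("site_id", ""),
        cell_id=header.get("cell_id", ""),
    )


def write_idealized(path: str | Path, record: IdealizedRecord) -> None:
    pd.DataFrame(
        {"frame": np.arange(record.duration_frames), "level": record.levels}
    ).to_csv(path, index=False)


def read_idealized(path: str | Path) -> IdealizedRecord:
    df = pd.read_csv(path)
    if "level" not in df.columns:
        raise FormatError(f"{path}: idealized-record CSV is missing column 'level'")
    return IdealizedRecord.from_levels(df["level"].to_numpy(int))


# ---------------------------------------------------------------------------
# Step recordings


def write_step_recording(path: str | Path, rec: StepRecording) -> None:
    """CSV with time_ms plus one current column per step voltage, JSON header sidecar."""
    cols = {"time_ms": rec.time_ms}
    for i, v in enumerate(rec.voltages_mV):
        cols[f"I_{v:g}mV_pA"] = rec.currents_pA[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)
    header = {
        "voltages_mV": list(map(float, rec.voltages_mV)),
        "capacitance_pF": rec.capacitance_pF,
        "holding_potential_mV": rec.holding_potential_mV,
    }
    Path(str(path) + ".protocol.json").write_text(json.dumps(header, indent=1))


def read_step_recording(path: str | Path) -> StepRecording:
    df = pd.read_csv(path)
    if "time_ms" not in df.columns:
        raise FormatError(f"{path}: step-recording CSV is missing column 'time_ms'")
    proto_path = Path(str(path) + ".protocol.json")
    if not proto_path.exists():
        raise FormatError(f"{path}: missing protocol sidecar {proto_path.name}")
    proto = json.loads(proto_path.read_text())
    voltages = np.asarray(proto["voltages_mV"], dtype=float)
    currents = np.column_stack([df[f"I_{v:g}mV_pA"].to_numpy(float) for v in voltages])
    return StepRecording(
        time_ms=df["time_ms"].to_numpy(float),
        currents_pA=currents,
        voltages_mV=voltages,
        capacitance_pF=float(proto["capacitance_pF"]),
        holding_potential_mV=float(proto.get("holding_potential_mV", -70.0)),
    )
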
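"""Plain-text and HDF5 persistence for rasters, drives, traces and configs."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .config import NetworkConfig
from .data import DriveSeries, PotentialTrace, SpikeRaster

__all__ = [
    "write_raster_text",
    "read_raster_text",
    "write_trace_csv",
    "read_trace_csv",
    "save_bundle",
    "load_bundle",
]


def write_raster_text(
    raster: SpikeRaster,
    path: str | Path,
    dt: float | None = None,
    lambda_exc: float | None = None,
    p_internal: float | None = None,
) -> None:
    """Two-column (unit_index, spike_time_ms) text raster with a header.

    Unit indices are 0-based.  Unit types are stored as an E/I string so
    the raster round-trips without the originating config.
    """
    meta = {
        "n_units": raster.n_units,
        "t_total": repr(float(raster.t_total)),
        "dt": "" if dt is None else repr(float(dt)),
        "lambda_exc": "" if lambda_exc is None else repr(float(lambda_exc)),
        "p_internal": "" if p_internal is None else repr(float(p_internal)),
    }
    lines = ["# " + " ".join(f"{k}={v}" for k, v in meta.items() if v != "")]
    lines.append("# unit_type=" + "".join("E" if e else "I" for e in raster.unit_type))
    order = np.lexsort((raster.units, raster.times))
    for u, t in zip(raster.units[order], raster.times[order]):
        lines.append(f"{int(u)} {float(t)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_raster_text(path: str | Path) -> tuple[SpikeRaster, dict]:
    """Read a raster written by :func:`write_raster_text`."""
    meta: dict = {}
    unit_type: np.ndarray | None = None
    units: list[int] = []
    times: list[float] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("unit_type="):
                s = body[len("unit_type="):]
                unit_type = np.array([c == "E" for c in s])
            else:
                for tok in body.split():
                    k, _, v = tok.partition("=")
                    meta[k] = v
            continue
        u, t = line.split()
        units.append(int(u))
        times.append(float(t))
    if unit_type is None:
        raise ValueError(f"{path}: missing unit_type header")
    raster = SpikeRaster(
        units=np.asarray(units, dtype=np.int64),
        times=np.asarray(times),
        unit_type=unit_type,
        t_total=float(meta["t_total"]),
    )
    return raster, meta


def write_trace_csv(trace: PotentialTrace, path: str | Path) -> None:
    lines = [f"# label={trace.label} dt={trace.dt!r} t_transient={trace.t_transient!r}"]
    lines.append("time_ms,potential_mV")
    for k, v in enumerate(trace.values):
        lines.append(f"{float(k * trace.dt)!r},{float(v)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trace_csv(path: str | Path) -> PotentialTrace:
    text = Path(path).read_text().splitlines()
    header = text[0]
    meta = {}
    for tok in header.lstrip("# ").split():
        k, _, v = tok.partition("=")
        meta[k] = v
    values = [float(line.split(",")[1]) for line in text[2:] if line.strip()]
    return PotentialTrace(
        values=np.asarray(values),
        dt=float(meta["dt"]),
        label=meta.get("label", "LIF"),
        t_transient=float(meta.get("t_transient", 0.0)),
    )


def save_bundle(
    path: str | Path,
    config: NetworkConfig | None = None,
    raster: SpikeRaster | None = None,
    drive: DriveSeries | None = None,
    traces: dict[str, PotentialTrace] | None = None,
    extras: dict[str, float] | None = None,
    mode: str = "w",
) -> None:
    """Write a compressed HDF5 container bundling simulation outputs."""
    opts = {"compression": "gzip", "compression_opts": 4}
    with h5py.File(path, mode) as f:
        if config is not None:
            grp = f.require_group("config")
            for k, v in config.to_dict().items():
                grp.attrs[k] = v
        if raster is not None:
            grp = f.require_group("raster")
            grp.create_dataset("units", data=raster.units, **opts)
            grp.create_dataset("times", data=raster.times, **opts)
            grp.create_dataset("unit_type", data=raster.unit_type.astype(np.int8), **opts)
            grp.attrs["t_total"] = raster.t_total
        if drive is not None:
            grp = f.require_group("drive")
            for name in ("phi_exc", "phi_inh", "phi_ext"):
                grp.create_dataset(name, data=getattr(drive, name), **opts)
            grp.attrs["dt"] = drive.dt
        for label, tr in (traces or {}).items():
            grp = f.require_group(f"traces/{label}")
            grp.create_dataset("values", data=tr.values, **opts)
            grp.attrs["dt"] = tr.dt
            grp.attrs["label"] = tr.label
            grp.attrs["t_transient"] = tr.t_transient
        if extras:
            grp = f.require_group("extras")
            for k, v in extras.items():
                grp.attrs[k] = v


def load_bundle(path: str | Path) -> dict:
    """Read back a bundle written by :func:`save_bundle`.

    Returns a dict with any of the keys ``config``, ``raster``,
    ``drive``, ``traces`` (label -> PotentialTrace), ``extras``.
    """
    out: dict = {}
    with h5py.File(path, "r") as f:
        if "config" in f:
            out["config"] = NetworkConfig.from_dict(
                {k: _native(v) for k, v in f["config"].attrs.items()}
            )
        if "raster" in f:
            grp = f["raster"]
            out["raster"] = SpikeRaster(
                units=grp["units"][:],
                times=grp["times"][:],
                unit_type=grp["unit_type"][:].astype(bool),
                t_total=float(grp.attrs["t_total"]),
            )
        if "drive" in f:
            grp = f["drive"]
            out["drive"] = DriveSeries(
                phi_exc=grp["phi_exc"][:],
                phi_inh=grp["phi_inh"][:],
                phi_ext=grp["phi_ext"][:],
                dt=float(grp.attrs["dt"]),
            )
        if "traces" in f:
            out["traces"] = {}
            for label, grp in f["traces"].items():
                out["traces"][label] = PotentialTrace(
                    values=grp["values"][:],
                    dt=float(grp.attrs["dt"]),
                    label=str(grp.attrs["label"]),
                    t_transient=float(grp.attrs["t_transient"]),
                )
        if "extras" in f:
            out["extras"] = {k: _native(v) for k, v in f["extras"].attrs.items()}
    return out


def _native(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, bytes):
        return v.decode()
    return v
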
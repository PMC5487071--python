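"""Readers/writers for the pipeline's file formats, with schema validation.

Formats
-------
* I-V data: CSV with header ``voltage_mV,current_pA_pF``
* AP waveform: CSV with header ``time_ms,voltage_mV``
* geometry: text header (kind, shape, dx, diffusion, regions; node-centred,
  0-based indices) followed by one ``region_id fx fy fz active`` record per
  node in C order
* I_K1 parameters: JSON with genotype label and fit residual
* probes: CSV ``time_ms`` + one column per probe
* snapshots: legacy-VTK structured-points ASCII (scalar V, mV)
* metrics: JSON with a provenance block (config hash, package version,
  wall time)
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry import TissueField
from .ik1 import IK1Params, IVCurve
from .synthetic import APWaveform

__all__ = [
    "SchemaError",
    "RunConfig",
    "write_iv_csv", "read_iv_csv",
    "write_waveform_csv", "read_waveform_csv",
    "write_geometry", "read_geometry",
    "write_params_json", "read_params_json",
    "write_probes_csv", "read_probes_csv",
    "write_vtk_snapshot", "read_vtk_snapshot",
    "write_metrics_json",
]


class SchemaError(ValueError):
    """A file does not match its expected schema."""


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_CONFIG_FIELDS = {
    "genotype", "regions", "dt_ms", "dx_mm", "d_iso", "anisotropy_ratio",
    "protocol", "intervention", "out_dir", "seed",
}


@dataclass(frozen=True)
class RunConfig:
    """Serialisable description of a simulation run."""

    genotype: str = "WT"
    regions: tuple = ("RA",)
    dt_ms: float = 0.02
    dx_mm: float = 0.25
    d_iso: float = 0.21
    anisotropy_ratio: float = 1.0
    protocol: dict = field(default_factory=dict)
    intervention: dict = field(default_factory=dict)
    out_dir: str = "."
    seed: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        d["regions"] = list(self.regions)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        unknown = set(d) - _CONFIG_FIELDS
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        d["regions"] = tuple(d.get("regions", ("RA",)))
        return cls(**d)

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# CSV formats
# ---------------------------------------------------------------------------

def _read_csv(path, required_cols):
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise SchemaError(f"{path}: not parseable as CSV ({exc})") from exc
    for col in required_cols:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r} "
                              f"(found {list(df.columns)})")
    if df[list(required_cols)].isna().any().any():
        raise SchemaError(f"{path}: non-numeric or missing values")
    return df


def write_iv_csv(curve: IVCurve, path) -> None:
    pd.DataFrame({"voltage_mV": curve.voltages,
                  "current_pA_pF": curve.currents}).to_csv(path, index=False)


def read_iv_csv(path, genotype: str | None = None) -> IVCurve:
    df = _read_csv(path, ("voltage_mV", "current_pA_pF"))
    return IVCurve(voltages=df["voltage_mV"].to_numpy(),
                   currents=df["current_pA_pF"].to_numpy(), genotype=genotype)


def write_waveform_csv(wf: APWaveform, path) -> None:
    pd.DataFrame({"time_ms": wf.times, "voltage_mV": wf.voltages}
                 ).to_csv(path, index=False)


def read_waveform_csv(path, cycle_length: float | None = None) -> APWaveform:
    df = _read_csv(path, ("time_ms", "voltage_mV"))
    t = df["time_ms"].to_numpy()
    if cycle_length is None:
        cycle_length = float(t[-1])
    return APWaveform(times=t, voltages=df["voltage_mV"].to_numpy(),
                      cycle_length=cycle_length)


def write_probes_csv(t, probes, path, labels=None) -> None:
    probes = np.atleast_2d(np.asarray(probes))
    if probes.shape[0] != len(t):
        probes = probes.T
    cols = {"time_ms": t}
    for k in range(probes.shape[1]):
        cols[labels[k] if labels else f"probe_{k}"] = probes[:, k]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_probes_csv(path):
    df = _read_csv(path, ("time_ms",))
    t = df.pop("time_ms").to_numpy()
    return t, df.to_numpy(), list(df.columns)


# ---------------------------------------------------------------------------
# parameter JSON
# ---------------------------------------------------------------------------

def write_params_json(params: IK1Params, path, residual: float | None = None,
                      converged: bool | None = None) -> None:
    d = {"g_k1": params.g_k1, "a": params.a, "b": params.b,
         "genotype": params.genotype}
    if params.mixture_weight is not None:
        d["mixture_weight"] = params.mixture_weight
    if residual is not None:
        d["fit_residual"] = residual
    if converged is not None:
        d["converged"] = converged
    Path(path).write_text(json.dumps(d, indent=2))


def read_params_json(path) -> IK1Params:
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: invalid JSON ({exc})") from exc
    for key in ("g_k1", "a", "b"):
        if key not in d:
            raise SchemaError(f"{path}: missing field {key!r}")
    return IK1Params(g_k1=d["g_k1"], a=d["a"], b=d["b"],
                     mixture_weight=d.get("mixture_weight"),
                     genotype=d.get("genotype"))


# ---------------------------------------------------------------------------
# geometry text format
# ---------------------------------------------------------------------------

def write_geometry(geom: TissueField, path) -> None:
    lines = [
        "# atrikir geometry v1 (node-centred, 0-based indices, C order)",
        f"shape {' '.join(str(s) for s in geom.shape)}",
        f"dx_mm {geom.dx:.17g}",
        f"d_iso {geom.d_iso:.17g}",
        f"anisotropy_ratio {geom.anisotropy_ratio:.17g}",
        f"regions {' '.join(geom.region_names)}",
        "# region_id fibre_x fibre_y fibre_z active",
    ]
    rid = geom.region_ids.ravel()
    fib = geom.fibres.reshape(-1, 3)
    act = geom.active.ravel()
    for k in range(geom.n_nodes):
        lines.append(f"{rid[k]} {fib[k, 0]:.17g} {fib[k, 1]:.17g} "
                     f"{fib[k, 2]:.17g} {int(act[k])}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_geometry(path) -> TissueField:
    lines = [ln for ln in Path(path).read_text().splitlines()
             if ln and not ln.startswith("#")]
    header = {}
    body_start = 0
    for k, ln in enumerate(lines):
        parts = ln.split()
        if parts[0] in ("shape", "dx_mm", "d_iso", "anisotropy_ratio", "regions"):
            header[parts[0]] = parts[1:]
            body_start = k + 1
        else:
            break
    for key in ("shape", "dx_mm", "regions"):
        if key not in header:
            raise SchemaError(f"{path}: missing geometry header field {key!r}")
    shape = tuple(int(s) for s in header["shape"])
    n = int(np.prod(shape))
    body = lines[body_start:]
    if len(body) != n:
        raise SchemaError(f"{path}: expected {n} node records, got {len(body)}")
    rid = np.empty(n, dtype=np.int32)
    fib = np.empty((n, 3))
    act = np.empty(n, dtype=bool)
    for k, ln in enumerate(body):
        parts = ln.split()
        if len(parts) != 5:
            raise SchemaError(f"{path}: bad node record on data line {k}: {ln!r}")
        rid[k] = int(parts[0])
        fib[k] = [float(p) for p in parts[1:4]]
        act[k] = bool(int(parts[4]))
    return TissueField(
        shape=shape, dx=float(header["dx_mm"][0]),
        region_ids=rid.reshape(shape), region_names=tuple(header["regions"]),
        fibres=fib.reshape(shape + (3,)), active=act.reshape(shape),
        d_iso=float(header.get("d_iso", ["0.21"])[0]),
        anisotropy_ratio=float(header.get("anisotropy_ratio", ["1.0"])[0]),
    )


# ---------------------------------------------------------------------------
# VTK legacy structured-points snapshots (plain ASCII)
# ---------------------------------------------------------------------------

def write_vtk_snapshot(v_field: np.ndarray, geom: TissueField, path,
                       name: str = "V_mV") -> None:
    """Scalar voltage snapshot as legacy-VTK STRUCTURED_POINTS ASCII."""
    v = np.asarray(v_field, dtype=float).reshape(geom.shape)
    dims3 = tuple(geom.shape) + (1,) * (3 - geom.ndim)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("atrikir membrane potential snapshot\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        # VTK orders x fastest; our arrays are C-ordered (x slowest)
        fh.write(f"DIMENSIONS {dims3[0]} {dims3[1]} {dims3[2]}\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {geom.dx} {geom.dx} {geom.dx}\n")
        fh.write(f"POINT_DATA {v.size}\n")
        fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        flat = v.reshape(dims3, order="C").transpose(2, 1, 0).ravel()
        np.savetxt(fh, flat, fmt="%.4f")


def read_vtk_snapshot(path):
    """Read back a snapshot written by :func:`write_vtk_snapshot`.

    Returns (array with x-slowest C ordering, dims, spacing).
    """
    lines = Path(path).read_text().splitlines()
    dims = spacing = None
    data_start = None
    for k, ln in enumerate(lines):
        if ln.startswith("DIMENSIONS"):
            dims = tuple(int(x) for x in ln.split()[1:4])
        elif ln.startswith("SPACING"):
            spacing = float(ln.split()[1])
        elif ln.startswith("LOOKUP_TABLE"):
            data_start = k + 1
            break
    if dims is None or data_start is None:
        raise SchemaError(f"{path}: not a structured-points VTK file")
    vals = np.array([float(x) for x in lines[data_start:data_start + int(np.prod(dims))]])
    if vals.size != np.prod(dims):
        raise SchemaError(f"{path}: truncated VTK data section")
    arr = vals.reshape(dims[::-1]).transpose(2, 1, 0)
    return np.squeeze(arr), dims, spacing


# ---------------------------------------------------------------------------
# metrics JSON with provenance
# ---------------------------------------------------------------------------

def write_metrics_json(metrics: dict, path, config: RunConfig | None = None,
                       wall_time_s: float | None = None) -> None:
    payload = dict(metrics)
    payload["provenance"] = {
        "package_version": __version__,
        "config_sha256": config.digest() if config is not None else None,
        "wall_time_s": wall_time_s,
        "written_at_unix": int(time.time()),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=float))
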
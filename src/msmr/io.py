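"""File round-tripping for traces, timestamps, curves and configs.

Trace files are plain text: a two-line header (``# bin_width_s=<float>``,
``# n=<int>``) followed by one integer count per line; read/write is
bit-exact.  Timestamp files hold one sorted float arrival time (seconds)
per line.  Curves are CSV with the column layout of
:data:`msmr.traces.CURVE_COLUMNS` plus correction flags.  Workflow and
simulation configs are YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .corrections import DetectorParams
from .errors import ConfigError, FormatError
from .models import PSFGeometry
from .simulate import SimulationConfig, Species
from .traces import MSMRCurve, PhotonTrace, bin_timestamps

__all__ = [
    "read_trace", "write_trace", "read_timestamps",
    "read_curve", "write_curve",
    "load_simulation_config", "load_detector_params",
]


def write_trace(trace: PhotonTrace, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# bin_width_s={trace.bin_width!r}\n")
        fh.write(f"# n={len(trace)}\n")
        np.savetxt(fh, trace.counts, fmt="%d")


def read_trace(path) -> PhotonTrace:
    path = Path(path)
    with path.open() as fh:
        header = {}
        for lineno in (1, 2):
            line = fh.readline().strip()
            if not line.startswith("#") or "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected '# key=value' header line")
            key, _, value = line[1:].strip().partition("=")
            header[key.strip()] = value.strip()
        if "bin_width_s" not in header or "n" not in header:
            raise FormatError(f"{path}: header must define bin_width_s and n")
        try:
            bin_width = float(header["bin_width_s"])
            n = int(header["n"])
        except ValueError as exc:
            raise FormatError(f"{path}: malformed header value: {exc}") from exc
        counts = np.empty(n, dtype=np.int64)
        for i in range(n):
            line = fh.readline()
            if not line:
                raise FormatError(f"{path}: expected {n} counts, file ends at {i}")
            try:
                c = int(line)
            except ValueError as exc:
                raise FormatError(f"{path}:{i + 3}: not an integer count: {line.strip()!r}") from exc
            if c < 0:
                raise FormatError(f"{path}:{i + 3}: negative count {c}")
            counts[i] = c
    return PhotonTrace(counts, bin_width)


def read_timestamps(path, bin_width: float, duration: float | None = None) -> PhotonTrace:
    """Read a sorted arrival-time file and bin it into a trace."""
    path = Path(path)
    try:
        ts = np.loadtxt(path, dtype=float, ndmin=1)
    except ValueError as exc:
        raise FormatError(f"{path}: malformed timestamp file: {exc}") from exc
    return bin_timestamps(ts, bin_width, duration=duration)


def write_curve(curve: MSMRCurve, path) -> None:
    curve.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_curve(path) -> MSMRCurve:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse curve CSV: {exc}") from exc
    required = {"T_s", "m1", "m2", "m3", "n_bins", "Q", "mu_cps"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing curve columns {sorted(missing)}")
    if np.any(np.diff(df["T_s"].to_numpy()) <= 0):
        raise FormatError(f"{path}: sampling times must be strictly increasing")
    return MSMRCurve.from_frame(df)


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ConfigError(f"{context}: missing required key {key!r}")
    return mapping[key]


def load_detector_params(block: dict) -> DetectorParams:
    """Detector block: dead_time_ns, afterpulse_prob, background_cps."""
    return DetectorParams(
        t_dead=float(block.get("dead_time_ns", 0.0)) * 1e-9,
        p_afterpulse=float(block.get("afterpulse_prob", 0.0)),
        background_rate=float(block.get("background_cps", 0.0)),
    )


def load_simulation_config(block: dict, seed: int | None = None) -> SimulationConfig:
    """Build a SimulationConfig from a parsed YAML mapping."""
    geo_block = _require(block, "geometry", "simulation config")
    geometry = PSFGeometry(r0=float(_require(geo_block, "r0_um", "geometry")),
                           z0=float(_require(geo_block, "z0_um", "geometry")))
    species = []
    for i, sp in enumerate(_require(block, "species", "simulation config")):
        species.append(Species(
            D=float(_require(sp, "D_um2_s", f"species[{i}]")),
            count=int(_require(sp, "count", f"species[{i}]")),
            mu0=float(_require(sp, "mu0_cps", f"species[{i}]")),
            k_on=float(sp.get("k_on_per_s", 0.0)),
            k_off=float(sp.get("k_off_per_s", 0.0)),
        ))
    kwargs = {}
    if "output_bin_width_s" in block:
        kwargs["output_bin_width"] = float(block["output_bin_width_s"])
    return SimulationConfig(
        species=tuple(species),
        geometry=geometry,
        duration=float(_require(block, "duration_s", "simulation config")),
        box_multiplier=float(block.get("box_multiplier", 12.0)),
        max_step_nm=float(block.get("max_step_nm", 20.0)),
        seed=int(block.get("seed", 0) if seed is None else seed),
        **kwargs,
    )


def load_yaml(path) -> dict:
    path = Path(path)
    try:
        with path.open() as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise FormatError(f"{path}: malformed YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise FormatError(f"{path}: top level must be a mapping")
    return data
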
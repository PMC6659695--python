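"""File formats: event tables, trace containers, rate-curve tables, configs.

Event sets travel as tab-separated text with a fixed eight-column schema
and a ``#``-prefixed provenance header that records units; readers
reject tables without a unit declaration, schema mismatches, and rows
whose force sign contradicts the stored direction.  Traces go to HDF5
(one group per trace: time/force datasets, assay metadata as attributes,
the ground-truth event log as a subgroup).  Experiment configurations
are YAML.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd
import yaml

from .bond_models import AnisotropicBond, RateLaw
from .synthetic import (
    EVENT_COLUMNS,
    EventSet,
    DwellSet,
    ForceTrace,
    MotorLinkage,
    PullingProtocol,
    RunSet,
    TrapConfig,
)

__all__ = [
    "SchemaError",
    "read_events",
    "write_events",
    "read_traces",
    "write_traces",
    "read_dwells",
    "write_dwells",
    "read_runs",
    "write_runs",
    "write_rate_curve",
    "bond_from_config",
    "law_from_config",
    "load_config",
]

_EVENT_UNITS = "t_bind:s t_unbind:s F_start:pN F_unbind:pN r_local:pN/s"


class SchemaError(ValueError):
    """Malformed table: wrong columns, units, or cell values."""


def _header_block(kind: str, units: str, extra: dict | None = None) -> str:
    lines = [f"# mtbond {kind} table", f"# units: {units}"]
    for key, val in (extra or {}).items():
        lines.append(f"# {key}: {val}")
    return "\n".join(lines) + "\n"


def write_events(events: EventSet, path: str | Path) -> None:
    """Write an event table (TSV, full-precision floats, unit header)."""
    df = events.to_frame()
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_block("events", _EVENT_UNITS, {"label": events.label,
                                                        "N": events.N}))
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_events(path: str | Path, label: str | None = None) -> EventSet:
    """Read an event table, validating schema, units, and sign conventions."""
    path = Path(path)
    header_lines: list[str] = []
    with open(path) as fh:
        body_start = 0
        lines = fh.readlines()
    for line in lines:
        if line.startswith("#"):
            header_lines.append(line)
            body_start += 1
        else:
            break
    if not any("units:" in h for h in header_lines):
        raise SchemaError(f"{path}: missing unit declaration in header block")
    body = "".join(lines[body_start:])
    df = pd.read_csv(_io.StringIO(body), sep="\t", dtype=str)
    got = tuple(df.columns)
    if got != EVENT_COLUMNS:
        missing = set(EVENT_COLUMNS) - set(got)
        extra = set(got) - set(EVENT_COLUMNS)
        raise SchemaError(
            f"{path}: column mismatch (missing={sorted(missing)}, "
            f"extra={sorted(extra)})"
        )
    if df.empty:
        import warnings

        warnings.warn(f"{path}: event table is empty", stacklevel=2)
        return EventSet(events=[], label=label or "")
    numeric = ["t_bind", "t_unbind", "F_start", "F_unbind", "r_local"]
    for col in numeric:
        try:
            df[col] = df[col].astype(float)
        except ValueError:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise SchemaError(
                f"{path}: non-numeric value in column {col!r}, row {bad + 1}"
            ) from None
    for i, d in enumerate(df["direction"]):
        if d not in ("forward", "backward"):
            raise SchemaError(
                f"{path}: invalid direction {d!r} in row {i + 1}, "
                "column 'direction'"
            )
    # cross-validate the redundant sign encoding
    F = df["F_unbind"].to_numpy()
    fwd = df["direction"].to_numpy() == "forward"
    bad_sign = (fwd & (F > 0)) | (~fwd & (F < 0))
    if np.any(bad_sign):
        row = int(np.flatnonzero(bad_sign)[0])
        raise SchemaError(
            f"{path}: force sign contradicts direction in row {row + 1}"
        )
    df["primary"] = df["primary"].map(
        {"True": True, "False": False, "true": True, "false": False,
         "1": True, "0": False}
    )
    if df["primary"].isna().any():
        row = int(df["primary"].isna().idxmax())
        raise SchemaError(f"{path}: invalid boolean in column 'primary', row {row + 1}")
    if label is None:
        for h in header_lines:
            if h.startswith("# label:"):
                label = h.split(":", 1)[1].strip()
    return EventSet.from_frame(df, label=label or "")


# ---------------------------------------------------------------------------
# trace container (HDF5)


def write_traces(traces: list[ForceTrace], path: str | Path) -> None:
    """One HDF5 group per trace: time/force datasets, metadata, truth log."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "mtbond-traces-v1"
        f.attrs["units"] = "t:s F:pN"
        for tr in traces:
            g = f.create_group(tr.trace_id)
            g.create_dataset("t", data=tr.t)
            g.create_dataset("F", data=tr.F)
            g.attrs["seed"] = tr.seed
            for key, val in (
                ("k_trap", tr.trap.k_trap),
                ("v_stage", tr.trap.v_stage),
                ("f_sample", tr.trap.f_sample),
                ("sigma_noise", tr.trap.sigma_noise),
                ("tau_bead", tr.trap.tau_bead),
                ("k_motor", tr.linkage.k_motor),
                ("rigid", tr.linkage.rigid),
                ("mode", tr.protocol.mode),
                ("sweep_duration", tr.protocol.sweep_duration),
            ):
                g.attrs[key] = val
            tg = g.create_group("truth")
            df = tr.truth.to_frame()
            for col in EVENT_COLUMNS:
                data = df[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                tg.create_dataset(col, data=data)


def read_traces(path: str | Path) -> list[ForceTrace]:
    traces: list[ForceTrace] = []
    with h5py.File(path, "r") as f:
        for trace_id in f:
            g = f[trace_id]
            trap = TrapConfig(
                k_trap=float(g.attrs["k_trap"]),
                v_stage=float(g.attrs["v_stage"]),
                f_sample=float(g.attrs["f_sample"]),
                sigma_noise=float(g.attrs["sigma_noise"]),
                tau_bead=float(g.attrs["tau_bead"]),
            )
            link = (
                MotorLinkage()
                if bool(g.attrs["rigid"])
                else MotorLinkage.compliant(float(g.attrs["k_motor"]))
            )
            proto = PullingProtocol(
                mode=str(g.attrs["mode"]),
                sweep_duration=float(g.attrs["sweep_duration"]),
            )
            cols = {}
            for col in EVENT_COLUMNS:
                data = g["truth"][col][()]
                if data.dtype.kind == "S":
                    data = data.astype(str)
                cols[col] = data
            truth = EventSet.from_frame(pd.DataFrame(cols, columns=list(EVENT_COLUMNS)))
            traces.append(
                ForceTrace(
                    t=g["t"][()],
                    F=g["F"][()],
                    trap=trap,
                    linkage=link,
                    protocol=proto,
                    seed=int(g.attrs["seed"]),
                    trace_id=trace_id,
                    truth=truth,
                )
            )
    return traces


# ---------------------------------------------------------------------------
# dwell / run tables


def write_dwells(dwells: DwellSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            _header_block(
                "dwells",
                "dwell:s frame_interval:s",
                {"frame_interval": dwells.frame_interval,
                 "n_discarded": dwells.n_discarded},
            )
        )
        pd.DataFrame({"dwell": dwells.dwells}).to_csv(
            fh, sep="\t", index=False, float_format="%.17g"
        )


def read_dwells(path: str | Path) -> DwellSet:
    frame = None
    n_disc = 0
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            if line.startswith("# frame_interval:"):
                frame = float(line.split(":", 1)[1])
            elif line.startswith("# n_discarded:"):
                n_disc = int(line.split(":", 1)[1])
        else:
            body.append(line)
    if frame is None:
        raise SchemaError(f"{path}: missing frame_interval in header")
    df = pd.read_csv(_io.StringIO("".join(body)), sep="\t", float_precision="round_trip")
    if list(df.columns) != ["dwell"]:
        raise SchemaError(f"{path}: expected single column 'dwell'")
    return DwellSet(
        dwells=df["dwell"].to_numpy(float),
        frame_interval=frame,
        n_discarded=n_disc,
    )


def write_runs(runs: RunSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            _header_block(
                "runs", "velocity:nm/s run_length:um", {"L_min": runs.L_min}
            )
        )
        pd.DataFrame(
            {"velocity": runs.velocities, "run_length": runs.run_lengths}
        ).to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_runs(path: str | Path) -> RunSet:
    L_min = 0.0
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            if line.startswith("# L_min:"):
                L_min = float(line.split(":", 1)[1])
        else:
            body.append(line)
    df = pd.read_csv(_io.StringIO("".join(body)), sep="\t", float_precision="round_trip")
    if list(df.columns) != ["velocity", "run_length"]:
        raise SchemaError(f"{path}: expected columns velocity, run_length")
    return RunSet(
        velocities=df["velocity"].to_numpy(float),
        run_lengths=df["run_length"].to_numpy(float),
        L_min=L_min,
    )


def write_rate_curve(curve, path: str | Path) -> None:
    """Rate-curve table: F, k, lo, hi, n_beyond, S plus a metadata block."""
    extra = {
        "bandwidth_pN": f"{curve.bandwidth:.17g}",
        "S_min": curve.S_min,
        "n_events": curve.n_events,
    }
    extra.update({k: v for k, v in curve.meta.items()})
    if curve.anchor_rate is not None:
        extra["zero_load_anchor_per_s"] = f"{curve.anchor_rate:.17g}"
        extra["zero_load_anchor_se"] = f"{curve.anchor_se:.17g}"
    with open(path, "w") as fh:
        fh.write(_header_block("rate-curve", "F:pN k:1/s lo:1/s hi:1/s S:1", extra))
        pd.DataFrame(
            {
                "F": curve.F,
                "k": curve.k,
                "lo": curve.lo,
                "hi": curve.hi,
                "n_beyond": curve.n_beyond,
                "S": curve.S,
            }
        ).to_csv(fh, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# configuration


def law_from_config(spec: dict) -> RateLaw:
    """Build a rate law from a config mapping.

    Either ``{type: ideal|bell_slip|slip_ideal|ideal_slip, ...params}`` or
    an explicit ``{segments: [...]}`` block.  Round-trips bit-exactly via
    :meth:`RateLaw.to_dict`.
    """
    if "segments" in spec:
        return RateLaw.from_dict(spec)
    kind = spec.get("type")
    F_max = float(spec.get("F_max", 25.0))
    if kind == "ideal":
        return RateLaw.ideal(float(spec["k0"]), F_max=F_max)
    if kind == "bell_slip":
        return RateLaw.bell_slip(float(spec["k0"]), float(spec["F_scale"]), F_max=F_max)
    if kind == "slip_ideal":
        return RateLaw.slip_ideal(
            float(spec["k0"]), float(spec["F_scale"]), float(spec["F_switch"]),
            F_max=F_max,
        )
    if kind == "ideal_slip":
        return RateLaw.ideal_slip(
            float(spec["k0"]), float(spec["F_switch"]), float(spec["F_scale"]),
            F_max=F_max,
        )
    raise SchemaError(f"unknown rate-law type {kind!r}")


def bond_from_config(spec: dict) -> AnisotropicBond:
    return AnisotropicBond(
        forward=law_from_config(spec["forward"]),
        backward=law_from_config(spec["backward"]),
    )


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg
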
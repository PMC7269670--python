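"""Serialization: configs as YAML, traces and event trains as tidy CSV, fits as JSON.

Every output carries enough metadata (seeds, parameters) to be regenerated
from scratch; round-trips are lossless at double precision.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import BoltzmannFit, ExpFit
from .cell import CellConfig, MorphologyStandIn, PassiveParams
from .drive import EventTrain
from .engine import Trace, TraceSet

__all__ = [
    "save_cell",
    "load_cell",
    "save_traces",
    "load_traces",
    "save_events",
    "load_events",
    "save_traces_h5",
    "load_traces_h5",
    "fit_to_json",
    "fit_from_json",
]


def _cell_to_dict(cell: CellConfig) -> dict:
    return {
        "morphology": {
            "soma": list(cell.morphology.soma),
            "dendrites": [list(d) for d in cell.morphology.dendrites],
        },
        "passive": dataclasses.asdict(cell.passive),
        "soma_channels_S_per_cm2": dict(cell.soma_channels),
        "dend_channels_S_per_cm2": dict(cell.dend_channels),
        "phenotype": cell.phenotype,
        "isa_profile": cell.isa_profile,
        "e_leak_soma_mV": cell.e_leak_soma,
        "e_leak_dend_mV": cell.e_leak_dend,
        "resting_potential_mV": cell.resting_potential,
        "seed": cell.seed,
    }


def save_cell(cell: CellConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_cell_to_dict(cell), sort_keys=True))


def load_cell(path) -> CellConfig:
    d = yaml.safe_load(Path(path).read_text())
    morph = MorphologyStandIn(
        soma=tuple(d["morphology"]["soma"]),
        dendrites=tuple(tuple(x[:2]) + (int(x[2]),) for x in d["morphology"]["dendrites"]),
    )
    return CellConfig(
        morphology=morph,
        passive=PassiveParams(**d["passive"]),
        soma_channels=dict(d["soma_channels_S_per_cm2"]),
        dend_channels=dict(d["dend_channels_S_per_cm2"]),
        phenotype=d["phenotype"],
        isa_profile=d["isa_profile"],
        e_leak_soma=d["e_leak_soma_mV"],
        e_leak_dend=d["e_leak_dend_mV"],
        resting_potential=d["resting_potential_mV"],
        seed=d["seed"],
    )


def save_traces(ts: TraceSet, path) -> None:
    """Tidy CSV: one row per (time, channel) sample."""
    frames = []
    for name, tr in ts.traces.items():
        frames.append(pd.DataFrame({"time_ms": tr.t, "name": name, "value": tr.y, "units": tr.units}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def load_traces(path) -> TraceSet:
    df = pd.read_csv(path, float_precision="round_trip")
    traces = {}
    dt = 0.0
    for name, g in df.groupby("name", sort=False):
        tr = Trace(g["time_ms"].to_numpy(), g["value"].to_numpy(), str(name), str(g["units"].iloc[0]))
        traces[str(name)] = tr
        dt = tr.dt
    return TraceSet(traces=traces, dt=dt)


def save_events(train: EventTrain, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# duration_ms={train.duration!r} seed={train.seed!r}\n")
        train.to_frame().to_csv(fh, index=False, float_format="%.17g")


def load_events(path) -> EventTrain:
    path = Path(path)
    header = path.read_text().splitlines()[0]
    meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    seed = None if meta.get("seed") in (None, "None") else int(meta["seed"])
    return EventTrain.from_frame(frame, duration=float(meta["duration_ms"]), seed=seed)


def fit_to_json(fit) -> str:
    if isinstance(fit, BoltzmannFit):
        return json.dumps({"type": "boltzmann", **dataclasses.asdict(fit)}, sort_keys=True)
    if isinstance(fit, ExpFit):
        d = dataclasses.asdict(fit)
        d["taus"] = list(d["taus"])
        d["amplitudes"] = list(d["amplitudes"])
        return json.dumps({"type": "exponential", **d}, sort_keys=True)
    raise TypeError(f"unsupported fit type {type(fit)!r}")


def fit_from_json(text: str):
    d = json.loads(text)
    kind = d.pop("type")
    if kind == "boltzmann":
        return BoltzmannFit(**d)
    if kind == "exponential":
        d["taus"] = tuple(d["taus"])
        d["amplitudes"] = tuple(d["amplitudes"])
        return ExpFit(**d)
    raise ValueError(f"unknown fit type {kind!r}")


def save_traces_h5(ts: TraceSet, path) -> None:
    """Compact binary container for trace sets (HDF5)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["dt_ms"] = ts.dt
        for name, tr in ts.traces.items():
            g = f.create_group(name)
            g.create_dataset("t", data=tr.t, compression="gzip")
            g.create_dataset("y", data=tr.y, compression="gzip")
            g.attrs["units"] = tr.units


def load_traces_h5(path) -> TraceSet:
    import h5py

    traces = {}
    with h5py.File(path, "r") as f:
        dt = float(f.attrs["dt_ms"])
        for name in f:
            g = f[name]
            traces[name] = Trace(g["t"][...], g["y"][...], name, str(g.attrs["units"]))
    return TraceSet(traces=traces, dt=dt)
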
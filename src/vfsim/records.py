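"""HDF5 persistence of simulation records and checkpoints, plus CSV export."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .coupling import SimulationRecord
from .errors import VfsimError
from .flow import FlowState
from .solid import SolidState

RECORD_VERSION = "1"

_SERIES_UNITS = {
    "time": "s", "marker_disp": "m", "min_area": "m^2", "flux": "m^3/s",
    "work_rate": "W", "work_acc": "J", "kinetic": "J", "strain": "J",
    "damping_acc": "J", "subiters": "count",
}


def write_record(record: SimulationRecord, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["version"] = RECORD_VERSION
        f.attrs["meta"] = json.dumps(record.meta)
        g = f.create_group("series")
        for name, data in record.series_dict().items():
            d = g.create_dataset(name, data=np.asarray(data))
            d.attrs["units"] = _SERIES_UNITS.get(name, "")
        snaps = f.create_group("snapshots")
        for i, snap in enumerate(record.snapshots):
            sg = snaps.create_group(f"{i:04d}")
            sg.attrs["time"] = snap["time"]
            for name in ("x", "area", "u", "p", "tau", "p_total"):
                sg.create_dataset(name, data=np.asarray(snap[name]))
        f.attrs["complete"] = True


def read_record(path) -> SimulationRecord:
    try:
        with h5py.File(path, "r") as f:
            version = f.attrs.get("version")
            if version != RECORD_VERSION:
                raise VfsimError(
                    f"record version mismatch: file has {version!r}, "
                    f"reader expects {RECORD_VERSION!r}")
            if not f.attrs.get("complete", False):
                raise VfsimError(f"record {path} is incomplete (truncated?)")
            series = {k: f["series"][k][...] for k in f["series"]}
            snaps = []
            for key in sorted(f["snapshots"]):
                sg = f["snapshots"][key]
                snap = {name: sg[name][...] for name in sg}
                snap["time"] = float(sg.attrs["time"])
                snaps.append(snap)
            meta = json.loads(f.attrs["meta"])
    except OSError as exc:
        raise VfsimError(f"cannot read record {path}: {exc}") from exc
    return SimulationRecord(snapshots=snaps, meta=meta, **series)


def export_csv(record: SimulationRecord, directory) -> list:
    """Mirror every series (and each snapshot) as CSV with a units header."""
    from pathlib import Path
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    series = record.series_dict()
    path = directory / "series.csv"
    with open(path, "w") as fh:
        fh.write("# units: " + ", ".join(
            f"{k}={_SERIES_UNITS.get(k, '')}" for k in series) + "\n")
        pd.DataFrame(series).to_csv(fh, index=False)
    written.append(path)
    for i, snap in enumerate(record.snapshots):
        path = directory / f"snapshot_{i:04d}.csv"
        with open(path, "w") as fh:
            fh.write(f"# t = {snap['time']} s; units: x=m, area=m^2, "
                     "u=m/s, p=Pa, tau=Pa, p_total=Pa\n")
            pd.DataFrame({k: snap[k] for k in
                          ("x", "area", "u", "p", "tau", "p_total")}
                         ).to_csv(fh, index=False)
        written.append(path)
    return written


# -- checkpointing -----------------------------------------------------------

def write_checkpoint(path, solid: SolidState, flow: FlowState, step: int,
                     series: dict, work_acc: float, damping_acc: float,
                     prev_power: float, prev_dpow: float,
                     snapshots: list) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["version"] = RECORD_VERSION
        f.attrs["step"] = step
        f.attrs["scalars"] = json.dumps(dict(
            work_acc=work_acc, damping_acc=damping_acc,
            prev_power=prev_power, prev_dpow=prev_dpow,
            solid_time=solid.time, flow_time=flow.time,
            Q=flow.Q, rho=flow.rho, mu_eff=flow.mu_eff,
            P_in=flow.P_in, P_out=flow.P_out, i_sep=flow.i_sep))
        sg = f.create_group("solid")
        sg.create_dataset("displacement", data=solid.displacement)
        sg.create_dataset("velocity", data=solid.velocity)
        sg.create_dataset("acceleration", data=solid.acceleration)
        fg = f.create_group("flow")
        for name in ("x", "area", "u", "p", "tau", "u_avg"):
            fg.create_dataset(name, data=getattr(flow, name))
        rg = f.create_group("series")
        for name, vals in series.items():
            rg.create_dataset(name, data=np.asarray(vals))
        hg = f.create_group("snapshots")
        for i, snap in enumerate(snapshots):
            g2 = hg.create_group(f"{i:04d}")
            g2.attrs["time"] = snap["time"]
            for name in ("x", "area", "u", "p", "tau", "p_total"):
                g2.create_dataset(name, data=np.asarray(snap[name]))
        f.attrs["complete"] = True


def read_checkpoint(path) -> dict:
    try:
        with h5py.File(path, "r") as f:
            if not f.attrs.get("complete", False):
                raise VfsimError(f"checkpoint {path} is incomplete")
            sc = json.loads(f.attrs["scalars"])
            solid = SolidState(
                displacement=f["solid/displacement"][...],
                velocity=f["solid/velocity"][...],
                acceleration=f["solid/acceleration"][...],
                time=sc["solid_time"])
            flow = FlowState(
                x=f["flow/x"][...], area=f["flow/area"][...],
                u=f["flow/u"][...], p=f["flow/p"][...],
                tau=f["flow/tau"][...], Q=sc["Q"], rho=sc["rho"],
                mu_eff=sc["mu_eff"], P_in=sc["P_in"], P_out=sc["P_out"],
                time=sc["flow_time"], i_sep=int(sc["i_sep"]),
                u_avg=f["flow/u_avg"][...])
            series = {k: list(f["series"][k][...]) for k in f["series"]}
            snaps = []
            for key in sorted(f["snapshots"]):
                g2 = f["snapshots"][key]
                snap = {name: g2[name][...] for name in g2}
                snap["time"] = float(g2.attrs["time"])
                snaps.append(snap)
            return dict(solid=solid, flow=flow, step=int(f.attrs["step"]),
                        series=series, work_acc=sc["work_acc"],
                        damping_acc=sc["damping_acc"],
                        prev_power=sc["prev_power"],
                        prev_dpow=sc["prev_dpow"], snapshots=snaps)
    except OSError as exc:
        raise VfsimError(f"cannot read checkpoint {path}: {exc}") from exc
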
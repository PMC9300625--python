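"""Snapshot container IO: HDF5 arrays + CSV tables + JSON manifest.

A snapshot restores a :class:`~angiomet.driver.SimulationState` bit-exactly
(including the RNG stream), so a stopped run can resume and reproduce the
uninterrupted trajectory.  Alongside the HDF5 state container, each snapshot
writes human-readable CSV exports of the cell table and the vessel edge
list, and the run manifest records the resolved config, its hash, the seed
and package versions.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np

from .config import SimConfig, resolve_config
from .driver import FIELD_SPECIES, SimulationState, metabolite_fields
from .fields import FieldGrid
from .lattice import CellPopulation, Lattice
from .metabolism import default_network, load_network
from .vasculature import SproutTip, VascularNetwork


def config_hash(config: SimConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _snapshot_paths(directory, step):
    directory = Path(directory)
    return (directory / f"snapshot_{step:06d}.h5",
            directory / f"cells_{step:06d}.csv",
            directory / f"network_{step:06d}.csv")


def write_snapshot(state: SimulationState, directory, step: int | None = None) -> dict:
    """Write one snapshot; returns its manifest entry."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if step is None:
        step = state.step_idx
    h5_path, cells_csv, net_csv = _snapshot_paths(directory, step)

    with h5py.File(h5_path, "w") as f:
        f.attrs["time_h"] = state.time_h
        f.attrs["step_idx"] = state.step_idx
        f.attrs["next_tip_id"] = state.next_tip_id
        f.attrs["config_hash"] = config_hash(state.config)
        f.attrs["config_json"] = json.dumps(state.config.to_dict(), sort_keys=True)
        f.attrs["rng_state"] = json.dumps(state.rng.bit_generator.state)
        f.attrs["counters"] = json.dumps(state.counters, sort_keys=True)

        g = f.create_group("cells")
        pop = state.pop
        for name in ("pos", "ctype", "state", "phase", "p53", "ivegf", "q_clock", "met"):
            g.create_dataset(name, data=getattr(pop, name))

        g = f.create_group("network")
        net = state.network
        g.create_dataset("node_pos", data=np.asarray(net.node_pos, dtype=np.int64).reshape(-1, 3))
        g.create_dataset("pressure", data=net.pressure)
        g.create_dataset("boundary_nodes", data=np.array(sorted(net.boundary), dtype=np.int64))
        g.create_dataset("boundary_pressures",
                         data=np.array([net.boundary[k] for k in sorted(net.boundary)]))
        for name in ("seg_a", "seg_b", "radius", "flow", "functional", "zero_flow_h"):
            g.create_dataset(name, data=np.asarray(getattr(net, name)))

        g = f.create_group("tips")
        tips = state.tips
        g.create_dataset("tip_id", data=np.array([t.tip_id for t in tips], dtype=np.int64))
        g.create_dataset("position", data=np.array([t.position for t in tips],
                                                   dtype=np.int64).reshape(-1, 3))
        g.create_dataset("attachment", data=np.array([t.attachment_node for t in tips],
                                                     dtype=np.int64))
        g.create_dataset("age", data=np.array([t.age for t in tips]))
        g.create_dataset("stalled_h", data=np.array([t.stalled_h for t in tips]))
        prev = np.array([t.prev_site if t.prev_site is not None else (-1, -1, -1)
                         for t in tips], dtype=np.int64).reshape(-1, 3)
        g.create_dataset("prev_site", data=prev)
        trail_flat = np.concatenate([np.asarray(t.trail, dtype=np.int64)
                                     for t in tips]) if tips else np.zeros(0, dtype=np.int64)
        offsets = np.cumsum([0] + [len(t.trail) for t in tips]).astype(np.int64)
        g.create_dataset("trail_flat", data=trail_flat)
        g.create_dataset("trail_offsets", data=offsets)

        g = f.create_group("fields")
        for sp in FIELD_SPECIES:
            g.create_dataset(sp, data=state.fields[sp].values)
        g = f.create_group("metabolite_fields")
        for sp, arr in metabolite_fields(state).items():
            g.create_dataset(sp, data=arr)

    state.pop.to_dataframe(step=step, time_h=state.time_h).to_csv(cells_csv, index=False)
    state.network.to_dataframe().to_csv(net_csv, index=False)
    return {"step": int(step), "time_h": float(state.time_h),
            "h5": h5_path.name, "cells_csv": cells_csv.name, "network_csv": net_csv.name}


def read_snapshot(directory, step: int) -> SimulationState:
    """Restore a :class:`SimulationState` bit-exactly from a snapshot."""
    h5_path, _, _ = _snapshot_paths(directory, step)
    with h5py.File(h5_path, "r") as f:
        config = resolve_config(json.loads(f.attrs["config_json"]))
        lattice = Lattice.from_config(config.lattice)
        met_net = None
        if config.metabolism.enabled:
            met_net = (load_network(config.metabolism.network)
                       if config.metabolism.network else default_network())
        g = f["cells"]
        pop = CellPopulation(lattice, n_met_species=g["met"].shape[1])
        pop.pos = g["pos"][...].astype(np.int64).reshape(-1, 3)
        pop.ctype = g["ctype"][...].astype(np.int8)
        pop.state = g["state"][...].astype(np.int8)
        pop.phase = g["phase"][...]
        pop.p53 = g["p53"][...]
        pop.ivegf = g["ivegf"][...]
        pop.q_clock = g["q_clock"][...]
        pop.met = g["met"][...].reshape(pop.pos.shape[0], -1)
        pop.occupancy.fill(-1)
        if pop.n:
            pop.occupancy[tuple(pop.pos.T)] = np.arange(pop.n)

        g = f["network"]
        net = VascularNetwork(lattice)
        node_pos = g["node_pos"][...]
        for site in node_pos:
            net.add_node(tuple(int(v) for v in site))
        net.pressure = g["pressure"][...]
        for node, p in zip(g["boundary_nodes"][...], g["boundary_pressures"][...]):
            net.boundary[int(node)] = float(p)
        net.seg_a = [int(v) for v in g["seg_a"][...]]
        net.seg_b = [int(v) for v in g["seg_b"][...]]
        net.radius = [float(v) for v in g["radius"][...]]
        net.flow = [float(v) for v in g["flow"][...]]
        net.functional = [bool(v) for v in g["functional"][...]]
        net.zero_flow_h = [float(v) for v in g["zero_flow_h"][...]]

        g = f["tips"]
        tips = []
        trail_flat = g["trail_flat"][...]
        offsets = g["trail_offsets"][...]
        for i in range(g["tip_id"].shape[0]):
            prev = tuple(int(v) for v in g["prev_site"][i])
            tips.append(SproutTip(
                tip_id=int(g["tip_id"][i]),
                position=tuple(int(v) for v in g["position"][i]),
                attachment_node=int(g["attachment"][i]),
                trail=[int(v) for v in trail_flat[offsets[i]:offsets[i + 1]]],
                age=float(g["age"][i]),
                prev_site=None if prev == (-1, -1, -1) else prev,
                stalled_h=float(g["stalled_h"][i]),
            ))

        fields = {}
        for sp in FIELD_SPECIES:
            fields[sp] = FieldGrid(sp, f["fields"][sp][...], lattice)

        rng = np.random.default_rng(0)
        rng.bit_generator.state = json.loads(f.attrs["rng_state"])
        state = SimulationState(
            config=config, lattice=lattice, pop=pop, network=net, tips=tips,
            fields=fields, met_net=met_net, rng=rng,
            time_h=float(f.attrs["time_h"]), step_idx=int(f.attrs["step_idx"]),
            next_tip_id=int(f.attrs["next_tip_id"]),
            counters=json.loads(f.attrs["counters"]),
        )
    return state


def write_run_manifest(state: SimulationState, directory, entries) -> Path:
    import numpy
    import scipy

    from . import __version__
    directory = Path(directory)
    manifest = {
        "config_hash": config_hash(state.config),
        "config": state.config.to_dict(),
        "seed": state.config.run.seed,
        "final_time_h": state.time_h,
        "counters": state.counters,
        "versions": {"angiomet": __version__, "numpy": numpy.__version__,
                     "scipy": scipy.__version__},
        "snapshots": entries,
    }
    path = directory / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def export_slice(directory, step: int, species: str, axis: int = 2,
                 out_path=None) -> Path:
    """Write the equatorial cross-section of one species to CSV.

    ``species`` may be a diffusible field (glucose/oxygen/vegf) or a
    metabolite name from the metabolic network.
    """
    h5_path, _, _ = _snapshot_paths(directory, step)
    with h5py.File(h5_path, "r") as f:
        if species in f["fields"]:
            arr = f["fields"][species][...]
        elif species in f["metabolite_fields"]:
            arr = f["metabolite_fields"][species][...]
        else:
            raise KeyError(f"species '{species}' not in snapshot "
                           f"(have {list(f['fields'])} + {list(f['metabolite_fields'])})")
    idx = arr.shape[axis] // 2
    plane = np.take(arr, idx, axis=axis)
    if out_path is None:
        out_path = Path(directory) / f"slice_{species}_{step:06d}.csv"
    np.savetxt(out_path, plane, delimiter=",", fmt="%.17g")
    return Path(out_path)
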
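"""Multiscale orchestration: the simulation state, the step loop and runs.

A step executes in fixed order: (1) quasi-steady field solves; (2)
subcellular ODE advance with local oxygen; (3) cellular-automaton step; (4)
vascular step (sprouting, tip migration, anastomosis, flow, remodeling); (5)
field re-solve; (6) per-cell metabolic integration against the frozen local
glucose/oxygen (one-way: metabolism never feeds back on growth).  The
metabolic layer is integrated only after the final field update of the step,
so the diffusible and metabolic models synchronize on the same frozen state.

The default scenario perfuses the domain with two countercurrent parent
vessels, grows healthy tissue to confluence during a burn-in phase (clock
running from -burn_in to 0), and implants a small tumour at t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np

from . import metabolism as mb
from .config import SimConfig
from .errors import PreconditionError, StateError
from .fields import FieldGrid, solve_quasi_steady, vegf_secretion_source
from .lattice import (CELL_CANCER, CELL_NORMAL, CellPopulation, Lattice,
                      ca_step, implant_tumour)
from .vasculature import VascularNetwork, compute_blood_flow, vascular_step

FIELD_SPECIES = ("oxygen", "vegf", "glucose")


@dataclass
class SimulationState:
    """Composition of all model layers plus clock and RNG."""
    config: SimConfig
    lattice: Lattice
    pop: CellPopulation
    network: VascularNetwork
    tips: list
    fields: dict                      # species -> FieldGrid
    met_net: mb.MetabolicNetwork | None
    rng: np.random.Generator
    time_h: float = 0.0
    step_idx: int = 0
    next_tip_id: int = 0
    counters: dict = dfield(default_factory=dict)

    def cell_count(self, cell_type=None) -> int:
        if cell_type is None:
            return self.pop.n
        return int(np.sum(self.pop.ctype == cell_type))


def _build_parent_vessels(net: VascularNetwork, lattice: Lattice, vcfg):
    """Two straight countercurrent parent vessels along x on opposite sides."""
    nx, ny, nz = lattice.dims
    zm = nz // 2
    rows = [(max(ny // 4, 0), vcfg.pressure_in, vcfg.pressure_out),
            (min(3 * ny // 4, ny - 1), vcfg.pressure_out, vcfg.pressure_in)]
    for y, p_start, p_end in rows:
        prev = net.add_node((0, y, zm))
        first = prev
        for i in range(1, nx):
            nxt = net.add_node((i, y, zm))
            net.add_segment(prev, nxt, vcfg.r_init)
            prev = nxt
        net.set_boundary(first, p_start)
        net.set_boundary(prev, p_end)
    return net


def _solve_all_fields(state: SimulationState):
    cfg = state.config
    qcu = cfg.cells.quiescent_cancer_uptake
    for species in FIELD_SPECIES:
        fcfg = getattr(cfg.field, species)
        production = None
        if species == "vegf":
            production = vegf_secretion_source(state.pop, state.lattice,
                                               fcfg.secretion_rate)
        solve_quasi_steady(state.fields[species], fcfg, state.pop, state.network,
                           production=production, quiescent_cancer_uptake=qcu)


def _metabolic_step(state: SimulationState, dt: float):
    if state.met_net is None or state.pop.n == 0:
        return
    cfg = state.config.metabolism
    env_species = list(cfg.env_map.keys())
    env = np.column_stack([
        state.pop.site_values(state.fields[cfg.env_map[s]].values)
        for s in env_species
    ])
    state.pop.met = mb.integrate_population(
        state.met_net, state.pop.met, env, env_species, dt,
        rtol=cfg.rtol, atol=cfg.atol)


def step(state: SimulationState, dt: float) -> SimulationState:
    """Advance the full multiscale state by ``dt`` hours (in place)."""
    if dt <= 0:
        raise PreconditionError("dt must be > 0")
    cfg = state.config
    try:
        _solve_all_fields(state)
    except Exception as exc:
        raise type(exc)(f"[phase 1: field solve] {exc}") from exc

    from .lattice import _advance_arrays
    pop = state.pop
    if pop.n:
        ox = pop.site_values(state.fields["oxygen"].values)
        pop.phase, pop.p53, pop.ivegf = _advance_arrays(
            pop.phase, pop.state, pop.p53, pop.ivegf, pop.ctype, ox, dt,
            cfg.cells.normal, cfg.cells.cancer)

    stats_ca = ca_step(pop, state.fields["oxygen"].values, cfg.cells, dt, state.rng)

    state.tips, state.next_tip_id, stats_v = vascular_step(
        state.network, state.tips, state.fields["vegf"].values,
        cfg.vasculature, state.rng, dt, state.next_tip_id)

    try:
        _solve_all_fields(state)
    except Exception as exc:
        raise type(exc)(f"[phase 5: field re-solve] {exc}") from exc

    try:
        _metabolic_step(state, dt)
    except Exception as exc:
        raise type(exc)(f"[phase 6: metabolism] {exc}") from exc

    state.time_h += dt
    state.step_idx += 1
    for k, v in {**stats_ca, **stats_v}.items():
        state.counters[k] = state.counters.get(k, 0) + v
    return state


def initialize_scenario(config: SimConfig) -> SimulationState:
    """Build the default scenario, deterministic given ``config.run.seed``.

    Parent vessels are laid down and perfused; healthy cells seeded at the
    configured density grow toward confluence during the burn-in (clock runs
    from -burn_in to 0); the tumour is implanted at t = 0 and all metabolic
    states start at the reference state.
    """
    config.validate()
    rng = np.random.default_rng(config.run.seed)
    lattice = Lattice.from_config(config.lattice)
    met_net = None
    n_met = 0
    if config.metabolism.enabled:
        met_net = (mb.load_network(config.metabolism.network)
                   if config.metabolism.network else mb.default_network())
        met_net.validate()
        for name in config.metabolism.env_map:
            if name not in met_net.sp_index:
                raise StateError(f"metabolism env_map names unknown species '{name}'")
        n_met = len(met_net.species)
    pop = CellPopulation(lattice, n_met_species=n_met)
    net = _build_parent_vessels(VascularNetwork(lattice), lattice, config.vasculature)
    compute_blood_flow(net, config.vasculature)

    # seed healthy cells at the configured density
    frac = config.run.initial_healthy_fraction
    n_seed = int(round(frac * lattice.n_sites))
    if n_seed:
        flat = rng.choice(lattice.n_sites, size=n_seed, replace=False)
        sites = np.column_stack(np.unravel_index(flat, lattice.dims))
        phases = rng.random(n_seed)
        for s, ph in zip(sites, phases):
            pop.add_cell(tuple(s), CELL_NORMAL, phase=float(ph))

    fields = {sp: FieldGrid.zeros(sp, lattice) for sp in FIELD_SPECIES}
    state = SimulationState(config=config, lattice=lattice, pop=pop, network=net,
                            tips=[], fields=fields, met_net=met_net, rng=rng,
                            time_h=-config.run.burn_in)

    dt = config.cells.dt
    saved_met = state.met_net
    state.met_net = None          # metabolism idle until tumour implantation
    while state.time_h < -1e-9:
        step(state, min(dt, -state.time_h))
    state.met_net = saved_met
    state.time_h = 0.0
    state.step_idx = 0   # clock and step counter start at implantation

    if config.run.tumour_radius_sites >= 0:
        centre = tuple(d // 2 for d in lattice.dims)
        implant_tumour(pop, centre, config.run.tumour_radius_sites, state.rng)
    if state.met_net is not None and pop.n:
        pop.met[:] = 1.0          # reference state for every cell
    _solve_all_fields(state)
    return state


def run(config: SimConfig, out_dir=None, progress=False):
    """Initialize and run to ``config.run.end_time``, writing snapshots.

    Returns the list of snapshot manifest entries (empty ``out_dir`` keeps
    everything in memory and returns the final state instead).
    """
    from . import snapshots

    state = initialize_scenario(config)
    dt = config.cells.dt
    entries = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        entries.append(snapshots.write_snapshot(state, out_dir, state.step_idx))
    next_snap = config.run.snapshot_every
    while state.time_h < config.run.end_time - 1e-9:
        step(state, min(dt, config.run.end_time - state.time_h))
        if out_dir is not None and (state.time_h >= next_snap - 1e-9
                                    or state.time_h >= config.run.end_time - 1e-9):
            entries.append(snapshots.write_snapshot(state, out_dir, state.step_idx))
            next_snap += config.run.snapshot_every
        if progress and state.step_idx % 20 == 0:
            c = state.pop.counts()
            print(f"t={state.time_h:8.1f} h  cells={c['total']:6d} "
                  f"(cancer {c['cancer']})  segments={state.network.n_segments}")
    if out_dir is None:
        return state
    snapshots.write_run_manifest(state, out_dir, entries)
    return entries


def run_batch(config: SimConfig, seeds):
    """Multi-seed batch runner for averaging over stochastic realizations."""
    import copy
    results = []
    for seed in seeds:
        cfg = copy.deepcopy(config)
        cfg.run.seed = int(seed)
        results.append(run(cfg, out_dir=None))
    return results


def metabolite_fields(state: SimulationState) -> dict:
    """Aggregate per-cell metabolite concentrations onto the lattice.

    Returns one 3D array per metabolic species (absolute mmol/l at occupied
    sites, zero elsewhere) — the arrays behind equatorial cross-section
    figures of intracellular glucose, lactate, pyruvate, f16bp, acetyl-CoA.
    """
    if state.met_net is None:
        return {}
    out = {}
    pos = tuple(state.pop.pos.T) if state.pop.n else None
    for i, sp in enumerate(state.met_net.species):
        arr = np.zeros(state.lattice.dims)
        if pos is not None:
            arr[pos] = state.pop.met[:, i] * state.met_net.c0[i]
        out[sp] = arr
    return out
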
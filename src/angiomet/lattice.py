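"""Cubic lattice, cell agents and the stochastic cellular-automaton update.

Each lattice site holds at most one cell (normal or cancer).  Subcellular
state per cell comprises cell-cycle phase in [0, 1], a p53 level and an
intracellular VEGF level; oxygen acts on all three.  The automaton applies,
in randomized order each step: division, quiescence transitions, p53
apoptosis, and random-walk movement, on the 26-neighbourhood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import CellsConfig, CellTypeParams, LatticeConfig
from .errors import PreconditionError, StateError

log = logging.getLogger(__name__)

CELL_NORMAL = 0
CELL_CANCER = 1
STATE_PROLIFERATING = 0
STATE_QUIESCENT = 1

CELL_TYPE_NAMES = {CELL_NORMAL: "normal", CELL_CANCER: "cancer"}
STATE_NAMES = {STATE_PROLIFERATING: "proliferating", STATE_QUIESCENT: "quiescent"}

#: 26-neighbourhood offsets (3D Moore neighbourhood), fixed order
NEIGHBOURS_26 = np.array(
    [(dx, dy, dz)
     for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
     if (dx, dy, dz) != (0, 0, 0)],
    dtype=np.int64,
)


@dataclass(frozen=True)
class Lattice:
    """Cubic grid of sites; physical side length on axis k is dims[k]*spacing (um)."""
    dims: tuple
    spacing: float

    def __post_init__(self):
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise PreconditionError("lattice dims must be three integers >= 1")
        if self.spacing <= 0:
            raise PreconditionError("lattice spacing must be > 0")

    @classmethod
    def from_config(cls, cfg: LatticeConfig) -> "Lattice":
        return cls(tuple(int(d) for d in cfg.dims), float(cfg.spacing))

    @property
    def n_sites(self) -> int:
        return int(np.prod(self.dims))

    def side_lengths(self):
        return tuple(d * self.spacing for d in self.dims)

    def in_bounds(self, site) -> bool:
        return all(0 <= site[k] < self.dims[k] for k in range(3))


@dataclass
class Cell:
    """Single-cell view used by the scalar subcellular API."""
    cell_type: int
    position: tuple
    phase: float
    state: int = STATE_PROLIFERATING
    p53_level: float = 0.0
    intracellular_vegf: float = 0.0
    clock_in_quiescence: float = 0.0


# ---------------------------------------------------------------------------
# subcellular ODEs


def _advance_arrays(phase, state, p53, ivegf, ctype, oxygen, dt, normal: CellTypeParams,
                    cancer: CellTypeParams):
    """Vectorized subcellular update (exact exponential step for the linear ODEs).

    Cycle phase advances at rate ``(ox/(ox+k_phi))/t_cycle`` for proliferating
    cells only, capped at 1.  p53: ``dp/dt = a - b*f(ox)*p`` with
    ``f = ox/(ox+k_p53)``; intracellular VEGF: ``dv/dt = a*k_v/(k_v+ox) - b*v``.
    The exponential update is unconditionally stable (well beyond dt = 0.5 h).
    """
    out_phase = phase.copy()
    out_p53 = p53.copy()
    out_ivegf = ivegf.copy()
    for ct, par in ((CELL_NORMAL, normal), (CELL_CANCER, cancer)):
        m = ctype == ct
        if not np.any(m):
            continue
        ox = oxygen[m]
        prolif = m & (state == STATE_PROLIFERATING)
        oxp = oxygen[prolif]
        rate = (oxp / (oxp + par.k_phi_ox)) / par.t_cycle
        out_phase[prolif] = np.minimum(phase[prolif] + rate * dt, 1.0)
        # p53: linear ODE with oxygen-dependent degradation
        b = par.p53_deg * ox / (ox + par.k_p53_ox)
        a = par.p53_prod
        eb = np.exp(-b * dt)
        with np.errstate(invalid="ignore", divide="ignore"):
            steady = np.where(b > 0, a / np.where(b > 0, b, 1.0), 0.0)
        out_p53[m] = np.where(b > 0, p53[m] * eb + steady * (1.0 - eb), p53[m] + a * dt)
        # intracellular VEGF: hypoxia-enhanced production (Hill switch in
        # oxygen, sharp around k_vegf_ox), linear degradation
        kn = par.k_vegf_ox ** par.vegf_hill
        av = par.vegf_prod * kn / (kn + ox ** par.vegf_hill)
        bv = par.vegf_deg
        ebv = np.exp(-bv * dt)
        out_ivegf[m] = ivegf[m] * ebv + (av / bv) * (1.0 - ebv)
    return out_phase, out_p53, out_ivegf


def advance_subcellular(cell: Cell, local_oxygen: float, dt: float,
                        params_normal: CellTypeParams,
                        params_cancer: CellTypeParams | None = None) -> Cell:
    """Advance one cell's subcellular state over ``dt`` hours.

    ``params_cancer`` defaults to ``params_normal`` so a single parameter set
    can be passed when only one cell type is involved.
    """
    if dt <= 0:
        raise PreconditionError("dt must be > 0")
    if local_oxygen < 0:
        raise PreconditionError("local oxygen must be >= 0")
    if params_cancer is None:
        params_cancer = params_normal
    phase, p53, ivegf = _advance_arrays(
        np.array([cell.phase]), np.array([cell.state]), np.array([cell.p53_level]),
        np.array([cell.intracellular_vegf]), np.array([cell.cell_type]),
        np.array([float(local_oxygen)]), float(dt), params_normal, params_cancer,
    )
    return replace(cell, phase=float(phase[0]), p53_level=float(p53[0]),
                   intracellular_vegf=float(ivegf[0]))


# ---------------------------------------------------------------------------
# population


class CellPopulation:
    """Structure-of-arrays cell container plus the site-occupancy map."""

    def __init__(self, lattice: Lattice, n_met_species: int = 0):
        self.lattice = lattice
        self.pos = np.zeros((0, 3), dtype=np.int64)
        self.ctype = np.zeros(0, dtype=np.int8)
        self.state = np.zeros(0, dtype=np.int8)
        self.phase = np.zeros(0, dtype=np.float64)
        self.p53 = np.zeros(0, dtype=np.float64)
        self.ivegf = np.zeros(0, dtype=np.float64)
        self.q_clock = np.zeros(0, dtype=np.float64)
        self.n_met_species = int(n_met_species)
        self.met = np.zeros((0, self.n_met_species), dtype=np.float64)
        self.occupancy = np.full(lattice.dims, -1, dtype=np.int64)

    @property
    def n(self) -> int:
        return self.pos.shape[0]

    def counts(self):
        return {
            "total": self.n,
            "normal": int(np.sum(self.ctype == CELL_NORMAL)),
            "cancer": int(np.sum(self.ctype == CELL_CANCER)),
            "proliferating": int(np.sum(self.state == STATE_PROLIFERATING)),
            "quiescent": int(np.sum(self.state == STATE_QUIESCENT)),
        }

    def add_cell(self, site, cell_type, phase=0.0, state=STATE_PROLIFERATING,
                 p53=0.0, ivegf=0.0, met_row=None):
        site = tuple(int(s) for s in site)
        if self.occupancy[site] != -1:
            raise StateError(f"site {site} already occupied")
        idx = self.n
        self.pos = np.vstack([self.pos, np.array([site], dtype=np.int64)])
        self.ctype = np.append(self.ctype, np.int8(cell_type))
        self.state = np.append(self.state, np.int8(state))
        self.phase = np.append(self.phase, float(phase))
        self.p53 = np.append(self.p53, float(p53))
        self.ivegf = np.append(self.ivegf, float(ivegf))
        self.q_clock = np.append(self.q_clock, 0.0)
        if met_row is None:
            met_row = np.zeros(self.n_met_species)
        self.met = np.vstack([self.met, np.asarray(met_row, dtype=np.float64).reshape(1, -1)]) \
            if self.n_met_species else np.zeros((idx + 1, 0))
        self.occupancy[site] = idx
        return idx

    def remove_sites(self, indices):
        """Mark cells dead and drop them (compacting arrays and occupancy)."""
        keep = np.ones(self.n, dtype=bool)
        keep[np.asarray(indices, dtype=np.int64)] = False
        self._compact(keep)

    def _compact(self, keep):
        self.pos = self.pos[keep]
        self.ctype = self.ctype[keep]
        self.state = self.state[keep]
        self.phase = self.phase[keep]
        self.p53 = self.p53[keep]
        self.ivegf = self.ivegf[keep]
        self.q_clock = self.q_clock[keep]
        self.met = self.met[keep]
        self.occupancy.fill(-1)
        if self.n:
            self.occupancy[tuple(self.pos.T)] = np.arange(self.n)

    def site_values(self, field: np.ndarray) -> np.ndarray:
        """Sample a lattice field at each cell's site."""
        if self.n == 0:
            return np.zeros(0)
        return field[tuple(self.pos.T)]

    def check_occupancy(self):
        occ = np.full(self.lattice.dims, -1, dtype=np.int64)
        for i in range(self.n):
            s = tuple(self.pos[i])
            if occ[s] != -1:
                raise StateError(f"two cells share site {s}")
            occ[s] = i
        if not np.array_equal(occ, self.occupancy):
            raise StateError("occupancy map out of sync with cell table")

    def get_cell(self, index: int) -> Cell:
        return Cell(
            cell_type=int(self.ctype[index]), position=tuple(self.pos[index]),
            phase=float(self.phase[index]), state=int(self.state[index]),
            p53_level=float(self.p53[index]),
            intracellular_vegf=float(self.ivegf[index]),
            clock_in_quiescence=float(self.q_clock[index]),
        )

    def to_dataframe(self, step: int = 0, time_h: float = 0.0) -> pd.DataFrame:
        return pd.DataFrame({
            "step": np.full(self.n, step),
            "time_h": np.full(self.n, time_h),
            "x": self.pos[:, 0], "y": self.pos[:, 1], "z": self.pos[:, 2],
            "cell_type": [CELL_TYPE_NAMES[int(t)] for t in self.ctype],
            "state": [STATE_NAMES[int(s)] for s in self.state],
            "phase": self.phase, "p53": self.p53, "ivegf": self.ivegf,
        })

    # -- neighbourhood helpers ------------------------------------------------

    def _empty_neighbours(self, site):
        nbrs = NEIGHBOURS_26 + np.asarray(site)
        ok = np.all((nbrs >= 0) & (nbrs < np.array(self.lattice.dims)), axis=1)
        nbrs = nbrs[ok]
        empty = self.occupancy[tuple(nbrs.T)] == -1
        return nbrs[empty]

    def occupied_neighbour_fraction(self) -> np.ndarray:
        """Per-cell fraction of in-bounds 26-neighbours that are occupied."""
        if self.n == 0:
            return np.zeros(0)
        dims = np.array(self.lattice.dims)
        occ_count = np.zeros(self.n)
        nb_count = np.zeros(self.n)
        for off in NEIGHBOURS_26:
            nb = self.pos + off
            ok = np.all((nb >= 0) & (nb < dims), axis=1)
            nb_count += ok
            idx = nb[ok]
            occ_count[ok] += self.occupancy[tuple(idx.T)] != -1
        return occ_count / np.maximum(nb_count, 1)


# ---------------------------------------------------------------------------
# automaton


def ca_step(pop: CellPopulation, oxygen: np.ndarray, cfg: CellsConfig, dt: float,
            rng: np.random.Generator) -> dict:
    """One stochastic automaton step; returns event counters.

    Phases run in fixed order (division, quiescence, apoptosis, movement),
    each visiting cells in this step's randomized order, so identical seeds
    give bitwise-identical trajectories.
    """
    if dt <= 0:
        raise PreconditionError("dt must be > 0")
    stats = {"divisions": 0, "deferred_divisions": 0, "quiescence_deaths": 0,
             "apoptoses": 0, "moves": 0}
    n0 = pop.n
    if n0 == 0:
        return stats
    order = rng.permutation(n0)

    # (a) division into a uniformly chosen empty 26-neighbour
    for i in order:
        if pop.state[i] == STATE_PROLIFERATING and pop.phase[i] >= 1.0:
            empty = pop._empty_neighbours(pop.pos[i])
            if len(empty) == 0:
                stats["deferred_divisions"] += 1
                continue
            target = empty[rng.integers(len(empty))]
            pop.phase[i] = 0.0
            met_row = pop.met[i] if pop.n_met_species else None
            pop.add_cell(target, int(pop.ctype[i]), phase=0.0,
                         p53=float(pop.p53[i]), ivegf=float(pop.ivegf[i]),
                         met_row=met_row)
            stats["divisions"] += 1

    # (b) quiescence transitions (oxygen thresholds per cell type)
    ox = pop.site_values(oxygen)
    enter = np.where(pop.ctype == CELL_CANCER, cfg.cancer.ox_quiesce_enter,
                     cfg.normal.ox_quiesce_enter)
    leave = np.where(pop.ctype == CELL_CANCER, cfg.cancer.ox_quiesce_leave,
                     cfg.normal.ox_quiesce_leave)
    tmax = np.where(pop.ctype == CELL_CANCER, cfg.cancer.t_quiesce_max,
                    cfg.normal.t_quiesce_max)
    go_q = (pop.state == STATE_PROLIFERATING) & (ox < enter)
    wake = (pop.state == STATE_QUIESCENT) & (ox > leave)
    pop.state[go_q] = STATE_QUIESCENT
    pop.state[wake] = STATE_PROLIFERATING
    pop.q_clock[wake] = 0.0
    quiescent = pop.state == STATE_QUIESCENT
    pop.q_clock[quiescent] += dt
    die_q = quiescent & (pop.q_clock > tmax)

    # (c) p53 apoptosis with density-dependent threshold
    dens = pop.occupied_neighbour_fraction()
    thr_low = np.where(pop.ctype == CELL_CANCER, cfg.cancer.p53_thr_low_density,
                       cfg.normal.p53_thr_low_density)
    thr_high = np.where(pop.ctype == CELL_CANCER, cfg.cancer.p53_thr_high_density,
                        cfg.normal.p53_thr_high_density)
    thr = np.where(dens >= cfg.density_cutoff, thr_high, thr_low)
    die_p53 = pop.p53 > thr

    stats["quiescence_deaths"] = int(np.sum(die_q))
    stats["apoptoses"] = int(np.sum(die_p53 & ~die_q))
    dead = die_q | die_p53
    if np.any(dead):
        pop.remove_sites(np.flatnonzero(dead))

    # (d) at most one random-walk hop per surviving motile cell
    n = pop.n
    if n:
        rate = np.where(pop.ctype == CELL_CANCER, cfg.cancer.movement_rate,
                        cfg.normal.movement_rate)
        p_move = np.minimum(rate * dt, 1.0)
        draws = rng.random(n)
        for i in rng.permutation(n):
            if draws[i] < p_move[i]:
                empty = pop._empty_neighbours(pop.pos[i])
                if len(empty) == 0:
                    continue
                target = tuple(empty[rng.integers(len(empty))])
                pop.occupancy[tuple(pop.pos[i])] = -1
                pop.pos[i] = target
                pop.occupancy[target] = i
                stats["moves"] += 1
    return stats


def implant_tumour(pop: CellPopulation, centre, radius_sites: int,
                   rng: np.random.Generator) -> int:
    """Replace all cells within ``radius_sites`` (Euclidean, site units) of
    ``centre`` by cancer cells with phase drawn uniformly in [0, 1).

    Returns the number of cancer cells implanted.  A ball reaching outside
    the lattice is clipped with a logged warning.  Re-implanting at the same
    site is idempotent in occupancy (the cancer cell is refreshed).
    """
    lattice = pop.lattice
    centre = tuple(int(c) for c in centre)
    if not lattice.in_bounds(centre):
        raise PreconditionError(f"tumour centre {centre} outside lattice")
    r = int(radius_sites)
    lo = [centre[k] - r for k in range(3)]
    hi = [centre[k] + r for k in range(3)]
    if any(lo[k] < 0 or hi[k] >= lattice.dims[k] for k in range(3)):
        log.warning("tumour ball at %s radius %d clipped to lattice bounds", centre, r)
    count = 0
    for x in range(max(lo[0], 0), min(hi[0], lattice.dims[0] - 1) + 1):
        for y in range(max(lo[1], 0), min(hi[1], lattice.dims[1] - 1) + 1):
            for z in range(max(lo[2], 0), min(hi[2], lattice.dims[2] - 1) + 1):
                if (x - centre[0]) ** 2 + (y - centre[1]) ** 2 + (z - centre[2]) ** 2 > r * r:
                    continue
                occ = pop.occupancy[x, y, z]
                if occ != -1:
                    pop.remove_sites([occ])
                pop.add_cell((x, y, z), CELL_CANCER, phase=float(rng.random()))
                count += 1
    return count
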
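"""Vascular network: graph, angiogenesis, anastomosis, blood flow, remodeling.

The network lives on the simulation lattice: nodes are lattice sites,
segments connect nodes and carry radius, flow and a functional flag.  Sprout
tips are individual agents performing a biased random walk up VEGF
gradients, laying microvessels behind them; a tip fuses (anastomoses) with
another tip or a functional vessel with probability ``1 - d/dx_max`` for
separation ``d < dx_max``, completing a perfusable loop.  Blood flow is
Poiseuille flow with node pressures from Kirchhoff balance, solved by
successive displacement (SOR).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve_triangular

from .config import VascularConfig
from .errors import ConfigError, NumericalError, PreconditionError

__all__ = [
    "VascularNetwork", "SproutTip", "anastomosis_probability",
    "attempt_anastomosis", "sprout_initiation", "tip_migration_step",
    "compute_blood_flow", "remodel_radii", "vascular_step",
]


def anastomosis_probability(distance: float, dx_max: float) -> float:
    """Probability that two sprout tips (or a tip and a functional vessel)
    separated by ``distance`` um fuse: ``1 - distance/dx_max`` below
    ``dx_max``, zero beyond (piecewise linear, continuous at ``dx_max``)."""
    if dx_max <= 0:
        raise PreconditionError("dx_max must be > 0")
    if distance < 0:
        raise PreconditionError("distance must be >= 0")
    if distance < dx_max:
        return 1.0 - distance / dx_max
    return 0.0


@dataclass
class SproutTip:
    """An active sprout-tip agent."""
    tip_id: int
    position: tuple                 # lattice site
    attachment_node: int            # node on the parent vessel
    trail: list = dfield(default_factory=list)   # node ids laid down (incl. attachment)
    age: float = 0.0
    prev_site: tuple | None = None
    stalled_h: float = 0.0
    active: bool = True


class VascularNetwork:
    """Lattice-anchored vessel graph with pressures, radii and flows."""

    def __init__(self, lattice):
        self.lattice = lattice
        self.node_pos: list[tuple] = []
        self.node_index: dict[tuple, int] = {}
        self.pressure = np.zeros(0)
        self.boundary: dict[int, float] = {}   # node id -> prescribed pressure
        # segment arrays
        self.seg_a: list[int] = []
        self.seg_b: list[int] = []
        self.radius: list[float] = []
        self.flow: list[float] = []
        self.functional: list[bool] = []
        self.zero_flow_h: list[float] = []

    # -- construction ---------------------------------------------------------

    def add_node(self, site) -> int:
        site = tuple(int(s) for s in site)
        if site in self.node_index:
            return self.node_index[site]
        idx = len(self.node_pos)
        self.node_pos.append(site)
        self.node_index[site] = idx
        self.pressure = np.append(self.pressure, 0.0)
        return idx

    def add_segment(self, a: int, b: int, radius: float) -> int:
        if a == b:
            raise PreconditionError("segment endpoints must differ")
        key = (min(a, b), max(a, b))
        for i, (sa, sb) in enumerate(zip(self.seg_a, self.seg_b)):
            if (min(sa, sb), max(sa, sb)) == key:
                return i          # segment already present
        self.seg_a.append(a)
        self.seg_b.append(b)
        self.radius.append(float(radius))
        self.flow.append(0.0)
        self.functional.append(False)
        self.zero_flow_h.append(0.0)
        return len(self.seg_a) - 1

    def set_boundary(self, node: int, pressure: float):
        self.boundary[node] = float(pressure)

    # -- queries --------------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_pos)

    @property
    def n_segments(self) -> int:
        return len(self.seg_a)

    def segment_length(self, i: int) -> float:
        a = np.asarray(self.node_pos[self.seg_a[i]], dtype=float)
        b = np.asarray(self.node_pos[self.seg_b[i]], dtype=float)
        return float(np.linalg.norm(a - b) * self.lattice.spacing)

    def functional_nodes(self) -> np.ndarray:
        """Node ids touched by at least one functional segment."""
        ids = set()
        for i in range(self.n_segments):
            if self.functional[i]:
                ids.add(self.seg_a[i])
                ids.add(self.seg_b[i])
        return np.array(sorted(ids), dtype=np.int64)

    def node_positions_um(self, ids=None) -> np.ndarray:
        pos = np.asarray(self.node_pos, dtype=float)
        if ids is not None:
            pos = pos[np.asarray(ids, dtype=np.int64)]
        return pos * self.lattice.spacing

    def to_dataframe(self):
        import pandas as pd
        rows = []
        for i in range(self.n_segments):
            a, b = self.seg_a[i], self.seg_b[i]
            rows.append({
                "ax": self.node_pos[a][0], "ay": self.node_pos[a][1], "az": self.node_pos[a][2],
                "bx": self.node_pos[b][0], "by": self.node_pos[b][1], "bz": self.node_pos[b][2],
                "radius_um": self.radius[i], "flow_um3_h": self.flow[i],
                "pressure_a_pa": self.pressure[a], "pressure_b_pa": self.pressure[b],
                "functional": bool(self.functional[i]),
            })
        return pd.DataFrame(rows, columns=["ax", "ay", "az", "bx", "by", "bz",
                                           "radius_um", "flow_um3_h",
                                           "pressure_a_pa", "pressure_b_pa", "functional"])


# ---------------------------------------------------------------------------
# blood flow


def compute_blood_flow(net: VascularNetwork, params: VascularConfig) -> VascularNetwork:
    """Solve node pressures (Kirchhoff balance, Poiseuille conductances
    ``g = pi R^4 / (8 mu L)``) by successive displacement (SOR), then set
    segment flows ``Q = g (p_a - p_b)`` and update functional flags.

    Components not connected to any boundary node get zero flow.  Raises
    :class:`NumericalError` if the iteration does not reach the residual
    tolerance within ``flow_max_iter`` sweeps.
    """
    if not net.boundary:
        raise ConfigError(["blood-flow solve requires at least one boundary node"])
    n = net.n_nodes
    m = net.n_segments
    if m == 0:
        return net
    a = np.asarray(net.seg_a)
    b = np.asarray(net.seg_b)
    lengths = np.array([net.segment_length(i) for i in range(m)])
    R = np.asarray(net.radius, dtype=float)
    g = np.pi * R ** 4 / (8.0 * params.viscosity * lengths)

    fixed = np.zeros(n, dtype=bool)
    pvals = np.zeros(n)
    for node, p in net.boundary.items():
        fixed[node] = True
        pvals[node] = p

    # nodes reachable from a boundary node (others are hydraulically isolated)
    import networkx as nx
    G = nx.Graph()
    G.add_nodes_from(range(n))
    G.add_edges_from(zip(a.tolist(), b.tolist()))
    reachable = np.zeros(n, dtype=bool)
    for comp in nx.connected_components(G):
        if any(fixed[v] for v in comp):
            for v in comp:
                reachable[v] = True

    free = reachable & ~fixed
    free_idx = np.flatnonzero(free)
    pressure = net.pressure.copy()
    pressure[fixed] = pvals[fixed]
    pressure[~reachable] = 0.0
    if free_idx.size:
        col = -np.ones(n, dtype=np.int64)
        col[free_idx] = np.arange(free_idx.size)
        # weighted graph Laplacian restricted to free nodes
        rows, cols, vals = [], [], []
        rhs = np.zeros(free_idx.size)
        for i in range(m):
            na, nb, gi = int(a[i]), int(b[i]), g[i]
            for u, v in ((na, nb), (nb, na)):
                if not free[u]:
                    continue
                cu = col[u]
                rows.append(cu); cols.append(cu); vals.append(gi)
                if free[v]:
                    rows.append(cu); cols.append(col[v]); vals.append(-gi)
                else:
                    rhs[cu] += gi * pressure[v]
        A = sp.csr_matrix((vals, (rows, cols)), shape=(free_idx.size, free_idx.size))
        x = pressure[free_idx]
        # SOR via sparse lower-triangular solves: M = D/omega + strict lower
        omega = params.sor_omega or _optimal_sor_omega(A)
        D = A.diagonal()
        M = sp.tril(A, k=-1, format="csr") + sp.diags(D / omega, format="csr")
        bnorm = np.linalg.norm(rhs) or 1.0
        resid = None
        best = np.inf
        stale = 0
        for _ in range(params.flow_max_iter):
            r = rhs - A @ x
            resid = np.linalg.norm(r) / bnorm
            if resid <= params.flow_tol:
                break
            # roundoff floor: stop once sweeps no longer reduce the residual
            if resid < best * 0.999:
                best = resid
                stale = 0
            else:
                stale += 1
                if stale > 100:
                    if resid <= max(1e3 * params.flow_tol, 1e-10):
                        break
                    raise NumericalError("blood-flow SOR stagnated", residual=resid)
            x = x + spsolve_triangular(M, r, lower=True)
        else:
            raise NumericalError("blood-flow SOR failed to converge", residual=resid)
        pressure[free_idx] = x

    net.pressure = pressure
    Q = g * (pressure[a] - pressure[b])
    Q[~reachable[a]] = 0.0
    inflow = sum(abs(_node_net_flow(net, node, g, pressure, a, b))
                 for node in net.boundary) / 2.0
    q_thr = params.flow_threshold_rel * max(inflow, 1e-300)
    for i in range(m):
        net.flow[i] = float(Q[i])
        net.functional[i] = bool(abs(Q[i]) > q_thr)
    return net


def _optimal_sor_omega(A) -> float:
    """Near-optimal SOR relaxation factor from the Jacobi spectral radius
    (power iteration on the Jacobi sweep matrix), ``w = 2/(1+sqrt(1-rho^2))``."""
    n = A.shape[0]
    if n < 3:
        return 1.0
    Dinv = 1.0 / A.diagonal()
    v = np.ones(n) + 1e-3 * np.sin(np.arange(n))
    rho = 0.0
    for _ in range(60):
        w = v - Dinv * (A @ v)       # Jacobi iteration matrix applied to v
        nrm = np.linalg.norm(w)
        if nrm == 0:
            return 1.0
        rho = nrm / np.linalg.norm(v)
        v = w / nrm
    rho = min(rho, 1.0 - 1e-10)
    return float(min(2.0 / (1.0 + np.sqrt(1.0 - rho ** 2)), 1.995))


def _node_net_flow(net, node, g, pressure, a, b):
    out = 0.0
    for i in range(len(g)):
        if a[i] == node:
            out += g[i] * (pressure[node] - pressure[b[i]])
        elif b[i] == node:
            out += g[i] * (pressure[node] - pressure[a[i]])
    return out


def kirchhoff_imbalance(net: VascularNetwork, params: VascularConfig) -> float:
    """Max interior-node flow imbalance relative to network throughput."""
    n = net.n_nodes
    net_flow = np.zeros(n)
    for i in range(net.n_segments):
        q = net.flow[i]
        net_flow[net.seg_a[i]] -= q
        net_flow[net.seg_b[i]] += q
    interior = np.ones(n, dtype=bool)
    for node in net.boundary:
        interior[node] = False
    throughput = sum(abs(net_flow[node]) for node in net.boundary) / 2.0
    if throughput == 0 or not np.any(interior):
        return 0.0
    return float(np.max(np.abs(net_flow[interior])) / throughput)


# ---------------------------------------------------------------------------
# remodeling


def remodel_radii(net: VascularNetwork, params: VascularConfig, dt: float) -> VascularNetwork:
    """Relax each functional segment's radius toward the wall-shear set point.

    Wall shear stress is ``tau = 4 mu |Q| / (pi R^3)``; radii follow
    ``dR/dt = remodel_rate * R * ln(tau/tau_ref)`` (multiplicative relaxation,
    fixed point at ``tau = tau_ref``), clamped to ``[r_min, r_max]``.
    Segments with negligible flow for longer than ``prune_after`` are removed.
    """
    if net.n_segments == 0:
        return net
    keep = []
    for i in range(net.n_segments):
        if net.functional[i]:
            net.zero_flow_h[i] = 0.0
            tau = 4.0 * params.viscosity * abs(net.flow[i]) / (np.pi * net.radius[i] ** 3)
            if tau > 0:
                r_new = net.radius[i] * np.exp(params.remodel_rate * np.log(tau / params.shear_ref) * dt)
                net.radius[i] = float(np.clip(r_new, params.r_min, params.r_max))
        else:
            net.zero_flow_h[i] += dt
        keep.append(net.functional[i] or net.zero_flow_h[i] <= params.prune_after)
    pruned = len(keep) - sum(keep)
    if pruned:
        for name in ("seg_a", "seg_b", "radius", "flow", "functional", "zero_flow_h"):
            setattr(net, name, [v for v, k in zip(getattr(net, name), keep) if k])
    net._pruned_last = pruned
    return net


# ---------------------------------------------------------------------------
# angiogenesis


def sprout_initiation(net: VascularNetwork, vegf: np.ndarray, tips: list,
                      params: VascularConfig, rng: np.random.Generator,
                      dt: float, next_tip_id: int) -> list:
    """Spawn new sprout tips from functional vessel nodes.

    Each functional node without an active tip sprouts with probability
    ``sprout_p_max * V/(V + sprout_v_half) * dt`` where V is local VEGF;
    nodes whose VEGF sits below the small activation threshold
    ``sprout_v_min`` stay quiescent (no angiogenesis in healthy tissue).
    Returns the list of newly created tips.
    """
    if dt <= 0:
        raise PreconditionError("dt must be > 0")
    busy = {t.attachment_node for t in tips if t.active}
    new = []
    for node in net.functional_nodes():
        node = int(node)
        if node in busy:
            continue
        site = net.node_pos[node]
        v = float(vegf[site])
        if v < params.sprout_v_min:
            continue
        p = min(params.sprout_p_max * v / (v + params.sprout_v_half) * dt, 1.0)
        if p > 0 and rng.random() < p:
            new.append(SproutTip(tip_id=next_tip_id, position=site,
                                 attachment_node=node, trail=[node]))
            next_tip_id += 1
    return new


def tip_migration_step(tip: SproutTip, vegf: np.ndarray, net: VascularNetwork,
                       params: VascularConfig, rng: np.random.Generator) -> SproutTip:
    """Move a tip one lattice site up the VEGF gradient (biased random walk).

    Neighbour k is chosen with probability proportional to
    ``exp(bias_weight * (V_k - V_here) / d_k)`` with ``d_k`` the neighbour
    distance in um; the immediately previous site is never re-entered.  The
    vacated site is appended to the trail as a new microvessel segment.
    """
    if not tip.active:
        return tip
    from .lattice import NEIGHBOURS_26
    lattice = net.lattice
    dims = np.array(lattice.dims)
    here = np.asarray(tip.position)
    cand = NEIGHBOURS_26 + here
    ok = np.all((cand >= 0) & (cand < dims), axis=1)
    cand = cand[ok]
    if tip.prev_site is not None:
        cand = cand[~np.all(cand == np.asarray(tip.prev_site), axis=1)]
    if len(cand) == 0:
        tip.stalled_h += 1.0
        return tip
    v_here = float(vegf[tuple(here)])
    v_nb = vegf[tuple(cand.T)]
    dist = np.linalg.norm((cand - here).astype(float), axis=1) * lattice.spacing
    logits = params.bias_weight * (v_nb - v_here) / dist
    logits -= logits.max()
    w = np.exp(logits)
    w /= w.sum()
    choice = rng.choice(len(cand), p=w)
    new_site = tuple(int(c) for c in cand[choice])
    old_node = net.add_node(tip.position)
    new_node = net.add_node(new_site)
    net.add_segment(old_node, new_node, params.r_init)
    tip.prev_site = tip.position
    tip.position = new_site
    tip.trail.append(new_node)
    return tip


def _bresenham_path(a, b):
    """Monotone 3D lattice path from a to b (inclusive), Bresenham-style."""
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    delta = b - a
    steps = int(np.max(np.abs(delta)))
    path = [tuple(a)]
    for s in range(1, steps + 1):
        pt = tuple(int(round(a[k] + delta[k] * s / steps)) for k in range(3))
        if pt != path[-1]:
            path.append(pt)
    return path


def _functional_candidates(net: VascularNetwork):
    """(ids, positions-in-sites) of functional-vessel nodes, for reuse
    across the tips of one vascular step."""
    ids = net.functional_nodes()
    pos = (np.asarray(net.node_pos, dtype=float)[ids].reshape(-1, 3)
           if ids.size else np.zeros((0, 3)))
    return ids, pos


def attempt_anastomosis(tip: SproutTip, net: VascularNetwork, tips: list,
                        params: VascularConfig, rng: np.random.Generator,
                        functional=None):
    """One anastomosis attempt for ``tip``.

    Candidates are all other active tips and all functional-vessel nodes
    within Euclidean distance ``dx_max`` of the tip, evaluated nearest-first
    (stable index tie-break); for each a uniform random number is drawn and
    compared against ``1 - d/dx_max``.  On the first success the tip trail is
    connected to the target by a straight lattice path and the tip (plus a
    partner tip, if tip-tip) is deactivated.  Returns an event dict or None.

    The tip's own trail nodes, and functional nodes within
    ``tip_exclusion_radius`` of the tip's attachment node, are excluded so a
    newborn sprout cannot instantly fuse back into its parent vessel.
    """
    if not tip.active:
        return None
    spacing = net.lattice.spacing
    here = np.asarray(tip.position, dtype=float) * spacing
    candidates = []   # (distance, order_key, ref)
    for other in tips:
        if other is tip or not other.active:
            continue
        d = float(np.linalg.norm(np.asarray(other.position, dtype=float) * spacing - here))
        if d < params.dx_max:
            candidates.append((d, ("tip", other.tip_id), other))
    own = set(tip.trail)
    attach = (np.asarray(net.node_pos[tip.attachment_node], dtype=float) * spacing
              if 0 <= tip.attachment_node < net.n_nodes else None)
    ids, pos_sites = functional if functional is not None else _functional_candidates(net)
    if ids.size:
        pos_um = pos_sites * spacing
        d_here = np.linalg.norm(pos_um - here, axis=1)
        keep = d_here < params.dx_max
        if attach is not None:
            keep &= np.linalg.norm(pos_um - attach, axis=1) >= params.tip_exclusion_radius
        for node, d in zip(ids[keep], d_here[keep]):
            node = int(node)
            if node in own:
                continue
            candidates.append((float(d), ("node", node), node))
    candidates.sort(key=lambda c: (c[0], c[1]))
    for d, key, ref in candidates:
        if rng.random() <= anastomosis_probability(d, params.dx_max):
            kind = key[0]
            target_site = ref.position if kind == "tip" else net.node_pos[ref]
            path = _bresenham_path(tip.position, target_site)
            prev = net.add_node(path[0])
            for site in path[1:]:
                nxt = net.add_node(site)
                net.add_segment(prev, nxt, params.r_init)
                prev = nxt
            tip.active = False
            if kind == "tip":
                ref.active = False
            return {"kind": kind, "distance_um": d, "tip": tip.tip_id,
                    "target": key[1], "path_len": len(path) - 1}
    return None


def vascular_step(net: VascularNetwork, tips: list, vegf: np.ndarray,
                  params: VascularConfig, rng: np.random.Generator, dt: float,
                  next_tip_id: int):
    """One vascular layer update: sprouting, tip migration, anastomosis,
    flow solve, remodeling.  Returns (tips, next_tip_id, counters)."""
    stats = {"sprouts": 0, "anastomoses": 0, "regressions": 0, "pruned": 0}
    new_tips = sprout_initiation(net, vegf, tips, params, rng, dt, next_tip_id)
    stats["sprouts"] = len(new_tips)
    next_tip_id += len(new_tips)
    tips = tips + new_tips
    p_step = min(params.tip_speed * dt, 1.0)
    functional = _functional_candidates(net)
    for tip in tips:
        if not tip.active:
            continue
        tip.age += dt
        if p_step > 0 and rng.random() < p_step:
            tip_migration_step(tip, vegf, net, params, rng)
        event = attempt_anastomosis(tip, net, tips, params, rng,
                                    functional=functional)
        if event is not None:
            stats["anastomoses"] += 1
        elif tip.age > params.max_sprout_age or tip.stalled_h > params.max_sprout_age:
            tip.active = False
            stats["regressions"] += 1
    tips = [t for t in tips if t.active]
    if net.boundary and net.n_segments:
        compute_blood_flow(net, params)
        remodel_radii(net, params, dt)
        stats["pruned"] = getattr(net, "_pruned_last", 0)
    return tips, next_tip_id, stats
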
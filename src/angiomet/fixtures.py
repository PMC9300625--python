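"""Programmatic toy-input generators and independent brute-force oracles.

Everything here is deterministic given its parameters and seed, and is
implemented independently of the modules it checks (direct loop assembly,
closed forms, Monte-Carlo counting) so it can serve as an oracle for the
production code paths.
"""

from __future__ import annotations

import numpy as np

from .config import VascularConfig
from .errors import PreconditionError
from .lattice import Lattice
from .metabolism import MetabolicNetwork, network_from_dict, reference_jacobian
from .vasculature import SproutTip, VascularNetwork, attempt_anastomosis, compute_blood_flow


# ---------------------------------------------------------------------------
# toy metabolic networks


def make_toy_metabolic_network(n_species: int, seed: int,
                               max_retries: int = 100) -> MetabolicNetwork:
    """Random linear-chain (optionally branched) lin-log network.

    ``n_species`` internal species X1..Xn between an external source S and
    sink P; all reference fluxes are equal (optionally split across a
    parallel branch), so ``N J0 = 0`` holds exactly by construction.
    Networks are resampled until the reference Jacobian is Hurwitz (all
    eigenvalue real parts negative); raises after ``max_retries`` failures.
    """
    if n_species < 2:
        raise PreconditionError("n_species must be >= 2")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        # dyadic reference flux so branch splits J -> (f J, (1-f) J) are exact
        J = float(np.round(rng.uniform(1.0, 5.0) * 16) / 16)
        species = [{"name": "S", "c0": float(rng.uniform(0.5, 2.0)), "external": True}]
        species += [{"name": f"X{i+1}", "c0": float(rng.uniform(0.1, 1.0))}
                    for i in range(n_species)]
        species.append({"name": "P", "c0": float(rng.uniform(0.5, 2.0)), "external": True})

        def els(sub, prod=None):
            d = {"substrate": {sub: float(rng.uniform(0.4, 1.2))}}
            if prod is not None:
                d["product"] = {prod: -float(rng.uniform(0.05, 0.35))}
            return d

        chain = ["S"] + [f"X{i+1}" for i in range(n_species)] + ["P"]
        reactions = []
        for k in range(len(chain) - 1):
            reactions.append({
                "name": f"r{k}", "J0": J,
                "stoich": {chain[k]: -1, chain[k + 1]: 1},
                "elasticities": els(chain[k], chain[k + 1] if k + 1 < len(chain) - 1 else None),
            })
        if n_species >= 3 and rng.random() < 0.5:
            # parallel branch across one interior edge, flux split f : 1-f
            k = int(rng.integers(1, n_species))   # edge X_k -> X_{k+1}
            f = float(rng.choice([0.25, 0.5]))    # dyadic split: exact flux balance
            reactions[k]["J0"] = (1.0 - f) * J
            reactions.append({
                "name": f"r{k}_branch", "J0": f * J,
                "stoich": dict(reactions[k]["stoich"]),
                "elasticities": els(chain[k], chain[k + 1]),
            })
        net = network_from_dict({"species": species, "reactions": reactions})
        eig = np.linalg.eigvals(reference_jacobian(net))
        if np.all(eig.real < -1e-9):
            return net
    raise PreconditionError(
        f"could not sample a stable toy network in {max_retries} attempts")


# ---------------------------------------------------------------------------
# dense linear field oracle


def dense_linear_field_oracle(scenario: dict) -> np.ndarray:
    """Directly assemble and solve the linearized quasi-steady field system.

    ``scenario`` keys: dims (triple), spacing (um), d (um^2/h), and per-site
    arrays ``kv`` (vessel exchange, 1/h), ``k_lin`` (linearized uptake, 1/h),
    ``src`` (volumetric source, mmol/(l h)); scalars ``decay`` (1/h), ``bc``
    ('neumann' | 'dirichlet' | 'dirichlet_x0') and ``bc_value``.

    Assembly is by explicit loops over sites and neighbours (no shared code
    with the production solver); the system is solved with a dense solve for
    <= 4096 unknowns and scipy's sparse direct solver above that.
    """
    dims = tuple(scenario["dims"])
    h = float(scenario["spacing"])
    d = float(scenario["d"])
    kv = np.asarray(scenario["kv"], dtype=float)
    k_lin = np.asarray(scenario["k_lin"], dtype=float)
    src = np.asarray(scenario["src"], dtype=float).copy()
    decay = float(scenario.get("decay", 0.0))
    bc = scenario.get("bc", "neumann")
    bc_value = float(scenario.get("bc_value", 0.0))
    nx, ny, nz = dims
    n = nx * ny * nz

    def flat(i, j, k):
        return (i * ny + j) * nz + k

    rows, cols, vals = [], [], []
    b = src.ravel().copy()
    w = d / h ** 2
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                p = flat(i, j, k)
                diag = kv[i, j, k] + k_lin[i, j, k] + decay
                for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    i2, j2, k2 = i + di, j + dj, k + dk
                    inside = 0 <= i2 < nx and 0 <= j2 < ny and 0 <= k2 < nz
                    if inside:
                        diag += w
                        rows.append(p)
                        cols.append(flat(i2, j2, k2))
                        vals.append(-w)
                    else:
                        x_min_face = di == -1 and i2 < 0
                        dirich = (bc == "dirichlet"
                                  or (bc == "dirichlet_x0" and x_min_face))
                        if dirich:
                            # ghost value 2*bc_value - c  (cell-centred face)
                            diag += 2.0 * w
                            b[p] += 2.0 * w * bc_value
                        # Neumann: mirror ghost, no contribution
                rows.append(p)
                cols.append(p)
                vals.append(diag)
    if n <= 4096:
        A = np.zeros((n, n))
        A[rows, cols] += np.array(vals)
        c = np.linalg.solve(A, b)
    else:
        import scipy.sparse as sp
        from scipy.sparse.linalg import spsolve
        A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        c = spsolve(A, b)
    return c.reshape(dims)


# ---------------------------------------------------------------------------
# anastomosis Monte-Carlo experiment


def anastomosis_frequency_experiment(distances_um, n_trials: int, seed: int,
                                     dx_max_um: float = 100.0) -> dict:
    """Empirical anastomosis acceptance frequency for isolated tip pairs.

    For each distance, two sprout tips separated by exactly that distance
    (1 um lattice spacing) undergo ``n_trials`` independent fusion attempts
    through the production :func:`attempt_anastomosis` path.  Returns
    ``{distance: (frequency, standard_error)}`` with the binomial SE.
    """
    if n_trials < 1:
        raise PreconditionError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    extent = int(max(distances_um)) + 2
    lattice = Lattice((extent, 3, 3), 1.0)
    params = VascularConfig(dx_max=float(dx_max_um), tip_exclusion_radius=0.0)
    results = {}
    for d in distances_um:
        net = VascularNetwork(lattice)
        hits = 0
        for _ in range(n_trials):
            t1 = SproutTip(tip_id=0, position=(0, 1, 1), attachment_node=-1, trail=[])
            t2 = SproutTip(tip_id=1, position=(int(round(d)), 1, 1),
                           attachment_node=-1, trail=[])
            event = attempt_anastomosis(t1, net, [t1, t2], params, rng)
            if event is not None:
                hits += 1
            # reset connectivity laid down by a successful fusion
            net = VascularNetwork(lattice)
        freq = hits / n_trials
        se = float(np.sqrt(max(freq * (1 - freq), 1e-12) / n_trials))
        results[float(d)] = (freq, se)
    return results


# ---------------------------------------------------------------------------
# loop-efficiency scenario (two parent vessels + static VEGF hotspot)


def loop_efficiency_experiment(dx_max_um: float, seeds, n_steps: int = 60,
                               n_tips_per_vessel: int = 12,
                               dims=(20, 20, 7), spacing_um: float = 20.0) -> list:
    """Completed anastomosis loops on a fixed two-parent-vessel scenario.

    Two countercurrent parent vessels run along x on opposite sides of the
    domain; a static VEGF hotspot sits between them.  A fixed cohort of
    sprout tips (evenly spaced on both vessels, identical across rules)
    migrates up the gradient for ``n_steps`` half-hour steps, attempting
    fusion under the distance rule with the given ``dx_max_um``; the return
    value is the completed-loop count per seed.  Passing
    ``dx_max_um = spacing`` reduces the rule to contact-only fusion.  The
    cohort is fixed (no re-sprouting) so the comparison isolates the fusion
    rule itself.
    """
    from .vasculature import (SproutTip, _functional_candidates,
                              attempt_anastomosis, tip_migration_step)

    counts = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        lattice = Lattice(tuple(dims), spacing_um)
        params = VascularConfig(dx_max=float(dx_max_um),
                                tip_exclusion_radius=float(dx_max_um))
        net = VascularNetwork(lattice)
        zm = dims[2] // 2
        y1, y2 = dims[1] // 4, 3 * dims[1] // 4
        for y, p_lo, p_hi in ((y1, params.pressure_in, params.pressure_out),
                              (y2, params.pressure_out, params.pressure_in)):
            prev = net.add_node((0, y, zm))
            first = prev
            for i in range(1, dims[0]):
                nxt = net.add_node((i, y, zm))
                net.add_segment(prev, nxt, params.r_init)
                prev = nxt
            net.set_boundary(first, p_lo)
            net.set_boundary(prev, p_hi)
        compute_blood_flow(net, params)
        functional = _functional_candidates(net)
        # static VEGF hotspot centred between the vessels
        grid = np.indices(dims).astype(float)
        centre = np.array([dims[0] / 2, dims[1] / 2, zm])
        r2 = sum((grid[k] - centre[k]) ** 2 for k in range(3)) * spacing_um ** 2
        vegf = 0.08 * np.exp(-r2 / (2 * (4 * spacing_um) ** 2))
        # fixed tip cohort, evenly spaced along both vessels
        tips = []
        step_x = max(dims[0] // n_tips_per_vessel, 1)
        tid = 0
        for y in (y1, y2):
            for i in range(0, dims[0], step_x):
                node = net.node_index[(i, y, zm)]
                tips.append(SproutTip(tid, (i, y, zm), attachment_node=node,
                                      trail=[node]))
                tid += 1
        loops = 0
        for _ in range(n_steps):
            for tip in tips:
                if not tip.active:
                    continue
                tip_migration_step(tip, vegf, net, params, rng)
                if attempt_anastomosis(tip, net, tips, params, rng,
                                       functional=functional) is not None:
                    loops += 1
        counts.append(loops)
    return counts
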
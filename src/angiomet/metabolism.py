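"""Lin-log kinetic model of central carbon metabolism.

A :class:`MetabolicNetwork` holds species with reference concentrations
``c0``, reactions with reference fluxes ``J0`` and elasticity coefficients
``eps`` per role (substrate, product, activator, inhibitor), and the
stoichiometric matrix ``N``.  The rate law is

    r_j = J0_j * (cE/cE0)_j * (1 + sum_i eps_ji * ln(c_i / c0_i))

with the elasticities entering exactly as stored (substrates/activators
typically positive, products/inhibitors negative).  Mass balances read
``d(c/c0)/dt = diag(c0)^-1 N r`` with external species (extracellular
glucose, oxygen, secreted lactate) clamped to the environment.

At the reference state all logarithms vanish, so ``r(c0) = J0`` exactly, and
a valid parameterization satisfies ``N J0 = 0`` on the internal species.
Integration runs in log-concentration space, which preserves positivity
structurally; the public single-cell integrator uses scipy's BDF (a stiff
error-controlled substitute for extrapolation codes such as LIMEX), while
the driver uses a batched backward-Euler with step-doubling error control to
advance thousands of cells at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import yaml
from scipy.integrate import solve_ivp

from .errors import NumericalError, PreconditionError, ValidationError

ROLES = ("substrate", "product", "activator", "inhibitor")

_X_FLOOR = 1e-12   # floor on normalized clamped externals (log arguments)


@dataclass
class MetabolicState:
    """Per-cell normalized metabolite vector c/c0 (dimensionless, > 0)."""
    x: np.ndarray
    time: float = 0.0


@dataclass
class MetabolicNetwork:
    species: list
    c0: np.ndarray
    external: np.ndarray            # bool per species
    reactions: list
    J0: np.ndarray
    enzyme: np.ndarray              # cE/cE0 per reaction, default 1
    N: np.ndarray                   # species x reactions
    elasticities: list              # per reaction: {role: {species: eps}}
    sp_index: dict = dfield(default_factory=dict)
    E: np.ndarray = None            # combined signed elasticity matrix (rx x sp)

    def __post_init__(self):
        self.c0 = np.asarray(self.c0, dtype=float)
        self.external = np.asarray(self.external, dtype=bool)
        self.J0 = np.asarray(self.J0, dtype=float)
        self.enzyme = np.asarray(self.enzyme, dtype=float)
        self.N = np.asarray(self.N, dtype=float)
        self.sp_index = {s: i for i, s in enumerate(self.species)}
        self.E = np.zeros((len(self.reactions), len(self.species)))
        for j, els in enumerate(self.elasticities):
            for role in ROLES:
                for sp_name, eps in (els.get(role) or {}).items():
                    if sp_name in self.sp_index:
                        self.E[j, self.sp_index[sp_name]] += float(eps)

    # -- validation -----------------------------------------------------------

    def problems(self) -> list:
        probs = []
        n_sp, n_rx = len(self.species), len(self.reactions)
        if self.c0.shape != (n_sp,):
            probs.append(f"c0 has shape {self.c0.shape}, expected ({n_sp},)")
        elif np.any(self.c0 <= 0):
            bad = [self.species[i] for i in np.flatnonzero(self.c0 <= 0)]
            probs.append(f"non-positive reference concentration for: {', '.join(bad)}")
        if self.N.shape != (n_sp, n_rx):
            probs.append(f"N has shape {self.N.shape}, expected ({n_sp}, {n_rx})")
        else:
            imbalance = self.N @ self.J0
            internal = ~self.external
            bad = np.flatnonzero(internal & (np.abs(imbalance) > 1e-10))
            if bad.size:
                names = ", ".join(f"{self.species[i]} ({imbalance[i]:+.3e})" for i in bad)
                probs.append(f"N*J0 is not balanced for internal species: {names}")
        for j, els in enumerate(self.elasticities):
            for role in ROLES:
                for sp_name in (els.get(role) or {}):
                    if sp_name not in self.sp_index:
                        probs.append(
                            f"reaction '{self.reactions[j]}' names unknown species "
                            f"'{sp_name}' in its {role} elasticities")
        return probs

    def validate(self) -> "MetabolicNetwork":
        probs = self.problems()
        if probs:
            raise ValidationError(probs)
        return self

    # -- state helpers --------------------------------------------------------

    @property
    def internal(self) -> np.ndarray:
        return ~self.external

    def reference_state(self) -> MetabolicState:
        return MetabolicState(x=np.ones(len(self.species)), time=0.0)

    def clamp_environment(self, x: np.ndarray, environment: dict) -> np.ndarray:
        """Return x with external species set to environment values (absolute
        mmol/l, normalized by c0; floored at a tiny positive value so the
        anoxic/aglycemic limit keeps log arguments finite)."""
        x = x.copy()
        for name, conc in environment.items():
            if name not in self.sp_index:
                raise PreconditionError(f"unknown environment species '{name}'")
            i = self.sp_index[name]
            if not self.external[i]:
                raise PreconditionError(f"species '{name}' is not external")
            x[i] = max(float(conc) / self.c0[i], _X_FLOOR)
        return x


# ---------------------------------------------------------------------------
# rate law and mass balances


def rates(net: MetabolicNetwork, x: np.ndarray) -> np.ndarray:
    """All reaction fluxes at normalized state x (same units as J0)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        bad = [net.species[i] for i in np.flatnonzero(x <= 0)]
        raise PreconditionError(f"non-positive concentration for: {', '.join(bad)}")
    return net.J0 * net.enzyme * (1.0 + net.E @ np.log(x))


def linlog_rate(net: MetabolicNetwork, state: MetabolicState, reaction_index: int) -> float:
    """Flux of one reaction under the lin-log law."""
    return float(rates(net, state.x)[reaction_index])


def rhs(net: MetabolicNetwork, x: np.ndarray) -> np.ndarray:
    """d(c/c0)/dt at normalized state x; zero for clamped external species."""
    dx = (net.N @ rates(net, x)) / net.c0
    dx[net.external] = 0.0
    return dx


def metabolic_rhs(net: MetabolicNetwork, state: MetabolicState) -> np.ndarray:
    return rhs(net, state.x)


def reference_jacobian(net: MetabolicNetwork) -> np.ndarray:
    """Jacobian of the internal mass balances at the reference state.

    ``d(dx_i/dt)/dx_k = C_ik / x_k`` with
    ``C = diag(1/c0) N diag(J0*enzyme) E``; at x = 1 this is just C restricted
    to internal rows/columns.  Its eigenvalues are the local stability
    diagnostic: all real parts negative means small perturbations decay.
    """
    C = (net.N * (net.J0 * net.enzyme)[None, :]) @ net.E / net.c0[:, None]
    idx = np.flatnonzero(net.internal)
    return C[np.ix_(idx, idx)]


# ---------------------------------------------------------------------------
# integration


def _log_space_system(net: MetabolicNetwork, environment: dict):
    """Internal ODE in y = ln(x_int) with externals clamped."""
    x_full = net.clamp_environment(np.ones(len(net.species)), environment or {})
    int_idx = np.flatnonzero(net.internal)
    ext_idx = np.flatnonzero(net.external)
    JE = net.J0 * net.enzyme
    E_int = net.E[:, int_idx]
    const = JE * (1.0 + net.E[:, ext_idx] @ np.log(x_full[ext_idx]))
    S_int = net.N[int_idx, :] / net.c0[int_idx, None]
    M = S_int @ (JE[:, None] * net.E[:, int_idx])   # d(dx/dt)/d(ln x_int)

    def f(y):
        # const already contains J0*enzyme*(1 + external log terms)
        x_int = np.exp(y)
        r = const + JE * (E_int @ y)
        return (S_int @ r) / x_int

    def jac(y, fy):
        x_int = np.exp(y)
        return M / x_int[:, None] - np.diag(fy)

    return int_idx, f, jac


def integrate_metabolism(net: MetabolicNetwork, state: MetabolicState,
                         environment: dict | None, duration: float,
                         rtol: float = 1e-6, atol: float = 1e-9) -> MetabolicState:
    """Integrate the mass balances over ``duration`` hours for one cell.

    External species are clamped to ``environment`` (absolute mmol/l).  Uses
    scipy BDF in log-concentration space (stiff, adaptive, structurally
    positive).  Raises :class:`NumericalError` on integrator failure.
    """
    if duration <= 0:
        raise PreconditionError("duration must be > 0")
    x = net.clamp_environment(np.asarray(state.x, dtype=float), environment or {})
    if np.any(x <= 0):
        bad = [net.species[i] for i in np.flatnonzero(x <= 0)]
        raise PreconditionError(f"non-positive concentration for: {', '.join(bad)}")
    int_idx, f, jac = _log_space_system(net, environment or {})
    y0 = np.log(x[int_idx])
    sol = solve_ivp(lambda t, y: f(y), (0.0, duration), y0, method="BDF",
                    jac=lambda t, y: jac(y, f(y)), rtol=rtol, atol=atol)
    if not sol.success:
        raise NumericalError(f"metabolic integration failed at t={sol.t[-1]:.4g} h: "
                             f"{sol.message}")
    out = x.copy()
    out[int_idx] = np.exp(sol.y[:, -1])
    return MetabolicState(x=out, time=state.time + duration)


def integrate_population(net: MetabolicNetwork, X: np.ndarray, env: np.ndarray,
                         env_species: list, duration: float,
                         rtol: float = 1e-6, atol: float = 1e-9,
                         max_steps: int = 4000) -> np.ndarray:
    """Advance many cells' metabolic states at once over ``duration`` hours.

    ``X`` is (n_cells, n_species) normalized; ``env`` is (n_cells, n_ext)
    absolute concentrations for ``env_species``.  Batched backward Euler in
    log space with step-doubling error control and local extrapolation
    (effective order 2); Newton systems are solved with numpy's batched
    linear solve.  Returns the new (n_cells, n_species) array.
    """
    B, n_sp = X.shape
    if B == 0:
        return X.copy()
    int_idx = np.flatnonzero(net.internal)
    ext_idx = np.array([net.sp_index[s] for s in env_species], dtype=np.int64)
    X = X.copy()
    xe = np.maximum(env / net.c0[ext_idx][None, :], _X_FLOOR)
    X[:, ext_idx] = xe
    JE = net.J0 * net.enzyme
    E_int = net.E[:, int_idx]
    E_ext = net.E[:, ext_idx]
    S_int = net.N[int_idx, :] / net.c0[int_idx, None]
    M = S_int @ (JE[:, None] * E_int)          # constant part of the Jacobian
    const_all = (1.0 + np.log(xe) @ E_ext.T) * JE[None, :]   # (B, n_rx)

    n = int_idx.size
    eye = np.eye(n)

    def f(Y, const):
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            r = const + (Y @ E_int.T) * JE[None, :]
            return (r @ S_int.T) / np.exp(Y)

    def be_step(Y, h, const):
        """Batched backward-Euler step with per-cell sizes h (Newton).

        Returns (Y1, ok_mask); cells whose Newton iteration fails are
        flagged instead of aborting the whole batch."""
        hcol = h[:, None]
        Y1 = Y + hcol * f(Y, const)
        ok = np.ones(Y.shape[0], dtype=bool)
        for _ in range(25):
            fy = f(Y1, const)
            with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
                G = Y1 - Y - hcol * fy
                # d f_i/dy_k = M_ik / x_i - delta_ik f_i
                x1 = np.exp(Y1)
                Jf = M[None, :, :] / x1[:, :, None]
                Jf -= fy[:, :, None] * eye[None, :, :]
                A = eye[None, :, :] - hcol[:, :, None] * Jf
            bad_rows = ~np.all(np.isfinite(A.reshape(A.shape[0], -1)), axis=1)
            if np.any(bad_rows):
                A[bad_rows] = eye
                G[bad_rows] = 0.0
                ok &= ~bad_rows
            try:
                delta = np.linalg.solve(A, G[:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                return Y1, np.zeros(Y.shape[0], dtype=bool)
            bad = ~np.all(np.isfinite(delta), axis=1)
            delta[bad] = 0.0
            ok &= ~bad
            Y1 = Y1 - delta
            if np.max(np.abs(delta)) < 1e-10 * (1.0 + np.max(np.abs(Y1))):
                return Y1, ok
        return Y1, ok & (np.max(np.abs(delta), axis=1) < 1e-7)

    Y = np.log(X[:, int_idx])
    t = np.zeros(B)
    h = np.full(B, duration)
    steps = 0
    active = np.ones(B, dtype=bool)
    while np.any(active):
        steps += 1
        if steps > max_steps:
            raise NumericalError(
                f"batched metabolic integration exceeded {max_steps} steps "
                f"(slowest cell at t={t.min():.4g} h)")
        idx = np.flatnonzero(active)
        Ya = Y[idx]
        ha = np.minimum(h[idx], duration - t[idx])
        ca = const_all[idx]
        Y_full, ok1 = be_step(Ya, ha, ca)
        Y_half, ok2 = be_step(Ya, ha / 2.0, ca)
        Y_two, ok3 = be_step(Y_half, ha / 2.0, ca)
        ok = ok1 & ok2 & ok3
        with np.errstate(invalid="ignore"):
            err = np.max(np.abs(Y_two - Y_full), axis=1)
            tol = atol + rtol * np.maximum(np.max(np.abs(Y_two), axis=1), 1.0)
            ratio = np.where(ok & np.isfinite(err), err / tol, np.inf)
        accept = ratio <= 1.0
        acc = idx[accept]
        Y[acc] = 2.0 * Y_two[accept] - Y_full[accept]   # local extrapolation
        t[acc] += ha[accept]
        with np.errstate(divide="ignore"):
            grow = np.where(ratio > 0, 0.9 / np.sqrt(np.maximum(ratio, 1e-8)), 2.0)
        h[idx] = ha * np.clip(grow, 0.1, 5.0)
        active[acc] = t[acc] < duration - 1e-12
    out = X
    out[:, int_idx] = np.exp(Y)
    return out


def find_steady_state(net: MetabolicNetwork, environment: dict | None = None,
                      x0: np.ndarray | None = None) -> MetabolicState:
    """Steady state of the clamped system (Newton in log space)."""
    from scipy.optimize import root
    int_idx, f, jac = _log_space_system(net, environment or {})
    x = net.clamp_environment(
        np.asarray(x0, dtype=float) if x0 is not None else np.ones(len(net.species)),
        environment or {})
    y0 = np.log(x[int_idx])
    sol = root(lambda y: f(y), y0, jac=lambda y: jac(y, f(y)), method="hybr",
               options={"xtol": 1e-12})
    achieved = float(np.max(np.abs(f(sol.x)))) if sol.x.size else 0.0
    if not sol.success and achieved > 1e-9:
        raise NumericalError(f"steady-state search failed: {sol.message}",
                             residual=achieved)
    out = x.copy()
    out[int_idx] = np.exp(sol.x)
    return MetabolicState(x=out)


# ---------------------------------------------------------------------------
# file IO and the bundled default network


def network_to_dict(net: MetabolicNetwork) -> dict:
    return {
        "species": [
            {"name": s, "c0": float(net.c0[i]), "external": bool(net.external[i])}
            for i, s in enumerate(net.species)
        ],
        "reactions": [
            {
                "name": r,
                "J0": float(net.J0[j]),
                "enzyme": float(net.enzyme[j]),
                "stoich": {net.species[i]: float(net.N[i, j])
                           for i in np.flatnonzero(net.N[:, j] != 0)},
                "elasticities": {role: dict(net.elasticities[j].get(role) or {})
                                 for role in ROLES
                                 if net.elasticities[j].get(role)},
            }
            for j, r in enumerate(net.reactions)
        ],
    }


def network_from_dict(d: dict) -> MetabolicNetwork:
    try:
        species = [s["name"] for s in d["species"]]
        c0 = np.array([float(s["c0"]) for s in d["species"]])
        external = np.array([bool(s.get("external", False)) for s in d["species"]])
        reactions = [r["name"] for r in d["reactions"]]
        J0 = np.array([float(r["J0"]) for r in d["reactions"]])
        enzyme = np.array([float(r.get("enzyme", 1.0)) for r in d["reactions"]])
    except (KeyError, TypeError) as exc:
        raise ValidationError([f"malformed network definition: missing {exc}"]) from None
    sp_index = {s: i for i, s in enumerate(species)}
    N = np.zeros((len(species), len(reactions)))
    problems = []
    elasticities = []
    for j, r in enumerate(d["reactions"]):
        for sp_name, coeff in (r.get("stoich") or {}).items():
            if sp_name not in sp_index:
                problems.append(f"reaction '{r['name']}' stoichiometry names unknown "
                                f"species '{sp_name}'")
                continue
            N[sp_index[sp_name], j] = float(coeff)
        elasticities.append({role: dict(r.get("elasticities", {}).get(role) or {})
                             for role in ROLES})
    if problems:
        raise ValidationError(problems)
    net = MetabolicNetwork(species=species, c0=c0, external=external,
                           reactions=reactions, J0=J0, enzyme=enzyme, N=N,
                           elasticities=elasticities)
    return net.validate()


def load_network(path) -> MetabolicNetwork:
    """Load and validate a metabolic-network definition (YAML)."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return network_from_dict(d)


def save_network(net: MetabolicNetwork, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(network_to_dict(net), fh, sort_keys=False)


def default_network() -> MetabolicNetwork:
    """Bundled HEPG2-like central-carbon network.

    Topology: glucose -> g6p -> f16bp -> pyruvate, branching to lactate
    (exported) and acetyl-CoA -> TCA -> oxygen-consuming respiration, with
    the pentose-phosphate shunt g6p -> 6-phosphogluconate -> f16bp.  The
    reference fluxes and elasticities are synthetic but internally
    consistent (flux-balanced at the reference state, locally stable); the
    file format accepts a full published parameterization verbatim when the
    user supplies one.
    """
    spec = {
        "species": [
            {"name": "glc_ext", "c0": 5.0, "external": True},
            {"name": "o2_ext", "c0": 0.13, "external": True},
            {"name": "lac_ext", "c0": 1.5, "external": True},
            {"name": "g6p", "c0": 0.2},
            {"name": "pg6", "c0": 0.05},
            {"name": "f16bp", "c0": 0.1},
            {"name": "pyr", "c0": 0.1},
            {"name": "lac", "c0": 1.0},
            {"name": "accoa", "c0": 0.05},
            {"name": "tca", "c0": 0.3},
        ],
        "reactions": [
            {"name": "glc_uptake_hk", "J0": 3.0,
             "stoich": {"glc_ext": -1, "g6p": 1},
             "elasticities": {"substrate": {"glc_ext": 0.8},
                              "inhibitor": {"g6p": -0.3}}},
            {"name": "pgi_pfk", "J0": 2.7,
             "stoich": {"g6p": -1, "f16bp": 1},
             "elasticities": {"substrate": {"g6p": 0.9},
                              "product": {"f16bp": -0.3}}},
            {"name": "ppp_oxidative", "J0": 0.3,
             "stoich": {"g6p": -1, "pg6": 1},
             "elasticities": {"substrate": {"g6p": 0.9},
                              "product": {"pg6": -0.4}}},
            {"name": "ppp_return", "J0": 0.3,
             "stoich": {"pg6": -1, "f16bp": 1},
             "elasticities": {"substrate": {"pg6": 0.9},
                              "product": {"f16bp": -0.1}}},
            {"name": "lower_glycolysis", "J0": 3.0,
             "stoich": {"f16bp": -1, "pyr": 2},
             "elasticities": {"substrate": {"f16bp": 0.8},
                              "product": {"pyr": -0.25}}},
            {"name": "ldh", "J0": 4.2,
             "stoich": {"pyr": -1, "lac": 1},
             "elasticities": {"substrate": {"pyr": 1.0},
                              "product": {"lac": -0.3}}},
            {"name": "lac_export", "J0": 4.2,
             "stoich": {"lac": -1, "lac_ext": 1},
             "elasticities": {"substrate": {"lac": 0.9},
                              "product": {"lac_ext": -0.2}}},
            {"name": "pdh", "J0": 1.8,
             "stoich": {"pyr": -1, "accoa": 1},
             "elasticities": {"substrate": {"pyr": 0.8, "o2_ext": 0.3},
                              "product": {"accoa": -0.4}}},
            {"name": "tca_cycle", "J0": 1.8,
             "stoich": {"accoa": -1, "tca": 1},
             "elasticities": {"substrate": {"accoa": 0.9},
                              "product": {"tca": -0.3}}},
            {"name": "respiration", "J0": 1.8,
             "stoich": {"tca": -1, "o2_ext": -3},
             "elasticities": {"substrate": {"tca": 0.9, "o2_ext": 0.5}}},
        ],
    }
    return network_from_dict(spec)
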
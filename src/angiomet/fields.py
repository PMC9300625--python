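"""Quasi-steady reaction-diffusion fields (oxygen, VEGF, glucose).

Each diffusible species obeys, at quasi steady state,

    D lap(c) + k_v(x) (c_blood - c) - r_uptake(c) I(x) + s(x) - delta c = 0

where ``k_v`` is the vessel-wall exchange coefficient assembled from the
functional vascular segments (``2 pi R P L_site / V_site`` per site), ``I``
indicates an occupied site, ``r_uptake`` is the Michaelis-Menten law
``r_max c/(K_M + c)`` with cell-type-specific parameters, ``s`` a production
source (VEGF secretion) and ``delta`` a first-order decay (VEGF).

The discretization is the standard second-order 7-point stencil with
zero-flux (or Dirichlet) faces; the nonlinear uptake is handled by Picard
iteration with the Michaelis denominator lagged one iteration, each linear
pass solved by conjugate gradients on the resulting symmetric M-matrix
(which keeps converged solutions non-negative without clipping).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import cg, factorized

from .config import FieldConfig, UptakeConfig
from .errors import ConfigError, NumericalError, PreconditionError
from .lattice import CELL_CANCER, CELL_NORMAL, STATE_QUIESCENT, Lattice

__all__ = ["FieldGrid", "glucose_uptake_rate", "solve_quasi_steady",
           "vessel_exchange_coefficients", "vegf_secretion_source",
           "uptake_coefficient_map"]


@dataclass
class FieldGrid:
    """Per-species concentration array on the lattice."""
    species: str
    values: np.ndarray
    lattice: Lattice

    @classmethod
    def zeros(cls, species: str, lattice: Lattice) -> "FieldGrid":
        return cls(species, np.zeros(lattice.dims), lattice)

    def equatorial_slice(self, axis: int = 2) -> np.ndarray:
        """Mid-plane cross-section (the Fig.-style equatorial slice)."""
        idx = self.lattice.dims[axis] // 2
        return np.take(self.values, idx, axis=axis)


def glucose_uptake_rate(c, params: UptakeConfig):
    """Michaelis-Menten uptake ``r_max c / (K_M + c)``; monotone, bounded by r_max.

    Cancer cells default to r_max = 3.3 mmol/(l h), normal cells to
    0.66 mmol/(l h), both with K_M = 0.2 mmol/l.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise PreconditionError("concentration must be >= 0")
    out = params.r_max * c / (params.k_m + c)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# source/sink assembly


def vessel_exchange_coefficients(lattice: Lattice, network) -> np.ndarray:
    """Per-site geometric vessel exchange factor ``sum(2 pi R * L/2) / V_site``.

    Each functional segment contributes half its length to each endpoint
    site.  Multiplying by the wall permeation coefficient P gives the
    first-order exchange rate (1/h) toward the intravascular concentration.
    """
    kv = np.zeros(lattice.dims)
    if network is None:
        return kv
    v_site = lattice.spacing ** 3
    for i in range(network.n_segments):
        if not network.functional[i]:
            continue
        L = network.segment_length(i)
        r = network.radius[i]
        w = 2.0 * np.pi * r * (L / 2.0) / v_site
        kv[network.node_pos[network.seg_a[i]]] += w
        kv[network.node_pos[network.seg_b[i]]] += w
    return kv


def uptake_coefficient_map(lattice: Lattice, pop, params: FieldConfig,
                           quiescent_cancer_uptake: str = "cancer"):
    """Per-site (r_max, K_M) arrays from cell occupancy.

    Quiescent cancer cells consume at the cancer rate by default (config
    switch ``cells.quiescent_cancer_uptake`` selects the normal rate instead).
    """
    r_max = np.zeros(lattice.dims)
    k_m = np.full(lattice.dims, 1.0)
    if pop is None or pop.n == 0:
        return r_max, k_m
    for i in range(pop.n):
        site = tuple(pop.pos[i])
        if pop.ctype[i] == CELL_CANCER:
            up = params.uptake_cancer
            if quiescent_cancer_uptake == "normal" and pop.state[i] == STATE_QUIESCENT:
                up = params.uptake_normal
        else:
            up = params.uptake_normal
        r_max[site] = up.r_max
        k_m[site] = up.k_m
    return r_max, k_m


def vegf_secretion_source(pop, lattice: Lattice, secretion_rate: float) -> np.ndarray:
    """Per-site VEGF production: ``secretion_rate * intracellular VEGF`` of the
    occupant.  Hypoxic cells carry high intracellular VEGF (via the
    subcellular ODE's oxygen dependence), so secretion localizes to hypoxic
    regions; an empty site produces nothing."""
    src = np.zeros(lattice.dims)
    if pop is None or pop.n == 0 or secretion_rate == 0:
        return src
    np.add.at(src, tuple(pop.pos.T), secretion_rate * pop.ivegf)
    return src


# ---------------------------------------------------------------------------
# Laplacian assembly (cached per lattice geometry and boundary condition)

_LAP_CACHE: dict = {}


def _neumann_laplacian_1d(n: int) -> sp.csr_matrix:
    """1D second-difference matrix with zero-flux (reflecting) boundaries."""
    if n == 1:
        return sp.csr_matrix((1, 1))
    main = -2.0 * np.ones(n)
    main[0] = main[-1] = -1.0
    off = np.ones(n - 1)
    return sp.diags([off, main, off], [-1, 0, 1], format="csr")


def _dirichlet_laplacian_1d(n: int) -> sp.csr_matrix:
    """1D second differences with cell-centred Dirichlet faces (ghost value
    ``2 c_face - c_0``); the face contribution goes to the right-hand side."""
    if n == 1:
        return sp.csr_matrix(np.array([[-4.0]]))
    main = -2.0 * np.ones(n)
    main[0] = main[-1] = -3.0
    off = np.ones(n - 1)
    return sp.diags([off, main, off], [-1, 0, 1], format="csr")


def _dirichlet_x0_laplacian_1d(n: int) -> sp.csr_matrix:
    """Dirichlet at the low face only, zero-flux at the high face."""
    if n == 1:
        return sp.csr_matrix(np.array([[-2.0]]))
    main = -2.0 * np.ones(n)
    main[0] = -3.0
    main[-1] = -1.0
    off = np.ones(n - 1)
    return sp.diags([off, main, off], [-1, 0, 1], format="csr")


def assemble_laplacian(lattice: Lattice, bc: str = "neumann"):
    """Sparse 7-point Laplacian (times h^2) for the given boundary condition.

    ``bc`` is 'neumann' (zero-flux everywhere), 'dirichlet' (prescribed value
    on all faces) or 'dirichlet_x0' (prescribed value on the x-min face,
    zero-flux elsewhere).  Returns (L, face_weight) where ``face_weight`` is
    a flat array holding the coefficient multiplying the face value in the
    right-hand side (zero for Neumann).
    """
    key = (lattice.dims, bc)
    if key in _LAP_CACHE:
        return _LAP_CACHE[key]
    nx, ny, nz = lattice.dims
    one = {n: sp.identity(n, format="csr") for n in {nx, ny, nz}}
    if bc == "neumann":
        mkx = mky = mkz = _neumann_laplacian_1d
    elif bc == "dirichlet":
        mkx = mky = mkz = _dirichlet_laplacian_1d
    elif bc == "dirichlet_x0":
        mkx = _dirichlet_x0_laplacian_1d
        mky = mkz = _neumann_laplacian_1d
    else:
        raise ConfigError([f"unknown boundary condition '{bc}'"])
    Lx, Ly, Lz = mkx(nx), mky(ny), mkz(nz)
    L = (sp.kron(sp.kron(Lx, one[ny]), one[nz])
         + sp.kron(sp.kron(one[nx], Ly), one[nz])
         + sp.kron(sp.kron(one[nx], one[ny]), Lz)).tocsr()
    face = np.zeros(lattice.dims)
    if bc in ("dirichlet", "dirichlet_x0"):
        face[0, :, :] += 2.0
        if bc == "dirichlet":
            face[-1, :, :] += 2.0
            if ny > 1:
                face[:, 0, :] += 2.0
                face[:, -1, :] += 2.0
            if nz > 1:
                face[:, :, 0] += 2.0
                face[:, :, -1] += 2.0
    _LAP_CACHE[key] = (L, face.ravel())
    return _LAP_CACHE[key]


# ---------------------------------------------------------------------------
# quasi-steady solve


def solve_quasi_steady(field: FieldGrid, params: FieldConfig, pop=None,
                       network=None, production: np.ndarray | None = None,
                       quiescent_cancer_uptake: str = "cancer") -> FieldGrid:
    """Solve the quasi-steady balance for one species in place.

    ``pop`` supplies the cellular sinks (may be None for cell-free tissue),
    ``network`` the vessel permeation source, ``production`` an optional
    per-site volumetric source (mmol/(l h)), used for VEGF secretion.

    Picard iteration lags the Michaelis denominator; convergence is declared
    when the nonlinear residual norm drops below ``params.tol`` relative to
    the source scale.  Raises :class:`NumericalError` on non-convergence.
    """
    lattice = field.lattice
    if params.d <= 0:
        raise ConfigError(["field diffusivity must be > 0"])
    h2 = lattice.spacing ** 2
    L, face_w = assemble_laplacian(lattice, params.bc)
    kv = vessel_exchange_coefficients(lattice, network).ravel() * params.p_wall
    r_max, k_m = uptake_coefficient_map(lattice, pop, params, quiescent_cancer_uptake)
    r_max = r_max.ravel()
    k_m = k_m.ravel()
    src = kv * params.c_blood
    if production is not None:
        src = src + production.ravel()
    if params.bc in ("dirichlet", "dirichlet_x0"):
        src = src + (params.d / h2) * face_w * params.bc_value
    A0 = (-params.d / h2) * L
    base_diag = kv + params.decay

    c = np.clip(field.values.ravel().copy(), 0.0, None)
    scale = max(float(np.max(src)), params.c_blood * max(float(np.max(kv)), 1.0), 1e-30)
    n = c.size
    converged = False
    resid = None
    for _ in range(params.max_picard):
        k_up = r_max / (k_m + c)                 # lagged linearized uptake
        A = A0 + sp.diags(base_diag + k_up)
        # nonlinear residual with the true Michaelis law
        true_sink = r_max * c / (k_m + c)
        resid_vec = A0 @ c + base_diag * c + true_sink - src
        resid = float(np.linalg.norm(resid_vec) / (np.sqrt(n) * scale))
        if resid <= params.tol:
            converged = True
            break
        if n <= 1024:
            c_new = factorized(A.tocsc())(src)
        else:
            # warm-started conjugate gradients on the symmetric M-matrix
            c_new, info = cg(A, src, x0=c, rtol=1e-13, atol=1e-30 * scale,
                             maxiter=10 * n, M=sp.diags(1.0 / A.diagonal()))
            if info != 0:
                raise NumericalError("CG failed inside Picard iteration", residual=resid)
        c = c_new
    if not converged:
        raise NumericalError("quasi-steady field solve did not converge", residual=resid)
    field.values = c.reshape(lattice.dims)
    return field
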
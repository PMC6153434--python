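"""Reaction-diffusion transport solvers.

Three culture configurations are covered:

* :class:`FineGridTransport` — the 3D lattice solver for spheroids.  Each
  diffusible solute has an extracellular concentration on every lattice site
  (6-point stencil, D_tissue inside occupied sites, D_medium elsewhere) plus
  an intracellular concentration in every cell; the surrounding unstirred
  medium is a 1D axial column of slabs coupled flux-conservatively to the
  box boundary (exactly, through a reduced boundary-mean/slab system).
  Diffusion with linear extracellular losses is advanced implicitly
  (backward Euler by default: positivity-preserving and exactly
  conservative on the flux form); the per-cell reaction network — membrane
  exchange, oxygen-dependent metabolism, chain conversion, kill hazards —
  is linear with piecewise-constant coefficients and is advanced by exact
  matrix exponentials between diffusion steps.
* :func:`simulate_monolayer` — depth is the only spatial coordinate; the
  medium column is discretised in 1D, the cell layer at the bottom holds one
  intracellular compartment per lineage.  Integrated with an adaptive stiff
  ODE method.
* :func:`simulate_mcl` — a multicellular layer slab between two well-stirred
  compartments (the diffusion-chamber geometry), cell volume fraction 0.5,
  mixed lineages per slab node.

Oxygen relaxes within seconds on these length scales, so during spheroid
growth and drug exposure it is solved as a quasi-steady radial profile
(Michaelis-Menten consumption) coupled to the medium column, refreshed at
short intervals; the monolayer and MCL solvers integrate O2 dynamically.

Units: uM, um, s throughout.  Amounts are reported in umol
(uM * um^3 * 1e-15).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.integrate import solve_ivp
from scipy.linalg import solve_banded

from .core import (VACANT, CellPopulation, CultureGeometry, LatticeGrid,
                   SoluteSpec)
from .pkpd import ProdrugModel

UM3_UM_TO_UMOL = 1e-15  # uM * um^3 -> umol
MOL_PER_S_TO_UM3_UM = 1e21  # mol/s -> uM * um^3 / s

CLIP_FLOOR = -1e-12  # uM; more-negative values indicate a solver defect


def michaelis_menten_O2_rate(C_O2, V_max: float, K_m: float):
    """Molar O2 consumption rate V_max * C / (K_m + C) (mol cell^-1 s^-1)."""
    C = np.asarray(C_O2, dtype=float)
    if np.any(C < 0):
        raise ValueError("O2 concentration must be >= 0")
    out = V_max * C / (K_m + C)
    return float(out) if out.ndim == 0 else out


def membrane_exchange(C_e, C_i, K_in: float, K_out: float, vol_ratio):
    """First-order trans-membrane exchange.

    Returns (dC_i/dt, dC_e/dt) with dC_i/dt = K_in*C_e - K_out*C_i and the
    extracellular side scaled by the extracellular/intracellular volume ratio
    so that moles are conserved exactly by construction.
    """
    if K_in < 0 or K_out < 0:
        raise ValueError("exchange rate constants must be >= 0")
    if np.any(np.asarray(vol_ratio) <= 0):
        raise ValueError("vol_ratio must be > 0")
    dCi = K_in * np.asarray(C_e, float) - K_out * np.asarray(C_i, float)
    return dCi, -dCi / vol_ratio


class _LUSolve:
    def __init__(self, lu):
        self._lu = lu

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        return self._lu.solve(rhs)


class _CGSolve:
    """Jacobi-preconditioned CG on the volume-symmetrised implicit system."""

    def __init__(self, K: sp.csr_matrix, volumes: np.ndarray,
                 rtol: float = 1e-9):
        self.K = K
        self.V = volumes
        self.rtol = rtol
        self._dinv = 1.0 / K.diagonal()
        self._M = spla.LinearOperator(K.shape, matvec=lambda x: self._dinv * x)
        self._x_prev: np.ndarray | None = None

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        b = self.V * rhs
        x0 = self._x_prev if self._x_prev is not None else rhs
        x, info = spla.cg(self.K, b, x0=x0, rtol=self.rtol, atol=0.0,
                          M=self._M, maxiter=2000)
        if info != 0:
            raise RuntimeError(f"CG failed to converge (info={info})")
        self._x_prev = x
        return x


@dataclass
class SolverSettings:
    """Numerical controls for the transport solvers."""

    rtol: float = 1e-6
    atol: float = 1e-9          # uM
    dt_max: float = 10.0        # s, fine-grid macro step
    theta: float = 1.0          # implicit weight: 1 backward Euler (default:
                                # positivity-preserving and exactly
                                # conservative), 0.5 Crank-Nicolson
    n_smoothing_steps: int = 4  # initial backward-Euler steps when theta=0.5
                                # (Rannacher smoothing of bolus profiles)
    o2_interval: float = 30.0   # s between quasi-steady O2 refreshes
    n_column_slabs: int = 6
    coupling: str = "1D axial medium column, flux-conservative at the box boundary"

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be > 0")


@dataclass
class TransportState:
    """Snapshot of all concentration fields (uM) at time ``t`` (s)."""

    t: float
    C_e: dict[str, np.ndarray]        # per-solute, per lattice site
    C_med: dict[str, np.ndarray]      # per-solute, per medium slab
    C_i: dict[str, np.ndarray]        # per-solute, per cell
    hazard: np.ndarray                # per cell, cumulative kill hazard
    O2_cell: np.ndarray               # per cell, uM


class FineGridTransport:
    """IMEX reaction-diffusion solver on the 3D lattice plus medium column.

    Parameters
    ----------
    grid, cells:
        Lattice with occupancy and the cell population (may be empty).
    model:
        Prodrug model providing solutes, metabolism map and kill models.
        May be ``None`` for pure-diffusion problems; then pass ``solutes``.
    geometry:
        Culture geometry; ``None`` gives a closed box (no medium column).
    site_sink:
        Optional per-site first-order sink (s^-1) applied to the first
        solute inside the implicit operator — used for continuum
        consumption problems (e.g. the spherical steady-state oracle).
    clamp:
        Optional ``(mask, value)`` holding selected sites of the first
        solute at a fixed concentration (Dirichlet condition).
    """

    def __init__(self, grid: LatticeGrid, cells: CellPopulation | None,
                 model: ProdrugModel | None,
                 geometry: CultureGeometry | None = None,
                 solutes: tuple[SoluteSpec, ...] | None = None,
                 settings: SolverSettings | None = None,
                 site_sink: np.ndarray | None = None,
                 clamp: tuple[np.ndarray, float] | None = None,
                 medium_volume: float | None = None):
        self.grid = grid
        self.cells = cells
        self.model = model
        self.geometry = geometry
        self.settings = settings or SolverSettings()
        self.solutes = tuple(solutes if solutes is not None else model.solutes)
        self.site_sink = site_sink
        self.clamp = clamp
        self._clip_events = 0
        self._steps = 0

        occ = grid.occupancy != VACANT
        self.occ = occ
        # Extracellular volume per site: vacant sites are fully extracellular,
        # occupied sites are half cell (volume fraction 0.5).
        self.V_e = np.where(occ, grid.site_volume * 0.5, grid.site_volume)
        self.V_i = grid.site_volume * 0.5  # per cell

        if cells is not None and len(cells):
            live = cells.state != 2  # necrotic cells freed their site
            self.cell_idx = np.flatnonzero(live)
            self.cell_sites = cells.site[self.cell_idx]
            self.cell_lines = cells.line_idx[self.cell_idx]
        else:
            self.cell_idx = np.empty(0, dtype=np.int64)
            self.cell_sites = np.empty(0, dtype=np.int64)
            self.cell_lines = np.empty(0, dtype=np.int64)

        # Medium column
        self.n_slabs = 0
        self.V_slab = np.empty(0)
        if geometry is not None:
            vol = medium_volume if medium_volume is not None else geometry.medium_volume
            box_ext = float(self.V_e.sum())
            col_vol = max(vol - box_ext, 0.1 * vol)
            self.n_slabs = self.settings.n_column_slabs
            self.V_slab = np.full(self.n_slabs, col_vol / self.n_slabs)
            self.col_height = col_vol / geometry.well_area
            self.h_slab = self.col_height / self.n_slabs

        n = grid.n_sites + self.n_slabs
        self.state = TransportState(
            t=0.0,
            C_e={s.name: np.zeros(grid.n_sites) for s in self.solutes},
            C_med={s.name: np.zeros(self.n_slabs) for s in self.solutes},
            C_i={s.name: np.zeros(self.cell_idx.size) for s in self.solutes},
            hazard=np.zeros(self.cell_idx.size),
            O2_cell=np.zeros(self.cell_idx.size),
        )
        self._lu: dict[tuple[str, float], spla.SuperLU] = {}
        self._ops: dict[str, sp.csr_matrix] = {}
        self._volumes = np.concatenate([self.V_e, self.V_slab])
        self._kmet_cache: np.ndarray | None = None

    # ------------------------------------------------------------------
    # operator assembly
    def _operator(self, solute: SoluteSpec) -> sp.csr_matrix:
        """Volume-weighted diffusion(+linear loss) operator: dC/dt = L C."""
        if solute.name in self._ops:
            return self._ops[solute.name]
        grid = self.grid
        N = grid.n_sites
        D_site = np.where(self.occ, solute.D_tissue, solute.D_medium)
        rows, cols, data = [], [], []

        def add_pairs(i_flat, j_flat, g):
            for a, b in ((i_flat, j_flat), (j_flat, i_flat)):
                rows.append(a); cols.append(b); data.append(g)
                rows.append(a); cols.append(a); data.append(-g)

        idx = np.arange(N).reshape(grid.dims)
        for axis in range(3):
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[axis] = slice(0, -1)
            sl_hi[axis] = slice(1, None)
            i_flat = idx[tuple(sl_lo)].ravel()
            j_flat = idx[tuple(sl_hi)].ravel()
            # harmonic-mean face diffusivity, conductance D*A/dx = D*dx
            Df = 2.0 * D_site[i_flat] * D_site[j_flat] / (
                D_site[i_flat] + D_site[j_flat] + 1e-300)
            add_pairs(i_flat, j_flat, Df * grid.dx)

        Ntot = N
        rows = np.concatenate([np.asarray(r).ravel() for r in rows])
        cols = np.concatenate([np.asarray(c).ravel() for c in cols])
        data = np.concatenate([np.asarray(d, dtype=float).ravel() for d in data])
        L = sp.coo_matrix((data, (rows, cols)), shape=(Ntot, Ntot)).tocsr()
        L = sp.diags(1.0 / self.V_e) @ L
        # linear extracellular losses inside the operator
        diag = np.zeros(Ntot)
        if solute.k_decay_medium:
            diag[:] = -solute.k_decay_medium
        if self.site_sink is not None and solute is self.solutes[0]:
            diag += -self.site_sink
        if diag.any():
            L = L + sp.diags(diag)
        if self.clamp is not None and solute is self.solutes[0]:
            # Dirichlet sites: zero time-derivative rows so the clamp holds
            # exactly during implicit solves (columns keep feeding flux).
            keep = np.ones(Ntot)
            keep[self.clamp[0]] = 0.0
            L = sp.diags(keep) @ L
        L = L.tocsr()
        self._ops[solute.name] = L
        return L

    def _boundary_sites(self) -> np.ndarray:
        if not hasattr(self, "_bsites"):
            bmask = np.zeros(self.grid.dims, dtype=bool)
            bmask[0, :, :] = bmask[-1, :, :] = True
            bmask[:, 0, :] = bmask[:, -1, :] = True
            bmask[:, :, 0] = bmask[:, :, -1] = True
            self._bsites = np.flatnonzero(bmask.ravel())
        return self._bsites

    def _column_exchange(self, solute: SoluteSpec, dt: float,
                         gas_conc: float | None) -> None:
        """Exact update of the box-boundary <-> medium-column exchange.

        All boundary sites couple to slab 0 with the same rate constant, so
        the subsystem reduces to (boundary mean, slabs): a small linear ODE
        solved by matrix exponential.  Per-site deviations from the boundary
        mean decay as exp(-a dt) exactly.  Conservation is exact.
        """
        bs = self._boundary_sites()
        Cb = self.state.C_e[solute.name][bs]
        V_b = self.V_e[bs]
        V_bs = float(V_b[0])  # boundary shell is vacant medium: uniform V_e
        a = solute.D_medium * self.grid.dx / V_bs
        n_b = bs.size
        M = self.n_slabs
        gas = gas_conc if (gas_conc is not None and solute.name == "O2") else None
        dim = 1 + M + (1 if gas is not None else 0)
        key = (solute.name, dt, None if gas is None else round(gas, 9))
        if not hasattr(self, "_col_cache"):
            self._col_cache = {}
        P = self._col_cache.get(key)
        if P is None:
            from scipy.linalg import expm
            G = np.zeros((dim, dim))
            G[0, 0] = -a
            G[0, 1] = a
            c = solute.D_medium * self.grid.dx * n_b / self.V_slab[0]
            G[1, 0] = c
            G[1, 1] = -c
            A_col = self.geometry.well_area
            g_ss = solute.D_medium * A_col / self.h_slab
            for j in range(M - 1):
                G[1 + j, 1 + j] += -g_ss / self.V_slab[j]
                G[1 + j, 2 + j] += g_ss / self.V_slab[j]
                G[2 + j, 1 + j] += g_ss / self.V_slab[j + 1]
                G[2 + j, 2 + j] += -g_ss / self.V_slab[j + 1]
            if gas is not None:
                g_top = solute.D_medium * A_col / (self.h_slab / 2.0)
                G[M, M] += -g_top / self.V_slab[-1]
                G[M, dim - 1] = g_top / self.V_slab[-1] * gas
            P = expm(G * dt)
            self._col_cache[key] = P
        ubar = float(Cb.mean())
        y = np.empty(dim)
        y[0] = ubar
        y[1:1 + M] = self.state.C_med[solute.name]
        if gas is not None:
            y[-1] = 1.0
        y_new = P @ y
        decay = np.exp(-a * dt)
        self.state.C_e[solute.name][bs] = y_new[0] + (Cb - ubar) * decay
        self.state.C_med[solute.name] = y_new[1:1 + M]

    def _solver_for(self, solute: SoluteSpec, dt: float, theta: float = 1.0):
        """Implicit solver for (I - theta*dt*L) x = r.

        Without Dirichlet clamping the system is symmetric positive definite
        in the volume-weighted inner product and is solved by Jacobi-
        preconditioned conjugate gradients with warm starts; with clamping
        (broken symmetry) a sparse LU factorisation is used instead.
        """
        key = (solute.name, dt, theta)
        if key not in self._lu:
            L = self._operator(solute)
            Ntot = L.shape[0]
            if self.clamp is not None:
                A = (sp.identity(Ntot, format="csr") - (theta * dt) * L).tocsc()
                lu = spla.splu(A)
                self._lu[key] = (_LUSolve(lu), L)
            else:
                # symmetrised K = M - theta*dt*M*L (M = diag of volumes)
                M = sp.diags(self.V_e)
                K = (M - (theta * dt) * (M @ L)).tocsr()
                K = (K + K.T) * 0.5  # clean round-off asymmetry
                self._lu[key] = (_CGSolve(K, self.V_e), L)
        return self._lu[key]

    # ------------------------------------------------------------------
    def set_uniform_medium(self, solute: str, conc: float,
                           include_interstitium: bool = False) -> None:
        """Put a well-mixed bolus in the medium (column + vacant box sites)."""
        C = self.state.C_e[solute]
        if include_interstitium:
            C[:] = conc
        else:
            C[~self.occ] = conc
        if self.n_slabs:
            self.state.C_med[solute][:] = conc

    def total_amount(self, solute: str) -> float:
        """Total tracked amount of a solute (umol), all compartments."""
        st = self.state
        amt = float(st.C_e[solute] @ self.V_e)
        if self.n_slabs:
            amt += float(st.C_med[solute] @ self.V_slab)
        if st.C_i[solute].size:
            amt += float(st.C_i[solute].sum() * self.V_i)
        return amt * UM3_UM_TO_UMOL

    # ------------------------------------------------------------------
    def step(self, dt: float, gas_O2: float | None = None) -> TransportState:
        """Advance all fields by ``dt`` (must be <= dt_max)."""
        if dt > self.settings.dt_max + 1e-12:
            raise ValueError(f"dt {dt} exceeds dt_max {self.settings.dt_max}")
        st = self.state
        theta = self.settings.theta
        if theta < 1.0 and self._steps < self.settings.n_smoothing_steps:
            theta = 1.0
        for s in self.solutes:
            if not s.diffusible:
                continue
            x = st.C_e[s.name]
            solver, L = self._solver_for(s, dt, theta=theta)
            rhs = x + ((1 - theta) * dt) * (L @ x)
            x = solver.solve(rhs)
            neg = x < 0
            if np.any(neg):
                if np.any(x < CLIP_FLOOR * 1e6):  # far beyond round-off
                    self._clip_events += int(np.count_nonzero(neg))
                x = np.clip(x, 0.0, None)
            st.C_e[s.name] = x
            if self.n_slabs:
                self._column_exchange(s, dt, gas_O2)
            if self.clamp is not None and s is self.solutes[0]:
                mask, value = self.clamp
                st.C_e[s.name][mask] = value
        if self.cell_idx.size and self.model is not None:
            self._reaction_step(dt)
        st.t += dt
        self._steps += 1
        return st

    def run(self, duration: float, gas_O2: float | None = None) -> TransportState:
        nstep = max(1, int(np.ceil(duration / self.settings.dt_max)))
        dt = duration / nstep
        for _ in range(nstep):
            self.step(dt, gas_O2=gas_O2)
        return self.state

    # ------------------------------------------------------------------
    def _line_kmet0(self) -> np.ndarray:
        if self._kmet_cache is None:
            lines = self.cells.lines
            arr = np.zeros(len(lines))
            for i, ln in enumerate(lines):
                spec = self.model.metabolism.get(ln.name)
                arr[i] = 0.0 if spec is None else spec.K_met0
            self._kmet_cache = arr
        return self._kmet_cache

    def _reaction_matrix(self, kmet: float) -> np.ndarray:
        """Generator of the per-cell linear reaction network.

        State ordering: [C_e of each solute at the cell's site, C_i of each
        solute, cumulative hazard].  Membrane exchange, intracellular losses,
        chain conversion, oxygen-dependent metabolism and the kill laws are
        all first-order, so a cell's reaction update over dt is the exact
        matrix exponential of this generator.
        """
        model = self.model
        names = [s.name for s in model.solutes]
        ns = len(names)
        A = np.zeros((2 * ns + 1, 2 * ns + 1))
        for k, s in enumerate(model.solutes):
            A[k, k] -= s.K_in
            A[k, ns + k] += s.K_out       # vol_ratio = 1 at occupied sites
            A[ns + k, k] += s.K_in
            A[ns + k, ns + k] -= s.K_out + s.k_loss_cell + s.k_chain
            if s.k_chain and s.child in names:
                A[ns + names.index(s.child), ns + k] += s.k_chain
        A[ns, ns] -= kmet                 # prodrug metabolism
        if model.met_target is not None:
            A[ns + names.index(model.met_target), ns] += kmet
        for km in model.kill_models:
            if km.mode == "metabolism_rate":
                A[2 * ns, ns] += km.K_c * kmet
            else:
                A[2 * ns, ns + names.index(km.acts_on)] += km.K_c
        return A

    def _reaction_step(self, dt: float) -> None:
        """Exact linear reaction update (matrix exponential per group of
        cells sharing a line and O2 level), then exact extracellular chain
        conversion.  The kill hazard accumulates as part of the same linear
        system, so survival is independent of the step subdivision."""
        from scipy.linalg import expm

        st = self.state
        model = self.model
        cs = self.cell_sites
        names = [s.name for s in model.solutes]
        ns = len(names)

        if model.metabolism:
            any_spec = next(iter(model.metabolism.values()))
            K_O2 = any_spec.K_O2
            kmet0 = self._line_kmet0()[self.cell_lines]
            kmet = kmet0 * K_O2 / (K_O2 + st.O2_cell)
        else:
            kmet = np.zeros(cs.size)

        # stack per-cell state vectors: (n_cells, 2*ns+1)
        Y = np.empty((cs.size, 2 * ns + 1))
        for k, n in enumerate(names):
            Y[:, k] = st.C_e[n][cs]
            Y[:, ns + k] = st.C_i[n]
        Y[:, 2 * ns] = st.hazard

        # group by (line, kmet): O2 is shell-wise constant, so the number of
        # distinct kmet values stays small
        key = np.round(kmet, 12)
        if not hasattr(self, "_expm_cache"):
            self._expm_cache = {}
        for kv in np.unique(key):
            members = np.flatnonzero(key == kv)
            ck = (float(kv), dt)
            P = self._expm_cache.get(ck)
            if P is None:
                P = expm(self._reaction_matrix(float(kv)) * dt)
                if len(self._expm_cache) < 4096:
                    self._expm_cache[ck] = P
            Y[members] = Y[members] @ P.T
        Y = np.clip(Y, 0.0, None)
        for k, n in enumerate(names):
            st.C_e[n][cs] = Y[:, k]
            st.C_i[n] = Y[:, ns + k]
        st.hazard = Y[:, 2 * ns]

        # exact extracellular chain conversion (medium chemistry)
        for s in model.solutes:
            n = s.name
            if s.k_chain_medium and s.child in st.C_e:
                f = np.exp(-s.k_chain_medium * dt)
                moved = st.C_e[n] * (1.0 - f)
                st.C_e[n] *= f
                st.C_e[s.child] += moved
                if self.n_slabs:
                    moved_m = st.C_med[n] * (1.0 - f)
                    st.C_med[n] *= f
                    st.C_med[s.child] += moved_m

    # ------------------------------------------------------------------
    def apply_hazards_to_cells(self) -> None:
        """Fold accumulated kill hazards into the agents' log-survival."""
        if self.cell_idx.size:
            self.cells.log_survival[self.cell_idx] -= self.state.hazard
            self.state.hazard = np.zeros(self.cell_idx.size)


def fields_frame(solver: FineGridTransport):
    """Per-site field export: x, y, z (um), site state, per-solute C_e and
    (for occupied sites) C_i — the CSV counterpart of a VTK image dump."""
    import pandas as pd
    grid = solver.grid
    ijk = grid.unravel(np.arange(grid.n_sites))
    xyz = (ijk + 0.5) * grid.dx
    data = {"x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
            "site_state": np.where(solver.occ, "cell", "medium")}
    for name, arr in solver.state.C_e.items():
        data[f"C_e_{name}_uM"] = arr
    for name, arr in solver.state.C_i.items():
        col = np.full(grid.n_sites, np.nan)
        col[solver.cell_sites] = arr
        data[f"C_i_{name}_uM"] = col
    return pd.DataFrame(data)


def step_fine_grid(solver: FineGridTransport, dt: float) -> TransportState:
    """Advance the fine-grid solver one step (see FineGridTransport.step)."""
    return solver.step(dt)


def couple_medium(solver: FineGridTransport, geometry: CultureGeometry,
                  dt: float, gas_O2: float | None = None) -> TransportState:
    """Advance the coupled fine-grid + medium-column system one step."""
    if solver.geometry is None or geometry.kind != "spheroid":
        raise ValueError("couple_medium requires a spheroid geometry with a column")
    return solver.step(dt, gas_O2=gas_O2)


# ----------------------------------------------------------------------
# quasi-steady radial oxygen
def radial_o2_profile(r_centers: np.ndarray, dr: float,
                      cell_counts: np.ndarray, occ_frac: np.ndarray,
                      D_tissue: float, D_medium: float,
                      Vmax: float, Km: float, C_boundary: float,
                      C_init: np.ndarray | None = None,
                      max_iter: int = 60, tol: float = 1e-8):
    """Steady-state radial O2 profile with Michaelis-Menten consumption.

    ``cell_counts[i]`` cells live in the spherical shell centred at
    ``r_centers[i]`` of width ``dr``; consumption is treated as a continuum
    sink over the shell volume.  Returns ``(C, Q)`` where C is the profile
    (uM) and Q the total consumption (uM um^3 / s).
    """
    n = r_centers.size
    V_shell = 4.0 / 3.0 * np.pi * (
        (r_centers + dr / 2) ** 3 - np.clip(r_centers - dr / 2, 0, None) ** 3)
    amax = cell_counts * Vmax * MOL_PER_S_TO_UM3_UM / V_shell  # uM/s at C>>Km
    D = D_tissue * occ_frac + D_medium * (1.0 - occ_frac)
    r_face = r_centers + dr / 2
    D_face = np.empty(n)
    D_face[:-1] = 0.5 * (D[:-1] + D[1:])
    D_face[-1] = D[-1]
    g_out = r_face ** 2 * D_face / dr          # conductance to next shell
    C = np.full(n, C_boundary) if C_init is None else C_init.copy()
    C = np.clip(C, 0.0, None)
    for _ in range(max_iter):
        k_lin = amax / (Km + C)
        lower = np.zeros(n)
        diag = np.zeros(n)
        upper = np.zeros(n)
        rhs = np.zeros(n)
        for i in range(n):
            acc = 0.0
            if i > 0:
                w = g_out[i - 1] / (r_centers[i] ** 2 * dr)
                lower[i] = -w
                acc += w
            if i < n - 1:
                w = g_out[i] / (r_centers[i] ** 2 * dr)
                upper[i] = -w
                acc += w
            else:
                w = g_out[i] / (r_centers[i] ** 2 * dr)
                acc += w
                rhs[i] += w * C_boundary
            diag[i] = acc + k_lin[i]
        ab = np.zeros((3, n))
        ab[0, 1:] = upper[:-1]
        ab[1, :] = diag
        ab[2, :-1] = lower[1:]
        C_new = solve_banded((1, 1), ab, rhs)
        C_new = np.clip(C_new, 0.0, None)
        if np.max(np.abs(C_new - C)) < tol * (1.0 + C_boundary):
            C = C_new
            break
        C = C_new
    uptake = amax * C / (Km + C)  # uM/s per shell volume
    Q = float(uptake @ V_shell)
    return C, Q


class TransientRadialO2:
    """Transient radial O2 around a consuming spheroid in unstirred medium.

    Semi-implicit integration (backward-Euler diffusion with Michaelis-Menten
    uptake linearised about the current state) of the spherically symmetric
    O2 field, starting from the well-mixed bolus value.  The early-time
    boundary layer this resolves is what sets the "initial" surface O2 after
    an oxygenated drug bolus — a developed-layer quasi-steady solve
    overstates the depletion.
    """

    def __init__(self, r_centers: np.ndarray, dr: float,
                 cell_counts: np.ndarray, occ_frac: np.ndarray,
                 D_tissue: float, D_medium: float, Vmax: float, Km: float,
                 C0: float):
        n = r_centers.size
        self.r = r_centers
        self.dr = dr
        self.Km = Km
        V_shell = 4.0 / 3.0 * np.pi * (
            (r_centers + dr / 2) ** 3
            - np.clip(r_centers - dr / 2, 0, None) ** 3)
        self.V_shell = V_shell
        self.amax = cell_counts * Vmax * MOL_PER_S_TO_UM3_UM / V_shell
        D = D_tissue * occ_frac + D_medium * (1.0 - occ_frac)
        rf = r_centers + dr / 2
        Df = np.empty(n)
        Df[:-1] = 0.5 * (D[:-1] + D[1:])
        Df[-1] = D[-1]
        g_out = rf ** 2 * Df / dr
        self._lower = np.zeros(n)
        self._upper = np.zeros(n)
        base = np.zeros(n)
        for i in range(n):
            if i > 0:
                w = g_out[i - 1] / (r_centers[i] ** 2 * dr)
                self._lower[i] = -w
                base[i] += w
            w = g_out[i] / (r_centers[i] ** 2 * dr)
            if i < n - 1:
                self._upper[i] = -w
            base[i] += w
        self._base = base
        self._g_bc = g_out[-1] / (r_centers[-1] ** 2 * dr)
        self.C = np.full(n, C0)

    def advance(self, dt_interval: float, C_boundary: float,
                dt_sub: float = 0.1) -> float:
        """Advance by ``dt_interval`` (s); returns consumed amount
        (uM um^3) for reservoir bookkeeping."""
        n = self.C.size
        ab = np.zeros((3, n))
        consumed = 0.0
        t = 0.0
        while t < dt_interval - 1e-9:
            h = min(dt_sub, dt_interval - t)
            k_lin = self.amax / (self.Km + self.C)
            ab[0, 1:] = self._upper[:-1]
            ab[1, :] = 1.0 / h + self._base + k_lin
            ab[2, :-1] = self._lower[1:]
            rhs = self.C / h
            rhs[-1] += self._g_bc * C_boundary
            self.C = np.clip(solve_banded((1, 1), ab, rhs), 0.0, None)
            consumed += float((k_lin * self.C * self.V_shell).sum()) * h
            t += h
        return consumed


def o2_boundary_from_column(gas_O2: float, Q: float, depth: float,
                            D_medium: float, area: float) -> float:
    """Quasi-steady O2 at the bottom of an unstirred medium column.

    A consumption flux Q (uM um^3/s) drawn from the bottom of a column of
    given depth with the gas-phase value held at the top gives a linear
    profile; the bottom value is clipped at zero when consumption exceeds
    what the column can deliver.
    """
    drop = Q * depth / (D_medium * area)
    return max(gas_O2 - drop, 0.0)


# ----------------------------------------------------------------------
# 1D monolayer model
@dataclass
class MonolayerResult:
    t: np.ndarray                      # s
    depth: np.ndarray                  # um, node centres (0 = cell layer)
    C_medium: dict[str, np.ndarray]    # (nt, nz)
    C_i: dict[str, np.ndarray]         # (nt, n_lineages)
    O2_medium: np.ndarray | None       # (nt, nz)
    hazard: np.ndarray                 # (nt, n_lineages)
    lineages: list[str]

    def survival(self, lineage: str) -> float:
        return float(np.exp(-self.hazard[-1, self.lineages.index(lineage)]))


def simulate_monolayer(model: ProdrugModel, lineage_counts: dict[str, int],
                       geometry: CultureGeometry, drug_conc: float,
                       duration: float, o2_bolus: float = 0.0,
                       gas_O2: float = 0.0, o2_params: dict | None = None,
                       cell_volume: float = 2500.0, n_nodes: int = 24,
                       settings: SolverSettings | None = None,
                       rtol: float | None = None) -> MonolayerResult:
    """Simulate a drug exposure of an anoxic monolayer culture.

    The medium is a 1D unstirred column of ``n_nodes`` slabs; all cells sit
    in the bottom slab, one intracellular compartment per lineage.  Kill
    hazards accumulate per lineage (all cells of a lineage share the same
    exposure history, so the lineage SF is exp(-hazard)).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    settings = settings or SolverSettings()
    lineages = list(lineage_counts)
    n_lin = len(lineages)
    total_cells = sum(lineage_counts.values())
    if total_cells == 0 and any(k.mode == "metabolism_rate"
                                for k in model.kill_models):
        import warnings
        warnings.warn("zero cell density with a metabolism-rate kill model: "
                      "no killing is possible")

    A = geometry.well_area
    depth = geometry.medium_depth
    dz = depth / n_nodes
    V_node = A * dz
    z = (np.arange(n_nodes) + 0.5) * dz
    V_cells = np.array([lineage_counts[l] * cell_volume for l in lineages])

    solutes = list(model.solutes)
    names = [s.name for s in solutes]
    prodrug = names[0]
    spec = {s.name: s for s in solutes}
    track_o2 = o2_bolus > 0 or gas_O2 > 0
    o2p = o2_params or {}
    Vmax = o2p.get("Vmax", 6e-17)
    Km = o2p.get("Km", 1.3)
    D_O2 = o2p.get("D_medium", 2000.0)
    K_O2 = (next(iter(model.metabolism.values())).K_O2
            if model.metabolism else 1.0)
    kmet0 = np.array([model.metabolism.get(l, None).K_met0
                      if l in model.metabolism else 0.0 for l in lineages])

    ns = len(names)
    n_med = ns * n_nodes
    n_int = ns * n_lin
    # state: [medium fields, intracellular per lineage, O2 nodes?, hazards]
    n_o2 = n_nodes if track_o2 else 0

    def unpack(y):
        med = y[:n_med].reshape(ns, n_nodes)
        ci = y[n_med:n_med + n_int].reshape(ns, n_lin)
        o2 = y[n_med + n_int:n_med + n_int + n_o2]
        return med, ci, o2

    def rhs(t, y):
        med, ci, o2 = unpack(y)
        dmed = np.zeros_like(med)
        dci = np.zeros_like(ci)
        dh = np.zeros(n_lin)
        O2_cells = o2[0] if track_o2 else 0.0
        kmet = kmet0 * K_O2 / (K_O2 + O2_cells)
        mrate = kmet * ci[names.index(prodrug)]
        for k, n in enumerate(names):
            s = spec[n]
            D = s.D_medium
            C = med[k]
            lap = np.zeros(n_nodes)
            lap[1:-1] = (C[2:] - 2 * C[1:-1] + C[:-2])
            lap[0] = (C[1] - C[0])
            lap[-1] = (C[-2] - C[-1])
            dmed[k] += D / dz ** 2 * lap
            dmed[k] -= s.k_decay_medium * C
            # membrane exchange with bottom node
            ex = s.K_in * C[0] - s.K_out * ci[k]      # per lineage
            dci[k] += ex
            dmed[k][0] -= (ex @ V_cells) / V_node
            dci[k] -= s.k_loss_cell * ci[k]
            if s.k_chain or s.k_chain_medium:
                j = names.index(s.child) if s.child in names else None
                if j is not None:
                    dci[j] += s.k_chain * ci[k]
                    dmed[j] += s.k_chain_medium * med[k]
                dci[k] -= s.k_chain * ci[k]
                dmed[k] -= s.k_chain_medium * med[k]
        ip = names.index(prodrug)
        dci[ip] -= mrate
        if model.met_target is not None:
            dci[names.index(model.met_target)] += mrate
        for km in model.kill_models:
            if km.mode == "metabolism_rate":
                dh += km.K_c * mrate
            else:
                dh += km.K_c * ci[names.index(km.acts_on)]
        do2 = np.zeros(n_o2)
        if track_o2:
            lap = np.zeros(n_nodes)
            lap[1:-1] = o2[2:] - 2 * o2[1:-1] + o2[:-2]
            lap[0] = o2[1] - o2[0]
            lap[-1] = o2[-2] - o2[-1]
            do2 = D_O2 / dz ** 2 * lap
            # gas interface at half spacing above the top node
            do2[-1] += 2.0 * D_O2 / dz ** 2 * (gas_O2 - o2[-1])
            cons = total_cells * michaelis_menten_O2_rate(
                max(o2[0], 0.0), Vmax, Km) * MOL_PER_S_TO_UM3_UM / V_node
            do2[0] -= cons
        return np.concatenate([dmed.ravel(), dci.ravel(), do2, dh])

    y0 = np.zeros(n_med + n_int + n_o2 + n_lin)
    med0 = np.zeros((ns, n_nodes))
    med0[0] = drug_conc
    y0[:n_med] = med0.ravel()
    if track_o2:
        y0[n_med + n_int:n_med + n_int + n_o2] = o2_bolus
    t_eval = np.linspace(0.0, duration, 25)
    sol = solve_ivp(rhs, (0.0, duration), y0, method="LSODA",
                    rtol=rtol or settings.rtol, atol=settings.atol,
                    t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"monolayer ODE solver failed: {sol.message}")
    nt = sol.t.size
    med = sol.y[:n_med].T.reshape(nt, ns, n_nodes)
    ci = sol.y[n_med:n_med + n_int].T.reshape(nt, ns, n_lin)
    o2 = (sol.y[n_med + n_int:n_med + n_int + n_o2].T
          if track_o2 else None)
    hz = sol.y[-n_lin:].T
    return MonolayerResult(
        t=sol.t, depth=z,
        C_medium={n: med[:, k, :] for k, n in enumerate(names)},
        C_i={n: ci[:, k, :] for k, n in enumerate(names)},
        O2_medium=o2, hazard=hz, lineages=lineages)


# ----------------------------------------------------------------------
# MCL two-compartment diffusion model
@dataclass
class MCLResult:
    t: np.ndarray                       # s
    donor: dict[str, np.ndarray]        # uM
    receiver: dict[str, np.ndarray]     # uM
    slab: dict[str, np.ndarray]         # (nt, nz) extracellular
    donor_amount: dict[str, np.ndarray]    # umol
    receiver_amount: dict[str, np.ndarray]
    donor_volume: np.ndarray            # um^3 over time (sampling depletion)
    receiver_volume: np.ndarray
    total_amount: dict[str, np.ndarray] = field(default_factory=dict)  # umol

    def receiver_normalized(self, solute: str, C0: float) -> np.ndarray:
        return self.receiver[solute] / C0

    def receiver_auc(self, solute: str, C0: float) -> float:
        return float(np.trapezoid(self.receiver_normalized(solute, C0), self.t))


def simulate_mcl(model: ProdrugModel, activator_fraction: float,
                 activator: str, target: str, geometry: CultureGeometry,
                 donor_bolus: float, duration: float,
                 acellular: bool = False, n_nodes: int = 20,
                 cell_volume: float = 2500.0,
                 settings: SolverSettings | None = None,
                 sample_times: np.ndarray | None = None,
                 sample_volume: float = 0.0,
                 n_times: int = 61) -> MCLResult:
    """Simulate drug + metabolite diffusion through an anoxic MCL.

    The multicellular layer is a 1D slab (cell volume fraction 0.5, mixed
    activator/target populations per node) between well-stirred donor and
    receiver compartments.  The chamber is anoxic, so prodrug metabolism
    runs at its anoxic maximum.  Optional ``sample_times``/``sample_volume``
    apply the per-draw depletion of compartment volumes.
    """
    if not 0.0 <= activator_fraction <= 1.0:
        raise ValueError("activator fraction must be in [0, 1]")
    settings = settings or SolverSettings()
    L = geometry.mcl_thickness
    A = geometry.mcl_area
    dz = L / n_nodes
    V_node = A * dz
    frac_cell = 0.0 if acellular else 0.5
    V_e_node = V_node * (1.0 - frac_cell)
    n_cells_node = V_node * frac_cell / cell_volume
    n_act = n_cells_node * activator_fraction
    n_tgt = n_cells_node * (1.0 - activator_fraction)

    solutes = list(model.solutes)
    names = [s.name for s in solutes]
    spec = {s.name: s for s in solutes}
    prodrug = names[0]
    ns = len(names)
    kmet_a = model.metabolism[activator].K_met0 if activator in model.metabolism else 0.0
    kmet_t = model.metabolism[target].K_met0 if target in model.metabolism else 0.0

    # state: per solute: donor, receiver, slab extracellular (nz),
    # activator intracellular (nz), target intracellular (nz)
    per_sol = 2 + 3 * n_nodes

    def unpack(y):
        return y.reshape(ns, per_sol)

    def make_rhs(V_donor, V_receiver):
        def rhs(t, y):
            Y = unpack(y)
            dY = np.zeros_like(Y)
            mrate_a = kmet_a * Y[0, 2 + n_nodes:2 + 2 * n_nodes]
            mrate_t = kmet_t * Y[0, 2 + 2 * n_nodes:]
            for k, n in enumerate(names):
                s = spec[n]
                don, rec = Y[k, 0], Y[k, 1]
                Ce = Y[k, 2:2 + n_nodes]
                Ca = Y[k, 2 + n_nodes:2 + 2 * n_nodes]
                Ct = Y[k, 2 + 2 * n_nodes:]
                D = s.D_tissue  # slab-region diffusivity
                flux = np.zeros(n_nodes)  # net in, uM/s on V_e_node
                g = D * A / dz
                # internal faces
                J = g * (Ce[:-1] - Ce[1:])
                flux[:-1] -= J / V_e_node
                flux[1:] += J / V_e_node
                # compartment faces (half-spacing)
                g_half = D * A / (dz / 2)
                J_d = g_half * (don - Ce[0])
                J_r = g_half * (Ce[-1] - rec)
                flux[0] += J_d / V_e_node
                flux[-1] -= J_r / V_e_node
                dY[k, 0] += -J_d / V_donor - s.k_decay_medium * don
                dY[k, 1] += J_r / V_receiver - s.k_decay_medium * rec
                dY[k, 2:2 + n_nodes] += flux - s.k_decay_medium * Ce
                # membrane exchange
                for (Ci, nc, sl) in ((Ca, n_act, slice(2 + n_nodes, 2 + 2 * n_nodes)),
                                     (Ct, n_tgt, slice(2 + 2 * n_nodes, per_sol))):
                    ex = s.K_in * Ce - s.K_out * Ci
                    dY[k, sl] += ex - s.k_loss_cell * Ci
                    if nc > 0:
                        dY[k, 2:2 + n_nodes] -= ex * (nc * cell_volume / V_e_node)
                if s.k_chain or s.k_chain_medium:
                    j = names.index(s.child) if s.child in names else None
                    rates = np.empty(per_sol)
                    rates[:2 + n_nodes] = s.k_chain_medium
                    rates[2 + n_nodes:] = s.k_chain
                    dY[k] -= rates * Y[k]
                    if j is not None:
                        dY[j] += rates * Y[k]
            ip = names.index(prodrug)
            dY[ip, 2 + n_nodes:2 + 2 * n_nodes] -= mrate_a
            dY[ip, 2 + 2 * n_nodes:] -= mrate_t
            if model.met_target is not None:
                im = names.index(model.met_target)
                dY[im, 2 + n_nodes:2 + 2 * n_nodes] += mrate_a
                dY[im, 2 + 2 * n_nodes:] += mrate_t
            return dY.ravel()
        return rhs

    y0 = np.zeros(ns * per_sol)
    Y0 = unpack(y0)
    Y0[0, 0] = donor_bolus

    seg_bounds = [0.0]
    if sample_times is not None and sample_volume > 0:
        seg_bounds.extend(float(ts) for ts in sample_times if 0 < ts < duration)
    seg_bounds.append(duration)
    V_d, V_r = geometry.donor_volume, geometry.receiver_volume
    all_t, all_y, all_vd, all_vr = [], [], [], []
    y = y0
    for a, b in zip(seg_bounds[:-1], seg_bounds[1:]):
        t_eval = np.linspace(a, b, max(2, int(np.ceil((b - a) / duration * n_times))))
        sol = solve_ivp(make_rhs(V_d, V_r), (a, b), y, method="LSODA",
                        rtol=settings.rtol, atol=settings.atol, t_eval=t_eval)
        if not sol.success:
            raise RuntimeError(f"MCL ODE solver failed: {sol.message}")
        all_t.append(sol.t)
        all_y.append(sol.y.T)
        all_vd.append(np.full(sol.t.size, V_d))
        all_vr.append(np.full(sol.t.size, V_r))
        y = sol.y[:, -1]
        is_sample = (sample_times is not None and sample_volume > 0
                     and bool(np.any(np.isclose(sample_times, b))))
        if is_sample:
            V_d = max(V_d - sample_volume, 0.1 * geometry.donor_volume)
            V_r = max(V_r - sample_volume, 0.1 * geometry.receiver_volume)
            all_vd[-1][-1] = V_d  # final point reports the post-draw volume
            all_vr[-1][-1] = V_r

    t = np.concatenate(all_t)
    Yt = np.concatenate(all_y, axis=0)  # (nt, ns*per_sol)
    Vd_t = np.concatenate(all_vd)
    Vr_t = np.concatenate(all_vr)
    Yt = Yt.reshape(t.size, ns, per_sol)
    donor = {n: Yt[:, k, 0] for k, n in enumerate(names)}
    receiver = {n: Yt[:, k, 1] for k, n in enumerate(names)}
    slab = {n: Yt[:, k, 2:2 + n_nodes] for k, n in enumerate(names)}
    total = {}
    for k, n in enumerate(names):
        Ca = Yt[:, k, 2 + n_nodes:2 + 2 * n_nodes]
        Ct = Yt[:, k, 2 + 2 * n_nodes:]
        total[n] = (donor[n] * Vd_t + receiver[n] * Vr_t
                    + slab[n].sum(axis=1) * V_e_node
                    + (Ca.sum(axis=1) * n_act + Ct.sum(axis=1) * n_tgt)
                    * cell_volume) * UM3_UM_TO_UMOL
    return MCLResult(
        t=t, donor=donor, receiver=receiver, slab=slab,
        donor_amount={n: donor[n] * Vd_t * UM3_UM_TO_UMOL for n in names},
        receiver_amount={n: receiver[n] * Vr_t * UM3_UM_TO_UMOL for n in names},
        donor_volume=Vd_t, receiver_volume=Vr_t, total_amount=total)
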
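"""Domain types: solutes, cell lines, kill models, the 3D lattice and culture
geometries.

Conventions
-----------
* Internal units are uM, um, s (see :mod:`hapabm.units`).
* The lattice is cubic with 0-based integer site indices; site centres sit at
  ``(i + 1/2) * dx`` and the spheroid centre at the grid centre.  A cubic site
  has twice the volume of an average cell, so occupied sites are half
  intracellular and half extracellular (cell volume fraction 0.5).
* Transport uses the 6-face-neighbour stencil; division may place daughters in
  any of the 26 surrounding sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

VACANT = -1

#: States a lattice cell can be in.  Transitions are one-way:
#: viable -> death_tagged -> necrotic.
STATE_VIABLE = 0
STATE_DEATH_TAGGED = 1
STATE_NECROTIC = 2
STATE_NAMES = {STATE_VIABLE: "viable", STATE_DEATH_TAGGED: "death_tagged",
               STATE_NECROTIC: "necrotic"}


@dataclass(frozen=True)
class SoluteSpec:
    """One diffusible (or purely intracellular) chemical species.

    Parameters
    ----------
    name:
        Identifier, e.g. ``"SN30000"`` or ``"M2"``.
    D_medium, D_tissue:
        Diffusivities in bulk medium and inside tissue (um^2/s).
    K_in, K_out:
        First-order membrane exchange rate constants (s^-1) acting on the
        intracellular concentration: dC_i/dt = K_in*C_e - K_out*C_i.
    k_decay_medium:
        First-order loss in cell-free medium (s^-1), e.g. chemical
        instability, excluding conversion to the tracked child solute.
    k_loss_cell:
        First-order intracellular loss other than tracked metabolism (s^-1).
    k_chain:
        First-order intracellular chemical conversion to ``child`` (s^-1).
    k_chain_medium:
        Conversion rate in cell-free medium (s^-1); ``None`` means equal to
        ``k_chain``.  Distinct values capture the nucleophile-rich cytosol
        converting the mustards much faster than culture medium does.
    child:
        Name of the next solute in the metabolic chain, or ``None``.
    diffusible:
        ``False`` for species confined to the cell of origin (K_in = K_out =
        0 is then required), e.g. a short-lived radical.
    """

    name: str
    D_medium: float = 0.0
    D_tissue: float = 0.0
    K_in: float = 0.0
    K_out: float = 0.0
    k_decay_medium: float = 0.0
    k_loss_cell: float = 0.0
    k_chain: float = 0.0
    k_chain_medium: float | None = None
    child: str | None = None
    diffusible: bool = True

    def __post_init__(self) -> None:
        for attr in ("D_medium", "D_tissue", "K_in", "K_out",
                     "k_decay_medium", "k_loss_cell", "k_chain"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{self.name}: {attr} must be >= 0")
        if self.k_chain_medium is None:
            object.__setattr__(self, "k_chain_medium", self.k_chain)
        elif self.k_chain_medium < 0:
            raise ValueError(f"{self.name}: k_chain_medium must be >= 0")
        if self.D_tissue > self.D_medium:
            raise ValueError(f"{self.name}: D_tissue must be <= D_medium")
        if not self.diffusible and (self.K_in != 0 or self.K_out != 0):
            raise ValueError(
                f"{self.name}: non-diffusing solute must have K_in = K_out = 0")


@dataclass(frozen=True)
class MetabolismSpec:
    """Oxygen-dependent first-order prodrug metabolism for one cell line.

    The rate constant follows the saturation form
    ``K_met(O2) = K_met0 * K_O2 / (K_O2 + O2)`` so that metabolism equals its
    anoxic maximum ``K_met0`` at O2 = 0 and is half-inhibited at O2 = K_O2.
    """

    K_met0: float  # s^-1 (anoxic)
    K_O2: float    # uM, half-maximal inhibition
    cell_line: str = ""

    def __post_init__(self) -> None:
        if self.K_met0 < 0:
            raise ValueError("K_met0 must be >= 0")
        if self.K_O2 <= 0:
            raise ValueError("K_O2 must be > 0")


@dataclass(frozen=True)
class KillModel:
    """Pharmacodynamic rule mapping exposure to a kill hazard.

    ``metabolism_rate`` mode: hazard rate = K_c * M' with M' = K_met * C_i
    (the cell kills itself through the transient radical it generates; no
    bystander killing is possible).  ``concentration`` mode: hazard rate =
    K_c * C_i of the cytotoxin, regardless of which cell generated it.
    K_c is stored in internal units (uM^-1 for metabolism_rate, uM^-1 s^-1
    for concentration).
    """

    mode: Literal["metabolism_rate", "concentration"]
    K_c: float
    acts_on: str

    def __post_init__(self) -> None:
        if self.mode not in ("metabolism_rate", "concentration"):
            raise ValueError(f"unknown kill-model mode {self.mode!r}")
        if self.K_c < 0:
            raise ValueError("K_c must be >= 0")


@dataclass(frozen=True)
class CellLineSpec:
    """One cell line: growth rate, role, and per-prodrug metabolism."""

    name: str
    role: Literal["activator", "target"]
    doubling_time: float  # s
    metabolism: dict[str, MetabolismSpec] = field(default_factory=dict)
    marker: str = ""

    def __post_init__(self) -> None:
        if self.doubling_time <= 0:
            raise ValueError("doubling_time must be > 0")

    def kmet0(self, solute: str) -> float:
        spec = self.metabolism.get(solute)
        return 0.0 if spec is None else spec.K_met0


@dataclass
class CultureGeometry:
    """Well / medium / lattice description for one culture configuration.

    All volumes are um^3 internally, lengths um, areas um^2.
    """

    kind: Literal["spheroid", "monolayer", "mcl"]
    medium_volume: float = 0.2e12       # 0.2 mL
    well_area: float = 0.328e8          # 32.8 mm^2 (0.2 mL / 6.1 mm)
    gas_O2: float = 0.0                 # uM at the medium-air interface
    initial_O2: float = 0.0             # uM, uniform at t = 0
    donor_volume: float = 8.5e12        # mL -> um^3 (mcl only)
    receiver_volume: float = 8.5e12
    mcl_thickness: float = 150.0        # um
    mcl_area: float = 0.3e8             # 0.3 cm^2

    def __post_init__(self) -> None:
        if self.medium_volume <= 0 or self.well_area <= 0:
            raise ValueError("volumes and areas must be > 0")

    @property
    def medium_depth(self) -> float:
        """Depth (um) consistent with volume and area."""
        return self.medium_volume / self.well_area


class LatticeGrid:
    """Regular cubic 3D lattice holding cell occupancy.

    The volume of a site is twice the mean cell volume, so a site containing
    a cell is half extracellular.  ``occupancy`` maps flat site index to a
    cell index (``VACANT`` if empty).
    """

    def __init__(self, dx: float, dims: tuple[int, int, int]):
        self.dx = float(dx)
        self.dims = tuple(int(d) for d in dims)
        self.occupancy = np.full(self.n_sites, VACANT, dtype=np.int64)

    @property
    def n_sites(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    @property
    def site_volume(self) -> float:
        return self.dx ** 3

    @property
    def center(self) -> np.ndarray:
        """Grid centre in site-index coordinates (may be half-integer)."""
        return (np.asarray(self.dims, dtype=float) - 1.0) / 2.0

    # -- index arithmetic ---------------------------------------------------
    def ravel(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk)
        return np.ravel_multi_index(tuple(ijk.T) if ijk.ndim == 2 else tuple(ijk),
                                    self.dims)

    def unravel(self, flat: np.ndarray) -> np.ndarray:
        return np.stack(np.unravel_index(flat, self.dims), axis=-1)

    def radii(self, flat: np.ndarray | None = None) -> np.ndarray:
        """Distance (um) of site centres from the grid centre."""
        if flat is None:
            flat = np.arange(self.n_sites)
        ijk = self.unravel(np.asarray(flat))
        return np.linalg.norm((ijk - self.center) * self.dx, axis=-1)

    def in_grid(self, ijk) -> bool:
        return all(0 <= ijk[a] < self.dims[a] for a in range(3))

    def n_occupied(self) -> int:
        return int(np.count_nonzero(self.occupancy != VACANT))


def build_lattice(mean_cell_volume: float, max_radius: float) -> LatticeGrid:
    """Construct a lattice whose cubic sites have twice the mean cell volume.

    The grid is sized to contain a sphere of ``max_radius`` (um) around its
    centre plus one vacant boundary shell.

    >>> grid = build_lattice(2500.0, 0.0)
    >>> round(grid.dx, 1)
    17.1
    """
    if mean_cell_volume <= 0:
        raise ValueError("mean_cell_volume must be > 0")
    if max_radius < 0:
        raise ValueError("max_radius must be >= 0")
    dx = (2.0 * mean_cell_volume) ** (1.0 / 3.0)
    n_half = int(np.ceil(max_radius / dx))
    n = 2 * n_half + 1 + 2  # sphere + one-site vacant shell each side
    return LatticeGrid(dx, (n, n, n))


# 6 face neighbours (transport stencil) and 26 surrounding sites (division).
FACE_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64)
MOORE_OFFSETS = np.array(
    [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
     if (i, j, k) != (0, 0, 0)], dtype=np.int64)


def neighbors(grid: LatticeGrid, site, connectivity: int = 6) -> list[tuple[int, int, int]]:
    """Face-adjacent (6) or surrounding (26) sites, clipped at boundaries."""
    site = tuple(int(s) for s in site)
    if not grid.in_grid(site):
        raise ValueError(f"site {site} outside grid of dims {grid.dims}")
    offsets = FACE_OFFSETS if connectivity == 6 else MOORE_OFFSETS
    out = []
    for off in offsets:
        cand = (site[0] + off[0], site[1] + off[1], site[2] + off[2])
        if grid.in_grid(cand):
            out.append(cand)
    return out


class CellPopulation:
    """Struct-of-arrays container for all lattice cells (the agents).

    Each agent carries its lattice site, cell line, volume, per-solute
    intracellular concentrations, a severe-hypoxia clock, accumulated
    log-survival (the integral of its kill hazard, <= 0) and a life state.
    """

    def __init__(self, lines: list[CellLineSpec]):
        self.lines = list(lines)
        self.site = np.empty(0, dtype=np.int64)       # flat site index
        self.line_idx = np.empty(0, dtype=np.int64)
        self.volume = np.empty(0, dtype=float)        # um^3
        self.severe_hypoxia_clock = np.empty(0, dtype=float)  # s
        self.log_survival = np.empty(0, dtype=float)  # ln survival, <= 0
        self.state = np.empty(0, dtype=np.int8)
        self.tag_time = np.empty(0, dtype=float)      # s since death-tagging
        self.C_i: dict[str, np.ndarray] = {}          # per-solute, uM

    def __len__(self) -> int:
        return self.site.size

    @property
    def n_viable(self) -> int:
        return int(np.count_nonzero(self.state == STATE_VIABLE))

    def line_name(self, idx: int) -> str:
        return self.lines[idx].name

    def add_cells(self, sites: np.ndarray, line_idx: np.ndarray,
                  volume: np.ndarray) -> None:
        n = len(sites)
        self.site = np.concatenate([self.site, np.asarray(sites, dtype=np.int64)])
        self.line_idx = np.concatenate([self.line_idx,
                                        np.asarray(line_idx, dtype=np.int64)])
        self.volume = np.concatenate([self.volume, np.asarray(volume, dtype=float)])
        self.severe_hypoxia_clock = np.concatenate(
            [self.severe_hypoxia_clock, np.zeros(n)])
        self.log_survival = np.concatenate([self.log_survival, np.zeros(n)])
        self.state = np.concatenate(
            [self.state, np.full(n, STATE_VIABLE, dtype=np.int8)])
        self.tag_time = np.concatenate([self.tag_time, np.zeros(n)])
        for name, arr in self.C_i.items():
            self.C_i[name] = np.concatenate([arr, np.zeros(n)])

    def ensure_solute(self, name: str) -> np.ndarray:
        if name not in self.C_i:
            self.C_i[name] = np.zeros(len(self))
        return self.C_i[name]

    def lineage_mask(self, lineage: str) -> np.ndarray:
        idx = [i for i, ln in enumerate(self.lines) if ln.name == lineage]
        if not idx:
            raise KeyError(f"unknown lineage {lineage!r}")
        return np.isin(self.line_idx, idx)

    def counts_by_line(self, viable_only: bool = True) -> dict[str, int]:
        mask = (self.state == STATE_VIABLE) if viable_only else np.ones(len(self), bool)
        return {ln.name: int(np.count_nonzero(mask & (self.line_idx == i)))
                for i, ln in enumerate(self.lines)}


class CellAgentView:
    """Read/write view of one agent in a :class:`CellPopulation`."""

    def __init__(self, cells: CellPopulation, idx: int):
        self._c = cells
        self.idx = int(idx)

    @property
    def site(self) -> int:
        return int(self._c.site[self.idx])

    @property
    def line(self) -> CellLineSpec:
        return self._c.lines[self._c.line_idx[self.idx]]

    @property
    def volume(self) -> float:
        return float(self._c.volume[self.idx])

    @property
    def C_i(self) -> dict[str, float]:
        return {n: float(a[self.idx]) for n, a in self._c.C_i.items()}

    @property
    def severe_hypoxia_clock(self) -> float:
        return float(self._c.severe_hypoxia_clock[self.idx])

    @property
    def log_survival(self) -> float:
        return float(self._c.log_survival[self.idx])

    @property
    def state(self) -> str:
        return STATE_NAMES[int(self._c.state[self.idx])]


def check_occupancy(grid: LatticeGrid, cells: CellPopulation) -> None:
    """Bookkeeping invariant: live agents and occupied sites correspond 1:1."""
    live = cells.state != STATE_NECROTIC
    occ_sites = np.flatnonzero(grid.occupancy != VACANT)
    if not np.array_equal(np.sort(cells.site[live]), occ_sites):
        raise AssertionError("lattice occupancy inconsistent with agent sites")
    back = grid.occupancy[cells.site[live]]
    if not np.array_equal(np.sort(back), np.sort(np.flatnonzero(live))):
        raise AssertionError("occupancy back-references inconsistent")
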
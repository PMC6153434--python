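"""Spheroid growth on the lattice: oxygen-dependent volume growth, division
with radial displacement, hypoxia death-tagging and central necrosis.

Cells grow exponentially in volume at ``(ln2 / doubling_time) * volume``
scaled by a Michaelis-Menten function of the local oxygen concentration, and
divide when the volume reaches a preset trigger (twice the birth volume, so
one cell cycle equals one doubling time at full oxygenation).  A daughter
occupies an adjacent vacant site; if none exists the chain of cells along
the most-radial lattice direction is shifted one site outward to create one.
Cells kept below the severe-hypoxia threshold for longer than the tagging
delay are marked for death and become necrotic (their site reverting to
vacant) after the lysis delay.

During growth, oxygen is solved as a quasi-steady radial profile
(consumption is the same for all lines, so the O2 field is close to
spherically symmetric) coupled to a quasi-steady unstirred medium column
with the incubator value at the gas interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .core import (MOORE_OFFSETS, STATE_DEATH_TAGGED, STATE_NECROTIC,
                   STATE_VIABLE, VACANT, CellLineSpec, CellPopulation,
                   LatticeGrid, build_lattice)
from .registry import ParameterRegistry, load_parameter_registry
from .transport import o2_boundary_from_column, radial_o2_profile


def _mm_scaling(halfsat: float) -> Callable[[np.ndarray], np.ndarray]:
    def scaling(O2):
        O2 = np.clip(np.asarray(O2, dtype=float), 0.0, None)
        return O2 / (halfsat + O2)
    return scaling


@dataclass
class GrowthParams:
    """Growth, division and hypoxic-death controls (internal units)."""

    birth_volume: float = 1750.0      # um^3
    divide_volume: float = 3500.0     # um^3, preset division trigger
    o2_scaling: Callable = field(default_factory=lambda: _mm_scaling(1.0))
    hypoxia_threshold: float = 4.0    # uM (reporting)
    severe_hypoxia_threshold: float = 0.15  # uM
    death_tag_delay: float = 24 * 3600.0    # s
    lysis_delay: float = 24 * 3600.0        # s
    hypoxic_death: bool = True

    def __post_init__(self) -> None:
        if self.severe_hypoxia_threshold >= self.hypoxia_threshold:
            raise ValueError("severe threshold must be below hypoxia threshold")
        if self.death_tag_delay < 0 or self.lysis_delay < 0:
            raise ValueError("delays must be >= 0")

    @classmethod
    def from_registry(cls, reg: ParameterRegistry, **overrides) -> "GrowthParams":
        kw = dict(
            birth_volume=float(reg.value("growth.birth_volume")),
            divide_volume=float(reg.value("growth.divide_volume")),
            o2_scaling=_mm_scaling(float(reg.value("growth.O2_halfsat"))),
            hypoxia_threshold=float(reg.value("growth.hypoxia_threshold")),
            severe_hypoxia_threshold=float(
                reg.value("growth.severe_hypoxia_threshold")),
            death_tag_delay=float(reg.value("growth.death_tag_delay")),
            lysis_delay=float(reg.value("growth.lysis_delay")),
        )
        kw.update(overrides)
        return cls(**kw)


def seed_spheroid(n_cells: int, activator_fraction: float,
                  lines: tuple[CellLineSpec, CellLineSpec],
                  seed: int | np.random.Generator,
                  mean_cell_volume: float = 2500.0,
                  max_radius: float | None = None,
                  params: GrowthParams | None = None,
                  volume_jitter: bool = True) -> tuple[LatticeGrid, CellPopulation]:
    """Seed ``n_cells`` in a compact sphere around the grid centre.

    Each cell is independently an activator with probability
    ``activator_fraction`` (lineage index 0 = activator, 1 = target).  With
    ``volume_jitter`` cells start uniformly distributed through the growth
    cycle (asynchronous population); without it every cell starts at the
    birth volume (deterministic division timing).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not 0.0 <= activator_fraction <= 1.0:
        raise ValueError("activator_fraction must be in [0, 1]")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    params = params or GrowthParams()
    if max_radius is None:
        dx = (2.0 * mean_cell_volume) ** (1 / 3)
        max_radius = 1.6 * dx * (3.0 * n_cells / (4.0 * np.pi)) ** (1 / 3) + 2 * dx
    grid = build_lattice(mean_cell_volume, max_radius)
    if n_cells > grid.n_sites:
        raise ValueError("n_cells exceeds grid capacity")
    order = np.argsort(grid.radii(), kind="stable")[:n_cells]
    cells = CellPopulation(list(lines))
    line_idx = (rng.random(n_cells) >= activator_fraction).astype(np.int64)
    if volume_jitter:
        # uniform in cycle age -> volume = birth * 2**u
        vol = params.birth_volume * 2.0 ** rng.random(n_cells)
    else:
        vol = np.full(n_cells, params.birth_volume)
    cells.add_cells(order, line_idx, vol)
    grid.occupancy[order] = np.arange(n_cells)
    return grid, cells


_MOORE_UNIT = MOORE_OFFSETS / np.linalg.norm(MOORE_OFFSETS, axis=1,
                                             keepdims=True)


def _radial_direction(grid: LatticeGrid, site_flat: int,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Outward lattice direction for the division push.

    Sampled among the outward-pointing Moore directions with weights
    concentrated around the radial vector (alignment^2).  A deterministic
    argmax funnels mass along the 26 quantised rays and grows spikes; the
    seeded weighted choice keeps the spheroid round while remaining
    reproducible.
    """
    vec = grid.unravel(np.asarray(site_flat)) - grid.center
    norm = np.linalg.norm(vec)
    if norm == 0:
        return MOORE_OFFSETS[0]
    dots = _MOORE_UNIT @ (vec / norm)
    if rng is None:
        return MOORE_OFFSETS[int(np.argmax(dots))]
    w = np.clip(dots, 0.0, None) ** 2
    tot = w.sum()
    if tot <= 0:
        return MOORE_OFFSETS[int(np.argmax(dots))]
    return MOORE_OFFSETS[int(rng.choice(len(MOORE_OFFSETS), p=w / tot))]


def divide(grid: LatticeGrid, cells: CellPopulation, ci: int,
           rng: np.random.Generator) -> None:
    """Divide cell ``ci``: mother and daughter each get half the volume.

    The daughter takes an adjacent vacancy (random among the 26 surrounding
    sites); if none exists, the chain of cells along the most-radial lattice
    direction is pushed one site outward and the freed site is used.
    """
    site = int(cells.site[ci])
    ijk = grid.unravel(np.asarray(site))
    cand = ijk + MOORE_OFFSETS
    inside = np.all((cand >= 0) & (cand < np.asarray(grid.dims)), axis=1)
    cand = cand[inside]
    flat = grid.ravel(cand)
    vacant = flat[grid.occupancy[flat] == VACANT]
    if vacant.size:
        target = int(rng.choice(vacant))
    else:
        d = _radial_direction(grid, site, rng)
        pos = ijk.copy()
        chain = []
        while True:
            pos = pos + d
            if not grid.in_grid(pos):
                raise RuntimeError(
                    "no path to a vacancy: grid full along the radial push "
                    f"direction from site {tuple(ijk)}")
            f = int(grid.ravel(pos))
            if grid.occupancy[f] == VACANT:
                break
            chain.append(f)
        # shift the chain outward one site, starting from the outermost
        prev_vacant = int(grid.ravel(pos))
        for f in reversed(chain):
            mover = grid.occupancy[f]
            grid.occupancy[prev_vacant] = mover
            cells.site[mover] = prev_vacant
            grid.occupancy[f] = VACANT
            prev_vacant = f
        target = prev_vacant
    half = cells.volume[ci] / 2.0
    cells.volume[ci] = half
    cells.add_cells(np.array([target]), np.array([cells.line_idx[ci]]),
                    np.array([half]))
    new_idx = len(cells) - 1
    grid.occupancy[target] = new_idx


def grow_step(grid: LatticeGrid, cells: CellPopulation, O2_cell: np.ndarray,
              params: GrowthParams, dt: float,
              rng: np.random.Generator) -> None:
    """Advance growth, division and hypoxic death by ``dt`` (s, <= 1 h)."""
    if dt > 3600.0 + 1e-9:
        raise ValueError("grow_step requires dt <= 1 h")
    viable = cells.state == STATE_VIABLE
    scale = params.o2_scaling(O2_cell)
    td = np.array([ln.doubling_time for ln in cells.lines])[cells.line_idx]
    growth = np.exp(np.log(2.0) / td * scale * dt)
    cells.volume[viable] *= growth[viable]

    # severe-hypoxia clock and death tagging
    if params.hypoxic_death:
        severe = O2_cell < params.severe_hypoxia_threshold
        cells.severe_hypoxia_clock[viable & severe] += dt
        cells.severe_hypoxia_clock[viable & ~severe] = 0.0
        to_tag = viable & (cells.severe_hypoxia_clock > params.death_tag_delay)
        cells.state[to_tag] = STATE_DEATH_TAGGED
        tagged = cells.state == STATE_DEATH_TAGGED
        cells.tag_time[tagged] += dt
        to_lyse = tagged & (cells.tag_time > params.lysis_delay)
        if np.any(to_lyse):
            grid.occupancy[cells.site[to_lyse]] = VACANT
            cells.state[to_lyse] = STATE_NECROTIC

    # division (deterministic volume trigger, with float-safe tolerance)
    ready = np.flatnonzero((cells.state == STATE_VIABLE)
                           & (cells.volume >= params.divide_volume * (1 - 1e-9)))
    for ci in ready:
        divide(grid, cells, int(ci), rng)


@dataclass
class GrowthResult:
    grid: LatticeGrid
    cells: CellPopulation
    diameter: float                     # um, equivalent sphere
    counts: dict[str, int]              # viable per lineage
    o2_profile: np.ndarray | None = None
    o2_radii: np.ndarray | None = None
    hypoxic_fraction: float = 0.0


def equivalent_diameter(grid: LatticeGrid) -> float:
    """Equivalent-sphere diameter from occupied lattice volume."""
    return (6.0 * grid.n_occupied() * grid.site_volume / np.pi) ** (1.0 / 3.0)


def _cell_o2(grid: LatticeGrid, cells: CellPopulation, reg: ParameterRegistry,
             gas_O2: float, medium_depth: float, well_area: float,
             prev: np.ndarray | None = None):
    """Quasi-steady radial O2 profile and per-cell O2 assignment."""
    dx = grid.dx
    live = cells.state != STATE_NECROTIC
    r_cells = grid.radii(cells.site)
    r_max = max(r_cells[live].max() if live.any() else 0.0, dx) + 3 * dx
    n_shell = int(np.ceil(r_max / dx))
    r_centers = (np.arange(n_shell) + 0.5) * dx
    shell_of = np.clip((r_cells / dx).astype(int), 0, n_shell - 1)
    counts = np.bincount(shell_of[live], minlength=n_shell).astype(float)
    V_shell = 4 / 3 * np.pi * ((r_centers + dx / 2) ** 3
                               - np.clip(r_centers - dx / 2, 0, None) ** 3)
    occ_frac = np.clip(counts * grid.site_volume / V_shell, 0.0, 1.0)
    D_t = float(reg.value("solute.O2.D_tissue"))
    D_m = float(reg.value("solute.O2.D_medium"))
    Vmax = float(reg.value("O2.Vmax"))
    Km = float(reg.value("O2.Km"))
    C_b = gas_O2
    C = prev
    if C is not None and C.size != n_shell:  # spheroid grew since last solve
        C = np.concatenate([C, np.full(max(n_shell - C.size, 0), C[-1])])[:n_shell]
    # couple the radial profile to the quasi-steady medium column
    for _ in range(8):
        C, Q = radial_o2_profile(r_centers, dx, counts, occ_frac,
                                 D_t, D_m, Vmax, Km, C_b, C_init=C)
        C_b_new = o2_boundary_from_column(gas_O2, Q, medium_depth, D_m, well_area)
        if abs(C_b_new - C_b) < 1e-3 * (1 + gas_O2):
            C_b = C_b_new
            break
        C_b = 0.5 * (C_b + C_b_new)
    O2_cell = C[shell_of]
    return O2_cell, C, r_centers


def grow_to_day(n_days: float, n_cells: int, activator_fraction: float,
                lines: tuple[CellLineSpec, CellLineSpec], seed: int,
                reg: ParameterRegistry | None = None,
                dt: float = 3600.0, params: GrowthParams | None = None,
                stop_at_cells: int | None = None,
                max_radius: float | None = None) -> GrowthResult:
    """Grow a co-culture spheroid for ``n_days`` with hourly O2 updates.

    ``stop_at_cells`` stops growth once the viable population reaches the
    given size (used to grow different seedings to a common diameter).
    Returns the final grid, population, equivalent-sphere diameter and
    viable per-lineage counts.
    """
    if n_days <= 0:
        raise ValueError("n_days must be > 0")
    reg = reg or load_parameter_registry()
    params = params or GrowthParams.from_registry(reg)
    rng = np.random.default_rng(seed)
    mean_vol = float(reg.value("cell.mean_volume"))
    if max_radius is None:
        growth_factor = 2.0 ** (n_days * 86400.0
                                / min(ln.doubling_time for ln in lines))
        n_final = (stop_at_cells if stop_at_cells is not None
                   else n_cells * growth_factor)
        dx = (2 * mean_vol) ** (1 / 3)
        max_radius = 1.6 * dx * (3 * n_final / (4 * np.pi)) ** (1 / 3) + 3 * dx
    grid, cells = seed_spheroid(n_cells, activator_fraction, lines, rng,
                                mean_cell_volume=mean_vol,
                                max_radius=max_radius, params=params)
    gas = float(reg.value("O2.airsat"))
    depth = float(reg.value("geometry.spheroid.medium_depth"))
    area = (float(reg.value("geometry.spheroid.medium_volume")) / depth)
    t, t_end = 0.0, n_days * 86400.0
    C_prev = None
    O2_cell = np.full(len(cells), gas)
    profile, radii = None, None
    while t < t_end - 1e-6:
        if stop_at_cells is not None and cells.n_viable >= stop_at_cells:
            break
        O2_cell_live, profile, radii = _cell_o2(
            grid, cells, reg, gas, depth, area, prev=C_prev)
        C_prev = profile
        grow_step(grid, cells, O2_cell_live, params, dt, rng)
        t += dt
        # newly added daughters inherit the local profile next step
    O2_cell, profile, radii = _cell_o2(grid, cells, reg, gas, depth, area,
                                       prev=C_prev)
    viable = cells.state == STATE_VIABLE
    hyp = float(np.mean(O2_cell[viable] < params.hypoxia_threshold)) \
        if viable.any() else 0.0
    return GrowthResult(grid=grid, cells=cells,
                        diameter=equivalent_diameter(grid),
                        counts=cells.counts_by_line(),
                        o2_profile=profile, o2_radii=radii,
                        hypoxic_fraction=hyp)


def crop_to_spheroid(grid: LatticeGrid, cells: CellPopulation,
                     margin: int = 3) -> tuple[LatticeGrid, CellPopulation]:
    """Copy the lattice cropped to the occupied bounding box plus a margin.

    Drug exposures only need the spheroid and a thin medium shell (the bulk
    medium is the 1D column), so cropping after growth keeps the implicit
    diffusion operator small.  Cell indices are preserved; necrotic agents
    are carried over without a site.
    """
    import copy as _copy
    live = cells.state != STATE_NECROTIC
    ijk = grid.unravel(cells.site[live])
    lo = np.maximum(ijk.min(axis=0) - margin, 0)
    hi = np.minimum(ijk.max(axis=0) + margin + 1, grid.dims)
    dims = tuple(int(h - l) for l, h in zip(lo, hi))
    sub = LatticeGrid(grid.dx, dims)
    new_cells = _copy.deepcopy(cells)
    new_ijk = grid.unravel(new_cells.site) - lo
    new_ijk = np.clip(new_ijk, 0, np.asarray(dims) - 1)
    new_cells.site = sub.ravel(new_ijk)
    sub.occupancy[:] = VACANT
    live_idx = np.flatnonzero(live)
    sub.occupancy[new_cells.site[live_idx]] = live_idx
    return sub, new_cells


def snapshot_frame(grid: LatticeGrid, cells: CellPopulation):
    """Per-cell growth snapshot (x, y, z in um, lineage, volume, state)."""
    import pandas as pd
    ijk = grid.unravel(cells.site)
    xyz = (ijk + 0.5) * grid.dx
    return pd.DataFrame({
        "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
        "lineage": [cells.line_name(i) for i in cells.line_idx],
        "volume": cells.volume,
        "state": cells.state,
        "severe_hypoxia_clock": cells.severe_hypoxia_clock,
    })
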
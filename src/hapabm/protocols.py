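"""End-to-end in-silico experiment drivers.

Each driver mirrors one wet-lab protocol: the 1-h anoxic monolayer
clonogenic assay, the 1-h anoxic spheroid co-culture assay (optionally with
the dissolved-O2 contamination bolus carried in by the drug solution), the
MCL diffusion assay, the metabolite-contribution decomposition, and the
spatial-heterogeneity seeding experiment.  All return tidy pandas tables.

Dose-response tables have columns ``prodrug_uM, lineage, SF, log10_SF,
activator_fraction, replicate``; clonogenic survival of a lineage is the
expectation over its viable cells of exp(log_survival) (selective plating is
idealised as perfect lineage separation).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import STATE_VIABLE, CellLineSpec, CultureGeometry
from .growth import GrowthParams, GrowthResult, grow_to_day
from .pkpd import ProdrugModel, build_model, cell_lines_from_registry
from .registry import ParameterRegistry, load_parameter_registry
from .transport import (FineGridTransport, SolverSettings, simulate_mcl,
                        simulate_monolayer)

SF_FLOOR = 10 ** -4.5  # assay detection limit


@dataclass
class ExposureProtocol:
    """Drug-exposure protocol shared by the assay drivers."""

    model: str = "sn30000"                      # short model name
    concentrations: tuple[float, ...] = (0.0,)  # uM
    duration: float = 3600.0                    # s
    o2_bolus: float = 0.0                       # uM at t = 0
    mixing_ratios: tuple[float, ...] = (0.0,)   # activator fractions
    activator: str = "POR-R"
    target: str = "PORko-G"
    n_seed_cells: int = 3000
    n_days: float = 4.0
    n_spheroids: int = 4                        # pooled per concentration
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be >= 0")


@dataclass
class IC90Result:
    lineage: str
    concentration: float            # uM at SF = 0.1
    bracket: tuple[float, float]    # grid points around the crossing


def _monolayer_geometry(reg: ParameterRegistry) -> CultureGeometry:
    return CultureGeometry(
        kind="monolayer",
        medium_volume=float(reg.value("geometry.monolayer.medium_volume")),
        well_area=float(reg.value("geometry.monolayer.well_area")))


def _spheroid_exposure_geometry(reg: ParameterRegistry) -> CultureGeometry:
    depth = float(reg.value("geometry.spheroid.medium_depth"))
    return CultureGeometry(
        kind="spheroid",
        medium_volume=float(reg.value("geometry.spheroid.exposure_volume")),
        well_area=float(reg.value("geometry.spheroid.medium_volume")) / depth)


def _mcl_geometry(reg: ParameterRegistry) -> CultureGeometry:
    return CultureGeometry(
        kind="mcl",
        donor_volume=float(reg.value("geometry.mcl.donor_volume")),
        receiver_volume=float(reg.value("geometry.mcl.receiver_volume")),
        mcl_thickness=float(reg.value("geometry.mcl.thickness")),
        mcl_area=float(reg.value("geometry.mcl.area")))


# ----------------------------------------------------------------------
def run_monolayer_assay(protocol: ExposureProtocol,
                        reg: ParameterRegistry | None = None,
                        lineages: tuple[str, ...] | None = None,
                        n_cells: int | None = None,
                        n_nodes: int = 16) -> pd.DataFrame:
    """Clonogenic dose-response of pure monolayer cultures.

    Each lineage is exposed separately (the wet assay plates single lines),
    including prodrug depletion by cellular metabolism in the finite medium
    volume and any dissolved-O2 bolus.
    """
    reg = reg or load_parameter_registry()
    model = build_model(protocol.model, reg)
    geometry = _monolayer_geometry(reg)
    if n_cells is None:
        n_cells = int(float(reg.value("geometry.monolayer.n_cells")))
    lineages = lineages or (protocol.activator, protocol.target)
    o2p = {"Vmax": float(reg.value("O2.Vmax")),
           "Km": float(reg.value("O2.Km")),
           "D_medium": float(reg.value("solute.O2.D_medium"))}
    cell_vol = float(reg.value("cell.mean_volume"))
    rows = []
    for lineage in lineages:
        for conc in protocol.concentrations:
            if conc == 0.0:
                sf = 1.0
            else:
                res = simulate_monolayer(
                    model, {lineage: n_cells}, geometry, conc,
                    protocol.duration, o2_bolus=protocol.o2_bolus,
                    o2_params=o2p, cell_volume=cell_vol, n_nodes=n_nodes)
                sf = res.survival(lineage)
            rows.append({"prodrug_uM": conc, "lineage": lineage, "SF": sf,
                         "log10_SF": np.log10(max(sf, 1e-300)),
                         "activator_fraction": 1.0 if lineage == protocol.activator else 0.0,
                         "replicate": 0})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
class _ExposureO2:
    """Radial O2 during a spheroid drug exposure with a dissolved-O2 bolus.

    The bolus enters well-mixed at t = 0; the radial O2 field (transient,
    fine mesh, semi-implicit Michaelis-Menten uptake) is advanced between
    drug-transport intervals and the unstirred medium column above the
    spheroid is depleted by the consumed amount.
    """

    def __init__(self, solver: FineGridTransport, reg: ParameterRegistry,
                 bolus: float, gas_O2: float = 0.0):
        self.solver = solver
        self.reg = reg
        self.gas_O2 = gas_O2
        self.col = np.full(max(solver.n_slabs, 1), bolus)
        self.D_m = float(reg.value("solute.O2.D_medium"))
        self.D_t = float(reg.value("solute.O2.D_tissue"))
        self.Vmax = float(reg.value("O2.Vmax"))
        self.Km = float(reg.value("O2.Km"))
        grid = solver.grid
        r_cells = grid.radii(solver.cell_sites)
        # The radial O2 domain extends well into the unstirred medium (the
        # spheroid's supply is limited by the diffusion shell around it, not
        # by the bulk reservoir) on a fine mesh: the surface boundary layer
        # is steep relative to the lattice spacing.
        dr = 5.0
        r_sph = r_cells.max() if r_cells.size else grid.dx
        r_max = r_sph + 800.0
        self.n_shell = int(np.ceil(r_max / dr))
        self.r_centers = (np.arange(self.n_shell) + 0.5) * dr
        self.shell_of = np.clip((r_cells / dr).astype(int), 0, self.n_shell - 1)
        self.counts = np.bincount(self.shell_of, minlength=self.n_shell).astype(float)
        V_shell = 4 / 3 * np.pi * ((self.r_centers + dr / 2) ** 3
                                   - np.clip(self.r_centers - dr / 2, 0, None) ** 3)
        self.V_shell = V_shell
        self.occ_frac = np.clip(self.counts * grid.site_volume / V_shell, 0, 1)
        self.dr = dr
        self.r_cells = r_cells
        self.profile = np.full(self.n_shell, bolus)
        # surface readout at the equivalent-sphere radius (the rough outer
        # fringe holds few cells and sits at near-medium O2)
        self.R_eq = (3.0 * self.counts.sum() * grid.site_volume
                     / (4.0 * np.pi)) ** (1.0 / 3.0)
        self.surface_O2: list[tuple[float, float]] = []
        self.bolus = bolus
        self._radial = None

    def update(self, t: float, dt_interval: float) -> None:
        sv = self.solver
        boundary = float(self.col[0])
        if self._radial is None:
            from .transport import TransientRadialO2
            self._radial = TransientRadialO2(
                self.r_centers, self.dr, self.counts, self.occ_frac,
                self.D_t, self.D_m, self.Vmax, self.Km, self.bolus)
        Q_amt = self._radial.advance(dt_interval, boundary)
        Q = Q_amt / max(dt_interval, 1e-9)  # uM um^3 / s average
        self.profile = self._radial.C
        sv.state.O2_cell = np.interp(self.r_cells, self.r_centers, self.profile)
        if self.counts.any():
            self.surface_O2.append(
                (t, float(np.interp(self.R_eq, self.r_centers, self.profile))))
        # deplete the column: sink Q at the bottom slab, gas value on top
        if sv.n_slabs:
            n = sv.n_slabs
            V = sv.V_slab
            g = self.D_m * sv.geometry.well_area / sv.h_slab
            # backward Euler on the slab chain
            import scipy.sparse as sp
            import scipy.sparse.linalg as spla
            main = np.zeros(n)
            off = np.full(n - 1, -g)
            main[:-1] += g
            main[1:] += g
            g_top = self.D_m * sv.geometry.well_area / (sv.h_slab / 2)
            main[-1] += g_top
            rhs = V * self.col / dt_interval
            rhs[-1] += g_top * self.gas_O2
            rhs[0] -= Q  # uM um^3 / s consumed by the spheroid
            A = sp.diags([off, V / dt_interval + main, off], [-1, 0, 1]).tocsc()
            self.col = np.clip(spla.spsolve(A, rhs), 0.0, None)


def spheroid_exposure(growth: GrowthResult, model: ProdrugModel,
                      reg: ParameterRegistry, conc: float, duration: float,
                      o2_bolus: float = 0.0,
                      settings: SolverSettings | None = None) -> dict:
    """Expose a grown spheroid to a prodrug bolus for ``duration`` seconds.

    Returns per-lineage surviving fractions plus diagnostics.  The input
    growth result is not mutated.
    """
    settings = settings or SolverSettings()
    from .growth import crop_to_spheroid
    grid, cells = crop_to_spheroid(growth.grid, growth.cells)
    geometry = _spheroid_exposure_geometry(reg)
    solver = FineGridTransport(grid, cells, model, geometry,
                               settings=settings)
    solver.set_uniform_medium(model.prodrug.name, conc)
    o2 = _ExposureO2(solver, reg, o2_bolus) if o2_bolus > 0 else None
    t, interval = 0.0, settings.o2_interval
    surface = []
    while t < duration - 1e-9:
        if o2 is not None:
            o2.update(t, min(interval, duration - t))
        t_next = min(t + interval, duration)
        solver.run(t_next - t)
        t = t_next
    solver.apply_hazards_to_cells()
    out = {"cells": cells}
    for lineage in {ln.name for ln in cells.lines}:
        mask = cells.lineage_mask(lineage) & (cells.state == STATE_VIABLE)
        if mask.any():
            out[lineage] = float(np.mean(np.exp(cells.log_survival[mask])))
    if o2 is not None:
        out["surface_O2"] = o2.surface_O2
    out["solver"] = solver
    return out


def run_spheroid_assay(protocol: ExposureProtocol,
                       reg: ParameterRegistry | None = None,
                       growths: dict | None = None,
                       settings: SolverSettings | None = None) -> pd.DataFrame:
    """Clonogenic dose-response of day-4 co-culture spheroids.

    One grown spheroid per (mixing ratio, replicate seed); replicates are
    pooled per concentration as in the wet protocol (clonogen-weighted).
    ``growths`` may supply pre-grown spheroids keyed (ratio, replicate).
    """
    reg = reg or load_parameter_registry()
    model = build_model(protocol.model, reg)
    lines = cell_lines_from_registry(reg, [protocol.activator, protocol.target])
    line_pair = (lines[protocol.activator], lines[protocol.target])
    growths = growths if growths is not None else {}
    rows = []
    for ratio in protocol.mixing_ratios:
        for rep in range(protocol.n_spheroids):
            key = (ratio, rep)
            if key not in growths:
                growths[key] = grow_to_day(
                    protocol.n_days, protocol.n_seed_cells, ratio, line_pair,
                    seed=protocol.seed + 1000 * rep + int(ratio * 100), reg=reg)
        for conc in protocol.concentrations:
            pooled: dict[str, list[tuple[float, int]]] = {}
            for rep in range(protocol.n_spheroids):
                g = growths[(ratio, rep)]
                if conc == 0.0:
                    res = {ln.name: 1.0 for ln in g.cells.lines}
                    counts = g.cells.counts_by_line()
                else:
                    res = spheroid_exposure(g, model, reg, conc,
                                            protocol.duration,
                                            o2_bolus=protocol.o2_bolus,
                                            settings=settings)
                    counts = g.cells.counts_by_line()
                for name in (protocol.activator, protocol.target):
                    if name in res and counts.get(name, 0) > 0:
                        pooled.setdefault(name, []).append(
                            (res[name], counts[name]))
            for name, vals in pooled.items():
                sf = sum(s * n for s, n in vals) / sum(n for _, n in vals)
                rows.append({"prodrug_uM": conc, "lineage": name,
                             "SF": sf, "log10_SF": np.log10(max(sf, 1e-300)),
                             "activator_fraction": ratio, "replicate": -1})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
def run_mcl_assay(protocol: ExposureProtocol,
                  reg: ParameterRegistry | None = None,
                  donor_bolus: float = 100.0, duration: float = 5 * 3600.0,
                  n_nodes: int = 20) -> dict[float, object]:
    """MCL diffusion assay: receiver C/C0 and metabolite output per ratio."""
    reg = reg or load_parameter_registry()
    model = build_model(protocol.model, reg)
    geometry = _mcl_geometry(reg)
    cell_vol = float(reg.value("cell.mean_volume"))
    out = {}
    for ratio in protocol.mixing_ratios:
        out[ratio] = simulate_mcl(
            model, ratio, protocol.activator, protocol.target, geometry,
            donor_bolus, duration, n_nodes=n_nodes, cell_volume=cell_vol)
    return out


def mcl_metabolite_amount(result, model: ProdrugModel) -> np.ndarray:
    """Total tracked metabolite amount (umol) in donor + receiver vs time."""
    mets = [s.name for s in model.solutes[1:]]
    return sum(result.donor_amount[m] + result.receiver_amount[m] for m in mets)


# ----------------------------------------------------------------------
def decompose_metabolite_contributions(
        growth_or_none, concentrations: dict[str, float],
        reg: ParameterRegistry | None = None,
        culture: str = "monolayer",
        activator: str = "POR-G", target: str = "PORko-R",
        settings: SolverSettings | None = None) -> pd.DataFrame:
    """Relative log kill attributable to each cytotoxic metabolite class.

    Runs the dichloro-metabolites model in full, then counterfactuals with
    each kill model's potency zeroed (transport unchanged), at the given
    per-lineage concentration.  The contribution of a metabolite is the
    log-kill lost when its potency is removed, normalised per lineage.
    """
    reg = reg or load_parameter_registry()
    full = build_model("pr104a-dichloro", reg)
    variants = {"full": full,
                "no_M1": full.zero_kc("PR104_M1"),
                "no_M2": full.zero_kc("PR104_M2")}
    rows = []
    for lineage, conc in concentrations.items():
        logkill = {}
        for tag, model in variants.items():
            if culture == "monolayer":
                geometry = _monolayer_geometry(reg)
                n_cells = int(float(reg.value("geometry.monolayer.n_cells")))
                res = simulate_monolayer(
                    model, {lineage: n_cells}, geometry, conc, 3600.0,
                    cell_volume=float(reg.value("cell.mean_volume")))
                sf = res.survival(lineage)
            else:
                res = spheroid_exposure(growth_or_none, model, reg, conc,
                                        3600.0, settings=settings)
                sf = res.get(lineage, 1.0)
            logkill[tag] = -np.log10(max(sf, 1e-300))
        c1 = max(logkill["full"] - logkill["no_M1"], 0.0)  # M1 contribution
        c2 = max(logkill["full"] - logkill["no_M2"], 0.0)  # M2 contribution
        tot = c1 + c2
        rows.append({"lineage": lineage, "culture": culture,
                     "logkill_full": logkill["full"],
                     "contrib_PR104HM": c1 / tot if tot else 0.0,
                     "contrib_dichloro": c2 / tot if tot else 0.0})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
def run_heterogeneity_experiment(
        initial_cells=(20, 2000, 20000), activator_fraction: float = 0.10,
        concentration: float = 40.0, n_seeds: int = 6,
        target_cells: int = 8000, seed: int = 0,
        reg: ParameterRegistry | None = None,
        activator: str = "POR-G", target: str = "PORko-R",
        settings: SolverSettings | None = None,
        doubling_time: float = 16 * 3600.0) -> pd.DataFrame:
    """Effect of seeding size (spatial heterogeneity of activators) on
    bystander killing of targets.

    Spheroids are seeded with different initial cell numbers at a fixed
    activator fraction, grown with equal doubling times and without hypoxic
    death to the same final size, then exposed to the prodrug; the target
    log kill is reported per replicate seed.
    """
    reg = reg or load_parameter_registry()
    model = build_model("pr104a-dichloro", reg)
    base = cell_lines_from_registry(reg, [activator, target])
    lines = (replace(base[activator], doubling_time=doubling_time),
             replace(base[target], doubling_time=doubling_time))
    params = GrowthParams.from_registry(reg, hypoxic_death=False)
    rows = []
    for n0 in initial_cells:
        if n0 > target_cells:
            raise ValueError("initial seeding exceeds the target size")
        for rep in range(n_seeds):
            g = grow_to_day(60.0, n0, activator_fraction, lines,
                            seed=seed + 7919 * rep + n0, reg=reg,
                            params=params, stop_at_cells=target_cells)
            res = spheroid_exposure(g, model, reg, concentration, 3600.0,
                                    settings=settings)
            sf_t = res.get(target, np.nan)
            rows.append({"initial_cells": n0, "replicate": rep,
                         "diameter_um": g.diameter,
                         "target_logkill": -np.log10(max(sf_t, 1e-300)),
                         "activator_fraction_realized":
                             g.counts.get(activator, 0) / max(sum(g.counts.values()), 1)})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
def ic90(dose_response: pd.DataFrame, lineage: str,
         activator_fraction: float | None = None) -> IC90Result:
    """Concentration giving 90% kill (SF = 0.1) by log-linear interpolation.

    The SF grid must bracket 0.1 and be monotone non-increasing in
    concentration (within noise); otherwise the call is rejected with the
    achieved SF range.
    """
    df = dose_response[dose_response["lineage"] == lineage]
    if activator_fraction is not None:
        df = df[df["activator_fraction"] == activator_fraction]
    df = df.groupby("prodrug_uM", as_index=False)["SF"].mean().sort_values(
        "prodrug_uM")
    conc = df["prodrug_uM"].to_numpy()
    sf = df["SF"].to_numpy()
    if sf.size < 2:
        raise ValueError("need at least two concentrations")
    if sf[-1] > sf[0]:
        raise ValueError("dose-response is not monotone decreasing")
    if not (sf.max() >= 0.1 >= sf.min()):
        raise ValueError(
            f"SF grid does not bracket 0.1 (range {sf.min():.3g}..{sf.max():.3g})")
    below = np.flatnonzero(sf <= 0.1)
    i = below[0]
    if sf[i] == 0.1 or i == 0:
        return IC90Result(lineage, float(conc[i]), (float(conc[i]), float(conc[i])))
    c0, c1 = conc[i - 1], conc[i]
    l0, l1 = np.log10(sf[i - 1]), np.log10(sf[i])
    c_star = c0 + (np.log10(0.1) - l0) * (c1 - c0) / (l1 - l0)
    return IC90Result(lineage, float(c_star), (float(c0), float(c1)))


# ----------------------------------------------------------------------
def run_manifest(reg: ParameterRegistry, protocol: ExposureProtocol | None,
                 seeds: list[int]) -> dict:
    """Reproducibility manifest: parameters (with provenance), seeds, and
    the list of ASSUMED parameters in use."""
    return {
        "seeds": list(seeds),
        "protocol": None if protocol is None else vars(protocol) | {
            "concentrations": list(protocol.concentrations),
            "mixing_ratios": list(protocol.mixing_ratios)},
        "assumed_parameters": reg.assumed(),
        "registry": reg.manifest(),
    }
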
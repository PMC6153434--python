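"""Hypoxia-activated prodrug pharmacology: the oxygen-dependent metabolism
chain and the kill-probability laws, with per-cell survival accounting.

Model structure
---------------
A prodrug is reduced intracellularly with an oxygen-dependent first-order
rate constant ``K_met(O2) = K_met0 * K_O2 / (K_O2 + O2)``, so metabolism is
maximal under anoxia and half-inhibited at O2 = K_O2.  The metabolism rate is
``M' = K_met * C_i`` and consumed prodrug appears stoichiometrically as the
next species in the chain (Prodrug -> Metabolite 1 -> Metabolite 2 ->
untracked products).

Two pharmacodynamic laws convert exposure to a kill probability over a small
interval dt:

* ``metabolism_rate`` mode (SN30000): P_kill = K_c * M' * dt.  The cytotoxin
  is a short-lived radical that never leaves the cell of origin, so only
  metabolising cells are killed — no bystander effect is possible.  The
  radical is treated as quasi-steady: the kill law consumes M' directly and
  the inert, diffusible 1-oxide/nor-oxide pool receives the stoichiometric
  flux.
* ``concentration`` mode (PR104A metabolites): P_kill = K_c * C_i * dt for
  the intracellular concentration of a diffusible cytotoxin, regardless of
  which cell generated it — the carrier of bystander killing.

Survival is accumulated as the hazard integral, survival =
exp(-int hazard dt), the dt -> 0 limit of the discrete products; this makes
survival independent of how the exposure is subdivided.  Activators and
targets have identical intrinsic sensitivity: only their metabolic capacity
(and hence their cytotoxin exposure) differs.

Three prodrug models are provided:

* ``SN30000_no_bystander`` — radical kill only, oxide pool tracked as inert.
* ``PR104A_HplusM`` — the hydroxylamine/amine metabolites (lumped
  "Metabolite 1") are the only cytotoxins.
* ``PR104A_dichloro`` — Metabolite 1 plus the more stable, lipophilic
  dichloro mustards (lumped "Metabolite 2"), each with its own potency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (STATE_VIABLE, CellLineSpec, CellPopulation, KillModel,
                   MetabolismSpec, SoluteSpec)
from .registry import ParameterRegistry

__all__ = [
    "ProdrugModel", "oxygen_dependent_kmet", "metabolism_rate",
    "kill_probability", "combine_kills", "surviving_fraction",
    "sn30000_model", "pr104a_hm_model", "pr104a_dichloro_model",
    "cell_lines_from_registry", "build_model",
]


def oxygen_dependent_kmet(spec: MetabolismSpec, O2) -> np.ndarray | float:
    """K_met(O2) = K_met0 * K_O2 / (K_O2 + O2)  (s^-1).

    Monotone decreasing in O2; equals K_met0 under anoxia.
    """
    O2 = np.asarray(O2, dtype=float)
    if np.any(O2 < 0):
        raise ValueError("O2 must be >= 0")
    out = spec.K_met0 * spec.K_O2 / (spec.K_O2 + O2)
    return float(out) if out.ndim == 0 else out


def metabolism_rate(kmet, C_i) -> np.ndarray | float:
    """M' = K_met * C  (uM/s)."""
    return kmet * C_i


def kill_probability(model: KillModel, driver, dt: float):
    """Instantaneous kill probability 1 - exp(-K_c * driver * dt).

    ``driver`` is M' (uM/s) in metabolism_rate mode or the cytotoxin
    intracellular concentration (uM) in concentration mode.  The hazard
    increment ``K_c * driver * dt`` is what accumulates on
    ``CellAgent.log_survival``.
    """
    h = hazard_increment(model, driver, dt)
    return 1.0 - np.exp(-h)


def hazard_increment(model: KillModel, driver, dt: float):
    if dt < 0:
        raise ValueError("dt must be >= 0")
    return model.K_c * np.asarray(driver, dtype=float) * dt


def combine_kills(P1, P2):
    """Independent-action combination: P = 1 - (1 - P1)(1 - P2)."""
    P1 = np.asarray(P1, dtype=float)
    P2 = np.asarray(P2, dtype=float)
    if np.any((P1 < 0) | (P1 > 1) | (P2 < 0) | (P2 > 1)):
        raise ValueError("kill probabilities must lie in [0, 1]")
    out = 1.0 - (1.0 - P1) * (1.0 - P2)
    return float(out) if out.ndim == 0 else out


def surviving_fraction(cells: CellPopulation, lineage: str | None = None,
                       mode: str = "expectation",
                       rng: np.random.Generator | None = None) -> float:
    """Clonogenic surviving fraction of the (viable) filtered population.

    ``expectation`` mode averages exp(log_survival) over viable cells;
    ``bernoulli`` mode samples each cell's clonogenicity once and returns the
    realised clonogen fraction (requires ``rng``).  Cells already tagged dead
    by hypoxia are excluded from the clonogen denominator.
    """
    mask = cells.state == STATE_VIABLE
    if lineage is not None:
        mask &= cells.lineage_mask(lineage)
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise ValueError(f"no viable cells in lineage filter {lineage!r}")
    p = np.exp(cells.log_survival[mask])
    if mode == "expectation":
        return float(np.mean(p))
    if mode == "bernoulli":
        if rng is None:
            raise ValueError("bernoulli mode requires an rng")
        return float(np.mean(rng.random(n) < p))
    raise ValueError(f"unknown surviving-fraction mode {mode!r}")


@dataclass(frozen=True)
class ProdrugModel:
    """A prodrug, its tracked metabolite chain, and its kill models.

    ``solutes`` lists the diffusible tracked species in chain order, starting
    with the prodrug.  ``metabolism`` maps cell-line name to the
    oxygen-dependent prodrug reduction kinetics.  ``met_target`` names the
    solute receiving the stoichiometric metabolic flux (for SN30000 this is
    the inert oxide pool downstream of the quasi-steady radical).
    """

    name: str
    solutes: tuple[SoluteSpec, ...]
    metabolism: dict[str, MetabolismSpec]
    kill_models: tuple[KillModel, ...]
    met_target: str | None

    @property
    def prodrug(self) -> SoluteSpec:
        return self.solutes[0]

    def solute(self, name: str) -> SoluteSpec:
        for s in self.solutes:
            if s.name == name:
                return s
        raise KeyError(name)

    def kmet(self, line: str, O2) -> np.ndarray | float:
        spec = self.metabolism.get(line)
        if spec is None or spec.K_met0 == 0.0:
            return np.zeros_like(np.asarray(O2, dtype=float)) if np.ndim(O2) else 0.0
        return oxygen_dependent_kmet(spec, O2)

    def zero_kc(self, acts_on: str) -> "ProdrugModel":
        """Counterfactual copy with one kill model's potency set to zero."""
        kms = tuple(replace(k, K_c=0.0) if k.acts_on == acts_on else k
                    for k in self.kill_models)
        return replace(self, kill_models=kms)


def _solute_from_registry(reg: ParameterRegistry, name: str,
                          child: str | None = None,
                          required=("D_medium", "D_tissue")) -> SoluteSpec:
    base = f"solute.{name}"
    reg.require([f"{base}.{f}" for f in required])
    get = lambda f: float(reg.get(f"{base}.{f}", 0.0))
    kcm = reg.get(f"{base}.k_chain_medium")
    return SoluteSpec(
        name=name, D_medium=get("D_medium"), D_tissue=get("D_tissue"),
        K_in=get("K_in"), K_out=get("K_out"),
        k_decay_medium=get("k_decay_medium"), k_loss_cell=get("k_loss_cell"),
        k_chain=get("k_chain"),
        k_chain_medium=None if kcm is None else float(kcm), child=child)


def _metabolism_map(reg: ParameterRegistry, prodrug: str,
                    lines: list[str]) -> dict[str, MetabolismSpec]:
    K_O2 = float(reg.value(f"solute.{prodrug}.K_O2"))
    out = {}
    for line in lines:
        key = f"solute.{prodrug}.kmet0.{line}"
        if key in reg:
            out[line] = MetabolismSpec(K_met0=float(reg.value(key)),
                                       K_O2=K_O2, cell_line=line)
    return out


_ALL_LINES = ["POR-R", "POR-G", "PORko-R", "PORko-G", "HCT116"]


def cell_lines_from_registry(reg: ParameterRegistry,
                             names: list[str] | None = None) -> dict[str, CellLineSpec]:
    names = names or _ALL_LINES
    out = {}
    for n in names:
        role = str(reg.value(f"line.{n}.role"))
        td = float(reg.value(f"line.{n}.doubling_time"))
        out[n] = CellLineSpec(name=n, role=role, doubling_time=td)
    return out


def sn30000_model(reg: ParameterRegistry) -> ProdrugModel:
    """SN30000 'no bystander effect' model.

    The cytotoxic radical is confined to the cell of origin, so killing is
    driven by the cell's own metabolism rate; the downstream 1-oxide and
    nor-oxide metabolites form an inert diffusible pool (tracked so the MCL
    metabolite readout can be simulated).
    """
    prodrug = _solute_from_registry(reg, "SN30000", child="SN_oxide")
    oxide = _solute_from_registry(reg, "SN_oxide")
    kill = KillModel(mode="metabolism_rate",
                     K_c=float(reg.value("solute.SN30000.K_c")),
                     acts_on="SN30000")
    return ProdrugModel(
        name="SN30000_no_bystander", solutes=(prodrug, oxide),
        metabolism=_metabolism_map(reg, "SN30000", _ALL_LINES),
        kill_models=(kill,), met_target="SN_oxide")


def pr104a_hm_model(reg: ParameterRegistry) -> ProdrugModel:
    """PR104A model in which PR104H+M (Metabolite 1) is the only cytotoxin.

    This is the model whose spheroid predictions fail directionally: the
    hydrophilic mustards diffuse too poorly to compensate for prodrug
    depletion at high activator fractions.
    """
    prodrug = _solute_from_registry(reg, "PR104A", child="PR104_M1")
    m1 = _solute_from_registry(reg, "PR104_M1")
    # Terminal species here: downstream products untracked.
    m1 = replace(m1, k_decay_medium=m1.k_decay_medium + m1.k_chain_medium,
                 k_loss_cell=m1.k_loss_cell + m1.k_chain, k_chain=0.0,
                 k_chain_medium=0.0, child=None)
    kill = KillModel(mode="concentration",
                     K_c=float(reg.value("solute.PR104_M1.K_c")),
                     acts_on="PR104_M1")
    return ProdrugModel(
        name="PR104A_HplusM", solutes=(prodrug, m1),
        metabolism=_metabolism_map(reg, "PR104A", _ALL_LINES),
        kill_models=(kill,), met_target="PR104_M1")


def pr104a_dichloro_model(reg: ParameterRegistry) -> ProdrugModel:
    """PR104A 'dichloro metabolites' model.

    Metabolite 1 (PR104H+M) converts chemically to Metabolite 2 (the lumped
    dichloro mustards A+B) in both compartments; both pools are cytotoxic
    with their own potencies, and Metabolite 2's stability and lipophilicity
    give it the long bystander range.
    """
    prodrug = _solute_from_registry(reg, "PR104A", child="PR104_M1")
    m1 = _solute_from_registry(reg, "PR104_M1", child="PR104_M2")
    m2 = _solute_from_registry(reg, "PR104_M2")
    k1 = KillModel(mode="concentration",
                   K_c=float(reg.value("solute.PR104_M1.K_c")),
                   acts_on="PR104_M1")
    k2 = KillModel(mode="concentration",
                   K_c=float(reg.value("solute.PR104_M2.K_c")),
                   acts_on="PR104_M2")
    return ProdrugModel(
        name="PR104A_dichloro", solutes=(prodrug, m1, m2),
        metabolism=_metabolism_map(reg, "PR104A", _ALL_LINES),
        kill_models=(k1, k2), met_target="PR104_M1")


_BUILDERS = {
    "sn30000": sn30000_model,
    "pr104a-hm": pr104a_hm_model,
    "pr104a-dichloro": pr104a_dichloro_model,
}


def build_model(name: str, reg: ParameterRegistry | None = None) -> ProdrugModel:
    """Build a prodrug model by short name (see ``_BUILDERS`` keys)."""
    from .registry import load_parameter_registry
    if reg is None:
        reg = load_parameter_registry()
    try:
        return _BUILDERS[name](reg)
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; choose from {sorted(_BUILDERS)}") from None
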
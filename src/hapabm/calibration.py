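"""Calibration of the free PKPD parameters (K_met0 per cell line, K_c per
metabolite) from monolayer dose-response data, with identifiability guards.

The loss is the sum of squared residuals on log10 surviving fraction between
the data and the forward monolayer model (run inside the objective), with
observed SF floored at the assay detection limit.  In the no-depletion limit
survival under either kill law depends on K_c and K_met0 only through their
product, so the fitter refuses to free both from a single lineage's curve —
multi-lineage data (which share K_c but not K_met0) are required to separate
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .protocols import ExposureProtocol, run_monolayer_assay
from .registry import ParameterRegistry, load_parameter_registry

SF_FLOOR = 10 ** -4.5


def loglinear_slope(dose_response: pd.DataFrame, lineage: str,
                    through_origin: bool = True) -> tuple[float, float]:
    """OLS slope of log10 SF vs concentration (per uM) with standard error.

    ``through_origin`` anchors the fit at (0, 0) — clonogenic survival is 1
    at zero dose by construction; duplicate concentrations are handled
    naturally by least squares.
    """
    df = dose_response[dose_response["lineage"] == lineage]
    x = df["prodrug_uM"].to_numpy(dtype=float)
    y = np.log10(np.clip(df["SF"].to_numpy(dtype=float), 1e-300, None))
    if x.size < 3:
        raise ValueError("need at least 3 points for a slope")
    if through_origin:
        sxx = float(x @ x)
        if sxx == 0:
            raise ValueError("all concentrations are zero")
        slope = float(x @ y) / sxx
        resid = y - slope * x
        dof = max(x.size - 1, 1)
        se = float(np.sqrt(resid @ resid / dof / sxx))
        return slope, se
    X = np.column_stack([x, np.ones_like(x)])
    coef, res_ss, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = max(x.size - 2, 1)
    cov = np.linalg.inv(X.T @ X) * float(resid @ resid) / dof
    return float(coef[0]), float(np.sqrt(cov[0, 0]))


@dataclass
class FitSpec:
    """What to fit: free registry parameters, bounds, and the data."""

    free: list[str]                       # registry parameter names
    bounds: dict[str, tuple[float, float]]
    data: pd.DataFrame                    # prodrug_uM, lineage, SF, replicate
    protocol: ExposureProtocol = field(
        default_factory=lambda: ExposureProtocol(model="sn30000"))
    seed: int = 0
    n_nodes: int = 8                      # medium discretisation in the objective
    n_cells: int | None = None            # override culture density (None = registry)
    max_iter: int = 60
    n_starts: int = 3

    def __post_init__(self) -> None:
        for name in self.free:
            lo, hi = self.bounds[name]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name} must be finite with lo < hi")


@dataclass
class FitResult:
    estimates: dict[str, float]           # internal units
    se: dict[str, float]
    loss: float
    n_eval: int
    converged: bool
    provenance: str = "FITTED"

    def patch(self, reg: ParameterRegistry) -> ParameterRegistry:
        return reg.patch(self.estimates, provenance="FITTED",
                         cite="monolayer dose-response calibration")


def _validate_data(data: pd.DataFrame) -> None:
    concs = np.unique(data.loc[data["prodrug_uM"] > 0, "prodrug_uM"])
    if concs.size < 2:
        raise ValueError("need multiple non-zero concentrations to fit")
    if concs.size < 4:
        raise ValueError("data must cover >= 4 concentrations")
    lsf = np.log10(np.clip(data["SF"].to_numpy(float), SF_FLOOR, None))
    if lsf.max() - lsf.min() < 2.0:
        raise ValueError(
            "data must span >= 2 decades of surviving fraction; "
            f"observed span {lsf.max() - lsf.min():.2f} (flat or degenerate data)")


def monolayer_objective(fitspec: FitSpec, reg: ParameterRegistry):
    """Sum-of-squares objective on log10 SF; runs the forward model."""
    data = fitspec.data
    lineages = tuple(sorted(data["lineage"].unique()))
    concs = tuple(sorted(np.unique(data.loc[data["prodrug_uM"] > 0,
                                            "prodrug_uM"])))
    obs = data[data["prodrug_uM"] > 0]
    y_obs = np.log10(np.clip(obs["SF"].to_numpy(float), SF_FLOOR, None))
    proto = ExposureProtocol(model=fitspec.protocol.model,
                             concentrations=concs,
                             duration=fitspec.protocol.duration,
                             activator=fitspec.protocol.activator,
                             target=fitspec.protocol.target)

    def loss(theta: np.ndarray) -> float:
        patched = reg.patch(dict(zip(fitspec.free, theta)))
        df = run_monolayer_assay(proto, patched, lineages=lineages,
                                 n_cells=fitspec.n_cells,
                                 n_nodes=fitspec.n_nodes)
        pred = df.set_index(["lineage", "prodrug_uM"])["SF"]
        y_pred = np.log10(np.clip(
            pred.loc[list(zip(obs["lineage"], obs["prodrug_uM"]))].to_numpy(float),
            SF_FLOOR, None))
        r = y_obs - y_pred
        return float(r @ r)

    return loss


def fit_monolayer(fitspec: FitSpec,
                  reg: ParameterRegistry | None = None) -> FitResult:
    """Fit the free parameters by bounded derivative-free minimisation.

    Multi-start local search from points spread over the bounds
    (deterministic given ``fitspec.seed``); approximate standard errors from
    the curvature of the residual sum of squares at the optimum.
    """
    reg = reg or load_parameter_registry()
    _validate_data(fitspec.data)
    lineages = fitspec.data["lineage"].unique()
    frees_kc = [n for n in fitspec.free if ".K_c" in n]
    frees_kmet = [n for n in fitspec.free if ".kmet0." in n]
    if frees_kc and frees_kmet and len(lineages) < 2:
        raise ValueError(
            "K_c and K_met0 are jointly unidentifiable from a single "
            "lineage's monolayer curve (only their product is constrained); "
            "supply multi-lineage data or fix one of them")
    loss = monolayer_objective(fitspec, reg)
    n_eval = 0

    def counted(theta):
        nonlocal n_eval
        n_eval += 1
        return loss(np.asarray(theta, float))

    lo = np.array([fitspec.bounds[n][0] for n in fitspec.free])
    hi = np.array([fitspec.bounds[n][1] for n in fitspec.free])
    rng = np.random.default_rng(fitspec.seed)

    if len(fitspec.free) == 1:
        res = optimize.minimize_scalar(
            lambda t: counted([t]), bounds=(lo[0], hi[0]), method="bounded",
            options={"xatol": 1e-3 * (hi[0] - lo[0]), "maxiter": fitspec.max_iter})
        best_x, best_f, ok = np.array([res.x]), res.fun, res.success
    else:
        starts = [0.5 * (lo + hi)]
        for _ in range(fitspec.n_starts - 1):
            starts.append(lo + rng.random(lo.size) * (hi - lo))
        best_x, best_f, ok = None, np.inf, False
        for x0 in starts:
            res = optimize.minimize(
                lambda t: counted(np.clip(t, lo, hi)), x0,
                method="Nelder-Mead",
                options={"maxiter": fitspec.max_iter * lo.size,
                         "xatol": 1e-4 * float(np.min(hi - lo)),
                         "fatol": 1e-8})
            if res.fun < best_f:
                best_x, best_f, ok = np.clip(res.x, lo, hi), res.fun, True
    if best_x is None or not np.isfinite(best_f):
        raise RuntimeError(f"fit did not converge after {n_eval} evaluations")

    # curvature-based SEs: var = 2 s^2 / (d2 loss / d theta^2)
    n_obs = int((fitspec.data["prodrug_uM"] > 0).sum())
    dof = max(n_obs - len(fitspec.free), 1)
    s2 = best_f / dof
    se = {}
    for i, name in enumerate(fitspec.free):
        h = 1e-3 * (hi[i] - lo[i])
        xp, xm = best_x.copy(), best_x.copy()
        xp[i] = min(xp[i] + h, hi[i])
        xm[i] = max(xm[i] - h, lo[i])
        d2 = (counted(xp) - 2 * best_f + counted(xm)) / ((xp[i] - best_x[i])
                                                         * (best_x[i] - xm[i]) + 1e-300)
        se[name] = float(np.sqrt(2 * s2 / d2)) if d2 > 0 else float("inf")
    return FitResult(estimates=dict(zip(fitspec.free, map(float, best_x))),
                     se=se, loss=float(best_f), n_eval=n_eval, converged=bool(ok))
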
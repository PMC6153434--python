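"""Synthetic 'experimental' data with the statistical structure the
analysis assumes: log-linear clonogenic survival with multiplicative
(lognormal) inter-replicate scatter and a counting floor, and MCL
donor/receiver time courses with additive measurement noise and the
per-draw sampling-volume depletion.

Lognormal noise keeps synthetic SF positive and its scatter multiplicative,
matching clonogenic-assay behaviour; the draw is mean-corrected so that the
expectation over replicates equals the noiseless forward-model SF.  Outputs
embed the true-parameter manifest in a header comment so parameter-recovery
tests are self-scoring.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocols import ExposureProtocol, run_mcl_assay, run_monolayer_assay, \
    _mcl_geometry
from .pkpd import build_model
from .registry import ParameterRegistry, load_parameter_registry
from .transport import simulate_mcl


@dataclass
class NoiseModel:
    """Replicate-level noise for synthetic datasets."""

    sf_noise: float = 0.15          # lognormal CV on surviving fraction
    counting_floor: float = 10 ** -4.5  # minimum detectable SF
    timecourse_noise: float = 0.02  # additive SD as a fraction of C0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sf_noise < 0 or self.timecourse_noise < 0:
            raise ValueError("noise CVs must be >= 0")
        if not 0.0 < self.counting_floor < 1.0:
            raise ValueError("counting_floor must be in (0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv * cv))
    # mean-corrected: E[factor] = 1
    return np.exp(rng.normal(-sigma * sigma / 2.0, sigma, size=n))


def synth_dose_response(protocol: ExposureProtocol, noise: NoiseModel,
                        reg: ParameterRegistry | None = None,
                        n_replicates: int = 3,
                        lineages: tuple[str, ...] | None = None,
                        true_params: dict[str, float] | None = None,
                        n_nodes: int = 8,
                        n_cells: int | None = None) -> pd.DataFrame:
    """Simulate a noisy monolayer dose-response dataset.

    ``true_params`` optionally patches registry entries (internal units)
    before the forward simulation; the applied values are embedded in
    ``df.attrs['true_params']`` for recovery scoring.
    """
    reg = reg or load_parameter_registry()
    if true_params:
        reg = reg.patch(true_params)
    clean = run_monolayer_assay(protocol, reg, lineages=lineages,
                                n_cells=n_cells, n_nodes=n_nodes)
    rng = noise.rng()
    rows = []
    for _, r in clean.iterrows():
        factors = _lognormal_factors(rng, noise.sf_noise, n_replicates)
        for rep in range(n_replicates):
            sf = float(r["SF"] * factors[rep])
            censored = sf < noise.counting_floor
            sf = max(sf, noise.counting_floor)
            rows.append({"prodrug_uM": r["prodrug_uM"],
                         "lineage": r["lineage"], "SF": sf,
                         "replicate": rep, "censored": censored})
    df = pd.DataFrame(rows)
    df.attrs["true_params"] = dict(true_params or {})
    df.attrs["noise"] = {"sf_noise": noise.sf_noise,
                         "counting_floor": noise.counting_floor,
                         "seed": noise.seed}
    return df


def dose_response_to_csv(df: pd.DataFrame, path_or_buf) -> None:
    """Write a dose-response table with the true-parameter manifest header."""
    header = "# manifest: " + json.dumps(
        {"true_params": df.attrs.get("true_params", {}),
         "noise": df.attrs.get("noise", {})}, sort_keys=True) + "\n"
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format="%.10g")
    text = header + buf.getvalue()
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def read_dose_response_csv(path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
        manifest = {}
        if first.startswith("# manifest:"):
            manifest = json.loads(first[len("# manifest:"):])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    df.attrs["true_params"] = manifest.get("true_params", {})
    df.attrs["noise"] = manifest.get("noise", {})
    return df


def synth_mcl_timecourse(protocol: ExposureProtocol, noise: NoiseModel,
                         reg: ParameterRegistry | None = None,
                         donor_bolus: float = 100.0,
                         duration: float = 5 * 3600.0,
                         sample_interval: float = 1800.0,
                         sample_volume: float = 100e9,  # 100 uL in um^3
                         activator_fraction: float = 0.5,
                         true_params: dict[str, float] | None = None) -> pd.DataFrame:
    """Simulate a noisy MCL diffusion time course with sampling depletion.

    100 uL is drawn from each compartment at every sampling time (reducing
    compartment volumes for the remainder of the run); additive Gaussian
    noise with SD ``timecourse_noise * C0`` is applied to sampled
    concentrations, clipped at zero (clip events counted in
    ``df.attrs['n_clipped']``).
    """
    reg = reg or load_parameter_registry()
    if true_params:
        reg = reg.patch(true_params)
    model = build_model(protocol.model, reg)
    geometry = _mcl_geometry(reg)
    sample_times = np.arange(sample_interval, duration + 1e-6, sample_interval)
    res = simulate_mcl(model, activator_fraction, protocol.activator,
                       protocol.target, geometry, donor_bolus, duration,
                       sample_times=sample_times, sample_volume=sample_volume,
                       cell_volume=float(reg.value("cell.mean_volume")))
    rng = noise.rng()
    sd = noise.timecourse_noise * donor_bolus
    rows = []
    n_clipped = 0
    grid_times = np.concatenate([[0.0], sample_times])
    for ts in grid_times:
        i = int(np.argmin(np.abs(res.t - ts)))
        for comp, series, vols in (("donor", res.donor, res.donor_volume),
                                   ("receiver", res.receiver, res.receiver_volume)):
            for sol in series:
                c = float(series[sol][i])
                if sd > 0:
                    c += float(rng.normal(0.0, sd))
                if c < 0:
                    c = 0.0
                    n_clipped += 1
                rows.append({"t_s": float(res.t[i]), "compartment": comp,
                             "solute": sol, "concentration_uM": c,
                             "amount_umol": c * float(vols[i]) * 1e-15})
    df = pd.DataFrame(rows)
    df.attrs["true_params"] = dict(true_params or {})
    df.attrs["n_clipped"] = n_clipped
    df.attrs["final_donor_volume_mL"] = float(res.donor_volume[-1] / 1e12)
    return df
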
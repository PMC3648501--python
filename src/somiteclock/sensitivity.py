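"""One-at-a-time parameter sensitivity of oscillation period and amplitude.

For a parameter perturbed from p_norm to p_pert the normalized finite
difference sensitivities are

    S_tau = (tau_pert - tau_norm)/(p_pert - p_norm) * p_norm/tau_norm
    S_A   = (A_pert   - A_norm)  /(p_pert - p_norm) * p_norm/A_norm

computed per readout gene at the three standard perturbation levels (1%,
10%, 50%, positive direction).  A parameter is significantly sensitive
when |S| >= 1.  A perturbation that kills the oscillation is recorded as a
status, not a number.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .network import PathwayModel, ParameterSet
from .oscillometry import measure
from .simulate import SimulationConfig, burn_in, integrate

__all__ = [
    "SensitivityStatus",
    "SensitivityRecord",
    "period_sensitivity",
    "amplitude_sensitivity",
    "sensitivity_scan",
    "significant",
    "records_to_frame",
    "DEFAULT_LEVELS",
]

DEFAULT_LEVELS = (0.01, 0.10, 0.50)
SIGNIFICANCE_THRESHOLD = 1.0


class SensitivityStatus(str, enum.Enum):
    OK = "ok"
    OSCILLATION_LOST = "oscillation_lost"
    SOLVER_FAILED = "solver_failed"


@dataclass
class SensitivityRecord:
    parameter: str
    gene: str
    level: float
    s_tau: float | None
    s_a: float | None
    significant_tau: bool
    significant_a: bool
    status: SensitivityStatus
    pathway: str = ""


def _normalized_sensitivity(
    y_norm: float, y_pert: float, p_norm: float, p_pert: float
) -> float:
    if p_pert == p_norm:
        raise ValueError("perturbed and normal parameter values are equal")
    if p_norm <= 0:
        raise ValueError("normal parameter value must be > 0")
    if y_norm <= 0:
        raise ValueError("normal readout value must be > 0")
    return (y_pert - y_norm) / (p_pert - p_norm) * (p_norm / y_norm)


def period_sensitivity(
    tau_norm: float, tau_pert: float, p_norm: float, p_pert: float
) -> float:
    """Normalized period sensitivity S_tau (finite-difference form)."""
    return _normalized_sensitivity(tau_norm, tau_pert, p_norm, p_pert)


def amplitude_sensitivity(
    a_norm: float, a_pert: float, p_norm: float, p_pert: float
) -> float:
    """Normalized amplitude sensitivity S_A (finite-difference form)."""
    return _normalized_sensitivity(a_norm, a_pert, p_norm, p_pert)


def _parameter_pathways(model: PathwayModel) -> dict[str, str]:
    """Map each parameter to the pathway of the reactions that use it."""
    out: dict[str, str] = {}
    for rxn in model.reactions:
        laws = [rxn.rate_law] + ([rxn.rate_law_reverse] if rxn.reversible else [])
        for law in laws:
            if law is None:
                continue
            for pname in law.parameter_names():
                prev = out.get(pname)
                if prev is None:
                    out[pname] = rxn.pathway
                elif prev != rxn.pathway:
                    out[pname] = "shared"
    for pool in model.pools:
        out.setdefault(pool.total_param, "pool")
    return out


def _measure_readouts(
    model: PathwayModel, config: SimulationConfig, window: float
) -> dict[str, tuple[float, float]] | None:
    """(period, amplitude) per readout gene after re-burn-in; None if dead."""
    res = burn_in(model, config)
    work = model.copy()
    work.set_initial_state(res.state)
    traj = integrate(work, SimulationConfig(
        t_end=window, output_dt=config.output_dt,
        rel_tol=config.rel_tol, abs_tol=config.abs_tol,
        max_burn_in=config.max_burn_in,
    ))
    out = {}
    for gene, species in model.readouts.items():
        s = measure(traj, species)
        if not s.is_oscillating:
            return None
        out[gene] = (s.period, s.amplitude)
    return out


def sensitivity_scan(
    model: PathwayModel,
    parameters: Sequence[str] | None = None,
    levels: Iterable[float] = DEFAULT_LEVELS,
    config: SimulationConfig | None = None,
    window: float = 1200.0,
) -> list[SensitivityRecord]:
    """Scan every (parameter, level) pair, measuring each readout gene.

    Each parameter is perturbed one at a time to p*(1+level); the model is
    re-burned-in and re-measured.  The scan is fully deterministic.
    Raises ValueError if the reference model does not oscillate.
    """
    config = config or SimulationConfig()
    ref = _measure_readouts(model, config, window)
    if ref is None:
        raise ValueError("reference model does not oscillate; cannot scan")
    pathways = _parameter_pathways(model)
    if parameters is None:
        parameters = sorted(model.parameters.values)
    records: list[SensitivityRecord] = []
    for pname in parameters:
        p_norm = model.parameters[pname]
        for level in levels:
            if p_norm == 0.0:
                # an inert (zero) parameter cannot be perturbed multiplicatively
                for gene in model.readouts:
                    records.append(SensitivityRecord(
                        pname, gene, level, 0.0, 0.0, False, False,
                        SensitivityStatus.OK, pathways.get(pname, "")))
                continue
            p_pert = p_norm * (1.0 + level)
            work = model.copy()
            work.parameters[pname] = p_pert
            try:
                pert = _measure_readouts(work, config, window)
            except Exception:
                pert = "failed"
            for gene in model.readouts:
                if pert == "failed":
                    records.append(SensitivityRecord(
                        pname, gene, level, None, None, False, False,
                        SensitivityStatus.SOLVER_FAILED, pathways.get(pname, "")))
                elif pert is None:
                    records.append(SensitivityRecord(
                        pname, gene, level, None, None, False, False,
                        SensitivityStatus.OSCILLATION_LOST, pathways.get(pname, "")))
                else:
                    tau_n, a_n = ref[gene]
                    tau_p, a_p = pert[gene]
                    s_tau = period_sensitivity(tau_n, tau_p, p_norm, p_pert)
                    s_a = amplitude_sensitivity(a_n, a_p, p_norm, p_pert)
                    records.append(SensitivityRecord(
                        pname, gene, level, s_tau, s_a,
                        abs(s_tau) >= SIGNIFICANCE_THRESHOLD,
                        abs(s_a) >= SIGNIFICANCE_THRESHOLD,
                        SensitivityStatus.OK, pathways.get(pname, "")))
    return records


def significant(records: Iterable[SensitivityRecord]) -> list[SensitivityRecord]:
    """Records with |S_tau| >= 1 or |S_A| >= 1 (the significance rule)."""
    return [r for r in records if r.significant_tau or r.significant_a]


def records_to_frame(records: Iterable[SensitivityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "gene": r.gene,
                "level": r.level,
                "S_tau": r.s_tau,
                "S_A": r.s_a,
                "significant_tau": r.significant_tau,
                "significant_A": r.significant_a,
                "status": r.status.value,
                "pathway": r.pathway,
            }
            for r in records
        ]
    )
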
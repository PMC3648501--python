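"""Parameter learning: correlation fitness and PSO-embedded simulated annealing.

The fitness of a parameter set against a panel of target expression
profiles is

    S = sum_i (1 - corr(V~_i, V_i)),    i = 1..N target genes,

where corr is the Pearson correlation between the simulated profile V~_i
(sampled at the target's time points, after burn-in) and the target V_i.
S is 0 iff every gene correlates perfectly and at most 2N under perfect
anticorrelation.  Because the correlation is computed on matched absolute
time points across two or more cycles, the score is sensitive to relative
phase - intentionally, since the phase relations between target genes are
part of the biology being fitted.

The optimiser embeds simulated-annealing acceptance inside a particle
swarm: personal bests (and through them the global best) may be replaced
by a worse candidate with Metropolis probability exp(-dS/T), with T cooled
geometrically each iteration.  At T -> 0 this reduces to plain PSO.

The synthetic target generator emulates a microarray-style time course:
per-gene sinusoids on a coarse grid spanning about two cycles, with the
stated phase tags (in-phase genes at phase 0, antiphase genes shifted by
half a period) and optional multiplicative log-normal noise.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .network import ParameterSet, PathwayModel
from .simulate import SimulationConfig, Trajectory, burn_in, integrate

__all__ = [
    "ExpressionProfile",
    "FitnessSpec",
    "OptimizerConfig",
    "OptimizerResult",
    "pearson_corr",
    "fitness",
    "pso_sa_optimize",
    "generate_target_profiles",
    "PhaseTag",
    "DEFAULT_SOMITE_PHASES",
    "calibrate_reference",
    "profiles_to_csv",
    "profiles_from_csv",
]


class PhaseTag(str, enum.Enum):
    IN_PHASE = "in_phase"
    ANTIPHASE = "antiphase"


#: the segmentation-clock panel: Lfng/Hes7/Nkd1 cycle together, Axin2/Dll1
#: in antiphase with them
DEFAULT_SOMITE_PHASES = {
    "Lfng": PhaseTag.IN_PHASE,
    "Hes7": PhaseTag.IN_PHASE,
    "Nkd1": PhaseTag.IN_PHASE,
    "Axin2": PhaseTag.ANTIPHASE,
    "Dll1": PhaseTag.ANTIPHASE,
}


@dataclass
class ExpressionProfile:
    gene: str
    times: np.ndarray  # minutes, strictly increasing
    values: np.ndarray  # expression, arbitrary units
    source: str = "synthetic"  # synthetic | simulated | file

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times/values length mismatch")
        if len(self.times) < 3:
            raise ValueError("an expression profile needs >= 3 time points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("profile times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")


@dataclass
class FitnessSpec:
    """Target profiles plus the gene -> readout-species mapping."""

    profiles: list[ExpressionProfile]
    readouts: dict[str, str]  # gene -> mRNA species name

    def __post_init__(self) -> None:
        for prof in self.profiles:
            if prof.gene not in self.readouts:
                raise ValueError(f"no readout species mapped for {prof.gene!r}")

    @property
    def n_genes(self) -> int:
        return len(self.profiles)


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation coefficient of two equal-length profiles.

    Raises ValueError for length mismatch, fewer than two points, or when
    either profile is constant (undefined correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    if x.size < 2:
        raise ValueError("correlation needs at least 2 points")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = float(np.sqrt(np.sum(dx * dx)))
    sy = float(np.sqrt(np.sum(dy * dy)))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined for a constant profile")
    return float(np.sum(dx * dy) / (sx * sy))


def fitness(
    model: PathwayModel,
    params: ParameterSet | dict | None,
    spec: FitnessSpec,
    sim_config: SimulationConfig | None = None,
) -> float:
    """Correlation fitness S of ``params`` on ``model`` against targets.

    The model is burned in, then simulated over the targets' time span and
    sampled at their time points.  Dead oscillations and solver failures
    return the worst score 2N rather than raising, so a search never loses
    swarm members.
    """
    n = spec.n_genes
    worst = 2.0 * n
    work = model.copy()
    if params is not None:
        if isinstance(params, dict):
            params = ParameterSet(dict(params))
        work.parameters = params
    cfg = sim_config or SimulationConfig()
    try:
        res = burn_in(work, cfg)
        work.set_initial_state(res.state)
        t_max = max(float(p.times[-1]) for p in spec.profiles)
        run = SimulationConfig(
            t_end=t_max,
            output_dt=min(cfg.output_dt, 1.0),
            rel_tol=cfg.rel_tol,
            abs_tol=cfg.abs_tol,
            max_burn_in=cfg.max_burn_in,
        )
        traj = integrate(work, run)
    except Exception:
        return worst
    s = 0.0
    for prof in spec.profiles:
        species = spec.readouts[prof.gene]
        sim_vals = np.interp(prof.times, traj.times, traj[species])
        try:
            c = pearson_corr(sim_vals, prof.values)
        except ValueError:  # flat simulation = dead oscillation
            return worst
        s += 1.0 - c
    return float(s)


# ---------------------------------------------------------------------------
# synthetic target profiles
# ---------------------------------------------------------------------------


def generate_target_profiles(
    genes_with_phases: dict[str, PhaseTag | str] | None = None,
    period: float = 120.0,
    n_points: int = 13,
    span: float = 240.0,
    noise_sd: float = 0.0,
    baseline: float = 2.0,
    amplitude: float = 1.0,
    seed: int | None = None,
) -> list[ExpressionProfile]:
    """Sinusoidal expression profiles emulating a microarray time course.

    Each gene is ``baseline + amplitude * sin(2*pi*(t - phi)/period)`` with
    phi = 0 (in_phase) or period/2 (antiphase), sampled at ``n_points``
    uniform times over ``span`` (default two cycles), with multiplicative
    log-normal noise of standard deviation ``noise_sd``.
    """
    if genes_with_phases is None:
        genes_with_phases = dict(DEFAULT_SOMITE_PHASES)
    if n_points < 6:
        raise ValueError("n_points must be >= 6")
    if baseline <= amplitude:
        raise ValueError("baseline must exceed amplitude (nonnegative signal)")
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, span, n_points)
    profiles = []
    for gene, tag in genes_with_phases.items():
        tag = PhaseTag(tag)
        phi = 0.0 if tag is PhaseTag.IN_PHASE else period / 2.0
        values = baseline + amplitude * np.sin(2 * np.pi * (times - phi) / period)
        if noise_sd > 0:
            values = values * rng.lognormal(mean=0.0, sigma=noise_sd, size=n_points)
        profiles.append(ExpressionProfile(gene, times, values, source="synthetic"))
    return profiles


def profiles_to_csv(profiles: Sequence[ExpressionProfile], path_or_buf) -> None:
    rows = [
        {"gene": p.gene, "time_min": t, "value": v}
        for p in profiles
        for t, v in zip(p.times, p.values)
    ]
    pd.DataFrame(rows).to_csv(path_or_buf, index=False, float_format="%.10g")


def profiles_from_csv(path_or_buf) -> list[ExpressionProfile]:
    df = pd.read_csv(path_or_buf)
    need = {"gene", "time_min", "value"}
    if not need.issubset(df.columns):
        raise ValueError(f"profile CSV must have columns {sorted(need)}")
    out = []
    for gene, grp in df.groupby("gene", sort=False):
        grp = grp.sort_values("time_min")
        out.append(
            ExpressionProfile(
                str(gene), grp["time_min"].to_numpy(), grp["value"].to_numpy(),
                source="file",
            )
        )
    return out


# ---------------------------------------------------------------------------
# PSO-embedded simulated annealing
# ---------------------------------------------------------------------------


@dataclass
class OptimizerConfig:
    swarm_size: int = 30
    iterations: int = 200
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    initial_temperature: float = 1.0
    cooling: float = 0.95
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.cooling < 1.0):
            raise ValueError("cooling factor must be in (0, 1)")
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid bounds for {name!r}: [{lo}, {hi}]")


@dataclass
class OptimizerResult:
    best_params: dict[str, float]
    best_score: float
    trace: np.ndarray  # accepted global-best score per iteration
    n_evaluations: int
    converged: bool
    seed: int


def pso_sa_optimize(
    objective: Callable[[dict[str, float]], float],
    config: OptimizerConfig,
) -> OptimizerResult:
    """Minimise ``objective`` over the bound box with PSO + SA acceptance.

    Standard PSO velocity/position updates with reflection at the bounds;
    the SA embedding lets a worse candidate replace a particle's personal
    best (and, through the personal bests, the published global best) with
    Metropolis probability exp(-dS/T).  The temperature cools geometrically
    per iteration, so the trace of the published best is monotone
    non-increasing once T is negligible.  Fully reproducible under seed.
    """
    if not config.bounds:
        raise ValueError("optimizer bounds must not be empty")
    rng = np.random.default_rng(config.seed)
    names = list(config.bounds)
    lo = np.array([config.bounds[n][0] for n in names])
    hi = np.array([config.bounds[n][1] for n in names])
    dim = len(names)
    ns = config.swarm_size

    def as_dict(x: np.ndarray) -> dict[str, float]:
        return {n: float(v) for n, v in zip(names, x)}

    pos = lo + rng.random((ns, dim)) * (hi - lo)
    vel = (rng.random((ns, dim)) - 0.5) * (hi - lo) * 0.2
    scores = np.array([float(objective(as_dict(x))) for x in pos])
    n_eval = ns

    pbest = pos.copy()
    pbest_s = scores.copy()
    g = int(np.argmin(pbest_s))
    gbest, gbest_s = pbest[g].copy(), float(pbest_s[g])
    # true incumbent: best ever seen, immune to SA acceptance of worse bests
    inc, inc_s = gbest.copy(), gbest_s

    temperature = config.initial_temperature
    trace = np.empty(max(config.iterations, 0))

    for it in range(config.iterations):
        r1 = rng.random((ns, dim))
        r2 = rng.random((ns, dim))
        vel = (
            config.inertia * vel
            + config.cognitive * r1 * (pbest - pos)
            + config.social * r2 * (gbest - pos)
        )
        pos = pos + vel
        # reflect at the bounds
        over_lo = pos < lo
        over_hi = pos > hi
        pos = np.where(over_lo, 2 * lo - pos, pos)
        pos = np.where(over_hi, 2 * hi - pos, pos)
        pos = np.clip(pos, lo, hi)  # guard against double reflection
        vel = np.where(over_lo | over_hi, -vel, vel)

        scores = np.array([float(objective(as_dict(x))) for x in pos])
        n_eval += ns

        for i in range(ns):
            ds = scores[i] - pbest_s[i]
            if ds <= 0 or (
                temperature > 0 and rng.random() < np.exp(-ds / temperature)
            ):
                pbest[i] = pos[i]
                pbest_s[i] = scores[i]
            if scores[i] < inc_s:
                inc, inc_s = pos[i].copy(), float(scores[i])
        g = int(np.argmin(pbest_s))
        gbest, gbest_s = pbest[g].copy(), float(pbest_s[g])
        # the trace records the *accepted* global best: at high temperature it
        # may rise (a worse best was accepted); once T ~ 0 it is monotone
        trace[it] = gbest_s
        temperature *= config.cooling

    if config.iterations == 0:
        trace = np.array([inc_s])
    return OptimizerResult(
        best_params=as_dict(inc),
        best_score=inc_s,
        trace=trace,
        n_evaluations=n_eval,
        converged=config.iterations > 0,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# reference calibration
# ---------------------------------------------------------------------------


def calibrate_reference(
    model_factory: Callable[[dict | None], PathwayModel],
    spec: FitnessSpec,
    config: OptimizerConfig,
    base_params: dict[str, float] | None = None,
    sim_config: SimulationConfig | None = None,
    phenotype_filter: Callable[[dict[str, float]], bool] | None = None,
) -> tuple[ParameterSet, dict]:
    """Fit free parameters against targets, optionally phenotype-filtered.

    Free parameters are the keys of ``config.bounds``; all others stay at
    ``base_params`` (or the model's reference values).  Returns the fitted
    ParameterSet and a provenance report (seed, config, final S).  When a
    phenotype filter is given and the optimum fails it, the result is
    flagged rather than silently accepted.
    """
    template = model_factory(base_params)
    fixed = dict(template.parameters.values)

    def obj(free: dict[str, float]) -> float:
        candidate = {**fixed, **free}
        return fitness(template, candidate, spec, sim_config)

    result = pso_sa_optimize(obj, config)
    fitted = {**fixed, **result.best_params}
    ok_phenotype = True
    if phenotype_filter is not None:
        ok_phenotype = bool(phenotype_filter(fitted))
    report = {
        "seed": config.seed,
        "iterations": config.iterations,
        "swarm_size": config.swarm_size,
        "n_evaluations": result.n_evaluations,
        "final_S": result.best_score,
        "converged": result.converged,
        "phenotype_pass": ok_phenotype,
        "free_parameters": sorted(config.bounds),
    }
    return ParameterSet(fitted, provenance="reference_calibrated"), report
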
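"""Compartmented reaction-network core.

A :class:`PathwayModel` is a list of species (each living in one of four
compartments), a list of reactions with symbolic rate laws, a parameter set,
piecewise-constant external inputs (the extracellular Wnt level, or the
constitutive Dll1 supply of the isolated Notch model) and conserved pools
(total RBP-j, total GSK3, total Dsh) that are represented algebraically
rather than as ODEs.  ``compile_rhs`` turns the network into a fast ODE
right-hand side; ``apply_perturbation`` implements timed in-silico
interventions (gene knockout, input removal/scaling, overexpression).

Knockout semantics: a gene knockout zeroes the gene's transcription Vmax at
the event time; existing mRNA and protein decay through their normal
degradation reactions afterwards.
"""

from __future__ import annotations

import copy as _copy
import enum
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .kinetics import RateLaw, RateLawForm

__all__ = [
    "Compartment",
    "SpeciesRole",
    "Species",
    "Reaction",
    "ParameterSet",
    "ConservedPool",
    "PathwayModel",
    "PerturbationKind",
    "Perturbation",
    "compile_rhs",
    "apply_perturbation",
    "validate",
    "ModelValidationError",
]


class Compartment(str, enum.Enum):
    EXTRACELLULAR = "extracellular"
    MEMBRANE = "membrane"
    CYTOPLASM = "cytoplasm"
    NUCLEUS = "nucleus"


class SpeciesRole(str, enum.Enum):
    MRNA = "mRNA"
    PROTEIN = "protein"
    COMPLEX = "complex"
    INPUT = "input"


@dataclass
class Species:
    name: str
    compartment: Compartment
    role: SpeciesRole
    is_dynamic: bool = True
    initial_value: float = 0.0


@dataclass
class Reaction:
    """One reaction; reversible reactions carry separate forward/backward laws.

    ``kind`` tags the biological step (synthesis, transcription, translation,
    transport, shuttling, binding, cleavage, conversion, degradation) and is
    what the perturbation machinery and the sensitivity report key on;
    ``gene`` names the gene for transcription/translation steps; ``pathway``
    is "notch", "wnt" or "crosstalk".
    """

    name: str
    reactants: dict[str, int] = field(default_factory=dict)
    products: dict[str, int] = field(default_factory=dict)
    modifiers: list[str] = field(default_factory=list)
    rate_law: RateLaw | None = None
    reversible: bool = False
    rate_law_reverse: RateLaw | None = None
    kind: str = ""
    gene: str | None = None
    pathway: str = ""
    note: str = ""


@dataclass
class ParameterSet:
    """Named nonnegative constants with units 1/min, a.u./min or a.u."""

    values: dict[str, float] = field(default_factory=dict)
    provenance: str = "user"  # reference_calibrated | user | literature

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __setitem__(self, name: str, value: float) -> None:
        self.values[name] = float(value)

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def copy(self) -> "ParameterSet":
        return ParameterSet(dict(self.values), self.provenance)


@dataclass
class ConservedPool:
    """Algebraic conservation: free = total - sum(bound dynamic species).

    The free concentration is exposed to rate laws under ``free_name`` and is
    never integrated, so the conservation law holds exactly by construction.
    """

    name: str
    total_param: str
    free_name: str
    bound_species: list[str]


@dataclass
class PathwayModel:
    model_id: str
    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    parameters: ParameterSet = field(default_factory=ParameterSet)
    inputs: dict[str, float] = field(default_factory=dict)
    pools: list[ConservedPool] = field(default_factory=list)
    target_genes: list[str] = field(default_factory=list)
    readouts: dict[str, str] = field(default_factory=dict)

    # -- bookkeeping --------------------------------------------------------
    def dynamic_species(self) -> list[Species]:
        return [s for s in self.species if s.is_dynamic]

    def dynamic_names(self) -> list[str]:
        return [s.name for s in self.species if s.is_dynamic]

    def species_by_name(self, name: str) -> Species:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_value for s in self.dynamic_species()])

    def set_initial_state(self, state: np.ndarray) -> None:
        dyn = self.dynamic_species()
        if len(state) != len(dyn):
            raise ValueError("state length mismatch")
        for s, v in zip(dyn, state):
            s.initial_value = float(v)

    def copy(self) -> "PathwayModel":
        return _copy.deepcopy(self)

    def pool_value(self, pool: ConservedPool, state: np.ndarray) -> float:
        """Total of a conserved pool evaluated from a state vector."""
        idx = {n: i for i, n in enumerate(self.dynamic_names())}
        return float(sum(state[idx[b]] for b in pool.bound_species))

    def compile_rhs(self) -> Callable[[np.ndarray, float], np.ndarray]:
        return compile_rhs(self)

    def validate(self) -> list[str]:
        return validate(self)


class ModelValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------


class PerturbationKind(str, enum.Enum):
    KNOCKOUT_GENE = "knockout_gene"
    KNOCKOUT_SPECIES = "knockout_species"
    REMOVE_INPUT = "remove_input"
    SCALE_INPUT = "scale_input"
    OVEREXPRESS_GENE = "overexpress_gene"


@dataclass
class Perturbation:
    kind: PerturbationKind
    target: str
    time: float = 0.0
    factor: float | None = None

    def __post_init__(self) -> None:
        self.kind = PerturbationKind(self.kind)
        if self.time < 0:
            raise ValueError("perturbation time must be >= 0")
        needs_factor = self.kind in (
            PerturbationKind.SCALE_INPUT,
            PerturbationKind.OVEREXPRESS_GENE,
        )
        if needs_factor:
            if self.factor is None or self.factor <= 0:
                raise ValueError(f"{self.kind.value} requires a positive factor")
        elif self.factor is not None:
            raise ValueError(f"{self.kind.value} takes no factor")


def _transcription_vmax_params(model: PathwayModel, gene: str) -> list[str]:
    names: list[str] = []
    for rxn in model.reactions:
        # a gene's supply step: true transcription, or the constant-rate
        # synthesis standing in for it in the isolated Notch model
        if rxn.kind in ("transcription", "synthesis") and rxn.gene == gene:
            base = rxn.rate_law
            if base is None:
                continue
            if base.form is RateLawForm.COMPOSITE:
                base = base.factors[0]
            names.extend(
                pname for slot, pname in base.constants.items() if slot != "hill_n"
            )
    return names


def _synthesis_rate_params(model: PathwayModel, species: str) -> list[str]:
    names: list[str] = []
    for rxn in model.reactions:
        if rxn.kind == "synthesis" and species in rxn.products:
            if rxn.rate_law is not None:
                names.extend(rxn.rate_law.parameter_names())
    return names


def apply_perturbation(model: PathwayModel, p: Perturbation) -> PathwayModel:
    """Return a modified copy of the model with the intervention applied.

    The event time is handled by the simulator (segment restart); this
    function applies only the structural change.
    """
    out = model.copy()
    if p.kind is PerturbationKind.KNOCKOUT_GENE:
        names = _transcription_vmax_params(out, p.target)
        if not names:
            raise KeyError(f"no transcription reaction for gene {p.target!r}")
        for n in names:
            out.parameters[n] = 0.0
    elif p.kind is PerturbationKind.OVEREXPRESS_GENE:
        names = _transcription_vmax_params(out, p.target)
        if not names:
            raise KeyError(f"no transcription reaction for gene {p.target!r}")
        for n in names:
            out.parameters[n] = out.parameters[n] * p.factor
    elif p.kind is PerturbationKind.KNOCKOUT_SPECIES:
        names = _synthesis_rate_params(out, p.target)
        if not names:
            raise KeyError(f"no synthesis reaction for species {p.target!r}")
        for n in names:
            out.parameters[n] = 0.0
    elif p.kind is PerturbationKind.REMOVE_INPUT:
        if p.target not in out.inputs:
            raise KeyError(f"unknown input {p.target!r}")
        out.inputs[p.target] = 0.0
    elif p.kind is PerturbationKind.SCALE_INPUT:
        if p.target not in out.inputs:
            raise KeyError(f"unknown input {p.target!r}")
        out.inputs[p.target] = out.inputs[p.target] * p.factor
    else:  # pragma: no cover
        raise ValueError(f"unknown perturbation kind {p.kind}")
    return out


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate(model: PathwayModel) -> list[str]:
    """Return a report of violated invariants (empty iff the model is valid)."""
    report: list[str] = []
    names = [s.name for s in model.species]
    seen = set()
    for n in names:
        if n in seen:
            report.append(f"duplicate species name {n!r}")
        seen.add(n)

    by_name = {s.name: s for s in model.species}
    for s in model.species:
        if s.role is SpeciesRole.MRNA and s.compartment is Compartment.EXTRACELLULAR:
            report.append(f"mRNA species {s.name!r} in extracellular compartment")
        if s.initial_value < 0:
            report.append(f"species {s.name!r} has negative initial value")

    algebraic = {p.free_name for p in model.pools} | set(model.inputs)
    known = set(names) | algebraic

    for pool in model.pools:
        if pool.total_param not in model.parameters:
            report.append(
                f"pool {pool.name!r} total parameter {pool.total_param!r} missing"
            )
        for b in pool.bound_species:
            if b not in by_name:
                report.append(f"pool {pool.name!r} member {b!r} unknown")

    for rxn in model.reactions:
        for sp, st in {**rxn.reactants, **rxn.products}.items():
            if sp not in by_name:
                report.append(f"reaction {rxn.name!r} references unknown species {sp!r}")
            if not (isinstance(st, int) and st > 0):
                report.append(
                    f"reaction {rxn.name!r} has non-positive-integer stoichiometry for {sp!r}"
                )
        for m in rxn.modifiers:
            if m not in known:
                report.append(f"reaction {rxn.name!r} modifier {m!r} unknown")
            net = rxn.products.get(m, 0) - rxn.reactants.get(m, 0)
            if net != 0:
                report.append(f"reaction {rxn.name!r} modifier {m!r} is consumed")
        laws = [rxn.rate_law] + ([rxn.rate_law_reverse] if rxn.reversible else [])
        for law in laws:
            if law is None:
                report.append(f"reaction {rxn.name!r} missing a rate law")
                continue
            for pname in law.parameter_names():
                if pname not in model.parameters:
                    report.append(
                        f"reaction {rxn.name!r} missing parameter {pname!r}"
                    )
                elif model.parameters[pname] < 0:
                    report.append(
                        f"parameter {pname!r} is negative ({model.parameters[pname]})"
                    )
            for sname in law.species_names():
                if sname not in known:
                    report.append(
                        f"reaction {rxn.name!r} rate law references unknown name {sname!r}"
                    )
        if rxn.kind == "degradation":
            for sp in rxn.reactants:
                s = by_name.get(sp)
                if (
                    s is not None
                    and s.role is SpeciesRole.MRNA
                    and s.compartment is not Compartment.CYTOPLASM
                ):
                    report.append(
                        f"mRNA degradation {rxn.name!r} acts outside the cytoplasm"
                    )
    return report


# ---------------------------------------------------------------------------
# ODE compilation (python code generation for speed)
# ---------------------------------------------------------------------------


def _law_expr(law: RateLaw, sym: dict[str, str], params: ParameterSet) -> str:
    """Render a rate law as a python expression over pre-clamped symbols."""
    form = law.form
    if form is RateLawForm.MASS_ACTION:
        k = params[law.constants["k"]]
        terms = [repr(k)] + [sym[s] for s in law.species]
        return "*".join(terms)
    if form is RateLawForm.MICHAELIS_MENTEN:
        vmax = params[law.constants["vmax"]]
        km = params[law.constants["km"]]
        s = sym[law.species[0]]
        return f"{vmax!r}*{s}/({km!r}+{s})"
    if form is RateLawForm.HILL_ACTIVATION:
        k = params[law.constants["k_half"]]
        n = float(law.constants["hill_n"])
        x = sym[law.species[0]]
        return f"({x}**{n!r}/({k!r}**{n!r}+{x}**{n!r}))"
    if form is RateLawForm.HILL_REPRESSION:
        k = params[law.constants["k_half"]]
        n = float(law.constants["hill_n"])
        x = sym[law.species[0]]
        return f"({k!r}**{n!r}/({k!r}**{n!r}+{x}**{n!r}))"
    if form is RateLawForm.POOL_FRACTION:
        total = params[law.constants["total"]]
        return f"({sym[law.species[0]]}/{total!r})"
    if form is RateLawForm.COMPOSITE:
        return "*".join(f"({_law_expr(f, sym, params)})" for f in law.factors)
    if form is RateLawForm.OPAQUE:
        import re

        expr = law.expression
        subs = {s: sym[s] for s in law.species}
        subs.update({p: repr(params[p]) for p in law.constants.values()})
        names = sorted(subs, key=len, reverse=True)
        pattern = re.compile(r"\b(" + "|".join(re.escape(n) for n in names) + r")\b")
        return "(" + pattern.sub(lambda m: subs[m.group(1)], expr) + ")"
    raise ValueError(f"cannot compile rate-law form {form}")


def compile_rhs(model: PathwayModel) -> Callable[[np.ndarray, float], np.ndarray]:
    """Compile the network to ``rhs(t, y) -> dy`` (scipy solve_ivp signature).

    Parameter and input values are baked in as literals, so the compiled
    function must be regenerated after any parameter change (perturbations do
    this via segment restart).  Concentrations are clamped at zero inside
    rate expressions so small solver undershoots cannot produce NaNs.
    """
    problems = validate(model)
    if problems:
        raise ModelValidationError("; ".join(problems))

    dyn = model.dynamic_names()
    index = {n: i for i, n in enumerate(dyn)}
    params = model.parameters

    # symbol table: dynamic species -> clamped locals; pools -> algebraic;
    # inputs -> literal constants
    sym: dict[str, str] = {}
    lines: list[str] = []
    for n, i in index.items():
        sym[n] = f"s{i}"
        lines.append(f"    s{i} = y[{i}] if y[{i}] > 0.0 else 0.0")
    for pool in model.pools:
        total = params[pool.total_param]
        bound = "+".join(sym[b] for b in pool.bound_species)
        expr = f"{total!r}-({bound})"
        lines.append(f"    {pool.free_name} = {expr} if ({expr}) > 0.0 else 0.0")
        sym[pool.free_name] = pool.free_name
    for name, value in model.inputs.items():
        sym[name] = repr(float(value))

    # reaction fluxes
    deriv_terms: dict[int, list[str]] = {i: [] for i in index.values()}
    for ri, rxn in enumerate(model.reactions):
        fwd = _law_expr(rxn.rate_law, sym, params)
        if rxn.reversible:
            back = _law_expr(rxn.rate_law_reverse, sym, params)
            lines.append(f"    v{ri} = ({fwd}) - ({back})")
        else:
            lines.append(f"    v{ri} = {fwd}")
        for sp, st in rxn.reactants.items():
            if model.species_by_name(sp).is_dynamic:
                deriv_terms[index[sp]].append(f"-{st}*v{ri}" if st != 1 else f"-v{ri}")
        for sp, st in rxn.products.items():
            if model.species_by_name(sp).is_dynamic:
                deriv_terms[index[sp]].append(f"+{st}*v{ri}" if st != 1 else f"+v{ri}")

    for i in range(len(dyn)):
        expr = "".join(deriv_terms[i]) or "0.0"
        lines.append(f"    dy[{i}] = {expr}")

    src = (
        "def _rhs(t, y, _np=__np):\n"
        f"    dy = _np.empty({len(dyn)})\n" + "\n".join(lines) + "\n    return dy\n"
    )
    ns: dict = {"__np": np, "math": math}
    exec(src, ns)  # noqa: S102 - generated from validated model structure
    fn = ns["_rhs"]
    fn.__doc__ = f"compiled rhs for model {model.model_id!r}"
    fn._source = src  # kept for debugging
    return fn
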
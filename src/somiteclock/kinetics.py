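"""Closed-form rate-law primitives.

Every reaction rate in the segmentation-clock models is composed from four
primitives: mass action, Michaelis-Menten, and the activating/repressing Hill
factors.  Time is in minutes and concentrations in arbitrary units (a.u.)
throughout; Hill factors are dimensionless.

The "negative Hill coefficient" convention used for repressors (e.g. Lfng
binding Notch at two sites, written as coefficient -2) is implemented as the
repression form K^n / (K^n + x^n).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "RateLawForm",
    "RateLaw",
    "mass_action_rate",
    "michaelis_menten_rate",
    "hill_activation",
    "hill_repression",
]


class RateLawForm(str, enum.Enum):
    MASS_ACTION = "mass_action"
    MICHAELIS_MENTEN = "michaelis_menten"
    HILL_ACTIVATION = "hill_activation"
    HILL_REPRESSION = "hill_repression"
    POOL_FRACTION = "pool_fraction"
    COMPOSITE = "composite"
    OPAQUE = "opaque"


def mass_action_rate(k: float, concentrations: Sequence[float]) -> float:
    """Rate k * prod(concentrations) in a.u./min (or 1/min units folded into k).

    Raises ValueError on a negative rate constant or concentration.
    """
    if k < 0:
        raise ValueError(f"mass-action rate constant must be >= 0, got {k}")
    rate = k
    for c in concentrations:
        if c < 0:
            raise ValueError(f"negative concentration {c} in mass-action rate")
        rate *= c
    return rate


def michaelis_menten_rate(vmax: float, km: float, s: float) -> float:
    """Saturating degradation/conversion rate Vmax * s / (Km + s).

    Bounded above by Vmax and monotone increasing in the substrate s.
    """
    if vmax < 0:
        raise ValueError(f"Vmax must be >= 0, got {vmax}")
    if km <= 0:
        raise ValueError(f"Km must be > 0, got {km}")
    if s < 0:
        raise ValueError(f"negative substrate concentration {s}")
    return vmax * s / (km + s)


def hill_activation(x: float, k: float, n: float) -> float:
    """Dimensionless activation factor x^n / (K^n + x^n) in [0, 1).

    Value 0.5 at x = K; n is the number of effector binding sites (1 for Dll1
    on Notch, 2 for the transcriptional activator complexes on their target
    promoters).
    """
    if k <= 0:
        raise ValueError(f"half-activation constant K must be > 0, got {k}")
    if n < 1:
        raise ValueError(f"Hill coefficient must be >= 1, got {n}")
    if x < 0:
        raise ValueError(f"negative effector concentration {x}")
    if x == 0.0:
        return 0.0
    # evaluate via (K/x)^n for numerical symmetry with hill_repression
    try:
        r = math.pow(k / x, n)
    except OverflowError:
        return 0.0
    if math.isinf(r):
        return 0.0
    return 1.0 / (1.0 + r)


def hill_repression(x: float, k: float, n: float) -> float:
    """Dimensionless repression factor K^n / (K^n + x^n) in (0, 1].

    The "Hill coefficient -n" convention: value 1 with no repressor, 0.5 at
    x = K, strictly decreasing in x.  Complementary to hill_activation:
    hill_activation(x, K, n) + hill_repression(x, K, n) == 1.
    """
    if k <= 0:
        raise ValueError(f"half-repression constant K must be > 0, got {k}")
    if n < 1:
        raise ValueError(f"Hill coefficient must be >= 1, got {n}")
    if x < 0:
        raise ValueError(f"negative repressor concentration {x}")
    if x == 0.0:
        return 1.0
    try:
        r = math.pow(k / x, n)
    except OverflowError:
        return 1.0
    if math.isinf(r):
        return 1.0
    return r / (1.0 + r)


@dataclass
class RateLaw:
    """Symbolic rate law: form + named constants + species references.

    ``constants`` maps the law's own slot names (k, vmax, km, k_half, hill_n)
    to parameter names resolved against the model's ParameterSet at compile
    time.  ``species`` lists the species (or algebraic pool / input) names the
    law reads, in the order the form expects:

    - mass_action:       any number of multiplied concentrations
    - michaelis_menten:  exactly one substrate
    - hill_activation / hill_repression: exactly one effector
    - pool_fraction:     exactly one species; factor = species / total-constant
    - composite:         species ignored; rate = factors[0] * factors[1] * ...
      where factors[0] is a base (mass_action or michaelis_menten) and the
      rest are dimensionless factors (hill_* or pool_fraction)
    - opaque:            an arbitrary python arithmetic expression over the
      names in ``species`` and ``constants`` (used for imported kinetic laws
      that do not match the native grammar); stored in ``expression``
    """

    form: RateLawForm
    constants: dict[str, str] = field(default_factory=dict)
    species: list[str] = field(default_factory=list)
    factors: list["RateLaw"] = field(default_factory=list)
    expression: str | None = None

    # -- constructors -------------------------------------------------------
    @staticmethod
    def mass_action(k: str, species: Sequence[str]) -> "RateLaw":
        return RateLaw(RateLawForm.MASS_ACTION, {"k": k}, list(species))

    @staticmethod
    def michaelis_menten(vmax: str, km: str, substrate: str) -> "RateLaw":
        return RateLaw(
            RateLawForm.MICHAELIS_MENTEN, {"vmax": vmax, "km": km}, [substrate]
        )

    @staticmethod
    def hill_act(effector: str, k_half: str, n: int) -> "RateLaw":
        return RateLaw(
            RateLawForm.HILL_ACTIVATION,
            {"k_half": k_half, "hill_n": str(n)},
            [effector],
        )

    @staticmethod
    def hill_rep(effector: str, k_half: str, n: int) -> "RateLaw":
        return RateLaw(
            RateLawForm.HILL_REPRESSION,
            {"k_half": k_half, "hill_n": str(n)},
            [effector],
        )

    @staticmethod
    def pool_fraction(species: str, total: str) -> "RateLaw":
        return RateLaw(RateLawForm.POOL_FRACTION, {"total": total}, [species])

    @staticmethod
    def opaque(expression: str, species: Sequence[str], parameters: Sequence[str]) -> "RateLaw":
        return RateLaw(
            RateLawForm.OPAQUE,
            {p: p for p in parameters},
            list(species),
            expression=expression,
        )

    @staticmethod
    def composite(base: "RateLaw", *factors: "RateLaw") -> "RateLaw":
        for f in factors:
            if f.form not in (
                RateLawForm.HILL_ACTIVATION,
                RateLawForm.HILL_REPRESSION,
                RateLawForm.POOL_FRACTION,
            ):
                raise ValueError(
                    f"composite factors must be dimensionless, got {f.form}"
                )
        return RateLaw(RateLawForm.COMPOSITE, {}, [], [base, *factors])

    # -- introspection ------------------------------------------------------
    def parameter_names(self) -> list[str]:
        """All ParameterSet names this law references (hill_n is a literal)."""
        names = []
        for slot, pname in self.constants.items():
            if slot != "hill_n":
                names.append(pname)
        for f in self.factors:
            names.extend(f.parameter_names())
        return names

    def species_names(self) -> list[str]:
        names = list(self.species)
        for f in self.factors:
            names.extend(f.species_names())
        return names

    def evaluate(self, conc: dict[str, float], params: dict[str, float]) -> float:
        """Reference (slow) evaluator used for validation and SBML checks."""
        form = self.form
        if form is RateLawForm.MASS_ACTION:
            return mass_action_rate(
                params[self.constants["k"]], [conc[s] for s in self.species]
            )
        if form is RateLawForm.MICHAELIS_MENTEN:
            return michaelis_menten_rate(
                params[self.constants["vmax"]],
                params[self.constants["km"]],
                conc[self.species[0]],
            )
        if form is RateLawForm.HILL_ACTIVATION:
            return hill_activation(
                conc[self.species[0]],
                params[self.constants["k_half"]],
                float(self.constants["hill_n"]),
            )
        if form is RateLawForm.HILL_REPRESSION:
            return hill_repression(
                conc[self.species[0]],
                params[self.constants["k_half"]],
                float(self.constants["hill_n"]),
            )
        if form is RateLawForm.POOL_FRACTION:
            total = params[self.constants["total"]]
            if total <= 0:
                raise ValueError("pool total must be > 0")
            return conc[self.species[0]] / total
        if form is RateLawForm.COMPOSITE:
            rate = 1.0
            for f in self.factors:
                rate *= f.evaluate(conc, params)
            return rate
        if form is RateLawForm.OPAQUE:
            env = {s: conc[s] for s in self.species}
            env.update({p: params[p] for p in self.constants.values()})
            env["pow"] = math.pow
            return float(eval(self.expression, {"__builtins__": {}}, env))  # noqa: S307
        raise ValueError(f"unknown rate-law form {form}")
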
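"""SBML Level 2 Version 4 export/import for pathway models.

The document layout follows the conventions of the CellDesigner-era
toolchain: compartments for extracellular space, membrane, cytoplasm and
nucleus; one SBML species per model species; global parameters; kinetic
laws written as explicit MathML trees for the rate-law grammar (mass
action, Michaelis-Menten, Hill activation/repression, pool fractions and
their products).  Model-specific conventions:

- external inputs (Wnt, the constant Dll1 supply signal) are exported as
  constant boundary species in the extracellular compartment;
- conserved pools (total RBP-j, GSK3, Dsh, Lef1) are exported as boundary
  species whose value is set by an assignmentRule ``free = total - sum of
  bound forms``, with the total a global parameter;
- reversible reactions carry ``fwd - back`` kinetic laws.

On import, kinetic-law MathML is matched back onto the native grammar;
math that does not match is wrapped in an opaque rate law (simulatable,
not introspectable) and reported in the import warnings.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

from lxml import etree

from .kinetics import RateLaw, RateLawForm
from .network import (
    Compartment,
    ConservedPool,
    ParameterSet,
    PathwayModel,
    Reaction,
    Species,
    SpeciesRole,
    validate,
)

__all__ = ["export_sbml", "import_sbml", "SBMLError", "read_sbml", "write_sbml"]

SBML_NS = "http://www.sbml.org/sbml/level2/version4"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
NSMAP = {None: SBML_NS}
M = "{%s}" % MATHML_NS
S = "{%s}" % SBML_NS


class SBMLError(ValueError):
    pass


# ---------------------------------------------------------------------------
# MathML construction
# ---------------------------------------------------------------------------


def _ci(name: str) -> etree._Element:
    el = etree.Element(M + "ci")
    el.text = " " + name + " "
    return el


def _cn(value: float) -> etree._Element:
    el = etree.Element(M + "cn")
    if value == int(value) and abs(value) < 1e15:
        el.text = " " + repr(int(value)) + " "
        if int(value) != value:  # pragma: no cover - defensive
            el.set("type", "real")
    else:
        el.text = " " + repr(float(value)) + " "
        el.set("type", "real")
    return el


def _apply(op: str, *args: etree._Element) -> etree._Element:
    el = etree.Element(M + "apply")
    el.append(etree.Element(M + op))
    for a in args:
        el.append(a)
    return el


def _pow(base: etree._Element, n: float) -> etree._Element:
    return _apply("power", base, _cn(n))


def _law_mathml(law: RateLaw) -> etree._Element:
    form = law.form
    if form is RateLawForm.MASS_ACTION:
        args = [_ci(law.constants["k"])] + [_ci(s) for s in law.species]
        if len(args) == 1:
            return args[0]
        return _apply("times", *args)
    if form is RateLawForm.MICHAELIS_MENTEN:
        s = law.species[0]
        num = _apply("times", _ci(law.constants["vmax"]), _ci(s))
        den = _apply("plus", _ci(law.constants["km"]), _ci(s))
        return _apply("divide", num, den)
    if form is RateLawForm.HILL_ACTIVATION:
        x, k = law.species[0], law.constants["k_half"]
        n = float(law.constants["hill_n"])
        return _apply(
            "divide", _pow(_ci(x), n), _apply("plus", _pow(_ci(k), n), _pow(_ci(x), n))
        )
    if form is RateLawForm.HILL_REPRESSION:
        x, k = law.species[0], law.constants["k_half"]
        n = float(law.constants["hill_n"])
        return _apply(
            "divide", _pow(_ci(k), n), _apply("plus", _pow(_ci(k), n), _pow(_ci(x), n))
        )
    if form is RateLawForm.POOL_FRACTION:
        return _apply("divide", _ci(law.species[0]), _ci(law.constants["total"]))
    if form is RateLawForm.COMPOSITE:
        return _apply("times", *[_law_mathml(f) for f in law.factors])
    raise SBMLError(f"cannot export rate-law form {form.value!r} to SBML")


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def export_sbml(model: PathwayModel) -> bytes:
    """Serialize a validated model to an SBML L2V4 document (UTF-8 bytes)."""
    problems = validate(model)
    if problems:
        raise SBMLError("model invalid: " + "; ".join(problems))

    root = etree.Element(S + "sbml", nsmap=NSMAP)
    root.set("level", "2")
    root.set("version", "4")
    mdl = etree.SubElement(root, S + "model")
    mdl.set("id", model.model_id or "pathway_model")

    used = {sp.compartment.value for sp in model.species} | {"extracellular"}
    loc = etree.SubElement(mdl, S + "listOfCompartments")
    for comp in Compartment:
        if comp.value in used:
            c = etree.SubElement(loc, S + "compartment")
            c.set("id", comp.value)
            c.set("size", "1")

    los = etree.SubElement(mdl, S + "listOfSpecies")

    def add_species(sid, comp, value, boundary=False, constant=False, role=None):
        sp = etree.SubElement(los, S + "species")
        sp.set("id", sid)
        sp.set("compartment", comp)
        sp.set("initialConcentration", repr(float(value)))
        if boundary:
            sp.set("boundaryCondition", "true")
        if constant:
            sp.set("constant", "true")
        if role is not None:
            sp.set("sboTerm", _ROLE_TO_SBO[role])
        return sp

    for s in model.species:
        add_species(s.name, s.compartment.value, s.initial_value, role=s.role)
    for name, value in model.inputs.items():
        add_species(name, "extracellular", value, boundary=True, constant=True,
                    role=SpeciesRole.INPUT)
    for pool in model.pools:
        add_species(pool.free_name, "cytoplasm", 0.0, boundary=True)

    lop = etree.SubElement(mdl, S + "listOfParameters")
    for pname in sorted(model.parameters.values):
        par = etree.SubElement(lop, S + "parameter")
        par.set("id", pname)
        par.set("value", repr(float(model.parameters[pname])))

    if model.pools:
        lor = etree.SubElement(mdl, S + "listOfRules")
        for pool in model.pools:
            rule = etree.SubElement(lor, S + "assignmentRule")
            rule.set("variable", pool.free_name)
            math = etree.SubElement(rule, M + "math")
            bound = [_ci(b) for b in pool.bound_species]
            total = _ci(pool.total_param)
            if len(bound) == 1:
                expr = _apply("minus", total, bound[0])
            else:
                expr = _apply("minus", total, _apply("plus", *bound))
            math.append(expr)

    lorx = etree.SubElement(mdl, S + "listOfReactions")
    for rxn in model.reactions:
        r = etree.SubElement(lorx, S + "reaction")
        r.set("id", rxn.name)
        r.set("reversible", "true" if rxn.reversible else "false")
        if rxn.reactants:
            lr = etree.SubElement(r, S + "listOfReactants")
            for spn, st in rxn.reactants.items():
                ref = etree.SubElement(lr, S + "speciesReference")
                ref.set("species", spn)
                ref.set("stoichiometry", str(st))
        if rxn.products:
            lp = etree.SubElement(r, S + "listOfProducts")
            for spn, st in rxn.products.items():
                ref = etree.SubElement(lp, S + "speciesReference")
                ref.set("species", spn)
                ref.set("stoichiometry", str(st))
        if rxn.modifiers:
            lm = etree.SubElement(r, S + "listOfModifiers")
            for spn in rxn.modifiers:
                ref = etree.SubElement(lm, S + "modifierSpeciesReference")
                ref.set("species", spn)
        kl = etree.SubElement(r, S + "kineticLaw")
        math = etree.SubElement(kl, M + "math")
        fwd = _law_mathml(rxn.rate_law)
        if rxn.reversible:
            math.append(_apply("minus", fwd, _law_mathml(rxn.rate_law_reverse)))
        else:
            math.append(fwd)

    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


_ROLE_TO_SBO = {
    SpeciesRole.MRNA: "SBO:0000278",
    SpeciesRole.PROTEIN: "SBO:0000252",
    SpeciesRole.COMPLEX: "SBO:0000253",
    SpeciesRole.INPUT: "SBO:0000280",
}
_SBO_TO_ROLE = {v: k for k, v in _ROLE_TO_SBO.items()}


def write_sbml(model: PathwayModel, path) -> None:
    with open(path, "wb") as fh:
        fh.write(export_sbml(model))


# ---------------------------------------------------------------------------
# import: MathML -> rate-law grammar
# ---------------------------------------------------------------------------


def _tag(el) -> str:
    return etree.QName(el).localname


@dataclass
class _Ctx:
    species: set[str]
    parameters: set[str]


def _mathml_to_expr(el, ctx: _Ctx) -> tuple[str, set[str], set[str]]:
    """Render MathML into a python expression; returns (expr, species, params)."""
    tag = _tag(el)
    if tag == "ci":
        name = el.text.strip()
        if name in ctx.species:
            return name, {name}, set()
        if name in ctx.parameters:
            return name, set(), {name}
        raise SBMLError(f"unknown identifier {name!r} in kinetic law")
    if tag == "cn":
        return repr(float(el.text.strip())), set(), set()
    if tag == "apply":
        children = list(el)
        op = _tag(children[0])
        args, spec, pars = [], set(), set()
        for ch in children[1:]:
            e, sp, pa = _mathml_to_expr(ch, ctx)
            args.append(e)
            spec |= sp
            pars |= pa
        ops = {"times": "*", "plus": "+", "divide": "/", "minus": "-"}
        if op in ops:
            if op == "minus" and len(args) == 1:
                return f"(-{args[0]})", spec, pars
            return "(" + ops[op].join(args) + ")", spec, pars
        if op == "power":
            return f"({args[0]}**{args[1]})", spec, pars
        raise SBMLError(f"unsupported MathML operator {op!r}")
    raise SBMLError(f"unsupported MathML construct {tag!r}")


def _match_ci(el, ctx: _Ctx) -> str | None:
    if _tag(el) == "ci":
        return el.text.strip()
    return None


def _match_pow(el, ctx: _Ctx) -> tuple[str, float] | None:
    """Match <apply><power/><ci/><cn/></apply> or a bare <ci/> (n=1)."""
    name = _match_ci(el, ctx)
    if name is not None:
        return name, 1.0
    if _tag(el) == "apply":
        ch = list(el)
        if _tag(ch[0]) == "power" and len(ch) == 3:
            base = _match_ci(ch[1], ctx)
            if base is not None and _tag(ch[2]) == "cn":
                return base, float(ch[2].text.strip())
    return None


def _match_law(el, ctx: _Ctx) -> RateLaw | None:
    """Match one MathML node against the native grammar; None if no match."""
    tag = _tag(el)
    if tag == "ci":
        name = el.text.strip()
        if name in ctx.parameters:  # bare constant-rate synthesis
            return RateLaw.mass_action(name, [])
        return None
    if tag != "apply":
        return None
    ch = list(el)
    op = _tag(ch[0])

    if op == "times":
        factors = []
        for sub in ch[1:]:
            f = _match_factor(sub, ctx)
            if f is None:
                return None
            factors.append(f)
        # merge leading mass-action pieces: parameter first, then species
        base_params = [f for f in factors if f.form is RateLawForm.MASS_ACTION]
        others = [f for f in factors if f.form is not RateLawForm.MASS_ACTION]
        if len(base_params) == 0:
            # Michaelis-Menten base with dimensionless factors
            mm = [f for f in others if f.form is RateLawForm.MICHAELIS_MENTEN]
            hills = [f for f in others if f.form in (
                RateLawForm.HILL_ACTIVATION, RateLawForm.HILL_REPRESSION,
                RateLawForm.POOL_FRACTION)]
            if len(mm) == 1 and len(mm) + len(hills) == len(others):
                return RateLaw.composite(mm[0], *hills) if hills else mm[0]
            return None
        k = None
        species: list[str] = []
        for f in base_params:
            if f.constants.get("k") is not None and f.constants["k"] != "":
                if k is None:
                    k = f.constants["k"]
                elif f.constants["k"] in ctx.species:  # pragma: no cover
                    species.append(f.constants["k"])
                else:
                    return None
            species.extend(f.species)
        if k is None:
            return None
        base = RateLaw.mass_action(k, species)
        mm = [f for f in others if f.form is RateLawForm.MICHAELIS_MENTEN]
        hills = [f for f in others if f.form in (
            RateLawForm.HILL_ACTIVATION, RateLawForm.HILL_REPRESSION,
            RateLawForm.POOL_FRACTION)]
        if mm or len(hills) != len(others):
            return None  # mixing a k-base with an MM factor is not native
        if not hills:
            return base
        return RateLaw.composite(base, *hills)

    if op == "divide":
        f = _match_factor(el, ctx)
        return f

    return None


def _match_factor(el, ctx: _Ctx) -> RateLaw | None:
    """Match a multiplicative factor: ci, MM quotient, Hill quotient, fraction."""
    tag = _tag(el)
    if tag == "ci":
        name = el.text.strip()
        if name in ctx.parameters:
            return RateLaw.mass_action(name, [])
        if name in ctx.species:
            return RateLaw(RateLawForm.MASS_ACTION, {"k": ""}, [name])
        return None
    if tag != "apply":
        return None
    ch = list(el)
    op = _tag(ch[0])
    if op == "times":
        law = _match_law(el, ctx)
        return law
    if op != "divide" or len(ch) != 3:
        return None
    num, den = ch[1], ch[2]

    # pool fraction: species / parameter
    n_name, d_name = _match_ci(num, ctx), _match_ci(den, ctx)
    if n_name in ctx.species and d_name in ctx.parameters:
        return RateLaw.pool_fraction(n_name, d_name)

    # Michaelis-Menten: (vmax * s) / (km + s)
    if _tag(num) == "apply" and _tag(list(num)[0]) == "times":
        parts = list(num)[1:]
        if len(parts) == 2:
            a, b = (_match_ci(parts[0], ctx), _match_ci(parts[1], ctx))
            if a in ctx.parameters and b in ctx.species and _tag(den) == "apply":
                dch = list(den)
                if _tag(dch[0]) == "plus" and len(dch) == 3:
                    km = _match_ci(dch[1], ctx)
                    s2 = _match_ci(dch[2], ctx)
                    if km in ctx.parameters and s2 == b:
                        return RateLaw.michaelis_menten(a, km, b)

    # Hill forms: x^n/(K^n + x^n) or K^n/(K^n + x^n)
    pnum = _match_pow(num, ctx)
    if pnum is not None and _tag(den) == "apply":
        dch = list(den)
        if _tag(dch[0]) == "plus" and len(dch) == 3:
            p1, p2 = _match_pow(dch[1], ctx), _match_pow(dch[2], ctx)
            if p1 and p2 and p1[1] == p2[1] == pnum[1]:
                n = pnum[1]
                names = {p1[0], p2[0]}
                if pnum[0] in names and len(names) == 2:
                    other = (names - {pnum[0]}).pop()
                    if pnum[0] in ctx.species and other in ctx.parameters:
                        return RateLaw.hill_act(pnum[0], other, int(n))
                    if pnum[0] in ctx.parameters and other in ctx.species:
                        return RateLaw.hill_rep(other, pnum[0], int(n))
    return None


def import_sbml(document: bytes | str) -> PathwayModel:
    """Reconstruct a PathwayModel from an SBML L2 document.

    Kinetic laws are matched against the native rate-law grammar; unmatched
    math becomes an opaque law (a warning is emitted).  Delay constructs
    and other unsupported features raise SBMLError.
    """
    if isinstance(document, str):
        document = document.encode()
    try:
        root = etree.fromstring(document)
    except etree.XMLSyntaxError as e:
        raise SBMLError(f"malformed XML: {e}") from None
    if _tag(root) != "sbml":
        raise SBMLError("not an SBML document")
    if root.get("level") not in ("2",):
        raise SBMLError(f"unsupported SBML level {root.get('level')!r}")
    for el in root.iter():
        if _tag(el) in ("delay", "csymbol"):
            raise SBMLError(f"unsupported construct {_tag(el)!r} in document")
    mdl = root.find(S + "model")
    if mdl is None:
        raise SBMLError("document has no <model>")

    params = {}
    for par in mdl.findall(f"{S}listOfParameters/{S}parameter"):
        params[par.get("id")] = float(par.get("value", "0"))

    rules = {}
    for rule in mdl.findall(f"{S}listOfRules/{S}assignmentRule"):
        math = rule.find(M + "math")
        rules[rule.get("variable")] = list(math)[0]

    species: list[Species] = []
    inputs: dict[str, float] = {}
    rule_species: dict[str, etree._Element] = {}
    for sp in mdl.findall(f"{S}listOfSpecies/{S}species"):
        sid = sp.get("id")
        comp = sp.get("compartment", "cytoplasm")
        value = float(sp.get("initialConcentration", sp.get("initialAmount", "0")))
        boundary = sp.get("boundaryCondition") == "true"
        constant = sp.get("constant") == "true"
        role = _SBO_TO_ROLE.get(sp.get("sboTerm", ""), SpeciesRole.PROTEIN)
        if boundary and constant:
            inputs[sid] = value
        elif boundary and sid in rules:
            rule_species[sid] = rules[sid]
        else:
            species.append(
                Species(sid, Compartment(comp), role, initial_value=value)
            )

    dynamic_names = {s.name for s in species}
    ctx = _Ctx(
        species=dynamic_names | set(inputs) | set(rule_species),
        parameters=set(params),
    )

    pools: list[ConservedPool] = []
    for free_name, math in rule_species.items():
        # expect total - bound or total - (b1 + b2 + ...)
        ok = False
        if _tag(math) == "apply":
            ch = list(math)
            if _tag(ch[0]) == "minus" and len(ch) == 3:
                total = _match_ci(ch[1], ctx)
                rest = ch[2]
                bound: list[str] = []
                if _match_ci(rest, ctx):
                    bound = [_match_ci(rest, ctx)]
                elif _tag(rest) == "apply" and _tag(list(rest)[0]) == "plus":
                    bound = [_match_ci(c, ctx) for c in list(rest)[1:]]
                if total in ctx.parameters and bound and all(
                    b in dynamic_names for b in bound
                ):
                    pools.append(ConservedPool(free_name, total, free_name, bound))
                    ok = True
        if not ok:
            raise SBMLError(
                f"assignment rule for {free_name!r} is not a conservation rule"
            )

    reactions: list[Reaction] = []
    n_opaque = 0
    for r in mdl.findall(f"{S}listOfReactions/{S}reaction"):
        rid = r.get("id")
        reactants = {
            ref.get("species"): int(float(ref.get("stoichiometry", "1")))
            for ref in r.findall(f"{S}listOfReactants/{S}speciesReference")
        }
        products = {
            ref.get("species"): int(float(ref.get("stoichiometry", "1")))
            for ref in r.findall(f"{S}listOfProducts/{S}speciesReference")
        }
        modifiers = [
            ref.get("species")
            for ref in r.findall(f"{S}listOfModifiers/{S}modifierSpeciesReference")
        ]
        kl = r.find(S + "kineticLaw")
        if kl is None:
            raise SBMLError(f"reaction {rid!r} has no kineticLaw")
        math = kl.find(M + "math")
        if math is None or len(math) == 0:
            raise SBMLError(f"reaction {rid!r} has empty kinetic math")
        node = list(math)[0]
        reversible = r.get("reversible") == "true"

        fwd_node, back_node = node, None
        if reversible and _tag(node) == "apply" and _tag(list(node)[0]) == "minus" \
                and len(list(node)) == 3:
            fwd_node, back_node = list(node)[1], list(node)[2]

        def to_law(n):
            nonlocal n_opaque
            law = _match_law(n, ctx)
            if law is None:
                expr, spec, pars = _mathml_to_expr(n, ctx)
                law = RateLaw.opaque(expr, sorted(spec), sorted(pars))
                n_opaque += 1
            return law

        fwd = to_law(fwd_node)
        back = to_law(back_node) if back_node is not None else None
        if reversible and back is None:
            # reversible flag without a minus structure: treat whole as forward
            reversible = False
        reactions.append(
            Reaction(
                rid, reactants, products, modifiers,
                rate_law=fwd, reversible=reversible, rate_law_reverse=back,
            )
        )

    if n_opaque:
        warnings.warn(
            f"{n_opaque} kinetic law(s) did not match the rate-law grammar; "
            "imported as opaque expressions",
            stacklevel=2,
        )

    model = PathwayModel(
        model_id=mdl.get("id", "imported"),
        species=species,
        reactions=reactions,
        parameters=ParameterSet(params, provenance="user"),
        inputs=inputs,
        pools=pools,
    )
    problems = validate(model)
    if problems:
        raise SBMLError("imported model invalid: " + "; ".join(problems))
    return model


def read_sbml(path) -> PathwayModel:
    with open(path, "rb") as fh:
        return import_sbml(fh.read())
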
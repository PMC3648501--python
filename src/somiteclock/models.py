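"""Builders for the three segmentation-clock models.

``build_notch_model``   - the Notch pathway in isolation: 12 ODE species.
``build_wnt_model``     - the Wnt pathway in isolation: 13 ODE species.
``build_combined_model``- the merged network with three crosstalk levels:
                          Wnt-driven Dll1 transcription replacing the
                          constant Dll1 supply, mutual NICD/active-Dsh
                          sequestration, and the Nkd1 axis (5 new ODEs).

Compartment and degradation conventions shared by all three models:
target genes are transcribed in the nucleus, mRNAs are exported to the
cytoplasm and degraded only there (Michaelis-Menten); proteins are
translated in the cytoplasm; shuttling transcription factors (NICD, Hes7)
degrade in both compartments.  RBP-j, GSK3, Lef1 and Dsh are conserved
pools handled algebraically.

Where the published description does not detail a step (mRNA export rates,
the Lef1 axis, nuclear shuttling constants), the reaction notes below flag
the step as a reconstruction consistent with the stated compartment rules.

Called with ``params=None``, each builder loads the shipped
reference-calibrated parameter set and the post-burn-in initial state from
the package's data files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from .kinetics import RateLaw
from .network import (
    Compartment as C,
    ParameterSet,
    PathwayModel,
    Reaction,
    ConservedPool,
    Species,
    SpeciesRole as R,
)

__all__ = [
    "ModelCatalogEntry",
    "MODEL_CATALOG",
    "build_notch_model",
    "build_wnt_model",
    "build_combined_model",
    "build_model",
    "reference_parameters",
]

_DEFAULT_INITIAL = 0.2  # a.u.; pre-burn-in placeholder level


@dataclass(frozen=True)
class ModelCatalogEntry:
    model_id: str
    expected_ode_count: int
    target_genes: tuple[str, ...]
    readout_species: tuple[str, ...]


MODEL_CATALOG = {
    "notch": ModelCatalogEntry(
        "notch", 12, ("Lfng", "Hes7"), ("Lfng_mRNA_cyt", "Hes7_mRNA_cyt")
    ),
    "wnt": ModelCatalogEntry(
        "wnt",
        13,
        ("Axin2", "Lef1", "Dll1"),
        ("Axin2_mRNA_cyt", "Lef1_mRNA_cyt", "Dll1_mRNA_cyt"),
    ),
    "combined": ModelCatalogEntry(
        "combined",
        29,
        ("Lfng", "Hes7", "Nkd1", "Axin2", "Dll1"),
        (
            "Lfng_mRNA_cyt",
            "Hes7_mRNA_cyt",
            "Nkd1_mRNA_cyt",
            "Axin2_mRNA_cyt",
            "Dll1_mRNA_cyt",
        ),
    ),
}


# ---------------------------------------------------------------------------
# reference parameter / state loading
# ---------------------------------------------------------------------------


def _load_reference(model_id: str) -> dict:
    fname = f"reference_{model_id}.json"
    with resources.files("somiteclock.data").joinpath(fname).open() as fh:
        return json.load(fh)


def reference_parameters(model_id: str) -> ParameterSet:
    """The shipped reference-calibrated parameter set for one model."""
    doc = _load_reference(model_id)
    return ParameterSet(dict(doc["parameters"]), provenance="reference_calibrated")


def _apply_reference(model: PathwayModel) -> PathwayModel:
    doc = _load_reference(model.model_id)
    model.parameters = ParameterSet(
        dict(doc["parameters"]), provenance="reference_calibrated"
    )
    for name, value in doc.get("inputs", {}).items():
        model.inputs[name] = float(value)
    init = doc.get("initial_state", {})
    for s in model.species:
        if s.name in init:
            s.initial_value = float(init[s.name])
    return model


def _coerce_params(params) -> ParameterSet | None:
    if params is None:
        return None
    if isinstance(params, ParameterSet):
        return params
    if isinstance(params, dict):
        return ParameterSet(dict(params))
    raise TypeError(f"params must be ParameterSet, dict or None, not {type(params)}")


# ---------------------------------------------------------------------------
# shared reaction blocks
# ---------------------------------------------------------------------------


def _gene_expression_block(
    gene: str,
    activator: str,
    repressor: str | None,
    protein_species: str | None,
    pathway: str,
) -> tuple[list[Species], list[Reaction]]:
    """Transcription -> mRNA export -> cytoplasmic decay (-> translation).

    Transcription is activated by ``activator`` with Hill coefficient 2 and,
    where ``repressor`` is given, repressed with Hill coefficient -2; dual
    regulation combines multiplicatively (AND logic).  mRNA export and
    translation rates are proportional to the mRNA concentration.
    """
    g = gene.lower()
    m_nuc, m_cyt = f"{gene}_mRNA_nuc", f"{gene}_mRNA_cyt"
    species = [
        Species(m_nuc, C.NUCLEUS, R.MRNA, initial_value=_DEFAULT_INITIAL),
        Species(m_cyt, C.CYTOPLASM, R.MRNA, initial_value=_DEFAULT_INITIAL),
    ]
    factors = [RateLaw.hill_act(activator, f"K_act_tx_{g}", 2)]
    if repressor is not None:
        factors.append(RateLaw.hill_rep(repressor, f"K_rep_tx_{g}", 2))
    reactions = [
        Reaction(
            f"tx_{g}",
            products={m_nuc: 1},
            modifiers=[activator] + ([repressor] if repressor else []),
            rate_law=RateLaw.composite(
                RateLaw.mass_action(f"V_tx_{g}", []), *factors
            ),
            kind="transcription",
            gene=gene,
            pathway=pathway,
        ),
        Reaction(
            f"exp_{g}_m",
            reactants={m_nuc: 1},
            products={m_cyt: 1},
            rate_law=RateLaw.mass_action(f"k_exp_{g}", [m_nuc]),
            kind="transport",
            gene=gene,
            pathway=pathway,
            note="nucleus-to-cytoplasm mRNA export; rate reconstructed",
        ),
        Reaction(
            f"deg_{g}_m",
            reactants={m_cyt: 1},
            rate_law=RateLaw.michaelis_menten(
                f"V_deg_{g}_m", f"K_deg_{g}_m", m_cyt
            ),
            kind="degradation",
            gene=gene,
            pathway=pathway,
        ),
    ]
    if protein_species is not None:
        reactions.append(
            Reaction(
                f"tl_{g}",
                products={protein_species: 1},
                modifiers=[m_cyt],
                rate_law=RateLaw.mass_action(f"k_tl_{g}", [m_cyt]),
                kind="translation",
                gene=gene,
                pathway=pathway,
            )
        )
    return species, reactions


def _mm_degradation(
    species: str, tag: str, kind_gene: str | None, pathway: str
) -> Reaction:
    return Reaction(
        f"deg_{tag}",
        reactants={species: 1},
        rate_law=RateLaw.michaelis_menten(f"V_deg_{tag}", f"K_deg_{tag}", species),
        kind="degradation",
        gene=kind_gene,
        pathway=pathway,
    )


# ---------------------------------------------------------------------------
# Notch
# ---------------------------------------------------------------------------


def _notch_network(include_dll1_supply: bool = True):
    """Species/reactions of the Notch pathway (no parameters attached)."""
    species = [
        Species("Dll1_protein", C.MEMBRANE, R.PROTEIN, initial_value=_DEFAULT_INITIAL),
        Species("Notch_receptor", C.MEMBRANE, R.PROTEIN, initial_value=_DEFAULT_INITIAL),
        Species("NICD_cyt", C.CYTOPLASM, R.PROTEIN, initial_value=_DEFAULT_INITIAL),
        Species("NICD_nuc", C.NUCLEUS, R.PROTEIN, initial_value=_DEFAULT_INITIAL),
        Species("NICD_RBPj", C.NUCLEUS, R.COMPLEX, initial_value=_DEFAULT_INITIAL),
        Species("Lfng_protein", C.CYTOPLASM, R.PROTEIN, initial_value=_DEFAULT_INITIAL),
        Species("Hes7_protein_cyt", C.CYTOPLASM, R.PROTEIN, initial_value=_DEFAULT_INITIAL),
        Species("Hes7_protein_nuc", C.NUCLEUS, R.PROTEIN, initial_value=_DEFAULT_INITIAL),
    ]
    reactions: list[Reaction] = []
    if include_dll1_supply:
        # constant-rate Dll1 supply, scaled by the external signal level;
        # replaced by Wnt-driven transcription in the combined model
        reactions.append(
            Reaction(
                "syn_dll1",
                products={"Dll1_protein": 1},
                rate_law=RateLaw.mass_action("k_syn_dll1", ["dll1_signal"]),
                kind="synthesis",
                gene="Dll1",
                pathway="notch",
            )
        )
    reactions += [
        _mm_degradation("Dll1_protein", "dll1_p", "Dll1", "notch"),
        Reaction(
            "syn_notch",
            products={"Notch_receptor": 1},
            rate_law=RateLaw.mass_action("k_syn_notch", []),
            kind="synthesis",
            pathway="notch",
        ),
        _mm_degradation("Notch_receptor", "notch", None, "notch"),
        Reaction(
            "cleave_nicd",
            reactants={"Notch_receptor": 1},
            products={"NICD_cyt": 1},
            modifiers=["Dll1_protein", "Lfng_protein"],
            rate_law=RateLaw.composite(
                RateLaw.mass_action("k_cleave", ["Notch_receptor"]),
                RateLaw.hill_act("Dll1_protein", "K_act_dll1", 1),
                RateLaw.hill_rep("Lfng_protein", "K_rep_lfng", 2),
            ),
            kind="cleavage",
            pathway="notch",
            note="NICD cleavage: mass action in Notch, Dll1 activation "
            "(one site), Lfng inhibition (two sites)",
        ),
        Reaction(
            "shuttle_nicd",
            reactants={"NICD_cyt": 1},
            products={"NICD_nuc": 1},
            reversible=True,
            rate_law=RateLaw.mass_action("k_nicd_in", ["NICD_cyt"]),
            rate_law_reverse=RateLaw.mass_action("k_nicd_out", ["NICD_nuc"]),
            kind="shuttling",
            pathway="notch",
        ),
        _mm_degradation("NICD_cyt", "nicd_cyt", None, "notch"),
        _mm_degradation("NICD_nuc", "nicd_nuc", None, "notch"),
        Reaction(
            "bind_rbpj",
            reactants={"NICD_nuc": 1},
            products={"NICD_RBPj": 1},
            modifiers=["RBPj_free"],
            reversible=True,
            rate_law=RateLaw.mass_action("k_bind_rbpj", ["NICD_nuc", "RBPj_free"]),
            rate_law_reverse=RateLaw.mass_action("k_unbind_rbpj", ["NICD_RBPj"]),
            kind="binding",
            pathway="notch",
            note="free RBP-j is the conserved remainder of the RBP-j pool",
        ),
        Reaction(
            "shuttle_hes7",
            reactants={"Hes7_protein_cyt": 1},
            products={"Hes7_protein_nuc": 1},
            reversible=True,
            rate_law=RateLaw.mass_action("k_hes7_in", ["Hes7_protein_cyt"]),
            rate_law_reverse=RateLaw.mass_action("k_hes7_out", ["Hes7_protein_nuc"]),
            kind="shuttling",
            pathway="notch",
        ),
        _mm_degradation("Lfng_protein", "lfng_p", "Lfng", "notch"),
        _mm_degradation("Hes7_protein_cyt", "hes7_pc", "Hes7", "notch"),
        _mm_degradation("Hes7_protein_nuc", "hes7_pn", "Hes7", "notch"),
    ]
    sp, rx = _gene_expression_block(
        "Lfng", "NICD_RBPj", "Hes7_protein_nuc", "Lfng_protein", "notch"
    )
    species += sp
    reactions += rx
    sp, rx = _gene_expression_block(
        "Hes7", "NICD_RBPj", "Hes7_protein_nuc", "Hes7_protein_cyt", "notch"
    )
    species += sp
    reactions += rx

    pools = [ConservedPool("RBPj", "RBPj_total", "RBPj_free", ["NICD_RBPj"])]
    return species, reactions, pools


def build_notch_model(params=None) -> PathwayModel:
    """The Notch pathway in isolation: 12 ODE species, constant Dll1 supply.

    The pacemaker is the Hes7 auto-repression loop (transcription ->
    mRNA export -> translation -> nuclear import -> repression) with
    saturating degradation; the Lfng loop modulates NICD cleavage.
    """
    species, reactions, pools = _notch_network(include_dll1_supply=True)
    model = PathwayModel(
        model_id="notch",
        species=species,
        reactions=reactions,
        inputs={"dll1_signal": 1.0},
        pools=pools,
        target_genes=["Lfng", "Hes7"],
        readouts={"Lfng": "Lfng_mRNA_cyt", "Hes7": "Hes7_mRNA_cyt"},
    )
    p = _coerce_params(params)
    if p is None:
        _apply_reference(model)
    else:
        model.parameters = p
    return model


# ---------------------------------------------------------------------------
# Wnt
# ---------------------------------------------------------------------------


def _wnt_network():
    species = [
        Species("Dsh_active", C.CYTOPLASM, R.PROTEIN, initial_value=_DEFAULT_INITIAL),
        Species("Axin2_protein", C.CYTOPLASM, R.PROTEIN, initial_value=_DEFAULT_INITIAL),
        Species("GSK3_Axin2", C.CYTOPLASM, R.COMPLEX, initial_value=_DEFAULT_INITIAL),
        Species("beta_catenin", C.CYTOPLASM, R.PROTEIN, initial_value=_DEFAULT_INITIAL),
        Species("beta_catenin_P", C.CYTOPLASM, R.PROTEIN, initial_value=_DEFAULT_INITIAL),
        Species("bcat_Lef1", C.NUCLEUS, R.COMPLEX, initial_value=_DEFAULT_INITIAL),
        Species("Dll1_protein", C.MEMBRANE, R.PROTEIN, initial_value=_DEFAULT_INITIAL),
    ]
    reactions = [
        Reaction(
            "act_dsh",
            products={"Dsh_active": 1},
            modifiers=["Dsh_inactive"],
            reversible=True,
            rate_law=RateLaw.composite(
                RateLaw.michaelis_menten("V_act_dsh", "K_act_dsh", "Dsh_inactive"),
                RateLaw.hill_act("Wnt", "K_wnt", 1),
            ),
            rate_law_reverse=RateLaw.michaelis_menten(
                "V_deact_dsh", "K_deact_dsh", "Dsh_active"
            ),
            kind="conversion",
            pathway="wnt",
            note="reversible Michaelis-Menten Dsh activation catalysed by "
            "Wnt (Hill coefficient 1)",
        ),
        Reaction(
            "axin2_deg_by_dsh",
            reactants={"Dsh_active": 1, "Axin2_protein": 1},
            rate_law=RateLaw.mass_action(
                "k_dsh_axin2", ["Dsh_active", "Axin2_protein"]
            ),
            kind="degradation",
            gene="Axin2",
            pathway="wnt",
            note="active Dsh binds Axin2 and destroys it; the engaged Dsh "
            "returns to the inactive pool",
        ),
        Reaction(
            "bind_gsk3_axin2",
            reactants={"Axin2_protein": 1},
            products={"GSK3_Axin2": 1},
            modifiers=["GSK3_free"],
            reversible=True,
            rate_law=RateLaw.mass_action("k_bind_gsk3", ["GSK3_free", "Axin2_protein"]),
            rate_law_reverse=RateLaw.mass_action("k_unbind_gsk3", ["GSK3_Axin2"]),
            kind="binding",
            pathway="wnt",
        ),
        Reaction(
            "phos_bcat",
            reactants={"beta_catenin": 1},
            products={"beta_catenin_P": 1},
            modifiers=["GSK3_Axin2"],
            reversible=True,
            rate_law=RateLaw.composite(
                RateLaw.michaelis_menten("V_phos_bcat", "K_phos_bcat", "beta_catenin"),
                RateLaw.pool_fraction("GSK3_Axin2", "GSK3_total"),
            ),
            rate_law_reverse=RateLaw.michaelis_menten(
                "V_dephos_bcat", "K_dephos_bcat", "beta_catenin_P"
            ),
            kind="conversion",
            pathway="wnt",
            note="catalytic rate scales with the GSK3-Axin2 fraction of "
            "total GSK3",
        ),
        _mm_degradation("beta_catenin_P", "bcat_p", None, "wnt"),
        Reaction(
            "syn_bcat",
            products={"beta_catenin": 1},
            rate_law=RateLaw.mass_action("k_syn_bcat", []),
            kind="synthesis",
            pathway="wnt",
        ),
        _mm_degradation("beta_catenin", "bcat", None, "wnt"),
        Reaction(
            "bind_bcat_lef1",
            reactants={"beta_catenin": 1},
            products={"bcat_Lef1": 1},
            modifiers=["Lef1_free"],
            reversible=True,
            rate_law=RateLaw.mass_action("k_bind_lef1", ["beta_catenin", "Lef1_free"]),
            rate_law_reverse=RateLaw.mass_action("k_unbind_lef1", ["bcat_Lef1"]),
            kind="binding",
            pathway="wnt",
            note="free Lef1 is the conserved remainder of the Lef1 pool",
        ),
        _mm_degradation("Dll1_protein", "dll1_p", "Dll1", "wnt"),
        _mm_degradation("Axin2_protein", "axin2_p", "Axin2", "wnt"),
    ]
    for gene, protein in (("Axin2", "Axin2_protein"), ("Lef1", None), ("Dll1", "Dll1_protein")):
        sp, rx = _gene_expression_block(gene, "bcat_Lef1", None, protein, "wnt")
        species += sp
        reactions += rx

    pools = [
        ConservedPool("Dsh", "Dsh_total", "Dsh_inactive", ["Dsh_active"]),
        ConservedPool("GSK3", "GSK3_total", "GSK3_free", ["GSK3_Axin2"]),
        ConservedPool("Lef1", "Lef1_total", "Lef1_free", ["bcat_Lef1"]),
    ]
    return species, reactions, pools


def build_wnt_model(params=None) -> PathwayModel:
    """The Wnt pathway in isolation: 13 ODE species, constant Wnt input.

    The pacemaker is the Axin2 negative feedback loop: the
    beta-catenin/Lef1 activator drives Axin2 transcription; Axin2 protein
    recruits GSK3 into the degradation complex, which phosphorylates
    beta-catenin and shuts the activator down.  Active Dsh antagonises
    Axin2 and is itself deactivated while degrading it.  Lef1 protein is a
    conserved nuclear pool; its mRNA is a pure readout.
    """
    species, reactions, pools = _wnt_network()
    model = PathwayModel(
        model_id="wnt",
        species=species,
        reactions=reactions,
        inputs={"Wnt": 1.0},
        pools=pools,
        target_genes=["Axin2", "Lef1", "Dll1"],
        readouts={
            "Axin2": "Axin2_mRNA_cyt",
            "Lef1": "Lef1_mRNA_cyt",
            "Dll1": "Dll1_mRNA_cyt",
        },
    )
    p = _coerce_params(params)
    if p is None:
        _apply_reference(model)
    else:
        model.parameters = p
    return model


# ---------------------------------------------------------------------------
# combined
# ---------------------------------------------------------------------------


def build_combined_model(params=None) -> PathwayModel:
    """The crosstalk model: Notch + Wnt merged plus five new ODE species.

    Crosstalk levels: (1) Dll1 is transcribed under Wnt control (the
    constant Dll1 supply of the isolated Notch model is removed); (2) NICD
    and active Dsh sequester each other in a reversible complex; (3) the
    Nkd1 axis - transcription activated by beta-catenin/Lef1 and repressed
    by Hes7, with the protein sequestering active Dsh.
    """
    n_species, n_reactions, n_pools = _notch_network(include_dll1_supply=False)
    w_species, w_reactions, w_pools = _wnt_network()

    seen: dict[str, Species] = {}
    species: list[Species] = []
    for s in n_species + w_species:
        if s.name not in seen:
            seen[s.name] = s
            species.append(s)

    rxn_names = set()
    reactions: list[Reaction] = []
    for r in n_reactions + w_reactions:
        if r.name in rxn_names:  # Dll1 protein degradation appears in both
            continue
        rxn_names.add(r.name)
        reactions.append(r)

    # level 2: mutual NICD / active-Dsh sequestration and inhibition.  The
    # complex turns over: its NICD moiety is destroyed and the engaged Dsh
    # returns to the inactive pool, so each pathway's signal level imposes a
    # real degradation flux on the other's - binding alone would carry no
    # net flux at steady state and could not transmit sustained changes.
    species.append(
        Species("NICD_Dsh", C.CYTOPLASM, R.COMPLEX, initial_value=_DEFAULT_INITIAL)
    )
    reactions.append(
        Reaction(
            "bind_nicd_dsh",
            reactants={"NICD_cyt": 1, "Dsh_active": 1},
            products={"NICD_Dsh": 1},
            reversible=True,
            rate_law=RateLaw.mass_action("k_bind_nicd_dsh", ["NICD_cyt", "Dsh_active"]),
            rate_law_reverse=RateLaw.mass_action("k_unbind_nicd_dsh", ["NICD_Dsh"]),
            kind="binding",
            pathway="crosstalk",
        )
    )
    reactions.append(
        Reaction(
            "deg_nicd_dsh",
            reactants={"NICD_Dsh": 1},
            rate_law=RateLaw.mass_action("k_deg_nicd_dsh", ["NICD_Dsh"]),
            kind="degradation",
            pathway="crosstalk",
            note="complex turnover: NICD destroyed, Dsh recycled inactive",
        )
    )

    # level 3: the Nkd1 axis
    sp, rx = _gene_expression_block(
        "Nkd1", "bcat_Lef1", "Hes7_protein_nuc", "Nkd1_protein", "crosstalk"
    )
    species += sp
    reactions += rx
    species.append(
        Species("Nkd1_protein", C.CYTOPLASM, R.PROTEIN, initial_value=_DEFAULT_INITIAL)
    )
    species.append(
        Species("Nkd1_Dsh", C.CYTOPLASM, R.COMPLEX, initial_value=_DEFAULT_INITIAL)
    )
    reactions += [
        _mm_degradation("Nkd1_protein", "nkd1_p", "Nkd1", "crosstalk"),
        Reaction(
            "bind_nkd1_dsh",
            reactants={"Nkd1_protein": 1, "Dsh_active": 1},
            products={"Nkd1_Dsh": 1},
            reversible=True,
            rate_law=RateLaw.mass_action("k_bind_nkd1_dsh", ["Nkd1_protein", "Dsh_active"]),
            rate_law_reverse=RateLaw.mass_action("k_unbind_nkd1_dsh", ["Nkd1_Dsh"]),
            kind="binding",
            pathway="crosstalk",
        ),
        Reaction(
            "deg_nkd1_dsh",
            reactants={"Nkd1_Dsh": 1},
            rate_law=RateLaw.mass_action("k_deg_nkd1_dsh", ["Nkd1_Dsh"]),
            kind="degradation",
            pathway="crosstalk",
            note="complex turnover: Nkd1 destroyed, Dsh recycled inactive; "
            "makes sustained Nkd1 a catalytic deactivator of Dsh",
        ),
    ]

    pools = [p for p in n_pools]
    for p in w_pools:
        if p.name == "Dsh":
            p = ConservedPool(
                "Dsh", "Dsh_total", "Dsh_inactive",
                ["Dsh_active", "NICD_Dsh", "Nkd1_Dsh"],
            )
        pools.append(p)

    model = PathwayModel(
        model_id="combined",
        species=species,
        reactions=reactions,
        inputs={"Wnt": 1.0},
        pools=pools,
        target_genes=["Lfng", "Hes7", "Nkd1", "Axin2", "Dll1"],
        readouts={
            "Lfng": "Lfng_mRNA_cyt",
            "Hes7": "Hes7_mRNA_cyt",
            "Nkd1": "Nkd1_mRNA_cyt",
            "Axin2": "Axin2_mRNA_cyt",
            "Dll1": "Dll1_mRNA_cyt",
        },
    )
    p = _coerce_params(params)
    if p is None:
        _apply_reference(model)
    else:
        model.parameters = p
    return model


_BUILDERS = {
    "notch": build_notch_model,
    "wnt": build_wnt_model,
    "combined": build_combined_model,
}


def build_model(model_id: str, params=None) -> PathwayModel:
    try:
        builder = _BUILDERS[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model {model_id!r}; choose from {sorted(_BUILDERS)}"
        ) from None
    return builder(params)
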
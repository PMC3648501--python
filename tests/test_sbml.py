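"""SBML L2V4 export/import: structure, round trips, error handling."""

import numpy as np
import pytest
from lxml import etree

from somiteclock import (
    SimulationConfig,
    build_model,
    build_notch_model,
    export_sbml,
    import_sbml,
    integrate,
)
from somiteclock.sbml import SBMLError

SBML_NS = "http://www.sbml.org/sbml/level2/version4"


def rhs_agreement(m1, m2, n_states=100, seed=0):
    """Max |rhs difference| over random nonnegative states (order-aligned)."""
    rhs1, rhs2 = m1.compile_rhs(), m2.compile_rhs()
    n1, n2 = m1.dynamic_names(), m2.dynamic_names()
    idx = [n2.index(n) for n in n1]
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_states):
        y = rng.uniform(0.0, 5.0, len(n1))
        y2 = np.empty_like(y)
        for i, j in enumerate(idx):
            y2[j] = y[i]
        d1 = rhs1(0.0, y)
        d2 = rhs2(0.0, y2)
        worst = max(worst, float(np.max(np.abs(d1 - np.array([d2[j] for j in idx])))))
    return worst


class TestExport:
    def test_document_structure(self):
        doc = export_sbml(build_notch_model())
        root = etree.fromstring(doc)
        assert root.tag == f"{{{SBML_NS}}}sbml"
        assert root.get("level") == "2" and root.get("version") == "4"
        model = root.find(f"{{{SBML_NS}}}model")
        species = model.findall(f"{{{SBML_NS}}}listOfSpecies/{{{SBML_NS}}}species")
        dynamic = [s for s in species if s.get("boundaryCondition") != "true"]
        assert len(dynamic) == 12
        reactions = model.findall(
            f"{{{SBML_NS}}}listOfReactions/{{{SBML_NS}}}reaction")
        assert len(reactions) >= 20
        # every reaction carries kinetic math
        for r in reactions:
            assert r.find(f"{{{SBML_NS}}}kineticLaw") is not None

    def test_identifier_references_resolve(self):
        """Internal consistency: every species/parameter referenced in a
        reaction or rule is declared."""
        doc = export_sbml(build_notch_model())
        root = etree.fromstring(doc)
        model = root.find(f"{{{SBML_NS}}}model")
        declared = {s.get("id") for s in model.findall(
            f"{{{SBML_NS}}}listOfSpecies/{{{SBML_NS}}}species")}
        declared |= {p.get("id") for p in model.findall(
            f"{{{SBML_NS}}}listOfParameters/{{{SBML_NS}}}parameter")}
        for ci in root.iter("{http://www.w3.org/1998/Math/MathML}ci"):
            assert ci.text.strip() in declared

    def test_invalid_model_rejected(self):
        m = build_notch_model()
        del m.parameters.values["k_cleave"]
        with pytest.raises(SBMLError, match="k_cleave"):
            export_sbml(m)


class TestRoundTrip:
    @pytest.mark.parametrize("model_id", ["notch", "wnt", "combined"])
    def test_rhs_identical_after_round_trip(self, model_id):
        m = build_model(model_id)
        m2 = import_sbml(export_sbml(m))
        assert rhs_agreement(m, m2) < 1e-12

    def test_structure_survives_round_trip(self):
        m = build_notch_model()
        m2 = import_sbml(export_sbml(m))
        assert set(m2.dynamic_names()) == set(m.dynamic_names())
        assert {r.name for r in m2.reactions} == {r.name for r in m.reactions}
        assert len(m2.pools) == len(m.pools)
        assert m2.inputs == m.inputs
        assert m2.parameters.values == m.parameters.values


class TestImport:
    def test_malformed_xml_rejected(self):
        with pytest.raises(SBMLError, match="malformed"):
            import_sbml(b"<sbml><unclosed>")

    def test_missing_kinetic_law_rejected(self):
        doc = export_sbml(build_notch_model()).decode()
        stripped = doc.replace("kineticLaw", "droppedLaw")
        with pytest.raises(SBMLError, match="kineticLaw"):
            import_sbml(stripped)

    def test_delay_construct_rejected(self):
        doc = export_sbml(build_notch_model()).decode()
        poisoned = doc.replace(
            "</model>",
            '<listOfEvents><event><delay/></event></listOfEvents></model>')
        with pytest.raises(SBMLError, match="delay"):
            import_sbml(poisoned)

    def test_hand_written_toy_simulates_to_steady_state(self):
        """A two-species toy (0 -> X -> Y -> 0) reaches X* = k/d1, Y* = d1 X*/d2."""
        toy = f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="{SBML_NS}" level="2" version="4">
 <model id="toy">
  <listOfCompartments><compartment id="cytoplasm" size="1"/></listOfCompartments>
  <listOfSpecies>
   <species id="X" compartment="cytoplasm" initialConcentration="0"/>
   <species id="Y" compartment="cytoplasm" initialConcentration="0"/>
  </listOfSpecies>
  <listOfParameters>
   <parameter id="k" value="1.0"/>
   <parameter id="d1" value="0.5"/>
   <parameter id="d2" value="0.25"/>
  </listOfParameters>
  <listOfReactions>
   <reaction id="syn_x" reversible="false">
    <listOfProducts><speciesReference species="X" stoichiometry="1"/></listOfProducts>
    <kineticLaw><math xmlns="http://www.w3.org/1998/Math/MathML">
      <ci> k </ci></math></kineticLaw>
   </reaction>
   <reaction id="convert" reversible="false">
    <listOfReactants><speciesReference species="X" stoichiometry="1"/></listOfReactants>
    <listOfProducts><speciesReference species="Y" stoichiometry="1"/></listOfProducts>
    <kineticLaw><math xmlns="http://www.w3.org/1998/Math/MathML">
      <apply><times/><ci> d1 </ci><ci> X </ci></apply></math></kineticLaw>
   </reaction>
   <reaction id="deg_y" reversible="false">
    <listOfReactants><speciesReference species="Y" stoichiometry="1"/></listOfReactants>
    <kineticLaw><math xmlns="http://www.w3.org/1998/Math/MathML">
      <apply><times/><ci> d2 </ci><ci> Y </ci></apply></math></kineticLaw>
   </reaction>
  </listOfReactions>
 </model>
</sbml>"""
        m = import_sbml(toy)
        traj = integrate(m, SimulationConfig(t_end=100.0))
        assert traj["X"][-1] == pytest.approx(2.0, rel=1e-4)   # k/d1
        assert traj["Y"][-1] == pytest.approx(4.0, rel=1e-3)   # k/d2

    def test_unmatched_math_becomes_opaque_but_simulatable(self):
        """A kinetic law outside the grammar imports with a warning and
        still integrates (here dx/dt = k (1 - X/2): logistic-style relaxation
        to X = 2)."""
        toy = f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="{SBML_NS}" level="2" version="4">
 <model id="toy2">
  <listOfCompartments><compartment id="cytoplasm" size="1"/></listOfCompartments>
  <listOfSpecies>
   <species id="X" compartment="cytoplasm" initialConcentration="0"/>
  </listOfSpecies>
  <listOfParameters><parameter id="k" value="0.5"/></listOfParameters>
  <listOfReactions>
   <reaction id="relax" reversible="false">
    <listOfProducts><speciesReference species="X" stoichiometry="1"/></listOfProducts>
    <kineticLaw><math xmlns="http://www.w3.org/1998/Math/MathML">
      <apply><times/><ci> k </ci>
        <apply><minus/><cn> 1 </cn>
          <apply><divide/><ci> X </ci><cn> 2 </cn></apply>
        </apply></apply></math></kineticLaw>
   </reaction>
  </listOfReactions>
 </model>
</sbml>"""
        with pytest.warns(UserWarning, match="opaque"):
            m = import_sbml(toy)
        traj = integrate(m, SimulationConfig(t_end=60.0))
        assert traj["X"][-1] == pytest.approx(2.0, rel=1e-3)
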
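"""Network core: compilation, validation, perturbation semantics."""

import numpy as np
import pytest

from somiteclock import (
    ParameterSet,
    PathwayModel,
    Perturbation,
    RateLaw,
    Reaction,
    SimulationConfig,
    Species,
    apply_perturbation,
    build_notch_model,
    build_wnt_model,
    integrate,
    validate,
)
from somiteclock.network import Compartment, ModelValidationError, SpeciesRole


class TestCompileRhs:
    def test_birth_death_closed_form(self, birth_death_model):
        rhs = birth_death_model.compile_rhs()
        # rhs(X) = k - d X; steady state k/d = 2
        assert rhs(0.0, np.array([0.0]))[0] == pytest.approx(0.5)
        assert rhs(0.0, np.array([2.0]))[0] == pytest.approx(0.0)
        assert rhs(0.0, np.array([4.0]))[0] == pytest.approx(-0.5)

    def test_zero_reactions_zero_derivative(self):
        m = PathwayModel(
            model_id="empty",
            species=[Species("X", Compartment.CYTOPLASM, SpeciesRole.PROTEIN)],
            parameters=ParameterSet({}),
        )
        assert m.compile_rhs()(0.0, np.array([3.0]))[0] == 0.0

    def test_missing_parameter_is_reported(self, birth_death_model):
        del birth_death_model.parameters.values["d"]
        with pytest.raises(ModelValidationError, match="'d'"):
            birth_death_model.compile_rhs()

    def test_stoichiometry_enters_derivative(self):
        m = PathwayModel(
            model_id="dimer",
            species=[
                Species("A", Compartment.CYTOPLASM, SpeciesRole.PROTEIN),
                Species("D", Compartment.CYTOPLASM, SpeciesRole.COMPLEX),
            ],
            reactions=[
                Reaction("dimerize", reactants={"A": 2}, products={"D": 1},
                         rate_law=RateLaw.mass_action("kf", ["A", "A"]))
            ],
            parameters=ParameterSet({"kf": 1.0}),
        )
        d = m.compile_rhs()(0.0, np.array([2.0, 0.0]))
        assert d[0] == pytest.approx(-8.0)  # -2 * kf * A^2
        assert d[1] == pytest.approx(4.0)

    def test_conserved_pool_is_algebraic(self, notch_model):
        """Free RBP-j is total minus complex, so conservation is exact."""
        traj = integrate(notch_model, SimulationConfig(t_end=600.0))
        total = notch_model.parameters["RBPj_total"]
        complex_level = traj["NICD_RBPj"]
        assert np.all(complex_level <= total + 1e-9)


class TestValidate:
    def test_reference_models_are_clean(self):
        assert validate(build_notch_model()) == []
        assert validate(build_wnt_model()) == []

    def test_extracellular_mrna_flagged(self):
        m = PathwayModel(
            model_id="bad",
            species=[Species("m", Compartment.EXTRACELLULAR, SpeciesRole.MRNA)],
            parameters=ParameterSet({}),
        )
        report = validate(m)
        assert any("extracellular" in r and "'m'" in r for r in report)

    def test_nuclear_mrna_degradation_flagged(self):
        m = PathwayModel(
            model_id="bad",
            species=[Species("m", Compartment.NUCLEUS, SpeciesRole.MRNA)],
            reactions=[
                Reaction("deg_m", reactants={"m": 1},
                         rate_law=RateLaw.michaelis_menten("V", "K", "m"),
                         kind="degradation")
            ],
            parameters=ParameterSet({"V": 1.0, "K": 1.0}),
        )
        assert any("outside the cytoplasm" in r for r in validate(m))

    def test_missing_rate_constant_named(self):
        m = build_notch_model()
        del m.parameters.values["k_cleave"]
        assert any("k_cleave" in r for r in validate(m))


class TestPerturbations:
    def test_gene_knockout_zeroes_transcription(self):
        m = build_notch_model()
        out = apply_perturbation(m, Perturbation("knockout_gene", "Hes7", 120))
        assert out.parameters["V_tx_hes7"] == 0.0
        assert m.parameters["V_tx_hes7"] > 0.0  # original untouched

    def test_overexpression_scales_vmax(self):
        m = build_wnt_model()
        v0 = m.parameters["V_tx_axin2"]
        out = apply_perturbation(
            m, Perturbation("overexpress_gene", "Axin2", 120, factor=3.0))
        assert out.parameters["V_tx_axin2"] == pytest.approx(3.0 * v0)

    def test_scale_input_identity_is_noop(self, wnt_model):
        cfg = SimulationConfig(t_end=480.0)
        a = integrate(wnt_model, cfg)
        b = integrate(wnt_model, cfg,
                      [Perturbation("scale_input", "Wnt", 60.0, factor=1.0)])
        # the segment restart changes the adaptive step sequence, so agreement
        # is to solver tolerance, not bitwise
        assert np.allclose(a.values, b.values, rtol=1e-4, atol=1e-6)

    def test_unknown_target_raises(self):
        m = build_notch_model()
        with pytest.raises(KeyError):
            apply_perturbation(m, Perturbation("knockout_gene", "Wnt5a", 0))

    def test_factor_validation(self):
        with pytest.raises(ValueError):
            Perturbation("overexpress_gene", "Axin2", 0, factor=-1.0)
        with pytest.raises(ValueError):
            Perturbation("knockout_gene", "Hes7", 0, factor=2.0)

    def test_knockout_gene_decay_contract(self, notch_model):
        """After a Hes7 knockout the mRNA decays to under 1% of its peak."""
        traj = integrate(notch_model, SimulationConfig(t_end=1200.0),
                         [Perturbation("knockout_gene", "Hes7", 120.0)])
        pre_peak = traj["Hes7_mRNA_cyt"][traj.times <= 120].max()
        assert traj["Hes7_mRNA_cyt"][-1] < 0.01 * pre_peak

    def test_remove_input_collapses_dsh(self, wnt_model):
        """Removing Wnt makes active Dsh collapse immediately."""
        traj = integrate(wnt_model, SimulationConfig(t_end=600.0),
                         [Perturbation("remove_input", "Wnt", 120.0)])
        pre = traj["Dsh_active"][traj.times <= 120].max()
        just_after = traj["Dsh_active"][traj.times >= 140][0]
        assert just_after < 0.05 * pre
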
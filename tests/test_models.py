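"""Model builders: structure, oscillation, phases, the time-rescaling oracle."""

import numpy as np
import pytest

from somiteclock import (
    MODEL_CATALOG,
    SimulationConfig,
    build_combined_model,
    build_model,
    build_notch_model,
    build_wnt_model,
    integrate,
    measure,
    phase_relation,
    validate,
)

NOTCH_STATE = {
    "Dll1_protein", "Notch_receptor", "NICD_cyt", "NICD_nuc", "NICD_RBPj",
    "Lfng_mRNA_nuc", "Lfng_mRNA_cyt", "Lfng_protein",
    "Hes7_mRNA_nuc", "Hes7_mRNA_cyt", "Hes7_protein_cyt", "Hes7_protein_nuc",
}


class TestStructure:
    def test_notch_has_exactly_12_ode_species(self):
        m = build_notch_model()
        assert set(m.dynamic_names()) == NOTCH_STATE
        assert len(m.dynamic_names()) == 12

    def test_wnt_has_exactly_13_ode_species(self):
        m = build_wnt_model()
        assert len(m.dynamic_names()) == 13

    def test_combined_adds_exactly_five_new_species(self):
        notch = set(build_notch_model().dynamic_names())
        wnt = set(build_wnt_model().dynamic_names())
        combined = set(build_combined_model().dynamic_names())
        new = combined - (notch | wnt)
        assert new == {"NICD_Dsh", "Nkd1_mRNA_nuc", "Nkd1_mRNA_cyt",
                       "Nkd1_protein", "Nkd1_Dsh"}
        # the merge shares Dll1 protein and drops nothing else
        assert combined == (notch | wnt) | new

    def test_combined_drops_constant_dll1_supply(self):
        notch = build_notch_model()
        combined = build_combined_model()
        assert any(r.name == "syn_dll1" for r in notch.reactions)
        assert not any(r.name == "syn_dll1" for r in combined.reactions)
        # Dll1 translation from the Wnt side is preserved
        assert any(r.name == "tl_dll1" for r in combined.reactions)

    def test_catalog_counts_match_builders(self):
        for entry in MODEL_CATALOG.values():
            m = build_model(entry.model_id)
            assert len(m.dynamic_names()) == entry.expected_ode_count
            assert tuple(m.target_genes) == entry.target_genes

    def test_all_builders_validate_clean(self):
        for model_id in MODEL_CATALOG:
            assert validate(build_model(model_id)) == []

    def test_unknown_model_id_rejected(self):
        with pytest.raises(KeyError):
            build_model("fgf")


class TestReferenceOscillation:
    @pytest.mark.parametrize("fixture_name", [
        "notch_reference", "wnt_reference", "combined_reference"])
    def test_every_target_mrna_cycles_near_120_min(self, request, fixture_name):
        traj = request.getfixturevalue(fixture_name)
        model = request.getfixturevalue(fixture_name.replace("_reference", "_model"))
        for gene, species in model.readouts.items():
            s = measure(traj, species)
            assert s.is_oscillating, f"{gene} not oscillating"
            assert s.period == pytest.approx(120.0, abs=12.0), gene

    def test_notch_fig_phase_structure(self, notch_reference):
        """Targets in phase with NICD, in antiphase with nuclear Hes7."""
        assert phase_relation(
            notch_reference, "Lfng_mRNA_cyt", "NICD_nuc"
        ).classification.value == "in_phase"
        assert phase_relation(
            notch_reference, "Lfng_mRNA_cyt", "Hes7_protein_nuc"
        ).classification.value == "antiphase"

    def test_wnt_internal_phase_structure(self, wnt_reference):
        """Active Dsh antiphase to the degradation complex and Axin2;
        the complex antiphase to the transcriptional activator."""
        pairs = [("Dsh_active", "GSK3_Axin2", "antiphase"),
                 ("Dsh_active", "Axin2_protein", "antiphase"),
                 ("GSK3_Axin2", "bcat_Lef1", "antiphase"),
                 ("GSK3_Axin2", "Axin2_protein", "in_phase")]
        for a, b, want in pairs:
            assert phase_relation(wnt_reference, a, b).classification.value == want


RATE_PREFIXES = ("k_", "V_")


def rescale_rates(params: dict, c: float) -> dict:
    """All rate constants and Vmax x c; Hill K's and pool totals untouched."""
    return {k: (v * c if k.startswith(RATE_PREFIXES) else v)
            for k, v in params.items()}


class TestTimeRescalingOracle:
    @pytest.mark.parametrize("model_id", ["notch", "wnt"])
    def test_doubling_rates_halves_period(self, model_id):
        base = build_model(model_id)
        params = dict(base.parameters.values)
        fast = build_model(model_id, rescale_rates(params, 2.0))
        for s_fast, s_base in zip(fast.species, base.species):
            s_fast.initial_value = s_base.initial_value

        cfg = SimulationConfig(t_end=1200.0)
        ref = integrate(base, cfg)
        half = integrate(fast, SimulationConfig(t_end=600.0))

        sp = base.readouts[base.target_genes[0]]
        t_ref = measure(ref, sp).period
        t_fast = measure(half, sp).period
        assert t_fast == pytest.approx(t_ref / 2.0, rel=0.02)

    def test_rescaled_trajectory_matches_time_compressed_original(self):
        """x_c(t) = x(ct) exactly: the compressed run retraces the original."""
        base = build_notch_model()
        fast = build_notch_model(
            rescale_rates(dict(base.parameters.values), 2.0))
        for s_fast, s_base in zip(fast.species, base.species):
            s_fast.initial_value = s_base.initial_value
        ref = integrate(base, SimulationConfig(t_end=600.0, output_dt=2.0))
        half = integrate(fast, SimulationConfig(t_end=300.0, output_dt=1.0))
        assert np.allclose(ref.values, half.values, rtol=1e-3, atol=1e-6)
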
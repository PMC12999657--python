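"""Local sensitivity analysis and parameter identification."""

import numpy as np
import pytest

import doxpbpk as d
from doxpbpk.errors import ConfigurationError
from doxpbpk.sensitivity import (
    FitParameter,
    FitSpec,
    ProfileFit,
    local_sensitivity,
    rank_sensitivities,
)


@pytest.fixture(scope="module")
def low_dose_scenario(fast_settings):
    """Dose scaled down 100x: unbound concentrations stay far below both
    Km values, so the system responds linearly to dose."""
    return d.ParentMetabolitePBPK.default(dose_mg=0.75, settings=fast_settings)


@pytest.fixture(scope="module")
def nm_scenario(fast_settings):
    return d.ParentMetabolitePBPK.default(genotype="NM", settings=fast_settings)


class TestLocalSensitivity:
    def test_dose_sensitivity_is_unity_in_linear_regime(self, low_dose_scenario):
        s = local_sensitivity(low_dose_scenario, "dose", "AUC_inf", "parent")
        assert s.sensitivity == pytest.approx(1.0, abs=0.02)
        assert s.perturbation == 0.10

    def test_inert_parameter_has_zero_sensitivity(self, nm_scenario):
        """Metabolite solubility never enters the systemic model (the
        metabolite is formed in the liver, not dosed orally)."""
        s = local_sensitivity(nm_scenario, "metabolite.solubility", "AUC_inf", "metabolite")
        assert s.sensitivity == 0.0

    def test_parent_cyp2d6_kcat_lowers_parent_exposure(self, nm_scenario):
        s = local_sensitivity(nm_scenario, "parent.CYP2D6.kcat", "AUC_inf", "parent")
        assert s.sensitivity < 0

    def test_unknown_parameter_raises_lookup_error(self, nm_scenario):
        with pytest.raises(LookupError):
            local_sensitivity(nm_scenario, "parent.banana", "AUC_inf", "parent")

    def test_finite_difference_consistency(self, low_dose_scenario):
        """S at perturbations 0.10 and 0.01 agree within 10% relative for
        a smooth parameter."""
        s_10 = local_sensitivity(
            low_dose_scenario, "parent.fraction_unbound", "AUC_inf", "parent", 0.10
        )
        s_01 = local_sensitivity(
            low_dose_scenario, "parent.fraction_unbound", "AUC_inf", "parent", 0.01
        )
        assert s_10.sensitivity == pytest.approx(s_01.sensitivity, rel=0.10)


class TestRankSensitivities:
    def test_known_ordering_dose_before_inert(self, low_dose_scenario):
        results = rank_sensitivities(
            low_dose_scenario, ["metabolite.solubility", "dose"],
            metric="AUC_inf", compound="parent",
        )
        assert [r.parameter for r in results] == ["dose", "metabolite.solubility"]
        assert results[0].influential and not results[1].influential

    def test_single_parameter_panel(self, low_dose_scenario):
        results = rank_sensitivities(low_dose_scenario, ["dose"])
        assert len(results) == 1

    def test_empty_panel_rejected(self, nm_scenario):
        with pytest.raises(ConfigurationError):
            rank_sensitivities(nm_scenario, [])

    def test_parent_auc_panel_ranks_clearance_drivers(self, nm_scenario):
        """The parameter panel of the parent AUC analysis: dose and
        fraction unbound dominate; the CYP2D6 parameters carry the
        clearance-role signs (kcat and reference concentration negative,
        Km positive)."""
        panel = [
            "dose",
            "parent.fraction_unbound",
            "parent.CYP2D6.kcat",
            "parent.CYP2D6.reference_concentration",
            "parent.CYP2D6.km",
        ]
        results = rank_sensitivities(nm_scenario, panel, metric="AUC_inf", compound="parent")
        by_name = {r.parameter: r for r in results}
        assert set(by_name) == set(panel)
        mags = [abs(r.sensitivity) for r in results]
        assert mags == sorted(mags, reverse=True)
        assert by_name["dose"].influential
        assert by_name["parent.CYP2D6.kcat"].sensitivity < 0
        assert by_name["parent.CYP2D6.reference_concentration"].sensitivity < 0
        assert by_name["parent.CYP2D6.km"].sensitivity > 0


class TestProfileFit:
    def test_empty_parameter_list_returns_initial_scenario(self, fast_scenario):
        spec = FitSpec(parameters=(), data=())
        res = ProfileFit(fast_scenario, spec).fit()
        assert res.success and res.n_iterations == 0
        assert res.params == {} and res.scenario is fast_scenario

    @pytest.mark.parametrize("start_factor", [0.5, 1.5])
    def test_noise_free_recovery_within_one_percent(
        self, fast_scenario, clean_metabolite_profile, start_factor
    ):
        """Noise-free synthetic data generated at the true turnover number
        are recovered to < 1% from start values perturbed by +/-50%."""
        true_kcat = 160.0
        spec = FitSpec(
            parameters=(
                FitParameter(
                    "metabolite.CYP2D6.kcat", true_kcat * start_factor, 1.0, 2000.0
                ),
            ),
            data=(clean_metabolite_profile,),
            duration_h=96.0,
        )
        res = ProfileFit(fast_scenario, spec).fit()
        assert res.success
        est = res.params["metabolite.CYP2D6.kcat"]
        assert abs(est - true_kcat) / true_kcat < 0.01

    def test_objective_improves_over_the_fit(self, fast_scenario, clean_metabolite_profile):
        spec = FitSpec(
            parameters=(FitParameter("metabolite.CYP2D6.kcat", 240.0, 1.0, 2000.0),),
            data=(clean_metabolite_profile,),
            duration_h=96.0,
        )
        res = ProfileFit(fast_scenario, spec).fit()
        assert res.trace[0] >= res.cost - 1e-12
        assert res.se["metabolite.CYP2D6.kcat"] >= 0

    def test_summary_reports_the_estimate(self, fast_scenario, clean_metabolite_profile):
        spec = FitSpec(
            parameters=(FitParameter("metabolite.CYP2D6.kcat", 200.0, 1.0, 2000.0),),
            data=(clean_metabolite_profile,),
            duration_h=96.0,
        )
        res = ProfileFit(fast_scenario, spec).fit()
        text = res.summary()
        assert "metabolite.CYP2D6.kcat" in text and "converged" in text

    def test_bounds_must_contain_initial(self):
        with pytest.raises(ConfigurationError):
            FitParameter("x", 10.0, 20.0, 30.0)
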
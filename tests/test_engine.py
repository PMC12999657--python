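"""Whole-body engine: rate law, assembly, mass balance, oracles."""

import dataclasses

import numpy as np
import pytest

import doxpbpk as d
from doxpbpk.errors import BuildError, SmallPopulationWarning


def _model(genotype=None, **kwargs):
    return d.build_model(
        d.doxepin(), d.nordoxepin(), d.reference_individual(), genotype,
        d.DoseRegimen(dose_mg=kwargs.pop("dose_mg", 75.0)), **kwargs,
    )


class TestMichaelisMentenRate:
    def test_zero_substrate_gives_zero(self):
        assert d.michaelis_menten_rate(260.0, 0.4, 88.0, 0.0, 1.8) == 0.0

    def test_half_saturation_is_half_the_maximal_rate(self):
        vmax = 260.0 * 0.4 * 1.0 * 1e3  # saturated, 1 L liver
        v = d.michaelis_menten_rate(260.0, 0.4, 88.0, 88.0, 1.0)
        assert v == pytest.approx(vmax / 2, rel=1e-12)

    def test_printed_parameter_example(self):
        """260/min * 0.40 uM enzyme at 1 uM substrate, Km 88 uM, 1 L."""
        v = d.michaelis_menten_rate(260.0, 0.40, 88.0, 1.0, 1.0)
        assert v == pytest.approx(1168.5, rel=1e-3)

    def test_zero_kcat_gives_zero(self):
        assert d.michaelis_menten_rate(0.0, 0.4, 88.0, 5.0, 1.8) == 0.0


class TestBuildModel:
    def test_pm_genotype_zeroes_both_cyp2d6_kcats(self):
        model = _model(d.GenotypeProfile(phenotype="PM"))
        assert model.parent.pathway("CYP2D6").kcat == 0.0
        assert model.metabolite.pathway("CYP2D6").kcat == 0.0

    def test_no_genotype_keeps_base_kcats(self):
        model = _model()
        assert model.parent.pathway("CYP2D6").kcat == 260.0
        assert model.metabolite.pathway("CYP2D6").kcat == 160.0

    def test_exactly_one_metabolite_forming_pathway(self):
        model = _model(d.GenotypeProfile(phenotype="UM"))
        formers = [
            p for c in (model.parent, model.metabolite)
            for p in c.pathways if p.product == "metabolite"
        ]
        assert len(formers) == 1 and formers[0].enzyme == "CYP2C19"

    def test_metabolite_forming_pathway_on_metabolite_rejected(self):
        bad_pathways = tuple(
            dataclasses.replace(p, product="metabolite")
            for p in d.nordoxepin().pathways
        )
        bad = dataclasses.replace(d.nordoxepin(), pathways=bad_pathways)
        with pytest.raises(BuildError):
            d.build_model(
                d.doxepin(), bad, d.reference_individual(), None,
                d.DoseRegimen(dose_mg=75.0),
            )

    def test_parent_without_cyp2c19_rejected(self):
        only_d6 = dataclasses.replace(
            d.doxepin(),
            pathways=(d.doxepin().pathway("CYP2D6"),),
        )
        with pytest.raises(BuildError):
            d.build_model(
                only_d6, d.nordoxepin(), d.reference_individual(), None,
                d.DoseRegimen(dose_mg=75.0),
            )


class TestSimulate:
    def test_zero_dose_gives_identically_zero_profiles(self):
        out = d.simulate(_model(dose_mg=0.0), duration_h=24.0)
        assert np.all(out.parent.concentrations == 0)
        assert np.all(out.metabolite.concentrations == 0)

    def test_pm_never_eliminates_through_cyp2d6(self):
        out = d.simulate(_model(d.GenotypeProfile(phenotype="PM")), duration_h=48.0)
        assert np.all(out.cumulative["parent_cyp2d6"] == 0)
        assert np.all(out.cumulative["metabolite_cyp2d6"] == 0)

    def test_mass_balance_closes(self, default_result):
        """absorbed = parent in body + parent eliminated + metabolite formed,
        and formed = metabolite in body + metabolite eliminated, to < 1e-6."""
        assert default_result.max_mass_balance_error < 1e-6

    def test_metabolite_formation_is_mole_for_mole(self, default_result):
        out = default_result.output
        formed = out.cumulative["parent_cyp2c19"][-1]
        accounted = (
            out.amounts_metabolite[-1]
            + out.cumulative["metabolite_cyp2d6"][-1]
            + out.cumulative["metabolite_hepatic"][-1]
        )
        assert formed == pytest.approx(accounted, rel=1e-9)

    def test_one_compartment_matches_bateman_closed_form(self):
        """Collapsed topology vs the analytic first-order absorption /
        elimination solution, within 0.1% relative everywhere."""
        dose, ka_min, cl, vol = 1.0e5, 0.05, 0.5, 50.0
        model = d.OneCompartmentModel(
            dose_nmol=dose, ka_per_min=ka_min, clearance_L_per_min=cl, volume_L=vol
        )
        grid = np.arange(0.25, 24.25, 0.25)
        prof = model.simulate(24.0, grid)
        ka, ke = ka_min * 60.0, cl / vol * 60.0  # 1/h
        analytic = dose * ka / (vol * (ka - ke)) * (
            np.exp(-ke * grid) - np.exp(-ka * grid)
        )
        np.testing.assert_allclose(prof.concentrations, analytic, rtol=1e-3)


@pytest.fixture(scope="module")
def auc_by_phenotype(fast_settings):
    auc = {}
    for phenotype in ("UM", "NM", "IM", "PM"):
        sc = d.ParentMetabolitePBPK.default(genotype=phenotype, settings=fast_settings)
        res = sc.simulate(duration_h=144.0)
        auc[phenotype] = (res.nca("parent").auc_inf, res.nca("metabolite").auc_inf)
    return auc


class TestGenotypeOrdering:
    def test_parent_exposure_rises_as_cyp2d6_capacity_falls(self, auc_by_phenotype):
        a = {k: v[0] for k, v in auc_by_phenotype.items()}
        assert a["PM"] > a["IM"] > a["NM"] > a["UM"]

    def test_metabolite_exposure_inverse_to_cyp2d6_activity(self, auc_by_phenotype):
        m = {k: v[1] for k, v in auc_by_phenotype.items()}
        assert m["PM"] > m["UM"]


class TestSimulatePopulation:
    def test_identical_individuals_collapse_the_band(self, fast_settings):
        ind = d.reference_individual()
        with pytest.warns(SmallPopulationWarning):
            summary = d.simulate_population(
                d.doxepin(), d.nordoxepin(), [ind] * 3, None,
                d.DoseRegimen(dose_mg=75.0), duration_h=24.0, settings=fast_settings,
            )
        stats = summary.statistics["doxepin"]
        np.testing.assert_allclose(stats["p5"], stats["mean"], rtol=1e-12)
        np.testing.assert_allclose(stats["p95"], stats["mean"], rtol=1e-12)

    def test_population_band_is_ordered(self, fast_settings):
        spec = d.DemographicSpec.from_study_group("doxepin", "non-genotyped", n=25)
        pop = d.build_population(spec, 5)
        summary = d.simulate_population(
            d.doxepin(), d.nordoxepin(), pop, None, d.DoseRegimen(dose_mg=75.0),
            duration_h=24.0, settings=fast_settings,
        )
        assert summary.n == 25
        for stats in summary.statistics.values():
            assert np.all(stats["p5"] <= stats["p95"] + 1e-12)
            assert np.all(stats["p5"] <= stats["mean"] + 1e-12)

    def test_empty_population_rejected(self):
        with pytest.raises(BuildError):
            d.simulate_population(
                d.doxepin(), d.nordoxepin(), [], None, d.DoseRegimen(dose_mg=75.0)
            )


def test_simulation_is_deterministic(fast_scenario):
    a = fast_scenario.simulate(duration_h=24.0)
    b = fast_scenario.simulate(duration_h=24.0)
    np.testing.assert_array_equal(a.parent.concentrations, b.parent.concentrations)
    np.testing.assert_array_equal(
        a.metabolite.concentrations, b.metabolite.concentrations
    )
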
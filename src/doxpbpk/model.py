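"""High-level modelling objects.

:class:`ParentMetabolitePBPK` is the scenario/model class: it holds the
compound parameterizations, genotype, dose regimen, virtual individual
and solver settings, and knows how to build and run the whole-body
engine. ``simulate()`` returns a :class:`SimulationResults` carrying the
profiles, exposure metrics, mass-balance diagnostics and a ``summary()``
table; ``simulate_population()`` returns population mean / 90%
prediction-interval bands. Parameters are addressable by dotted path
(e.g. ``"parent.CYP2D6.kcat"`` or ``"dose"``), which is what the
sensitivity and fitting layers perturb.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from . import engine
from .absorption import DoseRegimen
from .compounds import CompoundParameters, doxepin, nordoxepin
from .engine import SimulationSettings
from .errors import ConfigurationError
from .evaluation import PKMetrics, nca
from .genotype import GenotypeProfile
from .population import (
    DemographicSpec,
    VirtualIndividual,
    build_population,
    reference_individual,
)

__all__ = ["ParentMetabolitePBPK", "SimulationResults", "PopulationResults"]

_COMPOUND_SCALARS = (
    "log_p", "fraction_unbound", "solubility", "molecular_weight",
    "intestinal_permeability", "organ_permeability", "total_hepatic_clearance",
)
_PATHWAY_SCALARS = ("km", "kcat", "reference_concentration")
_REGIMEN_SCALARS = ("dose_mg", "t50_min", "shape_b")


@dataclass(frozen=True)
class ParentMetabolitePBPK:
    """A runnable parent+metabolite PBPK scenario.

    The genotype (if any) is applied to both compounds' CYP2D6 turnover
    numbers at construction, so subsequent parameter perturbations see
    the genotype-scaled values.
    """

    parent: CompoundParameters
    metabolite: CompoundParameters
    regimen: DoseRegimen
    individual: VirtualIndividual
    genotype: GenotypeProfile | None = None
    settings: SimulationSettings = field(default_factory=SimulationSettings)
    _genotype_applied: bool = False

    def __post_init__(self):
        if self.genotype is not None and not self._genotype_applied:
            object.__setattr__(
                self, "parent",
                self.parent.with_pathway_kcat("CYP2D6", self.genotype.kcat(self.parent.name)),
            )
            object.__setattr__(
                self, "metabolite",
                self.metabolite.with_pathway_kcat(
                    "CYP2D6", self.genotype.kcat(self.metabolite.name)
                ),
            )
            object.__setattr__(self, "_genotype_applied", True)

    # ------------------------------------------------------------------
    @classmethod
    def default(
        cls,
        genotype: GenotypeProfile | str | None = None,
        dose_mg: float = 75.0,
        formulation: str = "tablet_weibull",
        individual: VirtualIndividual | None = None,
        settings: SimulationSettings | None = None,
    ) -> "ParentMetabolitePBPK":
        """The bundled study setup: 75 mg single oral dose, reference
        subject, optional CYP2D6 phenotype (string or profile)."""
        if isinstance(genotype, str):
            genotype = GenotypeProfile(phenotype=genotype)
        return cls(
            parent=doxepin(),
            metabolite=nordoxepin(),
            regimen=DoseRegimen(dose_mg=dose_mg, formulation=formulation),
            individual=individual if individual is not None else reference_individual(),
            genotype=genotype,
            settings=settings if settings is not None else SimulationSettings(),
        )

    @classmethod
    def from_config(cls, config) -> "ParentMetabolitePBPK":
        """Build from a :class:`~doxpbpk.config.RunConfig` or a YAML path."""
        from .config import RunConfig, load_config

        if not isinstance(config, RunConfig):
            config = load_config(config)
        return config.scenario()

    # ------------------------------------------------------------------
    def build(self) -> engine.PBPKModel:
        # genotype already folded into the compound kcats
        return engine.build_model(
            self.parent, self.metabolite, self.individual, None, self.regimen,
            self.settings,
        )

    def simulate(
        self, duration_h: float = 96.0, output_grid_h=None
    ) -> "SimulationResults":
        out = engine.simulate(self.build(), duration_h, output_grid_h)
        return SimulationResults(scenario=self, output=out)

    def simulate_population(
        self,
        population: list[VirtualIndividual] | DemographicSpec,
        seed: int | None = None,
        duration_h: float = 96.0,
        output_grid_h=None,
    ) -> "PopulationResults":
        if isinstance(population, DemographicSpec):
            if seed is None:
                raise ConfigurationError("a seed is required to sample a population")
            population = build_population(population, seed)
        summary = engine.simulate_population(
            self.parent, self.metabolite, population, None, self.regimen,
            duration_h, output_grid_h, self.settings,
        )
        return PopulationResults(scenario=self, summary=summary, seed=seed)

    # ------------------------------------------------------------------
    # dotted-path parameter addressing
    def _resolve(self, path: str):
        parts = path.split(".")
        if path == "dose":
            parts = ["regimen", "dose_mg"]
        if len(parts) == 2 and parts[0] == "regimen" and parts[1] in _REGIMEN_SCALARS:
            return ("regimen", parts[1], None)
        if len(parts) == 2 and parts[0] in ("parent", "metabolite"):
            if parts[1] not in _COMPOUND_SCALARS:
                raise LookupError(f"unknown compound parameter {parts[1]!r}")
            return (parts[0], parts[1], None)
        if len(parts) == 3 and parts[0] in ("parent", "metabolite"):
            if parts[2] not in _PATHWAY_SCALARS:
                raise LookupError(f"unknown pathway parameter {parts[2]!r}")
            return (parts[0], parts[2], parts[1])
        raise LookupError(f"cannot address parameter {path!r}")

    def get_parameter(self, path: str) -> float:
        target, attr, enzyme = self._resolve(path)
        obj = getattr(self, target) if target != "regimen" else self.regimen
        if enzyme is not None:
            obj = obj.pathway(enzyme)
        value = getattr(obj, attr)
        if value is None:
            raise LookupError(f"parameter {path!r} is not set on this scenario")
        return float(value)

    def with_parameter(self, path: str, value: float) -> "ParentMetabolitePBPK":
        """Return a copy with one addressable parameter replaced."""
        target, attr, enzyme = self._resolve(path)
        if target == "regimen":
            return replace(self, regimen=replace(self.regimen, **{attr: value}))
        compound = getattr(self, target)
        if enzyme is None:
            compound = replace(compound, **{attr: value})
        else:
            pathway = compound.pathway(enzyme)
            new = tuple(
                replace(p, **{attr: value}) if p.enzyme == enzyme else p
                for p in compound.pathways
            )
            compound = replace(compound, pathways=new)
            del pathway
        return replace(self, **{target: compound})

    def scaled(self, path: str, factor: float) -> "ParentMetabolitePBPK":
        return self.with_parameter(path, self.get_parameter(path) * factor)


@dataclass(frozen=True)
class SimulationResults:
    """Results of one individual simulation."""

    scenario: ParentMetabolitePBPK
    output: engine.SimulationOutput

    @property
    def parent(self) -> engine.ConcentrationTimeProfile:
        return self.output.parent

    @property
    def metabolite(self) -> engine.ConcentrationTimeProfile:
        return self.output.metabolite

    @property
    def max_mass_balance_error(self) -> float:
        return self.output.max_mass_balance_error

    def profile(self, which: str) -> engine.ConcentrationTimeProfile:
        if which in ("parent", self.parent.compound):
            return self.parent
        if which in ("metabolite", self.metabolite.compound):
            return self.metabolite
        raise LookupError(f"unknown compound {which!r}")

    def nca(self, which: str = "parent") -> PKMetrics:
        return nca(self.profile(which))

    def to_frame(self) -> pd.DataFrame:
        """Long-format profile table (time_h, compound, concentration)."""
        frames = []
        for prof in (self.parent, self.metabolite):
            frames.append(
                pd.DataFrame(
                    {
                        "time_h": prof.times_h,
                        "compound": prof.compound,
                        "concentration_nmol_per_L": prof.concentrations,
                        "statistic": prof.kind,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        sc = self.scenario
        lines = [
            "Parent-metabolite PBPK simulation",
            "=" * 49,
            f"dose           : {sc.regimen.dose_mg:g} mg ({sc.regimen.formulation})",
            f"genotype       : {sc.genotype.phenotype if sc.genotype else 'non-genotyped'}",
            f"individual     : {sc.individual.weight:.1f} kg, {sc.individual.age:.0f} yr, {sc.individual.sex}",
            f"mass balance   : max rel. error {self.max_mass_balance_error:.2e}",
            "",
            f"{'compound':<14}{'AUCinf':>12}{'Cmax':>10}{'Tmax':>8}{'extrap':>9}",
            f"{'':<14}{'nmol*hr/L':>12}{'nmol/L':>10}{'h':>8}{'frac':>9}",
            "-" * 53,
        ]
        for which in ("parent", "metabolite"):
            prof = self.profile(which)
            m = self.nca(which)
            lines.append(
                f"{prof.compound:<14}{m.auc_inf:>12.2f}{m.cmax:>10.2f}"
                f"{m.tmax:>8.2f}{m.extrapolated_fraction:>9.3f}"
            )
        return "\n".join(lines)

    def plot(self, ax=None, log_scale: bool = True):
        """Concentration–time profiles for both compounds."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for prof in (self.parent, self.metabolite):
            ax.plot(prof.times_h, prof.concentrations, label=prof.compound)
        if log_scale:
            ax.set_yscale("log")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("plasma concentration (nmol/L)")
        ax.legend()
        return ax


@dataclass(frozen=True)
class PopulationResults:
    """Population mean and 90% prediction-interval profiles."""

    scenario: ParentMetabolitePBPK
    summary_data: engine.PopulationSummary = None
    seed: int | None = None

    def __init__(self, scenario, summary, seed=None):
        object.__setattr__(self, "scenario", scenario)
        object.__setattr__(self, "summary_data", summary)
        object.__setattr__(self, "seed", seed)

    @property
    def n(self) -> int:
        return self.summary_data.n

    def profile(self, compound: str, stat: str = "mean") -> engine.ConcentrationTimeProfile:
        return self.summary_data.profile(compound, stat)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for compound, stats in self.summary_data.statistics.items():
            for stat, conc in stats.items():
                rows.append(
                    pd.DataFrame(
                        {
                            "time_h": self.summary_data.times_h,
                            "compound": compound,
                            "concentration_nmol_per_L": conc,
                            "statistic": stat,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def summary(self) -> str:
        sc = self.scenario
        lines = [
            f"Virtual population simulation (n = {self.n})",
            f"dose {sc.regimen.dose_mg:g} mg, genotype "
            f"{sc.genotype.phenotype if sc.genotype else 'non-genotyped'}",
            f"{'compound':<14}{'mean Cmax':>12}{'p5 Cmax':>10}{'p95 Cmax':>10}  nmol/L",
        ]
        for compound, stats in self.summary_data.statistics.items():
            lines.append(
                f"{compound:<14}{stats['mean'].max():>12.2f}"
                f"{stats['p5'].max():>10.2f}{stats['p95'].max():>10.2f}"
            )
        return "\n".join(lines)

    def plot(self, compound: str, ax=None, observed=None):
        """Visual predictive check: mean line + 90% prediction band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.summary_data.times_h
        stats = self.summary_data.statistics[compound]
        ax.fill_between(t, stats["p5"], stats["p95"], alpha=0.3, label="90% PI")
        ax.plot(t, stats["mean"], label=f"{compound} mean")
        if observed is not None:
            ax.plot(observed.times_h, observed.concentrations, "o", label="observed")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("plasma concentration (nmol/L)")
        ax.legend()
        return ax
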
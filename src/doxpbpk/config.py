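"""Run configuration: schema, validation, and scenario assembly.

A run configuration is one human-readable YAML file whose defaults equal
the bundled study setup (75 mg single oral dose, bundled compound files,
reference demographics), so a config containing only a genotype block
reproduces the study conditions. Validation happens before any
computation and errors name the offending field.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import yaml

from .absorption import DoseRegimen
from .compounds import CompoundParameters, load_compound
from .engine import SimulationSettings
from .errors import ConfigurationError
from .genotype import GenotypeProfile
from .population import DemographicSpec

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    parent: CompoundParameters
    metabolite: CompoundParameters
    genotype: GenotypeProfile | None
    regimen: DoseRegimen
    population: DemographicSpec
    duration_h: float
    grid_step_h: float | None
    settings: SimulationSettings
    seed: int
    output_dir: str
    raw: dict = field(default_factory=dict, compare=False)

    def scenario(self, individual=None):
        from .model import ParentMetabolitePBPK
        from .population import reference_individual

        return ParentMetabolitePBPK(
            parent=self.parent,
            metabolite=self.metabolite,
            regimen=self.regimen,
            individual=individual if individual is not None else reference_individual(),
            genotype=self.genotype,
            settings=self.settings,
        )

    @property
    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.raw, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def _require(block: dict, key: str, context: str):
    if key not in block or block[key] is None:
        raise ConfigurationError(f"missing required field {key!r} in {context} block")
    return block[key]


def _genotype_from_block(block) -> GenotypeProfile | None:
    if block is None:
        return None
    if not isinstance(block, dict):
        raise ConfigurationError("genotype block must be a mapping")
    keys = [k for k in ("phenotype", "activity_score", "alleles") if block.get(k) is not None]
    if not keys:
        return None
    if len(keys) > 1:
        raise ConfigurationError(
            "genotype block must set exactly one of phenotype / activity_score / alleles"
        )
    if keys[0] == "phenotype":
        phenotype = block["phenotype"]
        if phenotype in (None, "non-genotyped"):
            return None
        return GenotypeProfile(phenotype=phenotype)
    if keys[0] == "activity_score":
        return GenotypeProfile.from_activity_score(float(block["activity_score"]))
    return GenotypeProfile.from_alleles(list(block["alleles"]))


def config_from_dict(raw: dict) -> RunConfig:
    raw = dict(raw or {})

    compounds = raw.get("compounds") or {}
    parent = load_compound(compounds.get("parent", "doxepin"))
    metabolite = load_compound(compounds.get("metabolite", "nordoxepin"))

    regimen_block = raw.get("regimen") or {}
    if "regimen" in raw and raw["regimen"] is not None:
        _require(regimen_block, "dose_mg", "regimen")
    regimen = DoseRegimen(
        dose_mg=float(regimen_block.get("dose_mg", 75.0)),
        formulation=regimen_block.get("formulation", "tablet_weibull"),
        t50_min=float(regimen_block.get("t50_min", 12.0)),
        shape_b=float(regimen_block.get("shape_b", 0.80)),
    )

    genotype = _genotype_from_block(raw.get("genotype"))

    pop_block = raw.get("population") or {}
    population = DemographicSpec(
        n=int(pop_block.get("n", 100)),
        female_fraction=float(pop_block.get("female_fraction", 0.0)),
        age_range=tuple(pop_block.get("age_range", (22.0, 50.0))),
        weight_range=tuple(pop_block.get("weight_range", (55.0, 90.0))),
        enzyme_gsd=float(pop_block.get("enzyme_gsd", 1.4)),
    )

    sim = raw.get("simulation") or {}
    settings = SimulationSettings(
        rtol=float(sim.get("rtol", 1e-8)),
        atol=float(sim.get("atol", 1e-10)),
    )
    duration_h = float(sim.get("duration_h", 96.0))
    if duration_h <= 0:
        raise ConfigurationError("duration_h must be > 0 in simulation block")
    grid_step_h = sim.get("grid_step_h")
    seed = int(sim.get("seed", 12345))

    return RunConfig(
        parent=parent,
        metabolite=metabolite,
        genotype=genotype,
        regimen=regimen,
        population=population,
        duration_h=duration_h,
        grid_step_h=None if grid_step_h is None else float(grid_step_h),
        settings=settings,
        seed=seed,
        output_dir=str(raw.get("output_dir", "doxpbpk_out")),
        raw=raw,
    )


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError("run configuration must be a YAML mapping")
    return config_from_dict(raw)
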
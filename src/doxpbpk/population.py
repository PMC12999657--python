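"""Virtual individuals and populations, and synthetic observed data.

Demographics are sampled uniformly within the printed study ranges (age,
weight; sex by the female fraction), and the bundled 70 kg reference
physiology is scaled allometrically: organ volumes by (weight/70),
regional blood flows by (weight/70)**0.75. Inter-individual variability
in hepatic enzyme expression is a lognormal multiplier with median 1
(geometric SD 1.4 by default) applied to the reference enzyme
concentration of each pathway.

Synthetic "observed" concentration data are model output corrupted by
proportional lognormal residual error with a stated coefficient of
variation; they stand in for the unpublished raw study profiles so the
fitting stage can be exercised end-to-end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "DemographicSpec",
    "VirtualIndividual",
    "SyntheticObservation",
    "load_reference_physiology",
    "load_study_demographics",
    "reference_individual",
    "sample_individual",
    "build_population",
    "generate_observed_profile",
]

REFERENCE_WEIGHT_KG = 70.0
ENZYMES = ("CYP2D6", "CYP2C19")


def load_reference_physiology() -> pd.DataFrame:
    """Bundled 70 kg reference organ volumes (L) and blood flows (L/min)."""
    with resources.files("doxpbpk.data").joinpath("reference_physiology.csv").open() as fh:
        return pd.read_csv(fh, index_col="organ")


def load_study_demographics() -> pd.DataFrame:
    """Bundled demographic/dose table of the clinical study groups."""
    with resources.files("doxpbpk.data").joinpath("study_demographics.csv").open() as fh:
        return pd.read_csv(fh)


@dataclass(frozen=True)
class DemographicSpec:
    """Target demographics of one simulated group."""

    n: int
    female_fraction: float = 0.0
    age_range: tuple[float, float] = (20.0, 50.0)
    weight_range: tuple[float, float] = (55.0, 90.0)
    enzyme_gsd: float = 1.4

    def __post_init__(self):
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")
        if not (0 <= self.female_fraction <= 1):
            raise ConfigurationError("female_fraction must be in [0, 1]")
        for name, (lo, hi) in (("age_range", self.age_range), ("weight_range", self.weight_range)):
            if lo > hi:
                raise ConfigurationError(f"{name} is empty: min {lo} > max {hi}")
        if self.enzyme_gsd < 1.0:
            raise ConfigurationError("enzyme_gsd must be >= 1")

    @classmethod
    def from_study_group(cls, compound: str, group: str, n: int | None = None) -> "DemographicSpec":
        """Spec for a bundled study group (e.g. ``("doxepin", "PM")``)."""
        table = load_study_demographics()
        row = table[(table.compound == compound) & (table.cyp2d6 == group)]
        if row.empty:
            raise ConfigurationError(f"no study group {group!r} for {compound!r}")
        row = row.iloc[0]
        return cls(
            n=int(n if n is not None else row.n),
            female_fraction=row.female_percent / 100.0,
            age_range=(float(row.age_min), float(row.age_max)),
            weight_range=(float(row.weight_min), float(row.weight_max)),
        )


@dataclass(frozen=True)
class VirtualIndividual:
    """Physiology of one simulated subject."""

    sex: str
    age: float
    weight: float
    organ_volumes: dict  # L, includes arterial_blood / venous_blood
    blood_flows: dict    # L/min (liver entry = hepatic-artery flow)
    enzyme_abundance_multipliers: dict = field(
        default_factory=lambda: {e: 1.0 for e in ENZYMES}
    )

    def __post_init__(self):
        if any(v <= 0 for v in self.organ_volumes.values()):
            raise ConfigurationError("organ volumes must be positive")
        if any(q <= 0 for q in self.blood_flows.values()):
            raise ConfigurationError("blood flows must be positive")
        if any(m <= 0 for m in self.enzyme_abundance_multipliers.values()):
            raise ConfigurationError("enzyme multipliers must be positive")
        if sum(self.organ_volumes.values()) >= self.weight / 1.0:
            raise ConfigurationError(
                "sum of organ volumes exceeds the body-weight-implied volume"
            )


def _scaled_physiology(weight: float) -> tuple[dict, dict]:
    phys = load_reference_physiology()
    vol_scale = weight / REFERENCE_WEIGHT_KG
    flow_scale = (weight / REFERENCE_WEIGHT_KG) ** 0.75
    volumes = {organ: v * vol_scale for organ, v in phys["volume_L"].items()}
    flows = {
        organ: q * flow_scale
        for organ, q in phys["flow_L_per_min"].items()
        if not math.isnan(q)
    }
    return volumes, flows


def reference_individual() -> VirtualIndividual:
    """The unscaled 70 kg reference subject (all multipliers 1)."""
    volumes, flows = _scaled_physiology(REFERENCE_WEIGHT_KG)
    return VirtualIndividual(
        sex="male", age=30.0, weight=REFERENCE_WEIGHT_KG,
        organ_volumes=volumes, blood_flows=flows,
    )


def sample_individual(spec: DemographicSpec, seed) -> VirtualIndividual:
    """Draw one virtual individual; deterministic for a fixed seed.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    weight = rng.uniform(*spec.weight_range)
    age = rng.uniform(*spec.age_range)
    sex = "female" if rng.uniform() < spec.female_fraction else "male"
    volumes, flows = _scaled_physiology(weight)
    sigma = math.log(spec.enzyme_gsd)
    multipliers = {e: float(np.exp(rng.normal(0.0, sigma))) for e in ENZYMES}
    return VirtualIndividual(
        sex=sex, age=age, weight=weight,
        organ_volumes=volumes, blood_flows=flows,
        enzyme_abundance_multipliers=multipliers,
    )


def build_population(spec: DemographicSpec, seed) -> list[VirtualIndividual]:
    """Sample ``spec.n`` independent virtual individuals."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [sample_individual(spec, rng) for _ in range(spec.n)]


def population_to_frame(population, seed=None) -> pd.DataFrame:
    """Flatten a population into one row per individual (delimited-text I/O)."""
    rows = []
    for i, ind in enumerate(population):
        row = {"id": i, "sex": ind.sex, "age_yr": ind.age, "weight_kg": ind.weight}
        row.update({f"mult_{e.lower()}": m for e, m in ind.enzyme_abundance_multipliers.items()})
        row.update({f"vol_{o}_L": v for o, v in ind.organ_volumes.items()})
        row.update({f"flow_{o}_L_min": q for o, q in ind.blood_flows.items()})
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SyntheticObservation:
    """Noisy synthetic observation of one concentration–time profile."""

    compound: str
    times_h: np.ndarray
    concentrations: np.ndarray  # nmol/L
    cv: float
    seed: int | None

    def __post_init__(self):
        t = np.asarray(self.times_h, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ConfigurationError("times must be strictly increasing")
        if np.any(c < 0):
            raise ConfigurationError("concentrations must be >= 0")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "concentrations", c)


def generate_observed_profile(profile, cv: float, seed) -> SyntheticObservation:
    """Corrupt a model profile with proportional lognormal residual error.

    The lognormal sigma is ``sqrt(ln(1 + cv**2))`` so the multiplicative
    noise has coefficient of variation exactly ``cv`` (and mean 1 after
    the -sigma^2/2 shift). ``cv = 0`` returns the profile unchanged.
    """
    if cv < 0:
        raise ConfigurationError("cv must be >= 0")
    conc = np.asarray(profile.concentrations, dtype=float)
    if cv == 0:
        noisy = conc.copy()
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1.0 + cv ** 2))
        factors = np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=conc.shape))
        noisy = conc * factors
    return SyntheticObservation(
        compound=profile.compound,
        times_h=np.asarray(profile.times_h, dtype=float),
        concentrations=noisy,
        cv=cv,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )
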
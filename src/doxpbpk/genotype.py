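"""CYP2D6 activity scores, phenotype classification, and genotype-specific
turnover numbers.

The consensus activity-score classification (CPIC/DPWG 2019) maps the sum
of the two allele scores x to a metabolizer phenotype: PM at x = 0, IM for
0 < x < 1.25, NM for 1.25 <= x <= 2.25, UM for x > 2.5. The printed rule
leaves (2.25, 2.5] unassigned; scores in that gap are classified NM with
an :class:`~doxpbpk.errors.ActivityScoreGapWarning` rather than inventing
a fifth category.

Genotype scaling acts only on the CYP2D6 kcat; the CYP2D6 Km is held
constant across genotypes, and CYP2C19 is not genotype-scaled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .errors import ActivityScoreGapWarning, ConfigurationError

__all__ = [
    "Phenotype",
    "GenotypeProfile",
    "phenotype_from_activity_score",
    "kcat_for",
    "activity_score_from_alleles",
    "ALLELE_ACTIVITY_SCORES",
    "CYP2D6_KCAT",
]

#: valid phenotype labels, in order of increasing metabolic capacity
PHENOTYPES = ("PM", "IM", "NM", "UM")
Phenotype = str  # plain string labels; validated at the boundaries

NON_GENOTYPED = "non-genotyped"

#: CYP2D6 turnover numbers (1/min) per compound and phenotype; the
#: non-genotyped entry is the base (development-population) value.
CYP2D6_KCAT: dict[str, dict[str, float]] = {
    "doxepin": {NON_GENOTYPED: 260.0, "UM": 505.0, "NM": 299.0, "IM": 85.0, "PM": 0.0},
    "nordoxepin": {NON_GENOTYPED: 160.0, "UM": 505.0, "NM": 165.0, "IM": 30.0, "PM": 0.0},
}

#: activity values of representative star alleles
ALLELE_ACTIVITY_SCORES: dict[str, float] = {
    "*1": 1.0, "*2": 1.0, "*27": 1.0, "*33": 1.0,
    "*17": 0.5, "*31": 0.5, "*49": 0.5,
    "*10": 0.25,
    "*3": 0.0, "*4": 0.0, "*5": 0.0, "*6": 0.0, "*36": 0.0,
}


def phenotype_from_activity_score(x: float) -> Phenotype:
    """Classify a CYP2D6 activity score into a metabolizer phenotype."""
    if x < 0:
        raise ConfigurationError(f"activity score must be >= 0, got {x}")
    if x == 0:
        return "PM"
    if x < 1.25:
        return "IM"
    if x <= 2.25:
        return "NM"
    if x <= 2.5:
        warnings.warn(
            f"activity score {x} falls in the unassigned interval (2.25, 2.5]; "
            "classified as NM (nearest bin below the UM bound)",
            ActivityScoreGapWarning,
            stacklevel=2,
        )
        return "NM"
    return "UM"


def kcat_for(compound: str, phenotype: str) -> float:
    """CYP2D6 turnover number (1/min) for a compound and phenotype.

    ``phenotype`` may be the ``"non-genotyped"`` pseudo-phenotype, which
    returns the base development-population value.
    """
    try:
        table = CYP2D6_KCAT[compound]
    except KeyError:
        raise LookupError(f"no CYP2D6 kcat table for compound {compound!r}") from None
    try:
        return table[phenotype]
    except KeyError:
        raise LookupError(
            f"unknown phenotype {phenotype!r}; expected one of "
            f"{sorted(table)}"
        ) from None


def activity_score_from_alleles(alleles) -> float:
    """Sum the activity values of a two-allele CYP2D6 diplotype."""
    if len(alleles) != 2:
        raise ConfigurationError(f"expected a two-allele diplotype, got {list(alleles)}")
    try:
        return sum(ALLELE_ACTIVITY_SCORES[a] for a in alleles)
    except KeyError as exc:
        raise ConfigurationError(
            f"allele {exc.args[0]!r} not in the bundled activity-score table"
        ) from None


@dataclass(frozen=True)
class GenotypeProfile:
    """A CYP2D6 genotype expressed as phenotype + per-compound kcat overrides."""

    phenotype: str
    activity_score: float | None = None
    kcat_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.phenotype not in PHENOTYPES and self.phenotype != NON_GENOTYPED:
            raise ConfigurationError(f"unknown phenotype {self.phenotype!r}")
        if self.activity_score is not None:
            implied = phenotype_from_activity_score(self.activity_score)
            if implied != self.phenotype:
                raise ConfigurationError(
                    f"activity score {self.activity_score} implies {implied}, "
                    f"not {self.phenotype}"
                )
        if not self.kcat_overrides:
            object.__setattr__(
                self,
                "kcat_overrides",
                {
                    (name, "CYP2D6"): kcat_for(name, self.phenotype)
                    for name in CYP2D6_KCAT
                },
            )
        for (_, enzyme), kcat in self.kcat_overrides.items():
            if enzyme != "CYP2D6":
                raise ConfigurationError("only CYP2D6 is genotype-scaled")
            if self.phenotype == "PM" and kcat != 0:
                raise ConfigurationError("PM requires a zero kcat override")

    @classmethod
    def from_activity_score(cls, x: float) -> "GenotypeProfile":
        return cls(phenotype=phenotype_from_activity_score(x), activity_score=x)

    @classmethod
    def from_alleles(cls, alleles) -> "GenotypeProfile":
        return cls.from_activity_score(activity_score_from_alleles(alleles))

    @classmethod
    def non_genotyped(cls) -> "GenotypeProfile":
        return cls(phenotype=NON_GENOTYPED)

    def kcat(self, compound: str) -> float:
        return self.kcat_overrides[(compound, "CYP2D6")]
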
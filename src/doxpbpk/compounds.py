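"""Compound parameterization, ionization, and tissue:plasma partitioning.

Houses the two study compounds (doxepin and its active metabolite
N-desmethyldoxepin), their physicochemical and ADME inputs, and the
composition-based calculation of tissue-to-plasma partition coefficients
(Kp) by the Rodgers–Rowland method (moderate-to-strong bases) or a
Schmitt-style scheme. Both methods read the same bundled tissue
composition table (see ``data/README.md`` for provenance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import pandas as pd
import yaml

from .errors import ConfigurationError

__all__ = [
    "EnzymePathway",
    "CompoundParameters",
    "TissueComposition",
    "ionized_fraction",
    "calc_partition_coefficients",
    "load_compound",
    "doxepin",
    "nordoxepin",
]

#: physiological pH conventions used by the partition methods
PH_PLASMA = 7.4
PH_INTRACELLULAR = 7.0
PH_BLOOD_CELLS = 7.22
HEMATOCRIT = 0.45


@dataclass(frozen=True)
class EnzymePathway:
    """One Michaelis–Menten metabolic route.

    Parameters
    ----------
    enzyme : str
        ``"CYP2D6"`` or ``"CYP2C19"``.
    km : float
        Michaelis constant, umol/L.
    kcat : float
        Turnover number, 1/min. Zero encodes the poor-metabolizer null
        pathway.
    reference_concentration : float
        Hepatic reference enzyme concentration, umol/L.
    product : str
        ``"metabolite"`` if the route forms the tracked metabolite
        mole-for-mole, ``"inactive"`` otherwise.
    """

    enzyme: str
    km: float
    kcat: float
    reference_concentration: float
    product: str = "inactive"

    def __post_init__(self):
        if self.enzyme not in ("CYP2D6", "CYP2C19"):
            raise ConfigurationError(f"unknown enzyme {self.enzyme!r}")
        if self.km <= 0:
            raise ConfigurationError("km must be > 0")
        if self.kcat < 0:
            raise ConfigurationError("kcat must be >= 0")
        if self.reference_concentration <= 0:
            raise ConfigurationError("reference_concentration must be > 0")
        if self.product not in ("metabolite", "inactive"):
            raise ConfigurationError(f"unknown pathway product {self.product!r}")


@dataclass(frozen=True)
class CompoundParameters:
    """Physicochemistry + ADME inputs for one compound.

    Units follow the printed conventions: molecular weight g/mol, Km uM,
    kcat 1/min, solubility mg/L, permeabilities cm/min, clearance L/min.
    """

    name: str
    molecular_weight: float
    log_p: float
    pka: float
    fraction_unbound: float
    solubility: float
    intestinal_permeability: float
    organ_permeability: float
    partition_method: str
    pathways: tuple[EnzymePathway, ...] = field(default_factory=tuple)
    total_hepatic_clearance: float | None = None
    compound_type: str = "base"
    blood_plasma_ratio: float = 1.0
    solubility_ph: float = 7.0

    def __post_init__(self):
        if self.molecular_weight <= 0:
            raise ConfigurationError("molecular_weight must be > 0")
        if not (0 < self.fraction_unbound <= 1):
            raise ConfigurationError("fraction_unbound must be in (0, 1]")
        if self.solubility <= 0:
            raise ConfigurationError("solubility must be > 0")
        if self.intestinal_permeability < 0 or self.organ_permeability <= 0:
            raise ConfigurationError("permeabilities must be positive")
        if self.partition_method not in ("rodgers_rowland", "schmitt"):
            raise ConfigurationError(
                f"unknown partition_method {self.partition_method!r}"
            )
        if self.total_hepatic_clearance is not None and self.total_hepatic_clearance < 0:
            raise ConfigurationError("total_hepatic_clearance must be >= 0")
        if self.compound_type not in ("base", "acid", "neutral"):
            raise ConfigurationError(f"unknown compound_type {self.compound_type!r}")
        object.__setattr__(self, "pathways", tuple(self.pathways))

    def pathway(self, enzyme: str) -> EnzymePathway:
        for p in self.pathways:
            if p.enzyme == enzyme:
                return p
        raise LookupError(f"{self.name} has no {enzyme} pathway")

    def with_pathway_kcat(self, enzyme: str, kcat: float) -> "CompoundParameters":
        """Return a copy with the named pathway's kcat replaced."""
        self.pathway(enzyme)  # raise early if absent
        new = tuple(
            replace(p, kcat=kcat) if p.enzyme == enzyme else p for p in self.pathways
        )
        return replace(self, pathways=new)


class TissueComposition:
    """Per-tissue fractional composition backing the partition methods.

    Wraps a table with columns ``f_ew`` (extracellular water), ``f_iw``
    (intracellular water), ``f_nl`` (neutral lipid), ``f_np`` (neutral
    phospholipid) — all volume fractions — and ``ap_mg_g`` (acidic
    phospholipid concentration, mg/g tissue). A ``blood_cells`` row is
    required by the Rodgers–Rowland base equations.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"f_ew", "f_iw", "f_nl", "f_np", "ap_mg_g"}
        missing = required - set(table.columns)
        if missing:
            raise ConfigurationError(f"composition table missing columns {sorted(missing)}")
        frac = table[["f_ew", "f_iw", "f_nl", "f_np"]]
        if (frac.values < 0).any() or (frac.values > 1).any():
            raise ConfigurationError("composition fractions must lie in [0, 1]")
        self.table = table

    @classmethod
    def bundled(cls) -> "TissueComposition":
        with resources.files("doxpbpk.data").joinpath("tissue_composition.csv").open() as fh:
            return cls(pd.read_csv(fh, index_col="tissue"))

    def row(self, tissue: str) -> pd.Series:
        if tissue not in self.table.index:
            raise ConfigurationError(f"no tissue composition entry for {tissue!r}")
        return self.table.loc[tissue]

    @property
    def tissues(self):
        return [t for t in self.table.index if t != "blood_cells"]


def ionized_fraction(pka: float, ph: float, is_base: bool = True) -> float:
    """Henderson–Hasselbalch ionized fraction for a monoprotic compound.

    For a base the ionized (protonated) fraction is ``1/(1 + 10**(ph - pka))``;
    for an acid ``1/(1 + 10**(pka - ph))``.
    """
    if not (math.isfinite(pka) and math.isfinite(ph)):
        raise ConfigurationError("pka and ph must be finite")
    delta = (ph - pka) if is_base else (pka - ph)
    return 1.0 / (1.0 + 10.0 ** delta)


def _ion_exponents(compound: CompoundParameters):
    """10**(pKa - pH) terms at intracellular / plasma / blood-cell pH.

    Zero for neutral compounds (no ionizable group acting in this model).
    Acids are not needed for the bundled compounds but are mapped through
    the same structure with sign-flipped exponents.
    """
    if compound.compound_type == "neutral":
        return 0.0, 0.0, 0.0
    sign = 1.0 if compound.compound_type == "base" else -1.0
    x = 10.0 ** (sign * (compound.pka - PH_INTRACELLULAR))
    y = 10.0 ** (sign * (compound.pka - PH_PLASMA))
    z = 10.0 ** (sign * (compound.pka - PH_BLOOD_CELLS))
    return x, y, z


def _rodgers_rowland_kpu(compound, comp_row, ka_ap, x, y):
    p = 10.0 ** compound.log_p
    lipid = (p * comp_row["f_nl"] + (0.3 * p + 0.7) * comp_row["f_np"]) / (1.0 + y)
    water = comp_row["f_ew"] + (1.0 + x) / (1.0 + y) * comp_row["f_iw"]
    acidic = ka_ap * comp_row["ap_mg_g"] * x / (1.0 + y)
    return water + acidic + lipid


def _rodgers_rowland_ka_ap(compound, bc_row, y, z):
    """Acidic-phospholipid association constant from blood-cell partitioning.

    Derived from the blood:plasma ratio and hematocrit; clamped at zero if
    the composition terms alone already explain the blood-cell partition.
    """
    bp = compound.blood_plasma_ratio
    kpu_bc = (bp - (1.0 - HEMATOCRIT)) / HEMATOCRIT / compound.fraction_unbound
    p = 10.0 ** compound.log_p
    water = (1.0 + z) / (1.0 + y) * bc_row["f_iw"]
    lipid = (p * bc_row["f_nl"] + (0.3 * p + 0.7) * bc_row["f_np"]) / (1.0 + y)
    if z <= 0:
        return 0.0
    ka = (kpu_bc - water - lipid) * (1.0 + y) / (bc_row["ap_mg_g"] * z)
    return max(ka, 0.0)


# Ion-partitioning factors of the Schmitt-style scheme (dimensionless,
# relative to the neutral species' affinity for the respective phase).
_SCHMITT_ION_NL = 1e-3    # ions barely enter neutral storage lipid
_SCHMITT_ION_NP = 0.3     # amphiphilic ions still bind phospholipid
_SCHMITT_ION_AP = 20.0    # electrostatic attraction cation <-> acidic lipid


def _schmitt_kpu(compound, comp_row, x, y):
    p = 10.0 ** compound.log_p
    k_pl = 0.3 * p + 0.7  # neutral-species phospholipid affinity scale
    water = comp_row["f_ew"] + (1.0 + x) / (1.0 + y) * comp_row["f_iw"]
    nl = comp_row["f_nl"] * p * (1.0 + _SCHMITT_ION_NL * x) / (1.0 + y)
    np_ = comp_row["f_np"] * k_pl * (1.0 + _SCHMITT_ION_NP * x) / (1.0 + y)
    f_ap = comp_row["ap_mg_g"] / 1000.0  # mg/g ~ volume fraction
    ap = f_ap * k_pl * (1.0 + _SCHMITT_ION_AP * x) / (1.0 + y)
    return water + nl + np_ + ap


def calc_partition_coefficients(
    compound: CompoundParameters,
    tissues: TissueComposition | None = None,
    organ_list: list[str] | None = None,
) -> dict[str, float]:
    """Tissue:plasma partition coefficients (Kp) for every model organ.

    Dispatches on ``compound.partition_method``; both methods are pure
    functions of the compound parameters and the bundled composition
    table, so the output is deterministic. ``Kp = Kpu * fu``.
    """
    if tissues is None:
        tissues = TissueComposition.bundled()
    organ_list = list(organ_list) if organ_list is not None else tissues.tissues
    x, y, z = _ion_exponents(compound)
    out = {}
    if compound.partition_method == "rodgers_rowland":
        ka_ap = _rodgers_rowland_ka_ap(compound, tissues.row("blood_cells"), y, z)
        for organ in organ_list:
            kpu = _rodgers_rowland_kpu(compound, tissues.row(organ), ka_ap, x, y)
            out[organ] = kpu * compound.fraction_unbound
    else:
        for organ in organ_list:
            kpu = _schmitt_kpu(compound, tissues.row(organ), x, y)
            out[organ] = kpu * compound.fraction_unbound
    for organ, kp in out.items():
        if not (kp > 0 and math.isfinite(kp)):
            raise ConfigurationError(f"non-positive Kp computed for {organ}")
    return out


def _compound_from_dict(d: dict) -> CompoundParameters:
    pathways = tuple(
        EnzymePathway(
            enzyme=p["enzyme"],
            km=float(p["km_uM"]),
            kcat=float(p["kcat_per_min"]),
            reference_concentration=float(p["reference_concentration_uM"]),
            product=p.get("product", "inactive"),
        )
        for p in d.get("pathways", [])
    )
    thc = d.get("total_hepatic_clearance_L_min")
    return CompoundParameters(
        name=d["name"],
        molecular_weight=float(d["molecular_weight"]),
        log_p=float(d["log_p"]),
        pka=float(d["pka"]),
        fraction_unbound=float(d["fraction_unbound"]),
        solubility=float(d["solubility_mg_per_L"]),
        solubility_ph=float(d.get("solubility_ph", 7.0)),
        intestinal_permeability=float(d["intestinal_permeability_cm_min"]),
        organ_permeability=float(d["organ_permeability_cm_min"]),
        partition_method=d["partition_method"],
        pathways=pathways,
        total_hepatic_clearance=None if thc is None else float(thc),
        compound_type=d.get("compound_type", "base"),
        blood_plasma_ratio=float(d.get("blood_plasma_ratio", 1.0)),
    )


def load_compound(source) -> CompoundParameters:
    """Load a compound parameter file (flat YAML key–value, bundled units).

    ``source`` is a path, or one of the bundled names ``"doxepin"`` /
    ``"nordoxepin"``.
    """
    if source in ("doxepin", "nordoxepin"):
        with resources.files("doxpbpk.data").joinpath(f"{source}.yaml").open() as fh:
            return _compound_from_dict(yaml.safe_load(fh))
    with open(source) as fh:
        return _compound_from_dict(yaml.safe_load(fh))


def doxepin() -> CompoundParameters:
    """Bundled parent-drug parameterization."""
    return load_compound("doxepin")


def nordoxepin() -> CompoundParameters:
    """Bundled active-metabolite parameterization."""
    return load_compound("nordoxepin")
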
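"""Whole-body PBPK mass balance for a parent drug and its metabolite.

The topology is 13 perfusion-limited, well-stirred organ compartments
(lung, brain, heart, kidney, liver, gut, spleen, stomach, muscle,
adipose, skin, bone, rest) plus arterial and venous blood. The lung sits
in series with the whole cardiac output; gut, spleen and stomach drain
into the liver through the portal vein; orally absorbed drug enters the
liver directly (portal uptake). All metabolism is hepatic: Michaelis–
Menten pathways driven by the unbound liver water concentration
(C_liver * fu / Kp_liver), with the CYP2C19 demethylation of the parent
feeding the metabolite mole-for-mole in the liver, CYP2D6 hydroxylating
both compounds to untracked products, and a linear intrinsic hepatic
clearance lumping the metabolite's remaining routes. Renal clearance is
excluded (negligible urinary excretion).

Internal units: amounts nmol, concentrations nmol/L, time minutes;
interfaces use hours. Enzyme kinetics use umol/L (Km, enzyme
concentration), hence the 1e3 factor in the rate law.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from . import absorption as absn
from .absorption import AbsorptionSettings, DoseRegimen, dose_in_nmol
from .compounds import CompoundParameters, TissueComposition, calc_partition_coefficients
from .errors import BuildError, SimulationError, SmallPopulationWarning
from .genotype import GenotypeProfile
from .population import VirtualIndividual

__all__ = [
    "ORGANS",
    "SimulationSettings",
    "PBPKModel",
    "ConcentrationTimeProfile",
    "SimulationOutput",
    "PopulationSummary",
    "michaelis_menten_rate",
    "build_model",
    "simulate",
    "simulate_population",
    "OneCompartmentModel",
    "default_output_grid",
]

ORGANS = (
    "lung", "brain", "heart", "kidney", "liver", "gut", "spleen",
    "stomach", "muscle", "adipose", "skin", "bone", "rest",
)
LUNG, LIVER = 0, 4
PORTAL = (5, 6, 7)          # gut, spleen, stomach
SYSTEMIC = (1, 2, 3, 8, 9, 10, 11, 12)  # organs draining directly to venous


@dataclass(frozen=True)
class SimulationSettings:
    """Solver and absorption configuration."""

    rtol: float = 1e-8
    atol: float = 1e-10          # nmol
    method: str = "LSODA"
    absorption: AbsorptionSettings = field(default_factory=AbsorptionSettings)
    #: state more negative than this (nmol) is a hard error
    negative_state_tolerance: float = 1e-6


@dataclass(frozen=True)
class ConcentrationTimeProfile:
    """Venous plasma concentrations of one compound on an output grid."""

    compound: str
    times_h: np.ndarray
    concentrations: np.ndarray  # nmol/L
    kind: str = "individual"    # individual | mean | p5 | p95

    def __post_init__(self):
        t = np.asarray(self.times_h, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.shape != c.shape:
            raise BuildError("times and concentrations must have equal length")
        if np.any(np.diff(t) <= 0):
            raise BuildError("times must be strictly increasing")
        if np.any(c < 0):
            raise BuildError("concentrations must be >= 0")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "concentrations", c)


@dataclass(frozen=True)
class PBPKModel:
    """A fully assembled parent+metabolite whole-body model."""

    parent: CompoundParameters
    metabolite: CompoundParameters
    individual: VirtualIndividual
    regimen: DoseRegimen
    kp_parent: dict
    kp_metabolite: dict
    genotype: GenotypeProfile | None = None
    settings: SimulationSettings = field(default_factory=SimulationSettings)


def michaelis_menten_rate(
    kcat: float, enzyme_conc: float, km: float, c_unbound: float, liver_volume: float
) -> float:
    """Hepatic Michaelis–Menten rate in nmol/min.

    ``kcat`` 1/min, ``enzyme_conc`` and ``km`` and ``c_unbound`` umol/L,
    ``liver_volume`` L. The 1e3 factor converts umol/min to nmol/min.
    """
    if c_unbound <= 0 or kcat == 0:
        return 0.0
    return kcat * enzyme_conc * c_unbound / (km + c_unbound) * liver_volume * 1e3


_KP_CACHE: dict[CompoundParameters, dict] = {}


def _kp_map(compound: CompoundParameters) -> dict:
    if compound not in _KP_CACHE:
        _KP_CACHE[compound] = calc_partition_coefficients(
            compound, TissueComposition.bundled(), ORGANS
        )
    return _KP_CACHE[compound]


def build_model(
    parent: CompoundParameters,
    metabolite: CompoundParameters,
    individual: VirtualIndividual,
    genotype: GenotypeProfile | None,
    regimen: DoseRegimen,
    settings: SimulationSettings | None = None,
) -> PBPKModel:
    """Assemble and validate the coupled parent+metabolite model.

    Genotype kcat overrides are applied to both compounds' CYP2D6
    pathways. Raises :class:`BuildError` on pathway misconfiguration
    (e.g. a metabolite-forming pathway on the metabolite itself).
    """
    formers = [p for p in parent.pathways if p.product == "metabolite"]
    if len(formers) != 1 or formers[0].enzyme != "CYP2C19":
        raise BuildError(
            "parent must carry exactly one metabolite-forming CYP2C19 pathway"
        )
    try:
        if parent.pathway("CYP2D6").product != "inactive":
            raise BuildError("parent CYP2D6 pathway must be inactivating")
    except LookupError:
        raise BuildError("parent must carry a CYP2D6 pathway") from None
    if any(p.product == "metabolite" for p in metabolite.pathways):
        raise BuildError("metabolite cannot carry a metabolite-forming pathway")
    try:
        metabolite.pathway("CYP2D6")
    except LookupError:
        raise BuildError("metabolite must carry a CYP2D6 pathway") from None
    if metabolite.total_hepatic_clearance is None:
        raise BuildError("metabolite must declare a total hepatic clearance")

    if genotype is not None:
        parent = parent.with_pathway_kcat("CYP2D6", genotype.kcat(parent.name))
        metabolite = metabolite.with_pathway_kcat("CYP2D6", genotype.kcat(metabolite.name))

    missing = [o for o in ORGANS if o not in individual.organ_volumes]
    if missing:
        raise BuildError(f"individual physiology missing organs {missing}")

    return PBPKModel(
        parent=parent,
        metabolite=metabolite,
        individual=individual,
        regimen=regimen,
        kp_parent=_kp_map(parent),
        kp_metabolite=_kp_map(metabolite),
        genotype=genotype,
        settings=settings if settings is not None else SimulationSettings(),
    )


def default_output_grid(duration_h: float) -> np.ndarray:
    """Output grid dense around absorption, coarser in the terminal phase."""
    pieces = [
        np.arange(0.0, min(4.0, duration_h), 0.1),
        np.arange(4.0, min(12.0, duration_h), 0.25),
        np.arange(12.0, min(24.0, duration_h), 0.5),
        np.arange(24.0, duration_h, 1.0),
        [duration_h],
    ]
    grid = np.unique(np.concatenate([np.asarray(p, dtype=float) for p in pieces]))
    return grid[grid <= duration_h]


# ---------------------------------------------------------------------------
# state layout:
#   0 solid, 1 lumen
#   2:17   parent  (13 organs, arterial, venous)
#   17:32  metabolite (same layout)
#   32:37  cumulative: absorbed, parent-CYP2C19 (= metabolite formed),
#          parent-CYP2D6, metabolite-CYP2D6, metabolite hepatic clearance
# ---------------------------------------------------------------------------
N_STATE = 37
_P0, _M0, _CUM = 2, 17, 32


class _RHS:
    """Precomputed right-hand side of the whole-body ODE system."""

    def __init__(self, model: PBPKModel):
        ind = model.individual
        self.vols = np.array([ind.organ_volumes[o] for o in ORGANS])
        self.v_art = ind.organ_volumes["arterial_blood"]
        self.v_ven = ind.organ_volumes["venous_blood"]
        flows = ind.blood_flows
        self.q = np.array([flows.get(o, 0.0) for o in ORGANS])  # lung entry 0
        self.q_portal = self.q[list(PORTAL)].sum()
        self.q_liver_out = self.q[LIVER] + self.q_portal
        self.q_co = self.q.sum()
        self.kp_p = np.array([model.kp_parent[o] for o in ORGANS])
        self.kp_m = np.array([model.kp_metabolite[o] for o in ORGANS])
        self.model = model

        liver_v = self.vols[LIVER]
        p, m = model.parent, model.metabolite
        # (kcat, E_ref * multiplier, km) per pathway, with unbound-liver scaling
        mult = ind.enzyme_abundance_multipliers
        self.p_c19 = p.pathway("CYP2C19")
        self.p_d6 = p.pathway("CYP2D6")
        self.m_d6 = m.pathway("CYP2D6")
        self.e_p_c19 = self.p_c19.reference_concentration * mult.get("CYP2C19", 1.0)
        self.e_p_d6 = self.p_d6.reference_concentration * mult.get("CYP2D6", 1.0)
        self.e_m_d6 = self.m_d6.reference_concentration * mult.get("CYP2D6", 1.0)
        self.liver_v = liver_v
        self.fu_kp_liver_p = p.fraction_unbound / self.kp_p[LIVER]
        self.fu_kp_liver_m = m.fraction_unbound / self.kp_m[LIVER]
        self.cl_h_m = m.total_hepatic_clearance or 0.0

    def _circulation(self, a: np.ndarray, kp: np.ndarray) -> tuple[np.ndarray, float]:
        """Perfusion fluxes for one compound; returns dA and liver C_out."""
        organs = a[:13]
        c_out = organs / (self.vols * kp)
        c_art = a[13] / self.v_art
        c_ven = a[14] / self.v_ven
        d = np.empty(15)
        d[LUNG] = self.q_co * (c_ven - c_out[LUNG])
        d[1:13] = self.q[1:13] * (c_art - c_out[1:13])
        # liver: hepatic artery + portal inflow - pooled outflow
        portal_in = sum(self.q[i] * c_out[i] for i in PORTAL)
        d[LIVER] = (
            self.q[LIVER] * c_art + portal_in - self.q_liver_out * c_out[LIVER]
        )
        d[13] = self.q_co * (c_out[LUNG] - c_art)
        d[14] = (
            sum(self.q[i] * c_out[i] for i in SYSTEMIC)
            + self.q_liver_out * c_out[LIVER]
            - self.q_co * c_ven
        )
        return d, c_out[LIVER]

    def __call__(self, t, y):
        m = self.model
        dy = np.zeros(N_STATE)

        r_diss, r_abs = absn.dissolution_absorption_rates(
            t, y[0], y[1], m.regimen, m.parent, m.settings.absorption
        )
        dy[0] = -r_diss
        dy[1] = r_diss - r_abs

        dp, _ = self._circulation(y[_P0:_P0 + 15], self.kp_p)
        dm, _ = self._circulation(y[_M0:_M0 + 15], self.kp_m)

        # hepatic metabolism from unbound liver water concentrations (umol/L)
        cu_p = max(y[_P0 + LIVER], 0.0) / self.liver_v * self.fu_kp_liver_p / 1e3
        cu_m = max(y[_M0 + LIVER], 0.0) / self.liver_v * self.fu_kp_liver_m / 1e3
        v_c19 = michaelis_menten_rate(
            self.p_c19.kcat, self.e_p_c19, self.p_c19.km, cu_p, self.liver_v
        )
        v_p_d6 = michaelis_menten_rate(
            self.p_d6.kcat, self.e_p_d6, self.p_d6.km, cu_p, self.liver_v
        )
        v_m_d6 = michaelis_menten_rate(
            self.m_d6.kcat, self.e_m_d6, self.m_d6.km, cu_m, self.liver_v
        )
        v_clh = self.cl_h_m * cu_m * 1e3  # L/min * umol/L * 1e3 -> nmol/min

        dp[LIVER] += r_abs - v_c19 - v_p_d6
        dm[LIVER] += v_c19 - v_m_d6 - v_clh

        dy[_P0:_P0 + 15] = dp
        dy[_M0:_M0 + 15] = dm
        dy[_CUM:_CUM + 5] = (r_abs, v_c19, v_p_d6, v_m_d6, v_clh)
        return dy


@dataclass(frozen=True)
class SimulationOutput:
    """Profiles plus the bookkeeping needed for mass-balance checks."""

    parent: ConcentrationTimeProfile
    metabolite: ConcentrationTimeProfile
    times_h: np.ndarray
    cumulative: dict          # nmol, keys: absorbed, parent_cyp2c19, ...
    amounts_parent: np.ndarray    # (n_times,) total parent nmol in the body
    amounts_metabolite: np.ndarray
    mass_balance_rel_error: np.ndarray

    @property
    def max_mass_balance_error(self) -> float:
        return float(self.mass_balance_rel_error.max())

    @property
    def profiles(self):
        return self.parent, self.metabolite


def simulate(
    model: PBPKModel,
    duration_h: float = 96.0,
    output_grid_h: np.ndarray | None = None,
) -> SimulationOutput:
    """Integrate the whole-body system over a single oral dose.

    Returns venous plasma profiles for both compounds on the output grid
    plus cumulative absorption/elimination bookkeeping. Raises
    :class:`SimulationError` on solver failure or on a negative state
    beyond tolerance.
    """
    grid_h = (
        default_output_grid(duration_h)
        if output_grid_h is None
        else np.asarray(output_grid_h, dtype=float)
    )
    rhs = _RHS(model)
    y0 = np.zeros(N_STATE)
    y0[0] = dose_in_nmol(model.regimen, model.parent)
    s = model.settings
    sol = solve_ivp(
        rhs,
        (0.0, duration_h * 60.0),
        y0,
        method=s.method,
        rtol=s.rtol,
        atol=s.atol,
        t_eval=grid_h * 60.0,
    )
    if not sol.success:
        raise SimulationError(
            f"ODE solver failed: {sol.message}",
            last_time_min=float(sol.t[-1]) if sol.t.size else 0.0,
            last_state=sol.y[:, -1] if sol.t.size else y0,
        )
    y = sol.y
    floor = -max(s.negative_state_tolerance * max(y0[0], 1.0), 100.0 * s.atol)
    if y.min() < floor:
        raise SimulationError(
            f"negative state beyond tolerance (min {y.min():.3e} nmol)",
            last_time_min=float(sol.t[-1]),
            last_state=y[:, -1],
        )
    y = np.clip(y, 0.0, None)

    v_ven = model.individual.organ_volumes["venous_blood"]
    conc_p = y[_P0 + 14] / v_ven
    conc_m = y[_M0 + 14] / v_ven
    cum = {
        "absorbed": y[_CUM],
        "parent_cyp2c19": y[_CUM + 1],
        "parent_cyp2d6": y[_CUM + 2],
        "metabolite_cyp2d6": y[_CUM + 3],
        "metabolite_hepatic": y[_CUM + 4],
    }
    amounts_p = y[_P0:_P0 + 15].sum(axis=0)
    amounts_m = y[_M0:_M0 + 15].sum(axis=0)
    # absorbed = parent in body + parent eliminated + metabolite formed;
    # metabolite formed = metabolite in body + metabolite eliminated
    scale = max(y0[0], 1.0)
    err_p = np.abs(
        cum["absorbed"] - (amounts_p + cum["parent_cyp2d6"] + cum["parent_cyp2c19"])
    )
    err_m = np.abs(
        cum["parent_cyp2c19"]
        - (amounts_m + cum["metabolite_cyp2d6"] + cum["metabolite_hepatic"])
    )
    rel_err = np.maximum(err_p, err_m) / scale

    return SimulationOutput(
        parent=ConcentrationTimeProfile(model.parent.name, grid_h, conc_p),
        metabolite=ConcentrationTimeProfile(model.metabolite.name, grid_h, conc_m),
        times_h=grid_h,
        cumulative=cum,
        amounts_parent=amounts_p,
        amounts_metabolite=amounts_m,
        mass_balance_rel_error=rel_err,
    )


@dataclass(frozen=True)
class PopulationSummary:
    """Arithmetic mean and 5th/95th percentile profiles per compound."""

    times_h: np.ndarray
    statistics: dict   # compound -> {"mean"|"p5"|"p95": array}
    n: int

    def profile(self, compound: str, stat: str) -> ConcentrationTimeProfile:
        return ConcentrationTimeProfile(
            compound, self.times_h, self.statistics[compound][stat], kind=stat
        )


def simulate_population(
    parent: CompoundParameters,
    metabolite: CompoundParameters,
    population: list[VirtualIndividual],
    genotype: GenotypeProfile | None,
    regimen: DoseRegimen,
    duration_h: float = 96.0,
    output_grid_h: np.ndarray | None = None,
    settings: SimulationSettings | None = None,
) -> PopulationSummary:
    """Simulate every individual and summarize per time point.

    Percentiles are empirical order statistics with linear interpolation
    (numpy's default). Populations below 20 individuals trigger a
    :class:`SmallPopulationWarning` — their percentile bands are noisy.
    """
    if not population:
        raise BuildError("population must be non-empty")
    if len(population) < 20:
        warnings.warn(
            f"population of {len(population)} individuals: empirical 5th/95th "
            "percentiles are unstable below n = 20",
            SmallPopulationWarning,
            stacklevel=2,
        )
    grid_h = (
        default_output_grid(duration_h)
        if output_grid_h is None
        else np.asarray(output_grid_h, dtype=float)
    )
    stacks = {parent.name: [], metabolite.name: []}
    for individual in population:
        model = build_model(parent, metabolite, individual, genotype, regimen, settings)
        out = simulate(model, duration_h, grid_h)
        stacks[parent.name].append(out.parent.concentrations)
        stacks[metabolite.name].append(out.metabolite.concentrations)
    statistics = {}
    for name, rows in stacks.items():
        arr = np.vstack(rows)
        statistics[name] = {
            "mean": arr.mean(axis=0),
            "p5": np.percentile(arr, 5, axis=0),
            "p95": np.percentile(arr, 95, axis=0),
        }
    return PopulationSummary(times_h=grid_h, statistics=statistics, n=len(population))


@dataclass(frozen=True)
class OneCompartmentModel:
    """Collapsed topology: first-order absorption, one well-mixed volume,
    linear clearance. Shares the solver settings of the full engine and is
    the target of the analytic (Bateman) cross-check."""

    dose_nmol: float
    ka_per_min: float
    clearance_L_per_min: float
    volume_L: float
    settings: SimulationSettings = field(default_factory=SimulationSettings)

    def simulate(self, duration_h: float, output_grid_h=None) -> ConcentrationTimeProfile:
        grid_h = (
            default_output_grid(duration_h)
            if output_grid_h is None
            else np.asarray(output_grid_h, dtype=float)
        )

        def rhs(t, y):
            depot, central = y
            r_in = self.ka_per_min * depot
            r_out = self.clearance_L_per_min * central / self.volume_L
            return [-r_in, r_in - r_out]

        sol = solve_ivp(
            rhs,
            (0.0, duration_h * 60.0),
            [self.dose_nmol, 0.0],
            method=self.settings.method,
            rtol=self.settings.rtol,
            atol=self.settings.atol,
            t_eval=grid_h * 60.0,
        )
        if not sol.success:
            raise SimulationError(f"ODE solver failed: {sol.message}")
        conc = np.clip(sol.y[1], 0.0, None) / self.volume_L
        return ConcentrationTimeProfile("one_compartment", grid_h, conc)
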
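"""Synthetic inputs: a toy photoautotroph model with hand-computable LP optima
and simulated batch-culture time series.

The toy model is a downscaled photoautotroph.  Light is converted to ATP
(1 ATP per photon), CO2 fixation costs 2 ATP per fixed-carbon unit (``ch2o``),
and biomass consumes 1 ch2o + 1 ATP, so with photon uptake bounded at P and
no GG the growth optimum is BOFmax = P/3 exactly.  GG synthesis costs
9 ch2o + 1 ATP (GG carries 9 carbons); salvaged glucose re-enters as 6 ch2o
(1 ATP at glucokinase unless phosphorolysis bypasses it) and glycerol as
3 ch2o (1 ATP at glycerol kinase).  All coefficients are small integers so
every optimum is exactly representable and derivable by hand:

    exogenous GG fixed at q, photon bound P —
        utilization closed              BOFmax = P/3
        hydrolysis + glycerol kinase    BOFmax = (P + 16 q)/3
        phosphorolysis + kinase         BOFmax = (P + 17 q)/3
        hydrolysis, kinase closed       BOFmax = (P + 11 q)/3
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .culture_analysis import CultureTimeSeries, ConversionConstants
from .gg_extension import default_gg_extension, extend_with_gg
from .model_core import MetabolicModel, Metabolite, Reaction

__all__ = [
    "ToyModelParams",
    "CultureSimParams",
    "make_toy_model",
    "toy_bofmax_closed_form",
    "simulate_culture",
]


@dataclass
class ToyModelParams:
    """Stoichiometric knobs of the toy photoautotroph (all small integers)."""

    photon_bound: float = 100.0     # mmol photons gDW^-1 h^-1
    atp_per_photon: int = 1
    atp_per_co2_fixed: int = 2
    biomass_ch2o: int = 1
    biomass_atp: int = 1
    ggps_ch2o: int = 9              # 9 carbons per GG
    ggps_atp: int = 1
    glucokinase_atp: int = 1
    glycerol_kinase_atp: int = 1
    carbons_glc: int = 6
    carbons_glyc: int = 3

    def __post_init__(self) -> None:
        if self.photon_bound <= 0:
            raise ValueError("photon_bound must be positive")
        if self.carbons_glc + self.carbons_glyc != self.ggps_ch2o:
            raise ValueError(
                "carbon conservation violated: glucose + glycerol carbons "
                f"({self.carbons_glc}+{self.carbons_glyc}) != GG carbons ({self.ggps_ch2o})"
            )


def toy_bofmax_closed_form(params: ToyModelParams, qGG: float = 0.0,
                           mode: str = "closed") -> float:
    """Hand-derived growth optimum of the toy model under exogenous GG.

    ``mode``: ``closed`` (no utilization), ``hydrolysis``/``phosphorolysis``
    (with glycerol kinase open), ``hydrolysis_no_glpK``.  Derivation: each
    biomass unit needs biomass_atp ATP plus biomass_ch2o carbon units at
    atp_per_co2_fixed ATP each unless displaced by salvaged GG carbon.
    """
    p = params
    atp_per_mu = p.biomass_atp + p.biomass_ch2o * p.atp_per_co2_fixed
    per_photon = p.atp_per_photon
    if mode == "closed":
        gain = 0.0
    elif mode == "hydrolysis":
        carbons = p.carbons_glc + p.carbons_glyc
        cost = p.glucokinase_atp + p.glycerol_kinase_atp
        gain = carbons * p.atp_per_co2_fixed - cost
    elif mode == "phosphorolysis":
        carbons = p.carbons_glc + p.carbons_glyc
        cost = p.glycerol_kinase_atp
        gain = carbons * p.atp_per_co2_fixed - cost
    elif mode == "hydrolysis_no_glpK":
        carbons = p.carbons_glc
        cost = p.glucokinase_atp
        gain = carbons * p.atp_per_co2_fixed - cost
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return (per_photon * p.photon_bound + gain * qGG) / atp_per_mu


def make_toy_model(params: ToyModelParams | None = None,
                   with_gg_extension: bool = True) -> MetabolicModel:
    """Build the toy photoautotroph, optionally with the GG extension applied."""
    p = params or ToyModelParams()

    def met(mid, formula=None, name=""):
        return Metabolite(id=mid, name=name or mid, formula=formula)

    metabolites = [
        met("photon_e"),
        met("co2_e", "CO2"), met("co2_c", "CO2"),
        met("pi_e", "H3O4P"), met("pi_c", "H3O4P"),
        met("h2o_e", "H2O"), met("h2o_c", "H2O"),
        met("atp_c"),                       # lumped energy currency, no formula
        met("ch2o_c", "CH2O", "fixed carbon unit"),
        met("glc__D_c", "C6H12O6", "D-glucose"),
        met("g6p_c", "C6H13O9P", "glucose 6-phosphate"),
        met("g1p_c", "C6H13O9P", "glucose 1-phosphate"),
        met("glyc_c", "C3H8O3", "glycerol"), met("glyc_e", "C3H8O3", "glycerol"),
        met("glyc3p_c", None, "glycerol 3-phosphate"),
        met("glcglyc_c", "C9H18O8", "glucosylglycerol"),
    ]

    def rxn(rid, stoich, lb, ub, name="", ex=False, sink=False):
        return Reaction(id=rid, name=name or rid, stoichiometry=stoich,
                        lower_bound=lb, upper_bound=ub,
                        is_exchange=ex, is_sink=sink)

    F = 1000.0
    reactions = [
        rxn("EX_photon(e)", {"photon_e": -1.0}, -p.photon_bound, 0.0,
            "photon exchange", ex=True),
        rxn("EX_co2(e)", {"co2_e": -1.0}, -F, F, "CO2 exchange", ex=True),
        rxn("EX_pi(e)", {"pi_e": -1.0}, -F, F, "phosphate exchange", ex=True),
        rxn("EX_h2o(e)", {"h2o_e": -1.0}, -F, F, "water exchange", ex=True),
        rxn("EX_glyc(e)", {"glyc_e": -1.0}, 0.0, F, "glycerol exchange (export)",
            ex=True),
        rxn("CO2t", {"co2_e": -1.0, "co2_c": 1.0}, -F, F),
        rxn("PIt", {"pi_e": -1.0, "pi_c": 1.0}, -F, F),
        rxn("H2Ot", {"h2o_e": -1.0, "h2o_c": 1.0}, -F, F),
        rxn("GLYCt", {"glyc_c": -1.0, "glyc_e": 1.0}, -F, F,
            "glycerol transport"),
        rxn("LIGHT", {"photon_e": -1.0, "atp_c": float(p.atp_per_photon)},
            0.0, F, "photosynthetic ATP generation"),
        rxn("CBB", {"co2_c": -1.0, "atp_c": -float(p.atp_per_co2_fixed),
                    "ch2o_c": 1.0}, 0.0, F, "carbon fixation"),
        rxn("BIOMASS_toy", {"ch2o_c": -float(p.biomass_ch2o),
                            "atp_c": -float(p.biomass_atp)}, 0.0, F,
            "biomass objective"),
        rxn("GGPS", {"ch2o_c": -float(p.ggps_ch2o), "atp_c": -float(p.ggps_atp),
                     "glcglyc_c": 1.0}, 0.0, F,
            "GG synthesis (GgpS + GgpP, lumped)"),
        rxn("GLK", {"glc__D_c": -1.0, "atp_c": -float(p.glucokinase_atp),
                    "g6p_c": 1.0}, 0.0, F, "glucokinase"),
        rxn("PGM", {"g1p_c": -1.0, "g6p_c": 1.0}, -F, F, "phosphoglucomutase"),
        rxn("G6PC", {"g6p_c": -1.0, "h2o_c": -1.0,
                     "ch2o_c": float(p.carbons_glc), "pi_c": 1.0}, 0.0, F,
            "glucose 6-phosphate catabolism to fixed-carbon units"),
        rxn("GLYK", {"glyc_c": -1.0, "atp_c": -float(p.glycerol_kinase_atp),
                     "glyc3p_c": 1.0}, 0.0, F, "glycerol kinase (GlpK)"),
        rxn("GLY3PC", {"glyc3p_c": -1.0, "ch2o_c": float(p.carbons_glyc),
                       "pi_c": 1.0}, 0.0, F,
            "glycerol 3-phosphate catabolism"),
    ]

    model = MetabolicModel(metabolites=metabolites, reactions=reactions,
                           objective_reaction_id="BIOMASS_toy",
                           id="gg_toy_photoautotroph")
    if with_gg_extension:
        model = extend_with_gg(model, default_gg_extension())
    return model


# ---------------------------------------------------------------------------
# simulated batch cultures
# ---------------------------------------------------------------------------


@dataclass
class CultureSimParams:
    """Generating parameters of a simulated salt-stressed batch culture.

    Growth is exponential at ``mu_true`` (d⁻¹) until the culture self-shades
    at ``od_linear_onset``, then linear with the slope matched at the switch
    (light limitation).  Extracellular glycerol accumulates at
    qGG_true × integrated biomass (0.2 gDW/L per OD₇₃₀, 24 h/day, one
    glycerol per GG cleaved).  Noise is multiplicative log-normal; the seed
    is mandatory for reproducibility.
    """

    mu_true: float = 0.6            # 1/day
    od0: float = 0.1
    qGG_true: float = 0.01          # mmol gDW^-1 h^-1
    od_linear_onset: float = 1.0
    noise_sd_od: float = 0.02       # relative
    noise_sd_glyc: float = 0.05     # relative
    sampling_times: tuple[float, ...] = tuple(np.arange(0.0, 10.01, 0.5))
    seed: int = 0
    strain: str = "synthetic"
    condition: str = "salt+GG"
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.od0 <= 0 or self.mu_true <= 0:
            raise ValueError("od0 and mu_true must be positive")


def _od_true(t: float, p: CultureSimParams) -> float:
    t_c = math.log(p.od_linear_onset / p.od0) / p.mu_true
    if t <= t_c or p.od0 >= p.od_linear_onset:
        return p.od0 * math.exp(p.mu_true * t)
    # linear phase with slope continuous at the switch
    return p.od_linear_onset * (1.0 + p.mu_true * (t - t_c))


def _od_integral(t: float, p: CultureSimParams) -> float:
    """∫0^t OD dt' in OD·days, analytic and piecewise."""
    t_c = math.log(p.od_linear_onset / p.od0) / p.mu_true
    if t <= t_c or p.od0 >= p.od_linear_onset:
        return p.od0 * (math.exp(p.mu_true * t) - 1.0) / p.mu_true
    exp_part = p.od0 * (math.exp(p.mu_true * t_c) - 1.0) / p.mu_true
    dt = t - t_c
    lin_part = p.od_linear_onset * dt + 0.5 * p.od_linear_onset * p.mu_true * dt**2
    return exp_part + lin_part


def simulate_culture(params: CultureSimParams,
                     constants: ConversionConstants | None = None,
                     ) -> CultureTimeSeries:
    """Generate one noisy OD₇₃₀ / extracellular-glycerol trajectory.

    The same seed always yields the bitwise-identical series.
    """
    p = params
    consts = constants or ConversionConstants()
    rng = np.random.default_rng(p.seed)
    times = list(p.sampling_times)
    od_true = np.array([_od_true(t, p) for t in times])
    # glycerol [mmol/L] = qGG [mmol/gDW/h] * 24 [h/d] * dw_per_od [g/L/OD] * ∫OD dt [OD·d]
    glyc_true = np.array(
        [p.qGG_true * 24.0 * consts.dw_per_od * _od_integral(t, p) for t in times])
    od = od_true * np.exp(rng.normal(0.0, p.noise_sd_od, size=len(times))) \
        if p.noise_sd_od > 0 else od_true
    glyc = glyc_true * np.exp(rng.normal(0.0, p.noise_sd_glyc, size=len(times))) \
        if p.noise_sd_glyc > 0 else glyc_true
    samples = [(float(t), float(o), float(g)) for t, o, g in zip(times, od, glyc)]
    return CultureTimeSeries(strain=p.strain, condition=p.condition,
                             replicate_id=p.replicate_id, samples=samples)
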
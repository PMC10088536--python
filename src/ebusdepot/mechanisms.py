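"""Physical mechanisms of drug accommodation after intratumoral injection.

Two candidate mechanisms are modeled for how an injected fluid bolus is
accommodated by tumor tissue:

1. **Darcy porous flow** — laminar flow of a Newtonian fluid through the
   tumor interstitium.  With a constant volumetric injection rate ``Q`` and
   spherical symmetry around the needle tip, Darcy's law integrates to the
   point-source pressure field ``P(r) = Q / (4 pi K r)``.  Requiring the
   pressure to fall to the tumor interstitial fluid pressure ``P_i`` at the
   observed depot radius ``R`` (beyond which flow ceases) yields an estimate
   of the hydraulic conductivity ``K = Q / (4 pi R P_i)``.  If that estimate
   exceeds literature values for tumor tissue by several orders of magnitude,
   porous flow cannot be the dominant transport mechanism.

2. **Tissue fracture** — the needle track seeds a crack that the injection
   pressure propagates, with the drug tunneling along the crack.  The
   steady-state tunneling threshold for a crack of width ``h`` in a layered
   material of elastic modulus ``E`` and mode I toughness ``Gamma`` is
   ``sigma_th = sqrt(pi E Gamma / (2 h))``.  Fracture is plausible when the
   stress generated by the injection exceeds this threshold.

Darcy quantities use cm / mmHg / s units (conductivity in
cm^2.mmHg^-1.s^-1, as tabulated in the tumor-physiology literature);
fracture quantities use SI internally and report stresses in kPa.
Conversions are centralized in :mod:`ebusdepot.units`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Literal

from . import units

__all__ = [
    "DarcyParams",
    "FractureParams",
    "MechanismReport",
    "darcy_pressure_profile",
    "darcy_conductivity",
    "conductivity_excess",
    "fracture_threshold",
    "pressure_from_flow",
    "mechanism_report",
    "K_LIT_DEFAULT",
    "default_darcy_params",
    "macro_fracture_params",
    "micro_fracture_params",
]

#: Representative literature hydraulic conductivity of tumor tissue,
#: cm^2.mmHg^-1.s^-1.  Tumor interstitium conductivities reported in the
#: perfusion literature are of order 1e-7 in these units; user-overridable
#: wherever it is consumed.
K_LIT_DEFAULT = 3.1831e-7

#: Cutoff (orders of magnitude of conductivity excess over literature
#: values) above which Darcy porous flow is ruled implausible.  Conservative
#: relative to the 4-5 orders observed; configurable in mechanism_report.
POROUS_EXCESS_CUTOFF_ORDERS = 3.0


@dataclass(frozen=True)
class DarcyParams:
    """Inputs for the radial Darcy-flow conductivity estimate.

    Attributes
    ----------
    q_inj_ml_per_s : volumetric injection rate Q (mL/s).
    p_i_mmhg : tumor interstitial fluid pressure P_i (mmHg).
    r_depot_cm : (low, high) range of the depot radius R (cm), the distance
        from the needle tip at which flow ceases.
    k_lit_range : (low, high) literature hydraulic conductivity bounds
        (cm^2.mmHg^-1.s^-1).
    """

    q_inj_ml_per_s: float
    p_i_mmhg: float
    r_depot_cm: tuple[float, float]
    k_lit_range: tuple[float, float] = (K_LIT_DEFAULT, K_LIT_DEFAULT)

    def __post_init__(self) -> None:
        if self.q_inj_ml_per_s <= 0:
            raise ValueError("q_inj_ml_per_s must be positive")
        if self.p_i_mmhg <= 0:
            raise ValueError("p_i_mmhg must be positive")
        lo, hi = self.r_depot_cm
        if not (0 < lo <= hi):
            raise ValueError("r_depot_cm must be an ordered positive range")
        klo, khi = self.k_lit_range
        if not (0 < klo <= khi):
            raise ValueError("k_lit_range must be an ordered positive range")


@dataclass(frozen=True)
class FractureParams:
    """Inputs for the crack-tunneling stress threshold.

    Attributes
    ----------
    e_mod_kpa : elastic modulus E of the tissue (kPa).
    toughness_j_per_m2 : mode I fracture toughness Gamma (J/m^2).
    crack_width_m : crack width h (m).
    regime : "macro" (single contiguous crack the size of the imaged depot)
        or "micro" (percolation of fine cracks below imaging resolution).
    prefactor : dimensionless constant under the square root; the default
        pi/2 reproduces the printed threshold values.
    poisson : optional Poisson ratio; when given, E is replaced by the
        plane-strain modulus E / (1 - nu^2).
    """

    e_mod_kpa: float
    toughness_j_per_m2: float
    crack_width_m: float
    regime: Literal["macro", "micro"] = "macro"
    prefactor: float = math.pi / 2.0
    poisson: float | None = None

    def __post_init__(self) -> None:
        if min(self.e_mod_kpa, self.toughness_j_per_m2, self.crack_width_m) <= 0:
            raise ValueError("e_mod_kpa, toughness_j_per_m2, crack_width_m must be positive")
        if self.regime not in ("macro", "micro"):
            raise ValueError(f"unknown regime {self.regime!r}")


def default_darcy_params() -> DarcyParams:
    """Default Darcy inputs: Q = 0.4 mL/s, P_i = 10 mmHg, R in 0.1-1 cm."""
    return DarcyParams(q_inj_ml_per_s=0.4, p_i_mmhg=10.0, r_depot_cm=(0.1, 1.0))


def macro_fracture_params(
    e_mod_kpa: float = 25.0, toughness_j_per_m2: float = 3300.0, crack_width_m: float = 0.01
) -> FractureParams:
    """Macro-crack regime defaults: E midpoint of 20-30 kPa, Gamma midpoint
    of 2.5-4.1 kJ/m^2 (adipose/muscle literature), h = 1 cm (imaged depot
    width)."""
    return FractureParams(e_mod_kpa, toughness_j_per_m2, crack_width_m, regime="macro")


def micro_fracture_params(
    e_mod_kpa: float = 25.0, toughness_j_per_m2: float = 330.0, crack_width_m: float = 800e-6
) -> FractureParams:
    """Micro-crack percolation defaults: Gamma = 330 J/m^2 and h = 800 um
    (brittle-interface cracks observed after injections into adipose
    tissue)."""
    return FractureParams(e_mod_kpa, toughness_j_per_m2, crack_width_m, regime="micro")


def darcy_pressure_profile(q_inj_ml_per_s: float, k: float, r_cm: float) -> float:
    """Pressure above far-field at radius ``r_cm`` from a point source.

    P(r) = Q / (4 pi K r), the spherically symmetric steady solution of
    Darcy's law with P -> 0 as r -> infinity.

    Parameters are Q in mL/s, K in cm^2.mmHg^-1.s^-1, r in cm; the result is
    in mmHg.
    """
    if q_inj_ml_per_s <= 0 or k <= 0:
        raise ValueError("q_inj_ml_per_s and k must be positive")
    if r_cm <= 0:
        raise ValueError("r_cm must be positive (r = 0 is the singular point)")
    return q_inj_ml_per_s / (4.0 * math.pi * k * r_cm)


def darcy_conductivity(q_inj_ml_per_s: float, r_depot_cm: float, p_i_mmhg: float) -> float:
    """Hydraulic conductivity implied by flow ceasing at the depot radius.

    Solves ``darcy_pressure_profile(Q, K, R) = P_i`` for K:
    K = Q / (4 pi R P_i), in cm^2.mmHg^-1.s^-1.
    """
    if min(q_inj_ml_per_s, r_depot_cm, p_i_mmhg) <= 0:
        raise ValueError("all inputs must be positive")
    return q_inj_ml_per_s / (4.0 * math.pi * r_depot_cm * p_i_mmhg)


def conductivity_excess(
    k_est: float | tuple[float, float], k_lit: float | tuple[float, float]
) -> tuple[float, float]:
    """Orders of magnitude by which estimated conductivity exceeds literature.

    Evaluates log10(k_est / k_lit) over the supplied scalars or (low, high)
    ranges and returns the (min, max) orders.
    """
    est = _as_range(k_est, "k_est")
    lit = _as_range(k_lit, "k_lit")
    ratios = [e / l for e in est for l in lit]
    logs = [math.log10(r) for r in ratios]
    return (min(logs), max(logs))


def _as_range(x: float | tuple[float, float], name: str) -> tuple[float, float]:
    if isinstance(x, (int, float)):
        pair = (float(x), float(x))
    else:
        pair = (float(x[0]), float(x[1]))
    if min(pair) <= 0:
        raise ValueError(f"{name} must be positive")
    return pair


def fracture_threshold(params: FractureParams) -> float:
    """Steady-state crack-tunneling stress threshold, in kPa.

    sigma_th = sqrt(prefactor * E * Gamma / h) with the default prefactor
    pi/2, i.e. sigma_th = sqrt(pi E Gamma / (2 h)).  E is converted to Pa
    (plane-strain corrected if a Poisson ratio is supplied), Gamma is in
    J/m^2 and h in m, so the root is in Pa.
    """
    e_pa = units.kpa_to_pa(params.e_mod_kpa)
    if params.poisson is not None:
        e_pa /= 1.0 - params.poisson**2
    sigma_pa = math.sqrt(params.prefactor * e_pa * params.toughness_j_per_m2 / params.crack_width_m)
    return units.pa_to_kpa(sigma_pa)


def pressure_from_flow(p_ref_kpa: float, q_ref_ml_per_s: float, q_ml_per_s: float) -> float:
    """Needle-tip pressure at flow ``q`` by linear scaling from a reference.

    Injection pressure measurements in tissue scale linearly with flow rate
    over the relevant range, so p = p_ref * q / q_ref.
    """
    if min(p_ref_kpa, q_ref_ml_per_s, q_ml_per_s) <= 0:
        raise ValueError("all inputs must be positive")
    return p_ref_kpa * q_ml_per_s / q_ref_ml_per_s


@dataclass
class MechanismReport:
    """Combined plausibility assessment of the two candidate mechanisms."""

    k_est_range: tuple[float, float]
    k_excess_orders: tuple[float, float]
    sigma_injection_kpa: tuple[float, float]
    sigma_threshold_macro_kpa: float
    sigma_threshold_micro_kpa: float
    porous_flow_plausible: bool
    fracture_plausible: bool
    narrative: str = ""
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_text(self) -> str:
        """Human-readable parameter/verdict table."""
        lo, hi = self.k_est_range
        olo, ohi = self.k_excess_orders
        slo, shi = self.sigma_injection_kpa
        lines = [
            "Mechanism assessment",
            "====================",
            "Darcy porous flow",
            f"  estimated K        : {lo:.3e} - {hi:.3e} cm^2.mmHg^-1.s^-1",
            f"  excess vs literature: {olo:.1f} - {ohi:.1f} orders of magnitude",
            f"  plausible          : {self.porous_flow_plausible}",
            "Tissue fracture",
            f"  threshold (macro)  : {self.sigma_threshold_macro_kpa:.1f} kPa",
            f"  threshold (micro)  : {self.sigma_threshold_micro_kpa:.1f} kPa",
            f"  injection stress   : {slo:.0f} - {shi:.0f} kPa",
            f"  plausible          : {self.fracture_plausible}",
            "",
            self.narrative,
        ]
        return "\n".join(lines)


def mechanism_report(
    darcy: DarcyParams | None = None,
    fracture_macro: FractureParams | None = None,
    fracture_micro: FractureParams | None = None,
    sigma_injection_kpa: tuple[float, float] = (240.0, 300.0),
    porous_cutoff_orders: float = POROUS_EXCESS_CUTOFF_ORDERS,
) -> MechanismReport:
    """Evaluate both mechanisms and issue plausibility verdicts.

    Decision rules:

    * porous flow is ruled implausible iff the *minimum* conductivity excess
      over literature values is at least ``porous_cutoff_orders`` orders of
      magnitude;
    * fracture is plausible iff the *minimum* injection stress exceeds the
      larger of the macro- and micro-regime tunneling thresholds.
    """
    darcy = darcy or default_darcy_params()
    fracture_macro = fracture_macro or macro_fracture_params()
    fracture_micro = fracture_micro or micro_fracture_params()
    s_lo, s_hi = sigma_injection_kpa
    if not (0 < s_lo <= s_hi):
        raise ValueError("sigma_injection_kpa must be an ordered positive range")

    r_lo, r_hi = darcy.r_depot_cm
    # K is decreasing in R: the small-radius end gives the larger estimate.
    k_hi = darcy_conductivity(darcy.q_inj_ml_per_s, r_lo, darcy.p_i_mmhg)
    k_lo = darcy_conductivity(darcy.q_inj_ml_per_s, r_hi, darcy.p_i_mmhg)
    excess = conductivity_excess((k_lo, k_hi), darcy.k_lit_range)
    porous_plausible = excess[0] < porous_cutoff_orders

    sig_macro = fracture_threshold(fracture_macro)
    sig_micro = fracture_threshold(fracture_micro)
    sig_max = max(sig_macro, sig_micro)
    fracture_plausible = s_lo > sig_max

    narrative = (
        f"Estimated tumor hydraulic conductivity ({k_lo:.2e}-{k_hi:.2e} "
        f"cm^2.mmHg^-1.s^-1) exceeds literature values by "
        f"{excess[0]:.1f}-{excess[1]:.1f} orders of magnitude; porous Darcy flow is "
        f"{'plausible' if porous_plausible else 'implausible'} "
        f"(cutoff {porous_cutoff_orders:.0f} orders). "
        f"Injection stress {s_lo:.0f}-{s_hi:.0f} kPa vs. crack-tunneling thresholds "
        f"{sig_macro:.0f} kPa (macro) and {sig_micro:.0f} kPa (micro): tissue fracture is "
        f"{'plausible' if fracture_plausible else 'implausible'}."
    )
    return MechanismReport(
        k_est_range=(k_lo, k_hi),
        k_excess_orders=excess,
        sigma_injection_kpa=(s_lo, s_hi),
        sigma_threshold_macro_kpa=sig_macro,
        sigma_threshold_micro_kpa=sig_micro,
        porous_flow_plausible=porous_plausible,
        fracture_plausible=fracture_plausible,
        narrative=narrative,
        params={
            "darcy": asdict(darcy),
            "fracture_macro": asdict(fracture_macro),
            "fracture_micro": asdict(fracture_micro),
        },
    )
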
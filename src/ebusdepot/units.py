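"""Central unit conversions.

Pressures appear in two unit systems: the Darcy-flow quantities (interstitial
fluid pressure, hydraulic conductivity) are conventionally tabulated in mmHg,
while tissue-mechanics quantities (elastic modulus, injection stress, fracture
thresholds) are in kPa or Pa.  Every conversion in the package goes through
these constants so the two systems are never mixed implicitly.
"""

MMHG_PER_KPA = 7.50062
KPA_PER_MMHG = 0.133322

UM_PER_M = 1e6
CM_PER_M = 100.0
ML_PER_CM3 = 1.0  # identity by definition; named for readability


def mmhg_to_kpa(p_mmhg: float) -> float:
    """Convert pressure from mmHg to kPa."""
    return p_mmhg * KPA_PER_MMHG


def kpa_to_mmhg(p_kpa: float) -> float:
    """Convert pressure from kPa to mmHg."""
    return p_kpa * MMHG_PER_KPA


def kpa_to_pa(p_kpa: float) -> float:
    return p_kpa * 1e3


def pa_to_kpa(p_pa: float) -> float:
    return p_pa * 1e-3


def um_to_m(x_um: float) -> float:
    return x_um / UM_PER_M


def cm_to_m(x_cm: float) -> float:
    return x_cm / CM_PER_M
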
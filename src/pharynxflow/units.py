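"""Unit conversions, centralized so geometry (mm/cm2/cm3) and the SI solver
cannot drift apart.

Convention: anatomy and tabulated metrics use mm (lengths), cm^2 (areas),
cm^3 (volumes), mL/s (flow); the solver works in SI throughout.
"""

MM_TO_M = 1e-3
M_TO_MM = 1e3

CM2_TO_M2 = 1e-4
M2_TO_CM2 = 1e4

CM3_TO_M3 = 1e-6
M3_TO_CM3 = 1e6

MM3_TO_CM3 = 1e-3

ML_S_TO_M3_S = 1e-6
M3_S_TO_ML_S = 1e6

MM2_TO_CM2 = 1e-2
CM2_TO_MM2 = 1e2


def flow_ml_s_to_si(q_ml_s: float) -> float:
    """mL/s -> m^3/s."""
    return q_ml_s * ML_S_TO_M3_S


def area_cm2_to_si(a_cm2: float) -> float:
    """cm^2 -> m^2."""
    return a_cm2 * CM2_TO_M2


def velocity_from_q_a(q_ml_s: float, a_cm2: float) -> float:
    """Mean velocity in m/s from a flow in mL/s through an area in cm^2."""
    return flow_ml_s_to_si(q_ml_s) / area_cm2_to_si(a_cm2)
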
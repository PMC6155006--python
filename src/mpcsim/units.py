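"""Unit conversions, centralized.

Interface conventions across the package:

* lengths in micrometres (µm),
* pressures in millimetres of mercury (mm Hg),
* volumetric flow in nanolitres per minute (nL/min),
* velocities in µm/s, wall shear in Pa,
* mineral density in mg/cc, osmolality in mOsm,
* time in hours.

All physics is computed in SI internally; these constants are the only
place conversion factors appear.
"""

MMHG_TO_PA = 133.322
PA_TO_MMHG = 1.0 / MMHG_TO_PA

UM_TO_M = 1e-6
M_TO_UM = 1e6

#: 1 m^3/s expressed in nL/min (1 nL = 1e-12 m^3).
M3_PER_S_TO_NL_PER_MIN = 1e12 * 60.0

#: dynamic viscosity: 1 mPa*s = 1e-3 Pa*s
MPAS_TO_PAS = 1e-3

HOURS_TO_S = 3600.0


def mmhg_to_pa(p: float) -> float:
    return p * MMHG_TO_PA


def pa_to_mmhg(p: float) -> float:
    return p * PA_TO_MMHG
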
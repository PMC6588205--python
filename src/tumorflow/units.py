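"""Unit conversions.

Geometry is stored in micrometres (the resolution of the segmented
networks); all solver arithmetic is done in a single consistent
{cm, s, mmHg} system and converted at module boundaries.  Reported
quantities follow microcirculation conventions: flows in nl/min,
velocities in mm/s or um/s, shear stresses in dyn/cm^2, perfusion in
ml/min/100g.
"""

# length
UM_TO_CM = 1.0e-4
CM_TO_UM = 1.0e4
MM_TO_UM = 1.0e3

# pressure / stress
MMHG_TO_PA = 133.322387415
MMHG_TO_DYN_CM2 = MMHG_TO_PA * 10.0  # 1 Pa = 10 dyn/cm^2
DYN_CM2_TO_MMHG = 1.0 / MMHG_TO_DYN_CM2

# viscosity: 1 cP = 1e-3 Pa s
CP_TO_MMHG_S = 1.0e-3 / MMHG_TO_PA

# volumetric flow: 1 cm^3 = 1 ml = 1e3 ul = 1e6 nl
CM3_S_TO_NL_MIN = 1.0e6 * 60.0
CM3_S_TO_UL_MIN = 1.0e3 * 60.0
CM3_S_TO_ML_MIN = 60.0
NL_MIN_TO_CM3_S = 1.0 / CM3_S_TO_NL_MIN
UL_MIN_TO_CM3_S = 1.0 / CM3_S_TO_UL_MIN

# velocity
CM_S_TO_UM_S = 1.0e4
CM_S_TO_MM_S = 10.0
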
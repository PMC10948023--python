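"""Physical constants and unit conventions.

Internal unit system (consistent, no hidden conversion factors downstream):

================  ==========
quantity          unit
================  ==========
length            µm
time              ms
voltage           mV
current           nA (stimulus currents are quoted in µA at the API surface)
conductance       µS
capacitance       nF
resistance        MΩ
concentration     µM
current density   mA/cm²
================  ==========

mV = nA·MΩ and nF·mV/ms = nA, so the cable equation closes without
scale factors once geometry is converted at construction time.
"""

import math

#: Gas constant, J/(K·mol)
R_GAS = 8.31
#: Model temperature, K (23 °C; ex-vivo room-temperature experiments)
T_KELVIN = 296.15
#: Faraday constant, C/mol
FARADAY = 9.6485e4

#: RT/2F in mV — prefactor of the divalent Nernst potential.
NERNST_CA_MV = 1e3 * R_GAS * T_KELVIN / (2.0 * FARADAY)

#: Specific membrane capacitance, µF/cm²
C_M_UF_CM2 = 1.0

#: Extracellular resistivity of retinal tissue, Ω·cm
RHO_EXT_OHM_CM = 1000.0

#: Intracellular resistivity, Ω·cm
RHO_AXIAL_RGC = 143.2
RHO_AXIAL_BC = 130.0

#: Default solver time step, ms
DT_MS = 0.025


def ca_flux_factor(shell_depth_nm: float) -> float:
    """Conversion factor from Ca current density to d[Ca]/dt.

    d[Ca]_i/dt = -i_Ca * factor, with i_Ca in mA/cm² (inward negative)
    and the result in µM/ms, for a submembrane shell of the given depth.
    factor = 1e3 / (2·F·d) with d in cm.
    """
    d_cm = shell_depth_nm * 1e-7
    return 1e3 / (2.0 * FARADAY * d_cm)


def point_source_mv(current_ua: float, rho_ohm_cm: float, r_um: float) -> float:
    """Extracellular potential of an ideal point source, in mV.

    V_e = I·ρ/(4πr); with I in µA, ρ in Ω·cm and r in µm the numeric
    result carries a factor 10: V_e[mV] = 10·I·ρ/(4π·r).
    """
    return 10.0 * current_ua * rho_ohm_cm / (4.0 * math.pi * r_um)
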
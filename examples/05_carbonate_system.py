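"""Seawater CO2-system chemistry of the three pH treatments.

Solves the carbonate system from each treatment's mean measured pair
(pH on the free scale + DIC) at the holding temperature and an assumed
salinity of 32, and prints the derived quantities: pCO2, carbonate
speciation, computed total alkalinity, and the aragonite/calcite
saturation states (Omega < 1 means the mineral tends to dissolve).
"""

import pandas as pd

from opilio.carbonate import WaterSample, solve_from_ph_dic, solve_from_ta_dic
from opilio.reference import FEMALE_TANK_CONDITIONS

rows = []
for treatment, cond in FEMALE_TANK_CONDITIONS.items():
    st = solve_from_ph_dic(WaterSample(temperature=cond["temperature"], salinity=32.0,
                                       ph_free=cond["ph_free"], dic=cond["dic"]))
    rows.append({"Treatment": treatment, "T (C)": st.temperature, "pH_F": st.ph_free,
                 "pCO2 (uatm)": st.pco2, "HCO3": st.hco3, "CO3": st.co3,
                 "TA": st.ta, "Omega_Ar": st.omega_aragonite,
                 "Omega_Ca": st.omega_calcite})
print(pd.DataFrame(rows).round(3).to_string(index=False))
print("\nOnly the ambient treatment is supersaturated for both calcite and "
      "aragonite; at pH 7.5 both minerals are undersaturated.")

# the solver inverts exactly: feed computed TA back with DIC and recover pH
st = solve_from_ph_dic(WaterSample(temperature=2.05, ph_free=7.50, dic=2.15))
back = solve_from_ta_dic(WaterSample(temperature=2.05, dic=2.15, ta=st.ta))
print(f"\nTA+DIC round trip recovers pH_free {back.ph_free:.6f} (input 7.50)")
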
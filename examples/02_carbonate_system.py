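"""Design an acidification treatment factorial with the carbonate solver.

Computes the equilibrium carbonate states of the 2 x 2 decoupling design
(pCO2 400/800 µatm x pH 8.1/7.8 at 25 degC) and the pH drop that doubling
pCO2 alone would cause at fixed alkalinity.
"""

from acidnit import carbonate as cs
from acidnit import synthetic_data as sd

env = cs.EnvConditions(temperature=25.0, salinity=30.0)

cells = sd.simulate_carbonate_factorial(env, ta_initial=2300.0)
print("pCO2 (µatm)  pH    DIC (µmol/kg)  TA (µmol/kg)  TA adjustment")
for (pco2, ph), cell in sorted(cells.items()):
    s = cell.state
    print(
        f"{pco2:8.0f}  {ph:5.2f}  {s.dic:12.1f}  {s.ta:12.1f}  {cell.ta_adjustment:+10.1f}"
    )

low = cs.solve_from_ta_pco2(2300.0, 400.0, env)
high = cs.solve_from_ta_pco2(2300.0, 800.0, env)
print()
print(f"pH at 400 µatm, TA 2300: {low.ph:.3f}")
print(f"pH at 800 µatm, TA 2300: {high.ph:.3f}")
print(f"pH drop from doubled pCO2 alone: {low.ph - high.ph:.3f} units")
print()
print("Each factorial cell states the DIC/TA the reactor must hold; the")
print("TA adjustment is the alkalinity the acid/base dosing must add (+)")
print("or remove (-) relative to the initial water.")
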
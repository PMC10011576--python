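"""Upscale the N2O response range to a global emission scenario.

Applies the +9.5% to +27.5% response of nitrification-derived N2O at a
0.21-unit pH decline to the nitrifier share of global estuarine + coastal
N2O emission, and expresses the increase as a share of the anthropogenic
total (6.9 Tg N2O-N per year).
"""

from acidnit import upscale as up

scenario = up.UpscaleScenario(
    baseline_emission=up.RECONSTRUCTED_BASELINE_TG,  # reconstructed placeholder
    response_low=0.095,
    response_high=0.275,
    nitrifier_share=0.5,
)
low, high = up.emission_increase(scenario)
pct_low, pct_high = up.share_of_anthropogenic(low, high, scenario.anthropogenic_total)

print(f"baseline estuarine+coastal emission = {scenario.baseline_emission} Tg N2O-N/yr (reconstructed)")
print(f"nitrifier share                     = {scenario.nitrifier_share}")
print(f"response range at dpH 0.21          = +{scenario.response_low:.1%} to +{scenario.response_high:.1%}")
print(f"emission increase                   = {low:.3f} to {high:.3f} Tg N2O-N/yr")
print(f"share of anthropogenic total        = {pct_low} % to {pct_high} % of {scenario.anthropogenic_total} Tg")
print()
print("Consistency check: inverting the increase bounds recovers the baseline:")
print(f"  implied baseline (low end)  = {up.implied_baseline(low, scenario.response_low):.3f} Tg")
print(f"  implied baseline (high end) = {up.implied_baseline(high, scenario.response_high):.3f} Tg")
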
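"""Estimate nitrification and N2O production rates from a tracer incubation.

Simulates a 24 h incubation of 4 L estuarine water spiked with 15NH4+ to an
atom fraction F = 0.2 at known true rates, then inverts the observations
with the two-point nitrification estimator and both N2O estimators.
"""

from acidnit import synthetic_data as sd
from acidnit import tracer_rates as tr

config = sd.SimulationConfig(
    true_nitrification_rate=100.0,  # nmol L-1 h-1
    true_n2o_rate=40.0,  # pmol N2O-N L-1 h-1
    noise_cv=0.0,  # noise-free, so recovery is exact
    seed=0,
)
series = sd.simulate_incubation(config)
first, last = series.data.iloc[0], series.data.iloc[-1]

obs0 = tr.NoxObservation(first.time_h, first.nox_umol_L, first.r15_nox)
obs1 = tr.NoxObservation(last.time_h, last.nox_umol_L, last.r15_nox)
n0 = tr.N2oObservation(first.time_h, first.n2o45_pmol, first.n2o46_pmol)
n1 = tr.N2oObservation(last.time_h, last.n2o45_pmol, last.n2o46_pmol)

f = series.tracer.F
nit = tr.nitrification_rate(obs0, obs1, f)
balance = tr.n2o_rate_atom_balance(n0, n1, f, series.volume)
printed = tr.n2o_rate_isotopologue(n0, n1, f, series.volume)

print(f"tracer atom fraction F          = {f:.3f}")
print(f"nitrification rate              = {nit.value:.2f} nmol L-1 h-1 (truth 100)")
print(f"N2O rate, atom balance          = {balance.value:.2f} pmol N L-1 h-1 (truth 40)")
print(f"N2O rate, mass-45/46 formula    = {printed.value:.2f} pmol N L-1 h-1")
print(f"formula / atom balance          = {printed.value / balance.value:.3f} (= 2 - F)")
print()
print("The mass-45/46 formula carries a (2 - F) factor under binomial")
print("pairing; the atom-balance estimator recovers the true N-atom rate.")
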
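"""Seawater carbonate-system solver for acidification treatment design.

Given any two of (pH, DIC, TA, pCO2) at a stated temperature and salinity,
the remaining quantities follow from the equilibrium constants of the
CO2/borate/water acid-base system.  This module implements the option set
used for glass-electrode pH + coulometric DIC work in estuarine and coastal
waters:

* K1, K2 — Mehrbach et al. (1973) as refit by Dickson & Millero (1987),
  seawater pH scale.
* K0 — Weiss (1974) CO2 solubility.
* KB — Dickson (1990a) boric acid, converted from the total to the seawater
  scale using KS (Dickson 1990b) and KF (Dickson & Riley 1979).
* KW — Millero (1995), seawater scale.
* Total boron — Uppström (1974) boron/chlorinity ratio.

Alkalinity is truncated to the carbonate + borate + water terms; nutrient
contributions (phosphate, silicate, ammonia) are deliberately excluded —
at the <=10 µM NH4+ level of tracer incubations they are negligible.
All concentrations are µmol per kg of solution; pCO2 is µatm (treated as
identical to fugacity, a <0.5% approximation at 1 atm).  Internally the
solver works on the seawater pH scale; :func:`nbs_to_sws` /
:func:`sws_to_nbs` provide an explicit conversion for electrode (NBS)
calibrations, off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

from .errors import DomainError, NoSolutionError

__all__ = [
    "EnvConditions",
    "ConstantSet",
    "CarbonateState",
    "constants",
    "total_boron",
    "speciate_from_ph_dic",
    "speciate_from_ph_pco2",
    "solve_ph_from_ta_dic",
    "solve_from_ta_pco2",
    "nbs_to_sws",
    "sws_to_nbs",
]

_PH_BRACKET = (2.0, 12.0)
_PH_TOL = 1e-10  # root-finder tolerance, pH units


@dataclass(frozen=True)
class EnvConditions:
    """Environmental inputs of the solver: temperature (°C), practical
    salinity, and pressure (surface work only, 0 dbar)."""

    temperature: float
    salinity: float
    pressure: float = 0.0

    def __post_init__(self) -> None:
        if not (-2.0 <= self.temperature <= 40.0):
            raise DomainError(f"temperature {self.temperature} °C outside [-2, 40]")
        if not (0.0 <= self.salinity <= 45.0):
            raise DomainError(f"salinity {self.salinity} outside [0, 45]")
        if self.pressure != 0.0:
            raise DomainError("only surface pressure (0 dbar) is supported")


@dataclass(frozen=True)
class ConstantSet:
    """Equilibrium constants at one (T, S), mol kg-1 units, with provenance.

    ``k0`` is the CO2 solubility (mol kg-1 atm-1); ``k1``/``k2`` the carbonic
    acid dissociations; ``kb`` boric acid; ``kw`` the water ion product.
    All proton-involving constants are reported on ``ph_scale``.
    """

    k0: float
    k1: float
    k2: float
    kb: float
    kw: float
    ph_scale: str = "seawater"
    provenance: tuple[str, ...] = (
        "K0: Weiss 1974",
        "K1,K2: Mehrbach 1973 refit by Dickson & Millero 1987 (SWS)",
        "KB: Dickson 1990a (total, converted to SWS)",
        "KW: Millero 1995 (SWS)",
        "TB: Uppström 1974",
    )

    def __post_init__(self) -> None:
        for name in ("k0", "k1", "k2", "kb", "kw"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.k1 > self.k2:
            raise ValueError("expected K1 > K2")


@dataclass(frozen=True)
class CarbonateState:
    """Full speciation of one water sample.

    pH on the solver's working (seawater) scale; dic/ta and all species in
    µmol kg-1; pco2 in µatm.  The DIC and TA closure identities
    ``dic = co2_star + hco3 + co3`` and
    ``ta = hco3 + 2*co3 + boh4 + oh - h`` hold to 1e-6 relative on every
    state this module returns.
    """

    ph: float
    dic: float
    ta: float
    pco2: float
    co2_star: float
    hco3: float
    co3: float
    boh4: float
    oh: float
    h: float
    constants: ConstantSet = field(repr=False, compare=False, default=None)


# ---------------------------------------------------------------------------
# equilibrium constants


def _ionic_strength(s: float) -> float:
    return 19.924 * s / (1000.0 - 1.005 * s)


def _total_sulfate(s: float) -> float:
    # Morris & Riley (1966), mol kg-1
    return 0.14 / 96.062 * s / 1.80655


def _total_fluoride(s: float) -> float:
    # Riley (1965), mol kg-1
    return 0.000067 / 18.998 * s / 1.80655


def _ks_free(tk: float, s: float) -> float:
    """Bisulfate dissociation, free scale (Dickson 1990b)."""
    i = _ionic_strength(s)
    ln_ks = (
        -4276.1 / tk
        + 141.328
        - 23.093 * math.log(tk)
        + (-13856.0 / tk + 324.57 - 47.986 * math.log(tk)) * math.sqrt(i)
        + (35474.0 / tk - 771.54 + 114.723 * math.log(tk)) * i
        - 2698.0 / tk * i**1.5
        + 1776.0 / tk * i**2
        + math.log(1.0 - 0.001005 * s)
    )
    return math.exp(ln_ks)


def _kf_free(tk: float, s: float) -> float:
    """Hydrogen fluoride dissociation, free scale (Dickson & Riley 1979)."""
    i = _ionic_strength(s)
    ln_kf = 1590.2 / tk - 12.641 + 1.525 * math.sqrt(i) + math.log(1.0 - 0.001005 * s)
    return math.exp(ln_kf)


def _total_to_sws(tk: float, s: float) -> float:
    """Multiplier converting a total-scale constant to the seawater scale."""
    ts, tf = _total_sulfate(s), _total_fluoride(s)
    ks, kf = _ks_free(tk, s), _kf_free(tk, s)
    return (1.0 + ts / ks + tf / kf) / (1.0 + ts / ks)


def constants(env: EnvConditions) -> ConstantSet:
    """Evaluate the equilibrium constants at the given T and S.

    Deterministic evaluation of the published functional forms listed in the
    module docstring; all proton-involving constants are returned on the
    seawater pH scale, mol kg-1.
    """
    tk = env.temperature + 273.15
    s = env.salinity

    # CO2 solubility, Weiss (1974), mol kg-1 atm-1
    t100 = tk / 100.0
    ln_k0 = (
        -60.2409
        + 93.4517 / t100
        + 23.3585 * math.log(t100)
        + s * (0.023517 - 0.023656 * t100 + 0.0047036 * t100**2)
    )
    k0 = math.exp(ln_k0)

    # Mehrbach refit by Dickson & Millero (1987), SWS
    pk1 = 3670.7 / tk - 62.008 + 9.7944 * math.log(tk) - 0.0118 * s + 0.000116 * s**2
    pk2 = 1394.7 / tk + 4.777 - 0.0184 * s + 0.000118 * s**2
    k1, k2 = 10.0**-pk1, 10.0**-pk2

    # Boric acid, Dickson (1990a), total scale -> SWS
    sq = math.sqrt(s)
    ln_kb = (
        (-8966.90 - 2890.53 * sq - 77.942 * s + 1.728 * s * sq - 0.0996 * s**2) / tk
        + 148.0248
        + 137.1942 * sq
        + 1.62142 * s
        - (24.4344 + 25.085 * sq + 0.2474 * s) * math.log(tk)
        + 0.053105 * sq * tk
    )
    kb = math.exp(ln_kb) * _total_to_sws(tk, s)

    # Water, Millero (1995), SWS
    ln_kw = (
        148.9802
        - 13847.26 / tk
        - 23.6521 * math.log(tk)
        + (118.67 / tk - 5.977 + 1.0495 * math.log(tk)) * sq
        - 0.01615 * s
    )
    kw = math.exp(ln_kw)

    return ConstantSet(k0=k0, k1=k1, k2=k2, kb=kb, kw=kw)


def total_boron(salinity: float) -> float:
    """Total boron, µmol kg-1, from the Uppström (1974) boron/salinity ratio.

    Linear in salinity and zero in fresh water.
    """
    if not (0.0 <= salinity <= 45.0):
        raise DomainError(f"salinity {salinity} outside [0, 45]")
    return 0.000232 / 10.811 * salinity / 1.80655 * 1e6


def nbs_to_sws(ph_nbs: float, env: EnvConditions) -> float:
    """Convert an NBS (electrode) pH to the seawater scale via the activity
    coefficient fH of Takahashi et al. (1982)."""
    return ph_nbs + math.log10(_fh(env))


def sws_to_nbs(ph_sws: float, env: EnvConditions) -> float:
    """Inverse of :func:`nbs_to_sws`."""
    return ph_sws - math.log10(_fh(env))


def _fh(env: EnvConditions) -> float:
    tk = env.temperature + 273.15
    return 1.2948 - 0.002036 * tk + (0.0004607 - 0.000001475 * tk) * env.salinity**2


# ---------------------------------------------------------------------------
# speciation and inverse solves


def _state_from_ph_dic(
    ph: float, dic_umol: float, env: EnvConditions, k: ConstantSet
) -> CarbonateState:
    h = 10.0**-ph  # mol kg-1, SWS
    dic = dic_umol * 1e-6
    denom = h * h + k.k1 * h + k.k1 * k.k2
    co2 = dic * h * h / denom
    hco3 = dic * k.k1 * h / denom
    co3 = dic * k.k1 * k.k2 / denom
    tb = total_boron(env.salinity) * 1e-6
    boh4 = tb * k.kb / (k.kb + h)
    oh = k.kw / h
    ta = hco3 + 2.0 * co3 + boh4 + oh - h
    pco2 = co2 / k.k0 * 1e6  # µatm
    to_u = 1e6
    return CarbonateState(
        ph=ph,
        dic=dic * to_u,
        ta=ta * to_u,
        pco2=pco2,
        co2_star=co2 * to_u,
        hco3=hco3 * to_u,
        co3=co3 * to_u,
        boh4=boh4 * to_u,
        oh=oh * to_u,
        h=h * to_u,
        constants=k,
    )


def speciate_from_ph_dic(
    ph: float, dic: float, env: EnvConditions, consts: ConstantSet | None = None
) -> CarbonateState:
    """Closed-form speciation from measured pH and DIC (µmol kg-1).

    This is the forward direction of the measurement protocol: pH and DIC
    are measured, TA and pCO2 are computed.  Ionization fractions of
    H2CO3*/HCO3-/CO3-- follow from [H+] = 10**-pH and (K1, K2); TA collects
    carbonate, borate and water terms; pCO2 = [CO2*]/K0.
    """
    if not (2.0 <= ph <= 12.0):
        raise DomainError(f"pH {ph} outside [2, 12]")
    if dic < 0:
        raise DomainError("DIC must be >= 0")
    k = consts if consts is not None else constants(env)
    return _state_from_ph_dic(ph, dic, env, k)


def speciate_from_ph_pco2(
    ph: float, pco2: float, env: EnvConditions, consts: ConstantSet | None = None
) -> CarbonateState:
    """Closed-form speciation from a pH and pCO2 (µatm) pair.

    Used for treatment design: a bubbling target pCO2 plus a pH setpoint
    imply the DIC (and hence TA) the equilibrated reactor must hold.
    """
    if not (2.0 <= ph <= 12.0):
        raise DomainError(f"pH {ph} outside [2, 12]")
    if pco2 < 0:
        raise DomainError("pCO2 must be >= 0")
    k = consts if consts is not None else constants(env)
    h = 10.0**-ph
    co2 = k.k0 * pco2 * 1e-6  # mol kg-1
    dic = co2 * (1.0 + k.k1 / h + k.k1 * k.k2 / (h * h))
    return _state_from_ph_dic(ph, dic * 1e6, env, k)


def _bracketed_ph_root(f, what: str) -> float:
    lo, hi = _PH_BRACKET
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0:
        raise NoSolutionError(
            f"no pH in [{lo}, {hi}] satisfies {what} (f({lo})={flo:.3g}, f({hi})={fhi:.3g})"
        )
    return brentq(f, lo, hi, xtol=_PH_TOL)


def solve_ph_from_ta_dic(
    ta: float, dic: float, env: EnvConditions, consts: ConstantSet | None = None
) -> CarbonateState:
    """Solve pH (and the full state) from TA and DIC, both µmol kg-1.

    Root of ``TA(pH, DIC) - TA_target`` by safeguarded bracketing on
    pH in [2, 12]; TA is strictly decreasing in [H+], so the root is unique
    within the bracket.  Raises :class:`NoSolutionError` when the target is
    not bracketed (physically implausible pair) instead of extrapolating.
    """
    if dic < 0:
        raise DomainError("DIC must be >= 0")
    k = consts if consts is not None else constants(env)

    def f(ph: float) -> float:
        return _state_from_ph_dic(ph, dic, env, k).ta - ta

    ph = _bracketed_ph_root(f, f"TA={ta} at DIC={dic}")
    return _state_from_ph_dic(ph, dic, env, k)


def solve_from_ta_pco2(
    ta: float, pco2: float, env: EnvConditions, consts: ConstantSet | None = None
) -> CarbonateState:
    """Solve the state from TA (µmol kg-1) and pCO2 (µatm).

    At fixed pCO2 the dissolved CO2* is fixed and DIC becomes a function of
    pH alone; the pH root matches the TA target with the same bracketing
    contract as :func:`solve_ph_from_ta_dic`.
    """
    if ta <= 0 or pco2 <= 0:
        raise DomainError("TA and pCO2 must be > 0")
    k = consts if consts is not None else constants(env)

    def f(ph: float) -> float:
        return speciate_from_ph_pco2(ph, pco2, env, k).ta - ta

    ph = _bracketed_ph_root(f, f"TA={ta} at pCO2={pco2}")
    return speciate_from_ph_pco2(ph, pco2, env, k)
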
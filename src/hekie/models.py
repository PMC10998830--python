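"""Closed-form kinetic and biophysical model equations.

Pure, side-effect-free functions shared by the fitting engine, the
mechanistic simulator and the synthetic-data generators.  Each function
implements one of the standard models used to analyse ATP
phosphoribosyltransferase (ATPPRT) kinetics and stability:

* sigmoidal thermal-unfolding curve (differential scanning fluorimetry),
* Michaelis–Menten saturation at fixed co-substrate,
* tight-binding quadratic titration of the catalytic subunit (HisG_S)
  with the regulatory subunit (HisZ),
* Hill dose–response inhibition,
* product formation through two consecutive irreversible first-order
  steps (single-turnover lag kinetics),
* linear solvent-viscosity dependence of kcat ratios,
* Eyring / macromolecular-rate-theory (MMRT) temperature dependence with
  an activation heat capacity,
* single-exponential single-turnover kinetics.

Units convention (applied consistently across the package): substrate
concentrations in mM, protein concentrations in uM, rates in 1/s,
catalytic efficiencies in 1/(M*s), energies in J/mol, temperatures in
kelvin inside thermodynamic expressions (helpers convert from Celsius).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal

import numpy as np

__all__ = [
    "PhysicalConstants",
    "CODATA",
    "MeltParams",
    "MichaelisParams",
    "TitrationParams",
    "DoseResponseParams",
    "TwoStepParams",
    "ViscosityParams",
    "MMRTParams",
    "SingleExpParams",
    "melt_fraction",
    "mm_rate",
    "catalytic_efficiency",
    "titration_rate",
    "holoenzyme_conc",
    "dose_response",
    "two_step_product",
    "viscosity_ratio",
    "eyring_log_rate",
    "mmrt_log_rate",
    "single_exp_product",
    "as_kelvin",
]


@dataclasses.dataclass(frozen=True)
class PhysicalConstants:
    """CODATA values for the Boltzmann, Planck and gas constants."""

    kb: float = 1.380649e-23  # J/K
    h: float = 6.62607015e-34  # J*s
    r: float = 8.314462618  # J/(mol*K)

    @property
    def kb_over_h(self) -> float:
        """Attempt-frequency prefactor kB/h, ~2.0837e10 1/(K*s)."""
        return self.kb / self.h


CODATA = PhysicalConstants()


def _require_finite(**values: float) -> None:
    for name, value in values.items():
        if not np.all(np.isfinite(value)):
            raise ValueError(f"parameter {name!r} must be finite, got {value!r}")


# ---------------------------------------------------------------------------
# parameter containers


@dataclasses.dataclass(frozen=True)
class MeltParams:
    """Logistic thermal-unfolding parameters: baselines, midpoint, slope."""

    ll: float  # lower (folded) baseline, fluorescence a.u.
    ul: float  # upper (unfolded) baseline, fluorescence a.u.
    tm: float  # melting temperature, deg C
    c: float  # transition slope, deg C

    def __post_init__(self) -> None:
        _require_finite(ll=self.ll, ul=self.ul, tm=self.tm, c=self.c)
        if self.ul <= self.ll:
            raise ValueError("upper baseline must exceed lower baseline")
        if self.c <= 0:
            raise ValueError("transition slope c must be positive")


@dataclasses.dataclass(frozen=True)
class MichaelisParams:
    kcat: float  # 1/s
    km: float  # mM

    def __post_init__(self) -> None:
        _require_finite(kcat=self.kcat, km=self.km)
        if self.kcat <= 0 or self.km <= 0:
            raise ValueError("kcat and Km must be positive")


@dataclasses.dataclass(frozen=True)
class TitrationParams:
    vmax: float  # rate units of the input (1/s when rates are v/G)
    kd_app: float  # uM

    def __post_init__(self) -> None:
        _require_finite(vmax=self.vmax, kd_app=self.kd_app)
        if self.vmax <= 0:
            raise ValueError("Vmax must be positive")
        if self.kd_app < 0:
            raise ValueError("Kd_app must be non-negative")


@dataclasses.dataclass(frozen=True)
class DoseResponseParams:
    ic50: float  # uM
    hill_n: float  # dimensionless

    def __post_init__(self) -> None:
        _require_finite(ic50=self.ic50, hill_n=self.hill_n)
        if self.ic50 <= 0 or self.hill_n <= 0:
            raise ValueError("IC50 and Hill coefficient must be positive")


@dataclasses.dataclass(frozen=True)
class TwoStepParams:
    """Two consecutive irreversible first-order steps; symmetric in (k2, k3)."""

    es: float  # product at completion, uM
    k2: float  # 1/s
    k3: float  # 1/s

    def __post_init__(self) -> None:
        _require_finite(es=self.es, k2=self.k2, k3=self.k3)
        if self.es <= 0 or self.k2 <= 0 or self.k3 <= 0:
            raise ValueError("ES, k2 and k3 must be positive")


@dataclasses.dataclass(frozen=True)
class ViscosityParams:
    m: float  # dimensionless slope

    def __post_init__(self) -> None:
        _require_finite(m=self.m)


@dataclasses.dataclass(frozen=True)
class MMRTParams:
    """Activation thermodynamics with heat capacity, referenced to T0.

    dh_t0 and ds_t0 are the activation enthalpy (J/mol) and entropy
    (J/(mol*K)) at the fixed reference temperature t0 (K, 298 by default,
    never fitted); dcp is the activation heat capacity (J/(mol*K)).
    """

    dh_t0: float
    ds_t0: float
    dcp: float = 0.0
    t0: float = 298.0

    def __post_init__(self) -> None:
        _require_finite(dh_t0=self.dh_t0, ds_t0=self.ds_t0, dcp=self.dcp, t0=self.t0)
        if self.t0 <= 0:
            raise ValueError("reference temperature T0 must be positive")


@dataclasses.dataclass(frozen=True)
class SingleExpParams:
    a: float  # amplitude, uM
    k_sto: float  # 1/s

    def __post_init__(self) -> None:
        _require_finite(a=self.a, k_sto=self.k_sto)
        if self.a <= 0 or self.k_sto <= 0:
            raise ValueError("amplitude and k_STO must be positive")


# ---------------------------------------------------------------------------
# model equations


def melt_fraction(temp_c, ll: float, ul: float, tm: float, c: float):
    """Logistic unfolding signal LL + (UL-LL)/(1+exp((Tm-T)/c)).

    Strictly increasing in T for c > 0; equals (LL+UL)/2 at T = Tm.
    """
    _require_finite(ll=ll, ul=ul, tm=tm, c=c)
    if c == 0:
        raise ValueError("transition slope c must be non-zero")
    temp_c = np.asarray(temp_c, dtype=float)
    arg = np.clip((tm - temp_c) / c, -700.0, 700.0)  # saturate, avoid overflow
    out = ll + (ul - ll) / (1.0 + np.exp(arg))
    return out if out.ndim else float(out)


def mm_rate(s, kcat: float, km: float):
    """Michaelis–Menten normalized rate v/E_T = kcat*S/(Km+S); S in mM."""
    _require_finite(kcat=kcat, km=km)
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("substrate concentration must be non-negative")
    out = kcat * s / (km + s)
    return out if out.ndim else float(out)


def catalytic_efficiency(kcat: float, km_mm: float) -> float:
    """kcat/Km in 1/(M*s) from kcat in 1/s and Km in mM.

    The mM→M conversion is done here so callers never mix unit systems.
    """
    _require_finite(kcat=kcat, km_mm=km_mm)
    if km_mm <= 0:
        raise ValueError("Km must be positive")
    return kcat / (km_mm * 1e-3)


def holoenzyme_conc(g, z, kd_app: float):
    """Holoenzyme concentration from the tight-binding quadratic (uM).

    Smaller root of (G-c)(Z-c) = Kd*c; always <= min(G, Z).  Tiny negative
    discriminants (floating-point noise at the stoichiometric point) are
    clamped to zero; anything worse is a hard numerical error.
    """
    _require_finite(kd_app=kd_app)
    g = np.asarray(g, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(g < 0) or np.any(z < 0) or kd_app < 0:
        raise ValueError("G, Z and Kd_app must be non-negative")
    b = g + z + kd_app
    disc = b * b - 4.0 * g * z
    floor = -1e-12 * np.maximum(b * b, 1.0)
    if np.any(disc < floor):
        raise ArithmeticError("binding quadratic discriminant is negative")
    disc = np.clip(disc, 0.0, None)
    out = (b - np.sqrt(disc)) / 2.0
    return out if out.ndim else float(out)


def titration_rate(z, vmax: float, kd_app: float, g: float):
    """Rate at HisZ concentration Z for fixed HisG_S concentration G.

    Equals Vmax * holoenzyme_conc(G, Z, Kd)/G; bounded by [0, Vmax] and
    non-decreasing in Z.
    """
    _require_finite(vmax=vmax)
    if g <= 0:
        raise ValueError("G must be positive")
    return vmax * holoenzyme_conc(g, z, kd_app) / g


def dose_response(i, ic50: float, hill_n: float):
    """Fractional activity v_i/v_0 = 1/(1 + (I/IC50)^n); monotone decreasing."""
    _require_finite(ic50=ic50, hill_n=hill_n)
    if ic50 <= 0 or hill_n <= 0:
        raise ValueError("IC50 and Hill coefficient must be positive")
    i = np.asarray(i, dtype=float)
    if np.any(i < 0):
        raise ValueError("inhibitor concentration must be non-negative")
    out = 1.0 / (1.0 + (i / ic50) ** hill_n)
    return out if out.ndim else float(out)


# Relative half-gap below which the consecutive-step expression switches to
# its analytic equal-rate limit to avoid catastrophic cancellation.
_EQUAL_RATE_RTOL = 1e-6


def two_step_product(t, es: float, k2: float, k3: float):
    """Product from two consecutive irreversible first-order steps (uM).

    P(t) = ES/(k2-k3) * [k2*(1-exp(-k3*t)) - k3*(1-exp(-k2*t))] for
    k2 != k3, with the analytic limit ES*[1-(1+k*t)*exp(-k*t)] when the
    rates coincide to within a relative tolerance.  Zero value and zero
    slope at t=0 (the lag), monotone, -> ES at long times; symmetric under
    exchange of k2 and k3.
    """
    _require_finite(es=es, k2=k2, k3=k3)
    if es <= 0 or k2 <= 0 or k3 <= 0:
        raise ValueError("ES, k2 and k3 must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if abs(k2 - k3) < _EQUAL_RATE_RTOL * max(k2, k3):
        k = 0.5 * (k2 + k3)
        out = es * (1.0 - (1.0 + k * t) * np.exp(-k * t))
    else:
        out = (es / (k2 - k3)) * (
            k2 * (1.0 - np.exp(-k3 * t)) - k3 * (1.0 - np.exp(-k2 * t))
        )
    return out if out.ndim else float(out)


def viscosity_ratio(eta_rel, m: float):
    """kcat(0)/kcat(eta) = m*(eta_rel - 1) + 1; intercept fixed at unity.

    eta_rel below 1 is extrapolation, not an error.
    """
    _require_finite(m=m)
    eta_rel = np.asarray(eta_rel, dtype=float)
    out = m * (eta_rel - 1.0) + 1.0
    return out if out.ndim else float(out)


def eyring_log_rate(temp_k, dh: float, ds: float, constants: PhysicalConstants = CODATA):
    """Linear Eyring expression ln(k/T); the dCp = 0 special case of MMRT."""
    return mmrt_log_rate(temp_k, dh, ds, 0.0, t0=298.0, constants=constants)


def mmrt_log_rate(
    temp_k,
    dh_t0: float,
    ds_t0: float,
    dcp: float,
    t0: float = 298.0,
    constants: PhysicalConstants = CODATA,
):
    """Macromolecular-rate-theory ln(kcat/T) with activation heat capacity.

    ln(k/T) = ln(kB/h) - [dH_T0 + dCp*(T-T0)]/(R*T)
              + [dS_T0 + dCp*ln(T/T0)]/R

    with temperatures in kelvin.  The dCp terms vanish exactly at T = T0,
    and dCp = 0 recovers the linear Eyring plot.
    """
    _require_finite(dh_t0=dh_t0, ds_t0=ds_t0, dcp=dcp, t0=t0)
    if t0 <= 0:
        raise ValueError("reference temperature T0 must be positive")
    temp_k = np.asarray(temp_k, dtype=float)
    if np.any(temp_k <= 0):
        raise ValueError("temperature must be positive kelvin")
    r = constants.r
    out = (
        math.log(constants.kb_over_h)
        - (dh_t0 + dcp * (temp_k - t0)) / (r * temp_k)
        + (ds_t0 + dcp * np.log(temp_k / t0)) / r
    )
    return out if out.ndim else float(out)


def single_exp_product(t, a: float, k_sto: float):
    """Single-exponential product rise A*(1-exp(-k_STO*t)); no lag."""
    _require_finite(a=a, k_sto=k_sto)
    if a <= 0 or k_sto <= 0:
        raise ValueError("amplitude and k_STO must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = a * (1.0 - np.exp(-k_sto * t))
    return out if out.ndim else float(out)


def as_kelvin(temp, unit: Literal["K", "C"] = "K"):
    """Convert a temperature (array) to kelvin from an explicit unit tag."""
    temp = np.asarray(temp, dtype=float)
    if unit == "K":
        out = temp
    elif unit == "C":
        out = temp + 273.15
    else:
        raise ValueError(f"unknown temperature unit {unit!r}; use 'K' or 'C'")
    return out if out.ndim else float(out)
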
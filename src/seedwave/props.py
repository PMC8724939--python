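"""Thermophysical properties and parametric material models for lentil seed.

All correlations take dry-basis moisture ``M`` (kg water per kg dry matter,
decimal) and absolute temperature ``T`` (K).  Two temperature conventions
coexist in the source correlations and are kept explicit here:

* the loss-factor polynomial and the specific-heat correlation use the
  Celsius temperature ``T' = T - 273.15``;
* both exponentials of the moisture-diffusivity model use kelvin.

The specific-heat correlation is evaluated with Celsius temperature even
though some renderings declare it in kelvin: a kelvin argument yields
Cp near 4000 J/kg/K for moist lentil, far outside the measured range for
pulses, while the Celsius form gives the expected ~1000-2500 J/kg/K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Universal gas constant, J/mol/K.  The diffusivity model takes Ea in
#: kJ/mol, so the Arrhenius exponent is Ea*1e3 / (R_GAS * T).
R_GAS = 8.3143

#: Vacuum permittivity, F/m.
EPS0 = 8.854e-12

#: Default magnetron frequency, Hz.
DEFAULT_FREQUENCY = 2.45e9


@dataclass(frozen=True)
class ThermoState:
    """Local thermodynamic state: absolute temperature and d.b. moisture."""

    T: float
    M: float

    def __post_init__(self):
        if not self.T > 0:
            raise ValueError(f"absolute temperature must be positive, got {self.T}")
        if self.M < 0:
            raise ValueError(f"dry-basis moisture must be non-negative, got {self.M}")

    @property
    def T_celsius(self) -> float:
        return self.T - 273.15


@dataclass(frozen=True)
class LossFactorModel:
    """Polynomial loss-factor model eps''(T', M) with wet-basis ash terms.

    eps'' = g0 + g1*T' + g2*T'^2 + 100*g3*M + 100*g4*M*T'
            + g5*A + g6*A^2 + g7*A*T'

    where T' is Celsius temperature, M dry-basis moisture and
    A = ash_db / (1 + M) the ash content converted to the wet basis.
    ``ash_db`` is the ash content in percent of dry matter; it is not
    printed by the source study, so it is configurable (default 2.6 %,
    typical for red lentil).  Positivity of eps'' is *not* enforced here;
    it is an optimisation constraint of the inverse problem.
    """

    g: tuple[float, ...]
    ash_db: float = 2.6

    def __post_init__(self):
        if len(self.g) != 8:
            raise ValueError("LossFactorModel needs exactly 8 coefficients g0..g7")
        object.__setattr__(self, "g", tuple(float(v) for v in self.g))

    def __call__(self, T, M):
        """Evaluate eps''.  ``T`` in kelvin; broadcasts over arrays."""
        T = np.asarray(T, dtype=float)
        M = np.asarray(M, dtype=float)
        Tc = T - 273.15
        A = self.ash_db / (1.0 + M)
        g0, g1, g2, g3, g4, g5, g6, g7 = self.g
        return (
            g0
            + g1 * Tc
            + g2 * Tc**2
            + 100.0 * g3 * M
            + 100.0 * g4 * M * Tc
            + g5 * A
            + g6 * A**2
            + g7 * A * Tc
        )


@dataclass(frozen=True)
class DiffusivityModel:
    """Arrhenius-with-moisture-coupling effective diffusivity model.

    D(T, M) = D0 * exp(-Ea*1e3 / (R*T)) * exp((a0*T - a1) * M)

    with D0 in m^2/s, Ea in kJ/mol, a0 in 1/K, a1 dimensionless and T in
    kelvin in both exponents.
    """

    D0: float
    Ea: float
    a0: float
    a1: float

    def __post_init__(self):
        if not self.D0 > 0:
            raise ValueError("pre-exponential factor D0 must be positive")
        if not self.Ea > 0:
            raise ValueError("activation energy Ea must be positive")

    def __call__(self, T, M):
        T = np.asarray(T, dtype=float)
        M = np.asarray(M, dtype=float)
        with np.errstate(over="ignore"):
            D = self.D0 * np.exp(-self.Ea * 1e3 / (R_GAS * T)) * np.exp(
                (self.a0 * T - self.a1) * M
            )
        if not np.all(np.isfinite(D)):
            raise FloatingPointError("non-finite diffusivity; check coefficients")
        return D

    def arrhenius(self, T) -> float:
        """Dry-limit Arrhenius diffusivity g(T) = D0 exp(-Ea/(R T))."""
        return self(T, 0.0)


@dataclass(frozen=True)
class MicrowaveSource:
    """Uniform-field microwave source description.

    The cavity field strength is either supplied directly (``E``) or
    derived from the available magnetron power ``Pav`` (W) and the
    reflection coefficient ``S11``.  The field-strength calibration
    comes in two published renderings; both are available:

    * ``sqrt_over`` (default): E = sqrt(2*Pav / (1 - S11^2)) in V/cm,
      converted to V/m;
    * ``sqrt_times``: E = sqrt(2*Pav * (1 - S11^2)), same units.

    Any constant miscalibration of E is absorbed into the fitted
    loss-factor scale, so inverse estimation is invariant to the choice
    up to a rescaling of the g coefficients.
    """

    Pav: float = 616.0
    S11: float = 0.421
    f: float = DEFAULT_FREQUENCY
    eps0: float = EPS0
    e_field_mode: str = "sqrt_over"
    E: float | None = None  # direct specification, V/m

    def __post_init__(self):
        if self.E is None:
            if not self.Pav > 0:
                raise ValueError("available power Pav must be positive")
            if not (0.0 <= self.S11 < 1.0):
                raise ValueError("reflection coefficient must satisfy 0 <= S11 < 1")
        if self.e_field_mode not in ("sqrt_over", "sqrt_times", "direct"):
            raise ValueError(f"unknown e_field_mode {self.e_field_mode!r}")


def density(M) -> np.ndarray | float:
    """Bulk density of lentil, kg/m^3, as a quadratic in d.b. moisture."""
    M = np.asarray(M, dtype=float)
    if np.any(M < 0):
        raise ValueError("dry-basis moisture must be non-negative")
    return (0.193 * M**2 - 0.311 * M + 1.4729) * 1e3


def specific_heat(T, M) -> np.ndarray | float:
    """Specific heat, J/kg/K.  T in kelvin; correlation uses T' (Celsius)
    and the wet-basis moisture fraction w = M/(1+M)."""
    T = np.asarray(T, dtype=float)
    M = np.asarray(M, dtype=float)
    Tc = T - 273.15
    w = M / (1.0 + M)
    return (0.5773 + 0.00709 * Tc + 6.22 * w - 9.14 * w**2) * 1e3


def thermal_conductivity(T, M) -> np.ndarray | float:
    """Effective thermal conductivity, W/m/K."""
    T = np.asarray(T, dtype=float)
    M = np.asarray(M, dtype=float)
    return 0.193 + 1e-4 * (T - 273.15) + 0.152 * M / (1.0 + M)


def latent_heat(T) -> np.ndarray | float:
    """Latent heat of water evaporation, J/kg; linear and decreasing in T."""
    T = np.asarray(T, dtype=float)
    return 2503000.0 - 2386.0 * (T - 273.15)


def loss_factor(state: ThermoState, model: LossFactorModel) -> float:
    """Dielectric loss factor eps'' at a single thermodynamic state."""
    return float(model(state.T, state.M))


def diffusivity(state: ThermoState, model: DiffusivityModel) -> float:
    """Effective moisture diffusivity, m^2/s, at a single state."""
    return float(model(state.T, state.M))


def field_strength(source: MicrowaveSource) -> float:
    """Cavity electric field strength in V/m.

    The power-based calibrations produce V/cm, converted here; a directly
    supplied field (``source.E`` or mode ``direct``) passes through in V/m.
    """
    if source.E is not None or source.e_field_mode == "direct":
        if source.E is None:
            raise ValueError("e_field_mode 'direct' requires an explicit E value")
        return float(source.E)
    if source.e_field_mode == "sqrt_over":
        e_v_per_cm = math.sqrt(2.0 * source.Pav / (1.0 - source.S11**2))
    else:  # sqrt_times
        e_v_per_cm = math.sqrt(2.0 * source.Pav * (1.0 - source.S11**2))
    return e_v_per_cm * 100.0


def volumetric_heating(E, eps_pp, source: MicrowaveSource) -> np.ndarray | float:
    """Dissipated microwave power density q = 2*pi*f*eps0*eps''*E^2, W/m^3."""
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise ValueError("field strength must be non-negative")
    return 2.0 * math.pi * source.f * source.eps0 * np.asarray(eps_pp, dtype=float) * E**2
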
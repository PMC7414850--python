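"""Stateless ionic-biophysics primitives.

Nernst and Goldman-Hodgkin-Katz (GHK) relations for anions, the combined
Cl-/HCO3- reversal potential of the GABA_A receptor (forward and inverse),
KCC2 co-transporter flux kinetics, and the conductance-to-permeability
calibration used by the dynamic simulators.

Unit conventions
----------------
Concentrations are millimolar (numerically equal to mol m-3), voltages are
millivolts, temperatures are degrees Celsius, KCC2 flux is umol m-2 s-1 and
currents are picoamperes.  "Permeability" throughout this package is a
whole-cell permeability (permeability x membrane area, m3 s-1), so that the
GHK expression yields a current rather than a current density.

Sign convention: a positive anion current denotes anion *influx*, i.e. the
direction that raises the intracellular anion concentration.  For Cl- at
physiological potentials above the Cl- Nernst potential this is also an
outward (hyperpolarizing) current in the conventional electrical sense; the
two views coincide because the carrier is an anion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "FARADAY",
    "IonConditions",
    "PermeabilitySet",
    "KCC2Params",
    "CONDITION_PRESETS",
    "get_conditions",
    "thermal_voltage",
    "nernst",
    "ghk_anion_current",
    "gaba_reversal",
    "cl_from_reversal",
    "kcc2_flux",
    "kcc2_half_activation_cl",
    "conductance_to_permeability",
]

GAS_CONSTANT = 8.31446261815324  # J mol-1 K-1
FARADAY = 96485.33212331001  # C mol-1

#: Extracellular Cl- of the recording ACSF: 126 NaCl + 2.5 KCl + 2 MgCl2 + 2 CaCl2.
RECORDING_ACSF_CL_MM = 126.0 + 2.5 + 2 * 2.0 + 2 * 2.0  # = 136.5


def thermal_voltage(temperature_c: float) -> float:
    """RT/F in millivolts at the given temperature (25.693 mV at 25 C)."""
    return GAS_CONSTANT * (temperature_c + 273.15) / FARADAY * 1e3


@dataclass(frozen=True)
class IonConditions:
    """Ionic concentrations (mM) on both sides of the membrane plus temperature.

    Only the species relevant to GABA_A signalling and KCC2 transport are
    carried: Cl-, HCO3- and K+.
    """

    cl_in: float
    cl_out: float
    hco3_in: float
    hco3_out: float
    k_in: float
    k_out: float
    temperature: float = 25.0

    def __post_init__(self) -> None:
        for name in ("cl_in", "cl_out", "hco3_in", "hco3_out", "k_in", "k_out"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")
        if not (0.0 <= self.temperature <= 45.0):
            raise ValueError(f"temperature must lie in [0, 45] C, got {self.temperature!r}")

    def with_cl_in(self, cl_in: float) -> "IonConditions":
        return replace(self, cl_in=cl_in)


#: Named condition presets.
#:
#: ``recording_acsf`` — whole-cell recording conditions used for E_GABA / [Cl-]_i
#: conversions: extracellular Cl- from the ACSF recipe (136.5 mM), HCO3- 26 mM
#: outside / 16 mM inside, room temperature.  ``cl_in`` holds the high-load
#: pipette value (29 mM) as a placeholder; conversions override it.
#:
#: ``point_model`` — the dynamic single-compartment model conditions:
#: extracellular Cl- 120 mM, HCO3- 30 mM outside / 15 mM inside.
CONDITION_PRESETS: dict[str, IonConditions] = {
    "recording_acsf": IonConditions(
        cl_in=29.0, cl_out=RECORDING_ACSF_CL_MM,
        hco3_in=16.0, hco3_out=26.0,
        k_in=140.0, k_out=2.5, temperature=25.0,
    ),
    "point_model": IonConditions(
        cl_in=5.0, cl_out=120.0,
        hco3_in=15.0, hco3_out=30.0,
        k_in=120.0, k_out=3.0, temperature=25.0,
    ),
}


def get_conditions(name: str, **overrides) -> IonConditions:
    """Return a named condition preset, optionally overriding fields."""
    try:
        base = CONDITION_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown condition preset {name!r}; available: {sorted(CONDITION_PRESETS)}"
        ) from None
    return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class PermeabilitySet:
    """Whole-cell Cl- permeability (m3 s-1) and the HCO3-:Cl- permeability ratio."""

    p_cl: float
    hco3_to_cl_ratio: float = 0.25

    def __post_init__(self) -> None:
        if self.p_cl < 0:
            raise ValueError("p_cl must be non-negative")
        if self.hco3_to_cl_ratio < 0:
            raise ValueError("hco3_to_cl_ratio must be non-negative")

    @property
    def p_hco3(self) -> float:
        return self.p_cl * self.hco3_to_cl_ratio


@dataclass(frozen=True)
class KCC2Params:
    """KCC2 transport kinetics: J = vmax * x / (1 + x), x = (Cl_i - K_o) / scale.

    ``null_offset`` (3 mM) is the intracellular Cl- at which extrusion vanishes
    when extracellular K+ sits at its resting value; ``michaelis_scale`` (12 mM)
    sets the concentration scale so that extrusion is half-maximal at
    Cl_i = 15 mM.
    """

    vmax: float
    null_offset: float = 3.0
    michaelis_scale: float = 12.0

    def __post_init__(self) -> None:
        if self.vmax < 0:
            raise ValueError("vmax must be non-negative")
        if self.michaelis_scale <= 0:
            raise ValueError("michaelis_scale must be positive")


def nernst(conc_in: float, conc_out: float, temperature: float, valence: int) -> float:
    """Nernst equilibrium potential in mV.

    For an anion (valence -1) this is (RT/F) ln(in/out); for a cation
    (valence +1), (RT/F) ln(out/in).
    """
    if conc_in <= 0 or conc_out <= 0:
        raise ValueError("concentrations must be positive")
    if valence not in (-1, 1):
        raise ValueError("valence must be -1 or +1")
    vt = thermal_voltage(temperature)
    return -vt / valence * math.log(conc_in / conc_out)


def ghk_anion_current(
    perm: float,
    v_m: float,
    conc_in: float,
    conc_out: float,
    temperature: float = 25.0,
) -> float:
    """GHK current (pA) carried by a monovalent anion.

    Positive = anion influx (raises the intracellular concentration).  The
    removable singularity at v_m = 0 is handled by a second-order series
    expansion for |v_m| below 1e-3 mV so the function is continuous there.

    ``perm`` is the whole-cell permeability in m3 s-1; concentrations in mM.
    """
    if conc_in <= 0 or conc_out <= 0:
        raise ValueError("concentrations must be positive")
    vt = thermal_voltage(temperature)  # mV
    u = v_m / vt  # dimensionless, = Vm F / RT
    if abs(v_m) < 1e-3:
        # u (ci - co e^u)/(1 - e^u) = (co e^u - ci) * u/(e^u - 1); expand
        # u/(e^u - 1) ~ 1 - u/2 + u^2/12 to avoid the 0/0 cancellation.
        series = (conc_out * math.exp(u) - conc_in) * (1.0 - u / 2.0 + u * u / 12.0)
        amps = perm * FARADAY * series
    else:
        eu = math.exp(u)
        amps = perm * FARADAY * u * (conc_in - conc_out * eu) / (1.0 - eu)
    return amps * 1e12  # A -> pA


def gaba_reversal(cond: IonConditions, ratio: float = 0.25) -> float:
    """GABA_A reversal potential (mV) from combined Cl-/HCO3- gradients.

    E = (RT/F) ln[(Cl_i + r HCO3_i) / (Cl_o + r HCO3_o)] with r the
    HCO3-:Cl- permeability ratio.  With r = 0 this reduces exactly to the
    Cl- Nernst potential.
    """
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    num = cond.cl_in + ratio * cond.hco3_in
    den = cond.cl_out + ratio * cond.hco3_out
    if num <= 0 or den <= 0:
        raise ValueError("effective anion concentrations must be positive")
    return thermal_voltage(cond.temperature) * math.log(num / den)


def cl_from_reversal(e_gaba: float, cond: IonConditions, ratio: float = 0.25) -> float:
    """Intracellular Cl- (mM) implied by a measured GABA_A reversal potential.

    Exact algebraic inverse of :func:`gaba_reversal` in its ``cl_in`` argument;
    the ``cl_in`` field of ``cond`` is ignored.
    """
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    vt = thermal_voltage(cond.temperature)
    cl_in = math.exp(e_gaba / vt) * (cond.cl_out + ratio * cond.hco3_out) - ratio * cond.hco3_in
    if cl_in <= 0:
        raise ValueError(
            f"E_GABA = {e_gaba:g} mV implies a non-positive intracellular Cl- "
            f"({cl_in:.3g} mM) under these conditions; the HCO3- contribution "
            "alone would account for a less negative reversal"
        )
    return cl_in


def kcc2_flux(cl_in: float, k_out: float, params: KCC2Params) -> float:
    """KCC2 Cl- extrusion flux (umol m-2 s-1), clamped at zero below the null point.

    J = vmax * x / (1 + x) with x = (Cl_i - K_o) / michaelis_scale.  The fixed
    3 mM null point of the static model is the special case ``k_out = 3``.
    Reverse-mode transport (Cl_i < K_o) is outside the validity of this form
    and returns 0.
    """
    x = (cl_in - k_out) / params.michaelis_scale
    if x <= 0.0:
        return 0.0
    return params.vmax * x / (1.0 + x)


def kcc2_half_activation_cl(params: KCC2Params, k_out: float | None = None) -> float:
    """Intracellular Cl- at which KCC2 flux is half of vmax (numerical solve).

    Solves kcc2_flux(c) = vmax/2 by bisection on the implemented flux rather
    than using the closed form, so the answer is a property of the code path
    used by the simulators.  With the default constants this is 15 mM.
    """
    from scipy.optimize import brentq

    if params.vmax <= 0:
        raise ValueError("vmax must be positive to define a half-activation point")
    ko = params.null_offset if k_out is None else k_out
    target = params.vmax / 2.0
    lo, hi = ko + 1e-12, ko + 1e4 * params.michaelis_scale
    return float(brentq(lambda c: kcc2_flux(c, ko, params) - target, lo, hi, xtol=1e-12))


def conductance_to_permeability(
    g_ns: float,
    cond: IonConditions,
    v_test: float = -60.0,
) -> float:
    """Whole-cell Cl- permeability (m3 s-1) matching an ohmic conductance.

    Returns P such that the GHK Cl- current at ``v_test`` equals the ohmic
    current g * (v_test - E_Cl) under the given conditions.  GHK is linear in
    P, so the calibration is a single division.  The test condition in the
    dynamic model is v_test = -60 mV with Cl_i = 5 mM.
    """
    if g_ns < 0:
        raise ValueError("conductance must be non-negative")
    if g_ns == 0.0:
        return 0.0
    e_cl = nernst(cond.cl_in, cond.cl_out, cond.temperature, valence=-1)
    driving = v_test - e_cl  # mV
    if abs(driving) < 1e-9:
        raise ValueError("zero driving force at v_test; calibration undefined")
    target_pa = g_ns * driving  # nS * mV = pA
    unit = ghk_anion_current(1.0, v_test, cond.cl_in, cond.cl_out, cond.temperature)
    return target_pa / unit
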
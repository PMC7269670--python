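"""Voltage-gated conductance models, centred on the two A-type potassium current
(I_SA) variants of CCK+ hippocampal interneurons.

The subthreshold-activated, inactivating potassium current I_SA comes in two
flavours in CA3 CCK+ interneurons: a right-shifted, fast-inactivating,
fast-recovering variant found in regular-spiking (RS) cells, and a left-shifted,
slowly inactivating, slowly recovering variant (I_SA_TOR) that, mixed with the RS
variant, produces the transient-outward-rectifier (TOR) firing phenotype.

Gating follows the standard Hodgkin-Huxley m*h formalism with first-order gate
exponents: steady states are single Boltzmann functions of voltage, the
activation time constant is fixed (fast relative to every phenomenon measured),
and the inactivation time constant tau_h(V) is a monotone-cubic interpolation
through measured anchor points (recovery time constants on the hyperpolarised
side, the inactivation decay time constant on the depolarised side).

All voltages are mV, times ms, conductance densities S/cm2, currents follow the
outward-positive convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "GatingParams",
    "ChannelModel",
    "IsaPreset",
    "CoreChannel",
    "boltzmann",
    "calibrate_from_anchors",
    "tau_h",
    "make_tau_h",
    "channel_current",
    "apply_hptx",
    "get_isa",
    "isa_densities",
    "ISA_PROFILES",
    "DENSITY_PRESETS",
    "CORE_PRESETS",
    "E_K",
    "E_NA",
    "SOMA_TO_DENDRITE_RATIO",
    "TOR_MIX_RS_TO_TOR",
]

#: Potassium reversal potential: currents are normalised to the driving force
#: "step voltage minus -90 mV" throughout.
E_K = -90.0
E_NA = 60.0

#: Somatic : dendritic I_SA density ratio used in all cell configurations.
SOMA_TO_DENDRITE_RATIO = 2.96

#: RS : TOR component density ratio in the TOR-cell I_SA mixture.
TOR_MIX_RS_TO_TOR = 3.0


def boltzmann(v, v_half: float, k: float, direction: str = "act"):
    """Boltzmann sigmoid 1/(1+exp(±(v−v_half)/k)).

    ``direction='act'`` increases with voltage, ``'inact'`` decreases. ``k`` is
    the (positive) slope factor in mV. Accepts scalars or arrays.
    """
    if not np.all(np.isfinite(v)) or not math.isfinite(v_half) or not math.isfinite(k):
        raise ValueError("boltzmann: non-finite voltage or parameter")
    if k <= 0:
        raise ValueError(f"boltzmann: slope k must be > 0, got {k}")
    if direction == "act":
        x = -(np.asarray(v, dtype=float) - v_half) / k
    elif direction == "inact":
        x = (np.asarray(v, dtype=float) - v_half) / k
    else:
        raise ValueError(f"boltzmann: direction must be 'act' or 'inact', got {direction!r}")
    out = 1.0 / (1.0 + np.exp(x))
    return float(out) if np.isscalar(v) or np.ndim(v) == 0 else out


def calibrate_from_anchors(
    v_half: float,
    anchor: tuple[float, float],
    direction: str = "inact",
    default_k: float = 10.0,
) -> float:
    """Solve the Boltzmann slope k that makes the curve pass through one anchor.

    ``anchor`` is a (voltage mV, fraction) pair with fraction strictly in (0,1).
    At the degenerate midpoint (v == v_half, fraction == 0.5) every slope is
    valid and ``default_k`` is returned.
    """
    v, f = anchor
    if not (0.0 < f < 1.0):
        raise ValueError(f"anchor fraction must lie strictly in (0,1), got {f}")
    if v == v_half:
        if abs(f - 0.5) < 1e-12:
            return default_k
        raise ValueError("no slope can move the curve off 0.5 at v == v_half")
    if abs(f - 0.5) < 1e-12:
        raise ValueError("fraction 0.5 away from v_half has no finite-slope solution")
    logit = math.log(1.0 / f - 1.0)
    if direction == "inact":
        k = (v - v_half) / logit
    elif direction == "act":
        k = -(v - v_half) / logit
    else:
        raise ValueError(f"direction must be 'act' or 'inact', got {direction!r}")
    if k <= 0:
        raise ValueError(
            f"anchor ({v} mV, {f}) lies on the wrong side of v_half={v_half} for a "
            f"{direction} curve"
        )
    return k


def _solve_two_anchor_boltzmann(
    a1: tuple[float, float], a2: tuple[float, float], direction: str = "act"
) -> tuple[float, float]:
    """(v_half, k) of the Boltzmann passing exactly through two anchors."""
    (v1, f1), (v2, f2) = a1, a2
    l1 = math.log(1.0 / f1 - 1.0)
    l2 = math.log(1.0 / f2 - 1.0)
    sgn = -1.0 if direction == "act" else 1.0
    # v - v_half = sgn * k * logit
    k = (v1 - v2) / (sgn * (l1 - l2))
    if k <= 0:
        raise ValueError("anchors are not ordered consistently with the direction")
    v_half = v1 - sgn * k * l1
    return v_half, k


def make_tau_h(anchors: Sequence[tuple[float, float]]):
    """Smooth positive tau_h(V) through every anchor, clamped outside the range.

    Monotone cubic (PCHIP) interpolation guarantees the curve passes through the
    printed anchor values exactly and cannot undershoot zero between anchors of
    one sign. Returns a vectorised callable.
    """
    if len(anchors) < 2:
        raise ValueError("need at least two tau anchors")
    pts = sorted(anchors)
    vs = np.array([p[0] for p in pts], dtype=float)
    ts = np.array([p[1] for p in pts], dtype=float)
    if len(np.unique(vs)) != len(vs):
        raise ValueError("anchor voltages must be distinct")
    if np.any(ts <= 0):
        raise ValueError("all tau anchors must be strictly positive")
    interp = PchipInterpolator(vs, ts, extrapolate=False)

    def tau(v):
        vv = np.clip(np.asarray(v, dtype=float), vs[0], vs[-1])
        out = interp(vv)
        return float(out) if np.ndim(v) == 0 else out

    return tau


def tau_h(v, anchors: Sequence[tuple[float, float]]):
    """Evaluate the anchored inactivation/recovery time constant at ``v`` (mV)."""
    return make_tau_h(anchors)(v)


@dataclass(frozen=True)
class GatingParams:
    """Boltzmann/anchor description of one m*h gated conductance."""

    v_half_act: float
    k_act: float
    exponent_act: int = 1
    tau_act: float = 1.0
    v_half_inact: float | None = None
    k_inact: float | None = None
    tau_inact_anchors: tuple[tuple[float, float], ...] = ()
    has_inactivation: bool = True

    def __post_init__(self):
        if self.k_act <= 0:
            raise ValueError("k_act must be > 0")
        if self.exponent_act < 1:
            raise ValueError("exponent_act must be >= 1")
        if self.tau_act <= 0:
            raise ValueError("tau_act must be > 0")
        if self.has_inactivation:
            if self.v_half_inact is None or self.k_inact is None:
                raise ValueError("inactivating gate requires v_half_inact and k_inact")
            if self.k_inact <= 0:
                raise ValueError("k_inact must be > 0")
            if any(t <= 0 for _, t in self.tau_inact_anchors):
                raise ValueError("tau anchors must be strictly positive")

    def m_inf(self, v):
        # steady state of one gate; the exponent is applied on the gate value
        # inside the current expression, not here
        return boltzmann(v, self.v_half_act, self.k_act, "act")

    def h_inf(self, v):
        if not self.has_inactivation:
            return np.ones_like(np.asarray(v, dtype=float)) if np.ndim(v) else 1.0
        return boltzmann(v, self.v_half_inact, self.k_inact, "inact")

    def tau_h_fn(self):
        return make_tau_h(self.tau_inact_anchors)


@dataclass(frozen=True)
class ChannelModel:
    """One voltage-gated conductance: gating + density + reversal."""

    name: str
    gating: GatingParams
    density: float  # S/cm2
    reversal: float = E_K

    def __post_init__(self):
        if self.density < 0:
            raise ValueError("density must be >= 0")


def channel_current(model: ChannelModel, v, m, h=1.0, area_um2: float | None = None):
    """Ohmic HH current I = density * m^a * h * (v − reversal).

    Returns the current density in mA/cm2 (outward positive); if ``area_um2`` is
    given, returns the absolute current in pA instead.
    """
    m = np.asarray(m, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.any(m < 0) or np.any(m > 1) or np.any(h < 0) or np.any(h > 1):
        raise ValueError("gate values must lie in [0,1]")
    a = model.gating.exponent_act
    # density [S/cm2] * mV = 1e-3 A/cm2 * 1e3 = mA/cm2 scale: S/cm2 * mV -> mA/cm2
    i_density = model.density * (m**a) * h * (np.asarray(v, dtype=float) - model.reversal)
    i_density = i_density  # S/cm2 * mV == mA/cm2
    if area_um2 is None:
        return i_density
    # mA/cm2 * um2: 1 um2 = 1e-8 cm2; mA -> pA factor 1e9
    return i_density * area_um2 * 1e-8 * 1e9


def apply_hptx(model: ChannelModel, shift: float) -> ChannelModel:
    """Heteropodatoxin-1 effect: depolarising shift of the activation V1/2.

    HpTX is a Kv4 gating-modifier toxin; its block is modelled as the measured
    shift of activation voltage dependence, all other parameters untouched.
    """
    if not math.isfinite(shift):
        raise ValueError("shift must be finite")
    if shift == 0:
        return model
    g = replace(model.gating, v_half_act=model.gating.v_half_act + shift)
    return replace(model, gating=g)


# --------------------------------------------------------------------------
# Calibrated parameter profiles
# --------------------------------------------------------------------------
# Inactivation: whole-cell steady-state availability curves.
#   TOR: V1/2 −64.5 mV, slope solved from 91.3% availability at −80 mV.
#   RS:  V1/2 −57.4 mV, slope solved from 52.7% availability at −60 mV (the
#        printed RS points are not consistent with a TOR-like ~6.6 mV slope, so
#        the RS slope is calibrated from its own curve).
TOR_INACT_VHALF_MEASURED = -64.5
TOR_INACT_K = calibrate_from_anchors(TOR_INACT_VHALF_MEASURED, (-80.0, 0.913), "inact")
# Channel-level V1/2, calibrated so the simulated whole-cell inactivation
# protocol (with its series-resistance bias) returns the measured −64.5 mV.
TOR_INACT_VHALF = -67.0
RS_INACT_VHALF_MEASURED = -57.4
# Channel-level value calibrated as for the TOR curve (protocol returns −57.4).
RS_INACT_VHALF = -59.69
# The two printed RS availability points (V1/2 −57.4 mV; 52.7% at −60 mV) sit
# 2.6 mV apart and cannot identify a slope; the RS curve shares the slope of
# the TOR curve (same Kv4.3 pore), which reproduces the printed −60 mV
# availability within its reported uncertainty.
RS_INACT_K = TOR_INACT_K

# Activation, nucleated-patch profile (near-ideal clamp of somatic membrane):
# V1/2 −16.4 / −8.9 mV with slopes solved from the activation measured at
# −40 mV (working points 0.10 and 0.025).
TOR_ACT_NUCLEATED = (-16.4, calibrate_from_anchors(-16.4, (-40.0, 0.10), "act"))
RS_ACT_NUCLEATED = (-8.9, calibrate_from_anchors(-8.9, (-40.0, 0.025), "act"))

# Activation, whole-cell profile: effective threshold-range Boltzmanns
# anchored to the whole-cell currents. The TOR variant is pinned by two
# constraints: (i) its activation at −40 mV is calibrated once so the
# TOR-configured whole-cell simulation reproduces the measured peak I_SA
# (683 pA at −40 mV) on the area-calibrated stand-in; (ii) its conductance
# foot at −52 mV is small (0.02), so the standing subthreshold current near
# rest is negligible. The resulting steepness (~2.4 mV) is an effective-model
# parameter: real Kv4 gating is m^4-like, and the foot of an m^4 conductance
# curve with a ~9-10 mV per-gate slope rises with an effective steepness of
# k/4 ~ 2.5 mV, which a first-order gate can only represent with a steep
# single Boltzmann. The RS working point at −40 mV sits inside the printed
# nucleated range (3.6 ± 1.8 % mean, 1.4 % median) and is calibrated so the
# RS whole-cell simulation reproduces its measured 148 pA at −40 mV.
TOR_ACT_WC_ANCHOR_40 = 0.72  # calibrated, see docs/methods.md
TOR_ACT_WC = _solve_two_anchor_boltzmann((-40.0, TOR_ACT_WC_ANCHOR_40), (-52.0, 0.02), "act")
RS_ACT_WC_ANCHOR_40 = 0.0215  # calibrated, see docs/methods.md
RS_ACT_WC = (-8.9, calibrate_from_anchors(-8.9, (-40.0, RS_ACT_WC_ANCHOR_40), "act"))

# Measured whole-cell inactivation/recovery time constants (ms): recovery at
# −120/−85/−75/−65 mV and the inactivation decay at −25 mV. These are outputs
# of the experimental procedure (series resistance, control-trace subtraction,
# exponential fitting), not channel parameters, and serve as calibration
# targets: the simulated protocols must return them.
TOR_TAU_H_MEASURED = ((-120.0, 4.4), (-85.0, 29.8), (-75.0, 46.2), (-65.0, 58.2), (-25.0, 71.2))
RS_TAU_H_MEASURED = ((-120.0, 3.3), (-85.0, 7.1), (-75.0, 8.0), (-65.0, 11.8), (-25.0, 18.8))

# Channel-level tau_h anchors, calibrated once per variant so that the full
# simulated whole-cell protocol (uncompensated Rs, −50 mV control subtraction,
# area-based exponential fits) reproduces every measured value above to ~2%.
# The −55/−45 mV pair is the closed-state-inactivation notch of the TOR
# variant (Kv4 channels inactivate faster from subthreshold closed states than
# their open-state decay or near-V1/2 recovery suggests); it lies in the
# voltage gap between the recovery and decay measurements.
TOR_TAU_H_ANCHORS = ((-120.0, 2.44), (-85.0, 33.24), (-75.0, 50.61), (-65.0, 58.58),
                     (-55.0, 40.0), (-45.0, 60.0), (-25.0, 61.28))
RS_TAU_H_ANCHORS = ((-120.0, 2.65), (-85.0, 9.40), (-75.0, 9.40), (-65.0, 12.84), (-25.0, 15.36))

# HpTX-sensitive component inactivation (alternative preset): V1/2 −64.0 / −56.8
# mV, decay at −25 mV 49.1 / 11.8 ms.
TOR_TAU_H_HPTX = ((-120.0, 2.44), (-85.0, 33.24), (-75.0, 50.61), (-65.0, 58.58), (-25.0, 49.1))
RS_TAU_H_HPTX = ((-120.0, 2.65), (-85.0, 9.40), (-75.0, 9.40), (-65.0, 12.84), (-25.0, 11.8))


def _gating(act, inact_vh, inact_k, tau_anchors):
    return GatingParams(
        v_half_act=act[0],
        k_act=act[1],
        v_half_inact=inact_vh,
        k_inact=inact_k,
        tau_inact_anchors=tuple(tau_anchors),
    )


#: Named I_SA gating profiles. ``whole_cell`` is the default used by the
#: simulation pipeline; ``nucleated`` matches the nucleated-patch activation
#: measurements; ``hptx`` describes the HpTX-sensitive component.
ISA_PROFILES: dict[tuple[str, str], GatingParams] = {
    ("tor", "whole_cell"): _gating(TOR_ACT_WC, TOR_INACT_VHALF, TOR_INACT_K, TOR_TAU_H_ANCHORS),
    ("rs", "whole_cell"): _gating(RS_ACT_WC, RS_INACT_VHALF, RS_INACT_K, RS_TAU_H_ANCHORS),
    ("tor", "nucleated"): _gating(
        TOR_ACT_NUCLEATED, TOR_INACT_VHALF, TOR_INACT_K, TOR_TAU_H_ANCHORS
    ),
    ("rs", "nucleated"): _gating(RS_ACT_NUCLEATED, RS_INACT_VHALF, RS_INACT_K, RS_TAU_H_ANCHORS),
    ("tor", "hptx"): _gating(TOR_ACT_WC, -64.0, TOR_INACT_K, TOR_TAU_H_HPTX),
    ("rs", "hptx"): _gating(RS_ACT_WC, -56.8, RS_INACT_K, RS_TAU_H_HPTX),
}


def get_isa(variant: str, profile: str = "whole_cell", density: float = 0.0) -> ChannelModel:
    """A calibrated I_SA channel model.

    ``variant`` is ``'rs'`` or ``'tor'``; ``profile`` selects the activation
    calibration (``whole_cell``, ``nucleated`` or ``hptx``).
    """
    key = (variant.lower(), profile)
    if key not in ISA_PROFILES:
        raise KeyError(
            f"unknown I_SA preset {variant!r}/{profile!r}; available: "
            f"{sorted(set(k[0] for k in ISA_PROFILES))} x "
            f"{sorted(set(k[1] for k in ISA_PROFILES))}"
        )
    return ChannelModel(name=f"isa_{variant.lower()}", gating=ISA_PROFILES[key], density=density)


@dataclass(frozen=True)
class IsaPreset:
    """Per-compartment-class I_SA densities (S/cm2) for one firing phenotype."""

    variant: str  # 'RS', 'TOR' (pure TOR-variant channel) or 'TOR_mix'
    soma: dict = field(default_factory=dict)  # channel name -> S/cm2
    dendrite: dict = field(default_factory=dict)


# Somatic densities (S/cm2); dendritic densities follow from the fixed
# 2.96:1 somato-dendritic ratio and are also printed independently.
G_RS_SOMA_RS_CELL = 297e-5
G_RS_DEND_RS_CELL = 99.1e-5
G_TOR_SOMA_TOR_CELL = 44e-5
G_RS_SOMA_TOR_CELL = 128e-5
G_TOR_DEND_TOR_CELL = 14.7e-5
G_RS_DEND_TOR_CELL = 42.7e-5

DENSITY_PRESETS: dict[str, IsaPreset] = {
    "RS": IsaPreset(
        "RS",
        soma={"isa_rs": G_RS_SOMA_RS_CELL},
        dendrite={"isa_rs": G_RS_DEND_RS_CELL},
    ),
    "TOR_mix": IsaPreset(
        "TOR_mix",
        soma={"isa_rs": G_RS_SOMA_TOR_CELL, "isa_tor": G_TOR_SOMA_TOR_CELL},
        dendrite={"isa_rs": G_RS_DEND_TOR_CELL, "isa_tor": G_TOR_DEND_TOR_CELL},
    ),
    # Pure TOR-variant channel at the total TOR-cell density: the configuration
    # whose simulated protocols reproduce the whole-cell TOR kinetics.
    "TOR": IsaPreset(
        "TOR",
        soma={"isa_tor": G_TOR_SOMA_TOR_CELL + G_RS_SOMA_TOR_CELL},
        dendrite={"isa_tor": G_TOR_DEND_TOR_CELL + G_RS_DEND_TOR_CELL},
    ),
}


def isa_densities(phenotype: str) -> IsaPreset:
    """I_SA densities for a phenotype: 'RS' or 'TOR' (the 3:1 RS:TOR mixture)."""
    p = phenotype.upper()
    if p == "TOR":
        return DENSITY_PRESETS["TOR_mix"]
    if p in DENSITY_PRESETS:
        return DENSITY_PRESETS[p]
    raise KeyError(f"unknown phenotype {phenotype!r}; use 'RS' or 'TOR'")


# --------------------------------------------------------------------------
# Core spiking conductances
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class CoreChannel:
    """Parameters of one core (non-I_SA) conductance.

    Kinetic constants live in :mod:`isasim.kinetics`; ``v_shift`` moves all
    Na/KDR voltage dependences rigidly along the voltage axis. The adaptation
    current is a slow, high-threshold K+ conductance responsible for
    spike-frequency accommodation.
    """

    name: str
    density_soma: float  # S/cm2
    density_dend: float = 0.0
    reversal: float = E_K
    v_shift: float = 0.0  # mV, Na/KDR kinetics shift
    v_half: float = 0.0  # mV, adaptation gate
    k: float = 1.0
    tau: float = 1.0  # ms, adaptation gate


# Densities tuned once so the RS-configured cell reproduces the measured AP
# phenotype: threshold ~-37.5 mV at the 50 mV/ms criterion, half-width ~0.5 ms,
# spike-frequency accommodation, rest -64.7 mV (see docs/methods.md).
CORE_PRESETS: dict[str, CoreChannel] = {
    "core_na": CoreChannel("core_na", 0.30, 0.02, reversal=E_NA),
    "core_kdr": CoreChannel("core_kdr", 0.30, 0.05, reversal=E_K),
    "core_adapt": CoreChannel(
        "core_adapt", 1e-3, 0.33e-3, reversal=E_K, v_half=-25.0, k=5.0, tau=100.0
    ),
    # e_leak is solved per cell so that the core-equipped cell rests at
    # -64.7 mV; the density sits in the measured gl range.
    "leak": CoreChannel("leak", 5.4e-5, 5.4e-5, reversal=-65.0),
}
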
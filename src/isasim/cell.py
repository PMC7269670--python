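"""Reduced compartmental CCK+ interneuron models.

A cell is a cylindrical soma plus a small set of unbranched cylindrical
dendrites — a stand-in for reconstructed CCK+IN morphologies whose total
membrane area is calibrated so that whole-cell voltage-clamp simulations
reproduce the measured I_SA amplitudes (683 pA at −40 mV in TOR cells,
148 pA in RS cells). Passive parameters sit in the experimentally fitted
ranges; the two firing phenotypes (RS and TOR) differ ONLY in their I_SA
channel complement: switching phenotype leaves every other conductance of a
given cell bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import channels as ch

__all__ = [
    "PassiveParams",
    "MorphologyStandIn",
    "CellConfig",
    "template_morphology",
    "build_cell",
    "build_protocol_cell",
    "nucleated_patch_cell",
    "total_conductance_ratio",
    "morphology_from_swc",
    "REST_MV",
    "AP_THRESHOLD_MV",
]

#: Measured resting potential the models are anchored to (mV).
REST_MV = -64.7
#: Measured AP threshold at the 50 mV/ms slope criterion (mV).
AP_THRESHOLD_MV = -37.52

MAX_SEGMENT_UM = 20.0


@dataclass(frozen=True)
class PassiveParams:
    """Passive cable parameters (cm uF/cm2, g_leak S/cm2, ra Ohm*cm)."""

    cm: float = 1.015
    g_leak: float = 5.4e-5
    e_leak: float = -65.0  # placeholder; solved at build time for -64.7 mV rest
    ra: float = 120.0

    def __post_init__(self):
        if not (0.82 <= self.cm <= 1.05):
            raise ValueError(f"cm={self.cm} outside the fitted range [0.82, 1.05] uF/cm2")
        if not (5e-5 <= self.g_leak <= 5.8e-5):
            raise ValueError(f"g_leak={self.g_leak} outside the fitted range [5e-5, 5.8e-5]")
        if self.ra <= 0:
            raise ValueError("ra must be positive")


@dataclass(frozen=True)
class MorphologyStandIn:
    """Soma + unbranched dendrites; lengths/diameters in um."""

    soma: tuple[float, float] = (20.0, 20.0)  # (diameter, length)
    dendrites: tuple[tuple[float, float, int], ...] = ()  # (length, diameter, nseg)

    def __post_init__(self):
        d, l = self.soma
        if d <= 0 or l <= 0:
            raise ValueError("soma dimensions must be positive")
        for length, diam, nseg in self.dendrites:
            if length <= 0 or diam <= 0:
                raise ValueError("dendrite dimensions must be positive")
            if nseg < 1:
                raise ValueError("segment count must be >= 1")
            if length / nseg > MAX_SEGMENT_UM + 1e-9:
                raise ValueError(
                    f"spatial discretisation {length / nseg:.1f} um exceeds "
                    f"{MAX_SEGMENT_UM} um per segment"
                )

    @property
    def soma_area_um2(self) -> float:
        d, l = self.soma
        return math.pi * d * l

    @property
    def dendrite_area_um2(self) -> float:
        return sum(math.pi * d * l for l, d, _ in self.dendrites)

    @property
    def total_area_um2(self) -> float:
        return self.soma_area_um2 + self.dendrite_area_um2

    @property
    def n_compartments(self) -> int:
        return 1 + sum(n for _, _, n in self.dendrites)


# Template stand-in: total area calibrated against the whole-cell I_SA
# amplitudes (see docs/methods.md). 4 dendrites keep the cell electrotonically
# compact (L ~ 0.3 lambda), matching the modest space-clamp error implied by
# the whole-cell recordings.
TEMPLATE_DENDRITE_LENGTH_UM = 407.0
TEMPLATE_DENDRITE_DIAM_UM = 5.0
TEMPLATE_N_DENDRITES = 4


def template_morphology(
    length_um: float = TEMPLATE_DENDRITE_LENGTH_UM,
    diam_um: float = TEMPLATE_DENDRITE_DIAM_UM,
    n_dendrites: int = TEMPLATE_N_DENDRITES,
) -> MorphologyStandIn:
    """The area-calibrated reference morphology."""
    nseg = int(math.ceil(length_um / MAX_SEGMENT_UM))
    return MorphologyStandIn(
        soma=(32.0, 32.0),
        dendrites=tuple((length_um, diam_um, nseg) for _ in range(n_dendrites)),
    )


@dataclass(frozen=True)
class CellConfig:
    """Fully assembled model cell.

    ``soma_channels`` / ``dend_channels`` map channel names to densities in
    S/cm2. I_SA gating follows the named calibration profile. ``e_leak_soma`` /
    ``e_leak_dend`` are solved so the core-equipped cell (I_SA excluded, so the
    value is phenotype-independent) rests at −64.7 mV; ``resting_potential`` is
    the computed equilibrium of the complete channel set.
    """

    morphology: MorphologyStandIn
    passive: PassiveParams
    soma_channels: dict
    dend_channels: dict
    phenotype: str
    isa_profile: str = "whole_cell"
    core: dict = field(default_factory=lambda: dict(ch.CORE_PRESETS))
    e_leak_soma: float = -65.0
    e_leak_dend: float = -65.0
    resting_potential: float = REST_MV
    seed: int | None = None

    def channel_density(self, name: str, compartment: str) -> float:
        table = self.soma_channels if compartment == "soma" else self.dend_channels
        return table.get(name, 0.0)

    def with_channels(self, soma=None, dend=None, **kw) -> "CellConfig":
        return replace(
            self,
            soma_channels=dict(self.soma_channels if soma is None else soma),
            dend_channels=dict(self.dend_channels if dend is None else dend),
            **kw,
        )

    def without_active_core(self) -> "CellConfig":
        """In-silico TTX/blocker cocktail: strip Na, KDR and adaptation."""
        drop = {"core_na", "core_kdr", "core_adapt"}
        return self.with_channels(
            soma={k: v for k, v in self.soma_channels.items() if k not in drop},
            dend={k: v for k, v in self.dend_channels.items() if k not in drop},
        )

    def isa_total_conductance_uS(self) -> float:
        """Sum of I_SA density * area over all compartment classes (uS)."""
        m = self.morphology
        tot = 0.0
        for name in ("isa_rs", "isa_tor"):
            tot += self.soma_channels.get(name, 0.0) * m.soma_area_um2
            tot += self.dend_channels.get(name, 0.0) * m.dendrite_area_um2
        return tot * 1e-8 * 1e6  # S/cm2 * um2 -> S, then -> uS


# Cell-to-cell variability: the printed "±" spreads of the per-cell adjusted
# densities, as coefficients of variation.
ISA_DENSITY_CV = {
    ("RS", "isa_rs", "soma"): 47.2 / 297.0,
    ("RS", "isa_rs", "dend"): 15.7 / 99.1,
    ("TOR", "isa_rs", "soma"): 20.3 / 128.0,
    ("TOR", "isa_rs", "dend"): 6.78 / 42.7,
    ("TOR", "isa_tor", "soma"): 7.0 / 44.0,
    ("TOR", "isa_tor", "dend"): 2.33 / 14.7,
}


def _steady_state_rest(cell: CellConfig) -> float:
    """Somatic resting potential from the full nonlinear steady state.

    Solved by damped fixed-point iteration on the cable equation with all gates
    at their local steady states (equivalent to a backward-Euler step with
    dt -> infinity); deferred import avoids a cycle with the engine module.
    """
    from .engine import steady_state_voltage

    return float(steady_state_voltage(cell)[0])


def build_cell(
    phenotype: str,
    morphology: MorphologyStandIn | None = None,
    seed: int | None = None,
    isa_profile: str = "whole_cell",
    passive: PassiveParams | None = None,
) -> CellConfig:
    """Assemble a model cell in RS or TOR configuration.

    With ``seed=None`` the mean (template) parameters are used; an integer seed
    jitters the I_SA densities by their printed cell-to-cell spreads and draws
    the passive parameters within their fitted ranges. For a given
    (morphology, seed) the two phenotypes share bit-identical passive and core
    parameters — only the I_SA entries differ.
    """
    p = phenotype.upper()
    if p not in ("RS", "TOR"):
        raise ValueError(f"phenotype must be 'RS' or 'TOR', got {phenotype!r}")
    morph = morphology if morphology is not None else template_morphology()

    core = dict(ch.CORE_PRESETS)
    if passive is None:
        if seed is None:
            passive = PassiveParams()
        else:
            ss = np.random.SeedSequence([seed, 0x5EED])
            rng = np.random.default_rng(ss)
            passive = PassiveParams(
                cm=float(rng.uniform(0.82, 1.05)),
                g_leak=float(rng.uniform(5e-5, 5.8e-5)),
            )

    preset = ch.isa_densities(p)
    soma_isa = dict(preset.soma)
    dend_isa = dict(preset.dendrite)
    if seed is not None:
        # jitter I_SA densities; stream independent of the passive draw and of
        # phenotype-shared parameters, keyed by phenotype + channel.
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x15A]))
        for table, cls in ((soma_isa, "soma"), (dend_isa, "dend")):
            for name in sorted(table):
                cv = ISA_DENSITY_CV[(p, name, cls)]
                table[name] = float(table[name] * max(0.1, 1.0 + cv * rng.standard_normal()))

    soma_channels = {
        "leak": passive.g_leak,
        "core_na": core["core_na"].density_soma,
        "core_kdr": core["core_kdr"].density_soma,
        "core_adapt": core["core_adapt"].density_soma,
        **soma_isa,
    }
    dend_channels = {
        "leak": passive.g_leak,
        "core_na": core["core_na"].density_dend,
        "core_kdr": core["core_kdr"].density_dend,
        "core_adapt": core["core_adapt"].density_dend,
        **dend_isa,
    }

    cell = CellConfig(
        morphology=morph,
        passive=passive,
        soma_channels=soma_channels,
        dend_channels=dend_channels,
        phenotype=p,
        isa_profile=isa_profile,
        core=core,
        seed=seed,
    )
    e_soma, e_dend = _solve_e_leak(cell)
    cell = replace(cell, e_leak_soma=e_soma, e_leak_dend=e_dend,
                   passive=replace(passive, e_leak=e_soma))
    cell = replace(cell, resting_potential=_steady_state_rest(cell))
    return cell


def _core_current_density(cell: CellConfig, v: float, compartment: str) -> float:
    """Steady outward current density (mA/cm2) of the non-leak, non-I_SA set."""
    from . import kinetics

    out = 0.0
    gna = cell.channel_density("core_na", compartment)
    gkdr = cell.channel_density("core_kdr", compartment)
    gad = cell.channel_density("core_adapt", compartment)
    s = cell.core["core_na"].v_shift
    if gna:
        m = kinetics.na_m_inf(v, s)
        h = kinetics.na_h_inf(v, s)
        out += gna * m**3 * h * (v - ch.E_NA)
    if gkdr:
        n = kinetics.kdr_n_inf(v, s)
        out += gkdr * n**4 * (v - ch.E_K)
    if gad:
        z = cell.core["core_adapt"]
        zs = ch.boltzmann(v, z.v_half, z.k, "act")
        out += gad * zs * (v - ch.E_K)
    return out


def _solve_e_leak(cell: CellConfig) -> tuple[float, float]:
    """Leak reversal per compartment class so the core set rests at −64.7 mV.

    I_SA is excluded on purpose: the value must be identical between the RS and
    TOR configuration of a cell (phenotype switch is I_SA-pure), so the actual
    equilibrium sits within ~2 mV of −64.7 mV depending on the small I_SA
    window current.
    """
    v = REST_MV
    gl = cell.passive.g_leak
    e_soma = v + _core_current_density(cell, v, "soma") / gl
    e_dend = v + _core_current_density(cell, v, "dend") / gl
    return float(e_soma), float(e_dend)


def total_conductance_ratio(tor: CellConfig, rs: CellConfig) -> float:
    """(sum I_SA density*area)_TOR / (sum I_SA density*area)_RS.

    Both configs must share the same morphology (paired-cell comparison).
    """
    if tor.morphology != rs.morphology:
        raise ValueError("configs must be built from the same morphology")
    denom = rs.isa_total_conductance_uS()
    if denom == 0:
        raise ValueError("RS configuration has zero I_SA conductance")
    return tor.isa_total_conductance_uS() / denom


def build_protocol_cell(
    variant: str,
    morphology: MorphologyStandIn | None = None,
    isa_profile: str = "whole_cell",
) -> CellConfig:
    """Voltage-clamp stand-in: passive cable + a single calibrated I_SA variant.

    ``variant='tor'`` places the TOR-variant channel at its component density
    (soma 44e-5 S/cm2, the slowly inactivating fraction of the TOR-cell
    mixture), ``'rs'`` the RS channel at the full RS-cell density
    (297e-5 S/cm2) — the configurations whose simulated protocols round-trip
    the printed whole-cell kinetics at realistic current magnitudes. Core
    spiking channels are absent, mirroring the TTX/blocker cocktail of the
    recordings.
    """
    key = "TOR" if variant.lower() == "tor" else "RS"
    if key == "TOR":
        preset = ch.IsaPreset(
            "TOR",
            soma={"isa_tor": ch.G_TOR_SOMA_TOR_CELL},
            dendrite={"isa_tor": ch.G_TOR_DEND_TOR_CELL},
        )
    else:
        preset = ch.DENSITY_PRESETS[key]
    morph = morphology if morphology is not None else template_morphology()
    passive = PassiveParams()
    cell = CellConfig(
        morphology=morph,
        passive=passive,
        soma_channels={"leak": passive.g_leak, **preset.soma},
        dend_channels={"leak": passive.g_leak, **preset.dendrite},
        phenotype=key,
        isa_profile=isa_profile,
    )
    e_soma, e_dend = _solve_e_leak(cell)
    return replace(cell, e_leak_soma=e_soma, e_leak_dend=e_dend)


def nucleated_patch_cell(variant: str) -> CellConfig:
    """Single small isopotential compartment with the nucleated-patch preset.

    Densities convert the measured conductance density (1.91 / 3.86 nS/pF for
    TOR / RS) through the specific capacitance (1.015 uF/cm2).
    """
    ns_per_pf = 1.91 if variant.lower() == "tor" else 3.86
    density = ns_per_pf * 1e-9 / 1e-12 * 1.015e-6  # S/cm2
    morph = MorphologyStandIn(soma=(5.0, 5.0), dendrites=())
    passive = PassiveParams()
    name = "isa_tor" if variant.lower() == "tor" else "isa_rs"
    cell = CellConfig(
        morphology=morph,
        passive=passive,
        soma_channels={"leak": passive.g_leak, name: density},
        dend_channels={"leak": passive.g_leak},
        phenotype=variant.upper(),
        isa_profile="nucleated",
    )
    e_soma, e_dend = _solve_e_leak(cell)
    return replace(cell, e_leak_soma=e_soma, e_leak_dend=e_dend)


def morphology_from_swc(path) -> MorphologyStandIn:
    """Map a standard SWC reconstruction onto the reduced stand-in.

    The soma (type 1) becomes an equivalent cylinder with the same surface
    area; every dendritic root branch (type 3 or 4) becomes one unbranched
    cable carrying the summed path length and the mean diameter of its
    subtree. Axonal samples (type 2) are ignored (axons are out of scope).
    """
    import pathlib

    rows = []
    for line in pathlib.Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        n, t, x, y, z, r, parent = line.split()[:7]
        rows.append((int(n), int(t), float(x), float(y), float(z), float(r), int(parent)))
    if not rows:
        raise ValueError(f"no SWC samples in {path}")
    by_id = {r[0]: r for r in rows}
    soma = [r for r in rows if r[1] == 1]
    if not soma:
        raise ValueError("SWC file has no soma (type 1) samples")
    soma_r = float(np.mean([r[5] for r in soma]))
    # equivalent cylinder with diameter = length = sphere-equivalent size
    soma_area = 4.0 * math.pi * soma_r**2
    soma_d = math.sqrt(soma_area / math.pi)

    # assign each dendritic sample to the root branch it descends from
    def root_of(sample):
        seen = set()
        while sample[6] in by_id and by_id[sample[6]][1] != 1:
            if sample[0] in seen:
                break
            seen.add(sample[0])
            sample = by_id[sample[6]]
        return sample[0]

    branches: dict[int, list] = {}
    for r in rows:
        if r[1] not in (3, 4):
            continue
        branches.setdefault(root_of(r), []).append(r)
    dends = []
    for samples in branches.values():
        length = 0.0
        diams = []
        for s in samples:
            p = by_id.get(s[6])
            if p is None or p[1] == 1:
                continue
            length += math.dist(s[2:5], p[2:5])
            diams.append(2.0 * s[5])
        if length <= 0 or not diams:
            continue
        diam = float(np.mean(diams))
        nseg = int(math.ceil(length / MAX_SEGMENT_UM))
        dends.append((length, diam, nseg))
    return MorphologyStandIn(soma=(soma_d, soma_d), dendrites=tuple(dends))
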
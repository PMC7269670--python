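"""Synthetic fixtures: morphology stand-ins, noisy protocol traces, event files.

The recordings and reconstructions behind the CCK+IN dataset are not available
as data, so every pipeline stage is exercised on synthetic stand-ins whose
ground truth is known and serialized alongside: jittered reduced morphologies
(for the population of model cells), and noisy voltage-clamp current fixtures
(for testing that the fitting pipeline recovers gating parameters).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import channels as ch
from .cell import (
    MorphologyStandIn,
    TEMPLATE_DENDRITE_DIAM_UM,
    TEMPLATE_DENDRITE_LENGTH_UM,
    TEMPLATE_N_DENDRITES,
    MAX_SEGMENT_UM,
    build_protocol_cell,
)

__all__ = [
    "FixtureSpec",
    "make_morphologies",
    "make_noisy_current_fixture",
]


@dataclass(frozen=True)
class FixtureSpec:
    """What a fixture emulates, its noise model, and its ground truth."""

    kind: str  # morphology | vclamp_trace | iclamp_trace | event_train
    noise_sd: float = 0.0
    ground_truth: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {"kind": self.kind, "noise_sd": self.noise_sd,
             "ground_truth": self.ground_truth, "seed": self.seed},
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "FixtureSpec":
        d = json.loads(text)
        return cls(kind=d["kind"], noise_sd=d["noise_sd"],
                   ground_truth=d["ground_truth"], seed=d["seed"])


def make_morphologies(n: int, seed: int, jitter: float = 0.2) -> list[MorphologyStandIn]:
    """``n`` reduced stand-ins jittered within ±``jitter`` of the template.

    Dimensions are drawn uniformly within the band, per seed; total membrane
    areas therefore stay within the band calibrated against the whole-cell
    current amplitudes. Deterministic for a given (n, seed).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    from .cell import template_morphology

    soma_d0, soma_l0 = template_morphology().soma
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x30F0]))
    out = []
    for _ in range(n):
        soma_d = soma_d0 * rng.uniform(1 - jitter, 1 + jitter)
        soma_l = soma_l0 * rng.uniform(1 - jitter, 1 + jitter)
        dends = []
        for _ in range(TEMPLATE_N_DENDRITES):
            L = TEMPLATE_DENDRITE_LENGTH_UM * rng.uniform(1 - jitter, 1 + jitter)
            d = TEMPLATE_DENDRITE_DIAM_UM * rng.uniform(1 - jitter, 1 + jitter)
            dends.append((L, d, int(np.ceil(L / MAX_SEGMENT_UM))))
        out.append(MorphologyStandIn(soma=(soma_d, soma_l), dendrites=tuple(dends)))
    return out


def make_noisy_current_fixture(
    variant: str,
    protocol: str,
    noise_sd_pA: float,
    seed: int,
    recovery_v: float = -85.0,
) -> tuple[dict, FixtureSpec]:
    """Simulate a clamp protocol and add Gaussian current noise.

    ``protocol`` is ``'inactivation'`` or ``'recovery'``. Returns the protocol
    result dictionary (with the noisy observable re-fitted downstream by the
    caller) and a FixtureSpec carrying the ground-truth gating parameters. The
    noise is additive on the measured quantity (peak currents in pA for the
    inactivation protocol; test-pulse areas, scaled equivalently, for the
    recovery protocol).
    """
    from . import protocols as proto_mod

    if noise_sd_pA < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF1C5]))
    cell = build_protocol_cell(variant)
    gp = ch.ISA_PROFILES[(variant.lower(), "whole_cell")]
    truth = {
        "v_half_inact": gp.v_half_inact,
        "k_inact": gp.k_inact,
        "tau_anchors": list(map(list, gp.tau_inact_anchors)),
    }
    if protocol == "inactivation":
        res = proto_mod.run_inactivation_protocol(cell)
        peaks = res["availability"]
        # noise on the underlying peak currents; express relative to the max
        # current amplitude so noise_sd is in pA for a ~1 nA maximal current
        imax_pA = 1000.0
        noisy = peaks + rng.normal(0.0, noise_sd_pA / imax_pA, size=len(peaks))
        from .analysis import fit_boltzmann

        fit = fit_boltzmann(res["prepulse_mV"], noisy, direction="inact")
        out = {**res, "availability_noisy": noisy, "fit_noisy": fit}
    elif protocol == "recovery":
        res = proto_mod.run_recovery_protocol(cell, recovery_v)
        areas = res["areas_pC"]
        scale = np.max(np.abs(areas))
        noisy = areas + rng.normal(0.0, noise_sd_pA / 1000.0 * scale, size=len(areas))
        from .analysis import fit_exponential

        fit = fit_exponential(res["intervals_ms"], noisy, 1)
        out = {**res, "areas_noisy": noisy, "fit_noisy": fit}
    else:
        raise ValueError("protocol must be 'inactivation' or 'recovery'")
    spec = FixtureSpec(kind="vclamp_trace", noise_sd=noise_sd_pA,
                       ground_truth=truth, seed=seed)
    return out, spec
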
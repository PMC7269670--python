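"""Gating parameters of the core spiking conductances.

The core set (transient Na+, delayed-rectifier K+, slow adaptation K+) uses the
same Boltzmann steady-state formalism as the I_SA models. The Na+ activation is
steep and right-placed so that the subthreshold Na+ window current stays small
below the measured AP threshold (−37.5 mV) — the regime in which a few hundred
pA of available I_SA can hold off spiking — while the takeoff remains sharp
enough that the 50 mV/ms slope criterion lands at the measured threshold.
Na+ activation is instantaneous (m = m_inf(V)); the h and n gates relax with
fixed time constants appropriate for the fast, narrow (~0.5 ms half-width)
interneuron action potential at 34.5–36 C.

Parameters were tuned once against the printed RS firing phenotype (threshold,
AP half-width, 10–20 Hz standardized-step firing, accommodation) and are not
per-cell adjustable; densities live in :data:`isasim.channels.CORE_PRESETS`.
"""

from __future__ import annotations

import numpy as np

# transient Na+
NA_M_VHALF = -31.0  # mV
NA_M_K = 5.0  # mV
NA_M_EXP = 3
NA_H_VHALF = -45.0  # mV
NA_H_K = 5.0  # mV
NA_H_TAU = 4.0  # ms

# delayed rectifier K+
KDR_N_VHALF = -20.0  # mV
KDR_N_K = 8.0  # mV
KDR_N_EXP = 4
KDR_N_TAU = 0.4  # ms


def _act(v, vhalf, k):
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - vhalf) / k))


def _inact(v, vhalf, k):
    return 1.0 / (1.0 + np.exp((np.asarray(v, dtype=float) - vhalf) / k))


def na_m_inf(v, s=0.0):
    return _act(v, NA_M_VHALF + s, NA_M_K)


def na_h_inf(v, s=0.0):
    return _inact(v, NA_H_VHALF + s, NA_H_K)


def kdr_n_inf(v, s=0.0):
    return _act(v, KDR_N_VHALF + s, KDR_N_K)
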
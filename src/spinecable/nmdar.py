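"""Voltage-dependent NMDA-receptor conductance and normalized current.

The magnesium block of the NMDA receptor makes its conductance rise
sigmoidally with membrane voltage:

    g(V) = 1 / (1 + a * exp(b V)),   V in mV, b < 0,

with a = 0.073 and b = -0.074 / mV.  The normalized receptor current is the
Ohmic approximation I = g(V) (V - V_reversal), with V_reversal = 0 mV.  The
receptor model is evaluated offline on recorded head-potential traces — it
does not feed back into the solver (calcium's contribution to the membrane
potential is negligible next to Na/K/Cl).

The receptor analysis uses a resting potential of -85 mV.  Because the
background charge is calibrated per segment to make the rest profile uniform,
changing the resting potential rigidly shifts every potential trace without
altering the dynamics of the deviations, so traces simulated at another rest
can be rebased exactly (see :func:`head_voltage_trace`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .solver import Trajectory

__all__ = [
    "NMDARParams",
    "conductance",
    "current",
    "head_voltage_trace",
    "peak_current_in_phase",
    "peak_boost_ratio",
]


@dataclass(frozen=True)
class NMDARParams:
    """Gating and reversal parameters (voltages in mV)."""

    a_gate: float = 0.073
    b_gate: float = -0.074   # 1/mV
    phi_reversal: float = 0.0
    phi_rest: float = -85.0

    def __post_init__(self) -> None:
        if self.a_gate <= 0:
            raise ValueError("a_gate must be > 0")


def conductance(v_mV, params: NMDARParams = NMDARParams()):
    """Normalized channel conductance g(V) in (0, 1), V in mV.

    Strictly increasing for b < 0 with asymptotes 0 (hyperpolarized) and 1
    (depolarized).
    """
    v = np.asarray(v_mV, dtype=float)
    g = 1.0 / (1.0 + params.a_gate * np.exp(params.b_gate * v))
    return float(g) if np.isscalar(v_mV) else g


def current(phi_head_mV, params: NMDARParams = NMDARParams()):
    """Normalized receptor current I = g(V) (V - V_reversal), V in mV.

    Negative (inward) for subthreshold head potentials; |I| grows as the
    head depolarizes through the physiological range toward -60 mV.
    """
    v = np.asarray(phi_head_mV, dtype=float)
    out = conductance(v, params) * (v - params.phi_reversal)
    return float(out) if np.isscalar(phi_head_mV) else out


def head_voltage_trace(traj: Trajectory, params: NMDARParams = NMDARParams()) -> np.ndarray:
    """Head-potential trace (mV) rebased to the receptor resting potential.

    The returned trace equals the head potential the same protocol would
    produce in a run initialized at ``params.phi_rest`` — exactly, because
    the per-segment background-charge calibration makes the potential
    deviations independent of the resting level.
    """
    return (traj.head_phi() - traj.phi_rest) * 1e3 + params.phi_rest


def peak_current_in_phase(
    traj: Trajectory,
    phase_index: int,
    params: NMDARParams = NMDARParams(),
    settle: float = 10e-6,
) -> float:
    """Peak |I_NMDA| (normalized) during one protocol phase.

    The first ``settle`` seconds are excluded so the capacitive discharge at
    a phase switch does not masquerade as receptor-current amplification
    (ignored for phases shorter than twice the settling time).
    """
    t0, t1 = traj.phase_bounds(phase_index)
    if t1 - t0 < 2 * settle:
        settle = 0.0
    m = (traj.times >= t0 + settle - 1e-12) & (traj.times <= t1 + 1e-12)
    i = current(head_voltage_trace(traj, params)[m], params)
    return float(np.max(np.abs(i)))


def peak_boost_ratio(
    traj_boosted: Trajectory,
    traj_control: Trajectory,
    params: NMDARParams = NMDARParams(),
    phase_boosted: int = -1,
    phase_control: int = -1,
) -> float:
    """Amplification of the peak NMDAR current by the depolarization boost.

    Ratio of the peak normalized |I_NMDA| during the dendritic-depolarization
    phase between a run preceded by synaptic input (boosted) and one without
    (control).  Identical trajectories give 1; >= 1 whenever the boosted head
    potential dominates pointwise during the phase.
    """
    def resolve(traj: Trajectory, idx: int) -> int:
        return idx % len(traj.protocol.phases)

    pb = peak_current_in_phase(traj_boosted, resolve(traj_boosted, phase_boosted), params)
    pc = peak_current_in_phase(traj_control, resolve(traj_control, phase_control), params)
    return pb / pc
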
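"""Current decomposition, resistance metrics, boost quantification, decay fits.

The axial electric current through each interface splits into a drift part
(driven by the potential gradient) and a diffusion part (driven by the
concentration gradients):

    I_drift,k = -(pi a^2 / r_e,k)|_if * dPhi/dx
    I_diff,k  = -(pi a^2 D_k e z_k)|_if * dn_k/dx

evaluated with the same series interface conductivities as the solver, so the
decomposition is exactly consistent with the fluxes actually stepped.  During
steady injection the total (drift + diffusion) current is spatially uniform
and equals the injected current; the *drift* current alone, multiplied by the
concentration-dependent resistivity profile, predicts the spine-head voltage
even when Ohm's law in terms of the injected current fails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .physics import (
    DEFAULT_CONSTANTS,
    IonSpecies,
    PhysicalConstants,
    SpineGeometry,
)
from .solver import (
    Trajectory,
    apply_dendritic_boundary,
    apply_synaptic_boundary,
    interface_conductivity,
)

__all__ = [
    "CurrentBreakdown",
    "ResistanceReport",
    "BoostMetrics",
    "current_decomposition",
    "cumulative_resistance",
    "voltage_divider_neck_resistance",
    "predicted_head_voltage",
    "boost_metrics",
    "pairing_boost",
    "fit_decay_time",
]


@dataclass
class CurrentBreakdown:
    """Per-interface, per-species drift and diffusion currents (A).

    Interface ``j`` sits on the left face of segment ``j``: j = 0 is the
    synaptic boundary, j = N the dendritic boundary, so there are N + 1
    interfaces for N segments.  Positive currents flow toward the dendritic
    end.
    """

    drift: np.ndarray      # (K, N+1)
    diffusion: np.ndarray  # (K, N+1)
    species: tuple[IonSpecies, ...]
    t: float

    @property
    def total_drift(self) -> np.ndarray:
        return self.drift.sum(axis=0)

    @property
    def total_diffusion(self) -> np.ndarray:
        return self.diffusion.sum(axis=0)

    @property
    def total(self) -> np.ndarray:
        return self.total_drift + self.total_diffusion

    def segment_drift(self) -> np.ndarray:
        """Total drift current attributed to each segment (mean of its faces)."""
        td = self.total_drift
        return 0.5 * (td[:-1] + td[1:])


@dataclass
class ResistanceReport:
    """Drift-current resistance along the spine (Ohm).

    ``cumulative[i]`` is the resistance from the synaptic end through segment
    ``i``; ``total`` is the sum over the requested range.
    """

    cumulative: np.ndarray
    total: float
    segment_range: slice


@dataclass
class BoostMetrics:
    """Early (Ohmic) vs late (diffusion-boosted) head depolarization.

    ``v_ohm``/``v_diff`` are head depolarizations relative to rest (V) at the
    plateau time and phase end; ``B`` is the relative increase of the
    apparent neck resistance, using the dendritic potential at the matching
    times as the reference.
    """

    v_ohm: float
    v_diff: float
    B: float
    t_ohm: float
    t_end: float


def _ghosted(traj: Trajectory, sample: int):
    """Reconstruct ghost-augmented concentration and potential arrays."""
    t = float(traj.times[sample])
    phase = traj.phase_at(min(t, traj.times[-1]))
    geom, species, const = traj.geom, traj.species, traj.const
    K, N = traj.conc.shape[1], traj.conc.shape[2]
    n = np.empty((K, N + 2))
    n[:, 1:-1] = traj.conc[sample]
    n[:, 0] = apply_synaptic_boundary(traj.conc[sample], geom, species, phase.i_in, const=const)
    n[:, -1], phi_right = apply_dendritic_boundary(species, traj.phi_rest, phase.clamp_offset)
    phi = np.empty(N + 2)
    phi[1:-1] = traj.phi[sample]
    phi[0] = phi[1]
    phi[-1] = phi_right
    a = np.empty(N + 2)
    a[1:-1] = geom.a
    a[0], a[-1] = geom.a[0], geom.a[-1]
    return n, phi, a


def current_decomposition(traj: Trajectory, t: float) -> CurrentBreakdown:
    """Split the axial current at time ``t`` into drift and diffusion parts.

    Boundary interfaces use the ghost-segment values, so the injected current
    appears in the decomposition at the synaptic interface.
    """
    sample = traj.sample_at(t)
    n, phi, a = _ghosted(traj, sample)
    const, geom = traj.const, traj.geom
    h = geom.h
    K = n.shape[0]
    n_if = n.shape[1] - 1

    drift = np.zeros((K, n_if))
    diffusion = np.zeros((K, n_if))
    for k, sp in enumerate(traj.species):
        sig_d = a**2 * sp.D
        sd_if = interface_conductivity(sig_d[:-1], sig_d[1:])
        diffusion[k] = -np.pi * const.e * sp.z * sd_if * np.diff(n[k]) / h
        if sp.z != 0:
            sig_e = a**2 * sp.D * const.e**2 * sp.z**2 * n[k] / const.kT
            se_if = interface_conductivity(sig_e[:-1], sig_e[1:])
            drift[k] = -np.pi * se_if * np.diff(phi) / h
    return CurrentBreakdown(drift=drift, diffusion=diffusion, species=traj.species,
                            t=float(traj.times[sample]))


def cumulative_resistance(
    n: np.ndarray,
    geom: SpineGeometry,
    const: PhysicalConstants = DEFAULT_CONSTANTS,
    species: tuple[IonSpecies, ...] | None = None,
    segment_range: slice | None = None,
) -> ResistanceReport:
    """Total drift-current resistance R_e = sum_i r_e(x_i) h / A(x_i).

    Parameters
    ----------
    n : array (K, N)
        Concentrations (1/m^3) at the evaluation time.
    segment_range : slice, optional
        Restrict the sum (e.g. ``geom.neck`` for the neck-only resistance);
        default is the full cable.
    """
    from .physics import drift_resistivity

    if species is None:
        raise ValueError("species tuple required")
    r_e = np.atleast_1d(drift_resistivity(n, species, const))
    terms = r_e * geom.h / geom.area
    rng = segment_range if segment_range is not None else slice(0, geom.n_segments)
    sel = terms[rng]
    return ResistanceReport(
        cumulative=np.cumsum(sel), total=float(np.sum(sel)), segment_range=rng
    )


def voltage_divider_neck_resistance(v_sp: float, v_den: float, i_syn: float) -> float:
    """Experimentally inferred neck resistance R_n = (V_sp - V_den) / I_syn.

    ``v_sp`` is the potential in the first head segment, ``v_den`` in the
    last dendritic segment (both in V), ``i_syn`` the synaptic current (A).
    """
    if i_syn == 0:
        raise ValueError("i_syn must be nonzero")
    return (v_sp - v_den) / i_syn


def predicted_head_voltage(traj: Trajectory, t: float) -> float:
    """Head depolarization predicted from the drift currents (V).

    Phi_est = sum_i I_e(x_i) r_e(x_i) h / A(x_i): the drift current through
    each segment times the segment's instantaneous drift resistance.  Unlike
    I_in * R_e, this remains accurate when diffusion currents flow.
    """
    from .physics import drift_resistivity

    sample = traj.sample_at(t)
    bd = current_decomposition(traj, t)
    r_e = np.atleast_1d(drift_resistivity(traj.conc[sample], traj.species, traj.const))
    return float(np.sum(bd.segment_drift() * r_e * traj.geom.h / traj.geom.area))


def boost_metrics(
    traj: Trajectory,
    phase_index: int = 0,
    t_ohm_offset: float = 10e-6,
) -> BoostMetrics:
    """Quantify the diffusion-current boost of the head depolarization.

    ``v_ohm`` samples the head potential ``t_ohm_offset`` (default 10 us)
    after phase onset — after the membrane capacitor has charged but before
    concentrations move; ``v_diff`` samples it at the end of the phase.  B is
    the ratio of head-to-dendrite potential differences at those two times,
    i.e. the relative increase of the apparent (voltage-divider) neck
    resistance under constant injected current.
    """
    t0, t1 = traj.phase_bounds(phase_index)
    t_ohm = t0 + t_ohm_offset
    if t_ohm > traj.times[-1] or t1 > traj.times[-1] + 1e-12:
        raise ValueError("requested sample times outside the trajectory")
    s_ohm, s_end = traj.sample_at(t_ohm), traj.sample_at(t1)
    v_ohm = traj.phi[s_ohm, 0] - traj.phi_rest
    v_diff = traj.phi[s_end, 0] - traj.phi_rest
    den_ohm = traj.phi[s_ohm, -1]
    den_end = traj.phi[s_end, -1]
    B = (traj.phi[s_end, 0] - den_end) / (traj.phi[s_ohm, 0] - den_ohm)
    return BoostMetrics(
        v_ohm=float(v_ohm), v_diff=float(v_diff), B=float(B),
        t_ohm=t_ohm, t_end=t1,
    )


def pairing_boost(
    traj: Trajectory,
    clamp_phase: int = 1,
    settle: float = 10e-6,
) -> float:
    """Depolarization boost (V) during a dendritic-depolarization phase.

    Peak head depolarization during the clamp phase minus the clamp offset,
    excluding the first ``settle`` seconds of the phase: at the phase switch
    the membrane capacitor discharges from the injection level within a few
    microseconds, and that transient is not part of the diffusion-driven
    boost.  Returns 0 for an unperturbed spine (clamp propagates without
    attenuation).
    """
    phase = traj.protocol.phases[clamp_phase]
    if phase.clamp_offset is None:
        raise ValueError("selected phase has no dendritic clamp")
    t0, t1 = traj.phase_bounds(clamp_phase)
    m = (traj.times >= t0 + settle) & (traj.times <= t1 + 1e-12)
    peak = float(np.max(traj.phi[m, 0]))
    return peak - (traj.phi_rest + phase.clamp_offset)


def fit_decay_time(
    traj: Trajectory,
    species_name: str,
    segment: int = 0,
    t_start: float | None = None,
    delta: float = 0.1e-3,
    window: float | None = None,
) -> float:
    """Exponential decay time (s) of a concentration relaxation.

    Log-linear least squares on ``n - n_rest`` over
    ``[t_start + delta, t_start + delta + window]`` (window defaults to the
    full remaining trace).  ``t_start`` defaults to the end of the last phase
    with nonzero injection.  Non-positive excursions in the window are
    refused (nothing to fit).
    """
    k = traj.species_index(species_name)
    if t_start is None:
        starts = traj.protocol.phase_starts
        inj = [i for i, p in enumerate(traj.protocol.phases) if p.i_in != 0]
        if not inj:
            raise ValueError("no injection phase; give t_start explicitly")
        t_start = starts[inj[-1]] + traj.protocol.phases[inj[-1]].duration
    lo = t_start + delta
    hi = traj.times[-1] if window is None else lo + window
    m = (traj.times >= lo) & (traj.times <= hi)
    if m.sum() < 3:
        raise ValueError("too few samples in the fit window")
    y = traj.conc[m, k, segment] - traj.species[k].n_rest
    if np.any(y <= 0):
        raise ValueError("non-positive excursion in fit window; fit refused")
    slope = np.polyfit(traj.times[m], np.log(y), 1)[0]
    if slope >= 0:
        raise ValueError("signal not decaying in fit window")
    return float(-1.0 / slope)
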
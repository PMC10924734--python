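# Methods

## Model

`spinecable` models a dendritic spine as a 1-D chain of cylindrical
segments (head, neck, dendrite) filled with a three-species electrolyte
(Na⁺, K⁺, Cl⁻).  Classical cable theory treats the axial current as purely
Ohmic; in a spine the injected charge measurably changes the intracellular
concentrations, and the resulting concentration gradients carry electric
*diffusion* currents through the neck.  The model therefore evolves the
number density nₖ of each mobile species by the Nernst–Planck continuity
equation on the cable,

    ∂nₖ/∂t = 1/(a² zₖ e) ∂ₓ( a²/r_{e,k} ∂ₓΦ ) + 1/a² ∂ₓ( a² Dₖ ∂ₓnₖ ),
    r_{e,k} = k_B T / (Dₖ e² zₖ² nₖ),

and *derives* the membrane potential from the net ionic charge through the
membrane capacitance,

    Φᵢ = aᵢ/(2 c_m) · Σₖ zₖ e nₖ,ᵢ   (background charge included with z = −1).

Substituting this relation for Φ closes the system in the K concentration
fields alone — no Poisson equation is solved.  The electroneutrality
coupling is stiff by construction: adding 1 mM of monovalent cation to a
80 nm-radius segment shifts its potential by ≈0.4 V, so any charge imbalance
is corrected within microseconds (the capacitor-charging timescale), while
the concentrations relax over milliseconds.

Assumptions: no membrane leak or channel currents (the only exchange with
the exterior is the synaptic influx and the dendritic reservoir); radial
uniformity; dilute-solution chemical potential μₖ = k_B T ln(nₖ/n_ref);
integer valences; temperature-independent diffusion constants; calcium is
not simulated (its contribution to the potential is negligible — the NMDAR
readout below stands in for it).

### Background charge

A fixed, immobile negative charge density n₀ enforces the chosen resting
potential.  It is calibrated per segment,
n₀,ᵢ = Σₖ zₖ nₖ^rest − 2 c_m Φ^rest/(aᵢ e), so the rest profile is uniform
despite the varying radius; "fixed" means fixed in time.  Because n₀ is
immobile it never enters resistivities or currents, only the charge sum.  A
consequence used by the NMDAR analysis: changing Φ^rest changes only n₀,
so potential *deviations* from rest are exactly independent of the resting
level, and traces can be rebased between −70 mV (solver default) and −85 mV
(receptor analysis) without re-simulation.

## Numerics

Explicit forward-Euler in time, central differences in space, one ghost
segment per end:

* synaptic end (x₀): zero gradient for Φ, K⁺ and Cl⁻; the sodium ghost
  carries an excess h·I_in/(D_Na e z_Na π a²) so the diffusive flux through
  the boundary interface equals the injected current;
* dendritic end (x_{N+1}): concentrations clamped to rest, potential
  clamped to Φ^rest (or Φ^rest + 6 mV during a simulated bAP).  Ghost
  potentials are boundary conditions, never derived from ghost
  concentrations — the sodium ghost excess encodes a flux, not a charge.

Interface conductivities are the series combination of the two adjacent
half-segments, σ_if = 2σᵢσⱼ/(σᵢ+σⱼ).  (The σᵢσⱼ/(σᵢ+σⱼ) form sometimes
written for this scheme is half the correct series value; it would double
every effective resistance and is inconsistent with the Ohmic plateau
I·R_e ≈ 6 mV reproduced here.)  Drift conductivities σ_{e,k} = a²/r_{e,k}
are recomputed from the instantaneous concentrations every step; diffusion
conductivities a²Dₖ are constant.  The update is simultaneous (all fluxes
from the pre-step state).  The hot loop is a numba kernel (~4 Ms steps/s on
one core for 14 segments × 3 species); a plain-numpy `step` implements the
identical update and the two are cross-checked to 1e-12 in the tests.

Stability: the scheme is explicit, so dt is bounded by the stiff
drift–electroneutrality coupling, whose rate scales with a·Σₖ Dₖzₖ²nₖ/h².
On the default grid (14 segments, h = 0.1 µm, dendrite radius 0.25 µm) the
measured threshold lies between 0.5 ns (stable) and 1 ns (unstable);
linearization about rest gives dt_max ≈ 0.8 ns.  The default dt is 0.5 ns.
A guard aborts a run when |Φ| exceeds 1 V (physical potentials stay below
~0.1 V) or turns non-finite.  Halving dt or h changes recorded outputs by
<10⁻⁴ and <2% respectively (tested); refining h by 2 tightens dt_max by 4,
so grid-refinement runs use 0.1 ns.  The high-chloride variant (below) is
stiffer (threshold ≈ 0.4 ns) and is run at 0.25 ns.

## Reference geometry and parameters

| parameter | value | note |
|---|---|---|
| segments | 5 head / 5 neck / 4 dendrite, h = 0.1 µm | total 1.4 µm |
| head radius | 250 nm | see below |
| neck radius | 35 nm | neck resistance at rest 230 MΩ |
| dendrite radius | 0.25 µm | see below |
| T | 310 K | |
| c_m | 0.01 F/m² | |
| Φ^rest | −70 mV | −85 mV for the NMDAR readout |
| rest Na/K/Cl | 10 / 140 / 10 mM | |
| D_Na, D_K, D_Cl | 0.65, 1.0, 1.0 ×10⁻⁹ m²/s | |
| dt | 0.5 ns (default), 0.1 ns also standard | |

Two geometry choices were genuinely open and were fixed by internal
consistency of the reference results rather than by quoted nominal values:

* **Head radius 250 nm.**  A nominal head volume of 0.01 µm³ (radius
  79.8 nm over the 0.5 µm head) is sometimes quoted for this setup, but it
  is not self-consistent with the other reference results: the sodium decay
  time V·L/(A·D) is 19.6 ms only for V = π(250 nm)²·0.5 µm ≈ 0.098 µm³,
  and with the 79.8 nm head the simulated reference values are far off
  (Na(10 ms) ≈ 58 mM instead of ≈29, τ ≈ 2.2 ms instead of ≈19).  With
  250 nm every reference quantity is reproduced within a few percent.
* **Dendrite radius 0.25 µm.**  The stability threshold pins it: the
  stiff-coupling rate grows with the radius, and 0.25 µm reproduces
  "stable at 0.5 ns, unstable at 1 ns", whereas 0.5 µm would make 0.5 ns
  diverge (dt_max ≈ 0.4 ns).  Its resistance contribution at rest is <2% of
  the neck's; doubling it moves the head voltage by ≈1% (tested).

## Analysis conventions

* **Current decomposition** uses the same interface conductivities as the
  solver, so drift + diffusion at every interface reproduces the stepped
  fluxes exactly; boundary interfaces use the ghost values, which makes the
  injected current appear at the synaptic interface.
* **Segment drift current** (for the voltage prediction
  Φ_est = Σᵢ I_e(xᵢ) r_e(xᵢ) Δx/Aᵢ) is the mean of the two face values.
* **V_ohm** is sampled 10 µs after phase onset — after the membrane
  capacitor has charged (RC ≈ 1 µs) but before concentrations move.  The
  same 10 µs settling window is excluded when picking the peak head
  depolarization (or peak NMDAR current) of a post-injection clamp phase,
  because the capacitive discharge from the injection level is not part of
  the diffusion-driven boost.
* **Decay fits** are log-linear least squares of nₖ − nₖ^rest starting
  0.1 ms after injection offset over the full remaining trace; a
  single-point 1/e reading would be noisier at coarse record strides.
* **Voltage-divider neck resistance** reads V_sp in the first head segment
  and V_den in the last dendritic segment.

## Parameter variants

* *equal diffusivity*: D_Na raised to 1.0×10⁻⁹ m²/s.  The total drift
  resistance R_e then *decreases* during injection (ion accumulation wins
  once the Na-for-K diffusivity penalty is gone).
* *symmetric electrolyte*: additionally Cl^rest = 150 mM and the background
  charge removed.  Na + K = Cl makes the mobile ions exactly
  charge-balanced, so the membrane-charge relation gives a 0 mV rest
  potential; the run starts there and depolarizations are reported relative
  to that baseline.  R_e decreases more strongly (chloride influx now
  compensates roughly half the sodium injection).
* default parameters: R_e *increases* — sodium's 35% lower diffusivity
  outweighs net ion accumulation.

## NMDAR readout

g(V) = 1/(1 + 0.073·exp(−0.074·V)) with V in mV; I = g·(V − 0 mV), V taken
as the potential of the first head segment (the nominal "voltage across the
synapse" is identically zero under the zero-gradient synaptic boundary).
The receptor is an offline readout on recorded traces rebased to a −85 mV
rest; it does not feed back into the solver.

## What a green test establishes — and what it does not

There is no synthetic-data generator in the statistical sense: the model
itself produces all inputs, and every experiment is a stated deterministic
protocol (geometry, electrolyte, current step, clamp).  A passing suite
establishes that *this* discretized model reproduces the published
simulation results and satisfies its conservation/consistency invariants;
it does not validate the biological realism of a leak-free, 1-D,
three-species spine, nor boundary effects of real dendrites beyond the
clamped reservoir 0.4 µm from the neck.

## Known limitations

* Explicit stepping only: production runs cost ~2×10⁶ steps per
  millisecond; implicit or operator-split schemes are out of scope.
* Concentrations are not positivity-protected; extreme protocols (e.g.
  11 nm necks at 35 pA) can leave the physiological regime where the B(ratio)
  collapse holds, though the guard catches outright divergence.
* The pairing-boost measurement depends on the 10 µs settling convention;
  values quoted to ±2% inherit that convention.
* No membrane channels, pumps, buffers, calcium dynamics, branched
  morphologies, or stochastic channel noise.
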
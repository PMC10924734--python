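"""Domain types and closed-form electrodiffusion physics.

All quantities are strict SI internally (m, s, V, A, number density in 1/m^3).
Millimolar, millivolt, picoampere etc. appear only at the I/O boundary, via the
explicit conversion helpers below.

The central relation is the membrane-charge form of the potential: a cylindrical
segment of radius ``a`` holds a net charge ``pi a^2 dx * sum_k z_k e n_k`` on a
membrane of capacitance ``2 pi a dx c_m``, so

    Phi_i = a_i / (2 c_m) * sum_k z_k e n_k,i

with the sum running over the mobile species *and* a fixed, immobile negative
background charge density ``n0`` that is calibrated once so that the resting
concentrations produce a uniform resting potential.  The potential is always
derived from the concentrations; it is never an independent state variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PhysicalConstants",
    "IonSpecies",
    "SpineGeometry",
    "SimState",
    "DEFAULT_CONSTANTS",
    "default_species",
    "mm_to_density",
    "density_to_mm",
    "potential_from_concentrations",
    "calibrate_background_charge",
    "drift_resistivity",
    "species_resistivities",
    "estimate_ion_count",
    "estimate_influx_count",
    "estimate_decay_time",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants and membrane properties (SI units).

    Parameters
    ----------
    e : float
        Elementary charge (C).
    k_B : float
        Boltzmann constant (J/K).
    N_A : float
        Avogadro constant (1/mol).
    T : float
        Absolute temperature (K).  Default 310 K (physiological).
    c_m : float
        Specific membrane capacitance (F/m^2).  Default 0.01 F/m^2.
    """

    e: float = 1.602176634e-19
    k_B: float = 1.380649e-23
    N_A: float = 6.02214076e23
    T: float = 310.0
    c_m: float = 0.01

    def __post_init__(self) -> None:
        for name in ("e", "k_B", "N_A", "T", "c_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def kT(self) -> float:
        """Thermal energy k_B * T (J)."""
        return self.k_B * self.T


DEFAULT_CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class IonSpecies:
    """One mobile ion species.

    Parameters
    ----------
    name : str
        Label, e.g. ``"Na"``.
    z : int
        Integer valence (dimensionless).  ``z = 0`` is allowed only for
        neutral tracer species used in diffusion tests.
    D : float
        Diffusion constant (m^2/s).
    n_rest_mM : float
        Resting (initial) concentration in mM.
    """

    name: str
    z: int
    D: float
    n_rest_mM: float

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("diffusion constant D must be > 0")
        if self.n_rest_mM < 0:
            raise ValueError("resting concentration must be >= 0")

    @property
    def n_rest(self) -> float:
        """Resting number density (1/m^3)."""
        return mm_to_density(self.n_rest_mM)


def default_species(
    *,
    equal_diffusivity: bool = False,
    cl_rest_mM: float = 10.0,
) -> tuple[IonSpecies, IonSpecies, IonSpecies]:
    """The standard Na/K/Cl intracellular electrolyte.

    Defaults: Na 10 mM (D = 0.65e-9 m^2/s), K 140 mM (D = 1.0e-9), Cl 10 mM
    (D = 1.0e-9).  ``equal_diffusivity=True`` raises sodium's diffusivity to
    1.0e-9 m^2/s (all species equal); ``cl_rest_mM`` overrides the chloride
    resting concentration (150 mM in the symmetric-electrolyte variant).
    """
    d_na = 1.0e-9 if equal_diffusivity else 0.65e-9
    return (
        IonSpecies("Na", +1, d_na, 10.0),
        IonSpecies("K", +1, 1.0e-9, 140.0),
        IonSpecies("Cl", -1, 1.0e-9, cl_rest_mM),
    )


@dataclass(frozen=True)
class SpineGeometry:
    """1-D chain of cylindrical segments: head, neck, then dendrite.

    Segments are ordered from the synaptic end (index 0) to the dendritic end
    (index N-1) and share a common length ``h``.

    Parameters
    ----------
    n_head, n_neck, n_dend : int
        Segment counts per region.
    h : float
        Segment length (m).
    radii : tuple of float
        Per-segment radius (m), length ``n_head + n_neck + n_dend``.
    """

    n_head: int
    n_neck: int
    n_dend: int
    h: float
    radii: tuple[float, ...]

    def __post_init__(self) -> None:
        if min(self.n_head, self.n_neck, self.n_dend) < 1:
            raise ValueError("each region needs at least one segment")
        if self.h <= 0:
            raise ValueError("segment length h must be > 0")
        if len(self.radii) != self.n_segments:
            raise ValueError(
                f"expected {self.n_segments} radii, got {len(self.radii)}"
            )
        if any(a <= 0 for a in self.radii):
            raise ValueError("all radii must be > 0")

    @classmethod
    def from_region_radii(
        cls,
        head_radius: float,
        neck_radius: float,
        dend_radius: float,
        *,
        n_head: int = 5,
        n_neck: int = 5,
        n_dend: int = 4,
        h: float = 0.1e-6,
    ) -> "SpineGeometry":
        """Build a geometry with one radius per region."""
        radii = (
            (head_radius,) * n_head
            + (neck_radius,) * n_neck
            + (dend_radius,) * n_dend
        )
        return cls(n_head, n_neck, n_dend, h, radii)

    @property
    def n_segments(self) -> int:
        return self.n_head + self.n_neck + self.n_dend

    @property
    def total_length(self) -> float:
        """Total cable length (m)."""
        return self.n_segments * self.h

    @property
    def a(self) -> np.ndarray:
        """Per-segment radius (m) as an array."""
        return np.asarray(self.radii, dtype=float)

    @property
    def area(self) -> np.ndarray:
        """Cross-sectional area pi a^2 (m^2) per segment."""
        return np.pi * self.a**2

    @property
    def membrane_area(self) -> np.ndarray:
        """Lateral membrane area 2 pi a h (m^2) per segment."""
        return 2.0 * np.pi * self.a * self.h

    @property
    def volume(self) -> np.ndarray:
        """Segment volume pi a^2 h (m^3)."""
        return self.area * self.h

    @property
    def head(self) -> slice:
        return slice(0, self.n_head)

    @property
    def neck(self) -> slice:
        return slice(self.n_head, self.n_head + self.n_neck)

    @property
    def dend(self) -> slice:
        return slice(self.n_head + self.n_neck, self.n_segments)

    def region_of(self, i: int) -> str:
        if i < self.n_head:
            return "head"
        if i < self.n_head + self.n_neck:
            return "neck"
        return "dend"

    def refined(self, factor: int) -> "SpineGeometry":
        """Same spine, each segment split into ``factor`` equal pieces."""
        radii = tuple(a for a in self.radii for _ in range(factor))
        return SpineGeometry(
            self.n_head * factor,
            self.n_neck * factor,
            self.n_dend * factor,
            self.h / factor,
            radii,
        )


@dataclass
class SimState:
    """Instantaneous solver state.

    ``n`` holds number densities (1/m^3) of each mobile species per segment,
    shape ``(K, N)``; ``n0`` is the fixed background-charge density (1/m^3)
    per segment.  The potential is *derived* via
    :func:`potential_from_concentrations`, never stored.
    """

    t: float
    n: np.ndarray
    n0: np.ndarray
    species: tuple[IonSpecies, ...]

    def phi(self, geom: SpineGeometry, const: PhysicalConstants = DEFAULT_CONSTANTS) -> np.ndarray:
        return potential_from_concentrations(self.n, self.n0, self.species, geom, const)

    def copy(self) -> "SimState":
        return replace(self, n=self.n.copy(), n0=self.n0.copy())


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

def mm_to_density(c_mM: float | np.ndarray, const: PhysicalConstants = DEFAULT_CONSTANTS):
    """Convert a concentration in mM to a number density in 1/m^3.

    1 mM = 1 mol/m^3, so the density is ``c * N_A``.
    """
    c = np.asarray(c_mM, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    out = c * const.N_A
    return float(out) if np.isscalar(c_mM) else out


def density_to_mm(n: float | np.ndarray, const: PhysicalConstants = DEFAULT_CONSTANTS):
    """Inverse of :func:`mm_to_density`."""
    out = np.asarray(n, dtype=float) / const.N_A
    return float(out) if np.isscalar(n) else out


# ---------------------------------------------------------------------------
# potential and background charge
# ---------------------------------------------------------------------------

def potential_from_concentrations(
    n: np.ndarray,
    n0: np.ndarray,
    species: tuple[IonSpecies, ...],
    geom: SpineGeometry,
    const: PhysicalConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Membrane potential per segment (V) from the summed ion charge.

    Phi_i = a_i/(2 c_m) * (sum_k z_k e n_k,i  -  e n0_i); the background
    charge carries valence -1 and is immobile.
    """
    z = np.array([s.z for s in species], dtype=float)
    n = np.asarray(n, dtype=float)
    charge = const.e * (z @ (n[:, None] if n.ndim == 1 else n) - n0)
    return geom.a * charge / (2.0 * const.c_m)


def calibrate_background_charge(
    geom: SpineGeometry,
    species: tuple[IonSpecies, ...],
    phi_rest: float,
    const: PhysicalConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Background-charge density n0 per segment (1/m^3).

    Chosen so that the resting concentrations produce ``phi_rest`` in every
    segment:  n0_i = sum_k z_k n_k^rest - 2 c_m phi_rest / (a_i e).  Because
    the deviation from net-cation density scales with 1/a_i, n0 is
    per-segment even though it is fixed in time.
    """
    net_cation = sum(s.z * s.n_rest for s in species)
    n0 = net_cation - 2.0 * const.c_m * phi_rest / (geom.a * const.e)
    if np.any(n0 < 0):
        raise ValueError(
            "calibration produced a negative background charge; "
            "check resting concentrations and phi_rest"
        )
    return n0


def rest_state(
    geom: SpineGeometry,
    species: tuple[IonSpecies, ...],
    phi_rest: float,
    const: PhysicalConstants = DEFAULT_CONSTANTS,
) -> SimState:
    """Initial condition: uniform resting concentrations, calibrated n0."""
    n = np.tile(
        np.array([s.n_rest for s in species])[:, None], (1, geom.n_segments)
    )
    n0 = calibrate_background_charge(geom, species, phi_rest, const)
    return SimState(t=0.0, n=n, n0=n0, species=tuple(species))


# ---------------------------------------------------------------------------
# resistivities
# ---------------------------------------------------------------------------

def drift_resistivity(
    n: np.ndarray,
    species: tuple[IonSpecies, ...],
    const: PhysicalConstants = DEFAULT_CONSTANTS,
) -> np.ndarray | float:
    """Electrical resistivity for drift currents, r_e (Ohm m).

    r_e = k_B T / sum_k D_k e^2 z_k^2 n_k, summed over mobile species only
    (the immobile background charge carries no current).  All-zero
    concentrations give ``inf``.

    Parameters
    ----------
    n : array, shape (K,) or (K, N)
        Number densities (1/m^3) per species (rows ordered like ``species``).
    """
    n = np.asarray(n, dtype=float)
    n2 = n[:, None] if n.ndim == 1 else n
    z2D = np.array([s.D * s.z**2 for s in species])
    cond = const.e**2 * np.tensordot(z2D, n2, axes=(0, 0))
    with np.errstate(divide="ignore"):
        r = np.where(cond > 0, const.kT / np.where(cond > 0, cond, 1.0), np.inf)
    return float(r[0]) if n.ndim == 1 else r


def species_resistivities(
    n_k: float | np.ndarray,
    sp: IonSpecies,
    const: PhysicalConstants = DEFAULT_CONSTANTS,
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Per-species drift and diffusional resistivities (r_e,k, r_c,k).

    r_e,k = k_B T / (D_k e^2 z_k^2 n_k)   (Ohm m)
    r_c,k = r_e,k * e * z_k               (Ohm m C)

    Zero concentration is signalled as infinite resistivity.
    """
    if sp.z == 0:
        raise ValueError("resistivities are undefined for a neutral species")
    n_k = np.asarray(n_k, dtype=float)
    denom = sp.D * const.e**2 * sp.z**2 * n_k
    with np.errstate(divide="ignore"):
        r_e = np.where(denom > 0, const.kT / np.where(denom > 0, denom, 1.0), np.inf)
    r_c = r_e * const.e * sp.z
    if n_k.ndim == 0:
        return float(r_e), float(r_c)
    return r_e, r_c


# ---------------------------------------------------------------------------
# back-of-envelope estimators
# ---------------------------------------------------------------------------

def estimate_ion_count(
    volume: float, c_mM: float, const: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Number of ions in ``volume`` (m^3) at concentration ``c_mM``."""
    if volume < 0:
        raise ValueError("volume must be >= 0")
    return volume * mm_to_density(c_mM, const)


def estimate_influx_count(
    current: float,
    duration: float,
    z: int = 1,
    const: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Number of ions delivered by ``current`` (A) over ``duration`` (s)."""
    if current < 0 or duration < 0:
        raise ValueError("current and duration must be >= 0")
    if z == 0:
        raise ValueError("valence must be nonzero")
    return current * duration / (abs(z) * const.e)


def estimate_decay_time(
    head_volume: float, neck_length: float, neck_area: float, D: float
) -> float:
    """Diffusive equilibration time tau = V L / (A D) (s).

    The single-compartment estimate for a head of volume V emptying through a
    neck of length L and cross-section A by diffusion alone (no
    electroneutrality coupling).
    """
    if min(head_volume, neck_length, neck_area, D) <= 0:
        raise ValueError("all arguments must be > 0")
    return head_volume * neck_length / (neck_area * D)
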
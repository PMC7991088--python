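"""Per-frame FRET geometry: inter-fluorophore distance, orientation factor, efficiency.

The observables follow the standard single-pair FRET description. For a donor
and acceptor fluorophore the efficiency depends only on the distance ``D``
between the two chromophores and on the orientation factor ``kappa^2``::

    kappa = cos(theta_T) - 3 cos(theta_D) cos(theta_A)
    E     = 1 / (1 + (2 / (3 kappa^2)) * (D / R0)^6)

where ``theta_T`` is the angle between the two transition dipoles and
``theta_D``, ``theta_A`` the angles each dipole makes with the donor->acceptor
separation direction. ``R0`` is the Foerster radius quoted for the isotropic
orientational average ``<kappa^2> = 2/3``, so that ``E(D=R0, 2/3) = 1/2``.

For a genetically encoded sensor built from two fluorescent-protein modules,
``D`` is the distance between the geometric centers of the two modules, and
each transition dipole is approximated by the axis from the module's geometric
center to the C-alpha of its Ser147 — a direction that tracks the chromophore
dipole orientation obtained from quantum-chemical calculations across many
fluorescent-protein variants.

All lengths are in nanometres, times in nanoseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "ForsterParams",
    "LabeledFrame",
    "FretObservables",
    "separation",
    "dipole_direction",
    "kappa_squared",
    "fret_efficiency",
    "frame_observables",
    "batch_observables",
    "kappa2_orientation_scan",
]

#: Tolerance for the unit-norm precondition on dipole / separation directions.
UNIT_NORM_TOL = 1e-6

#: Default Foerster radius for the CFP/YFP pair at kappa^2 = 2/3, in nm.
#: A literature consensus value; override per run via ForsterParams.
DEFAULT_R0_ISO_NM = 4.9


class DegenerateGeometryError(ValueError):
    """Raised when a geometric construction is ill-defined (zero-length vector)."""


@dataclass(frozen=True)
class ForsterParams:
    """Photophysical parameters of the donor/acceptor pair.

    Parameters
    ----------
    r0_iso : float
        Foerster radius in nm, defined at the isotropic orientational average
        ``kappa^2 = 2/3``. Default 4.9 nm (CFP/YFP literature value).
    """

    r0_iso: float = DEFAULT_R0_ISO_NM

    def __post_init__(self) -> None:
        if not np.isfinite(self.r0_iso) or self.r0_iso <= 0:
            raise ValueError(f"r0_iso must be positive and finite, got {self.r0_iso}")


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} contains non-finite coordinates")
    return v


@dataclass(frozen=True)
class LabeledFrame:
    """Geometric reference points of one time point of a two-fluorophore sensor.

    Coordinates are in nm. ``donor_tip`` / ``acceptor_tip`` are the C-alpha
    (or equivalent coarse-grained bead) of Ser147 of the respective fluorescent
    module; together with the module's geometric center they define the
    transition-dipole direction.
    """

    time: float
    donor_center: np.ndarray
    donor_tip: np.ndarray
    acceptor_center: np.ndarray
    acceptor_tip: np.ndarray
    ca_coords: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "donor_center", _as_vec3(self.donor_center, "donor_center"))
        object.__setattr__(self, "donor_tip", _as_vec3(self.donor_tip, "donor_tip"))
        object.__setattr__(self, "acceptor_center", _as_vec3(self.acceptor_center, "acceptor_center"))
        object.__setattr__(self, "acceptor_tip", _as_vec3(self.acceptor_tip, "acceptor_tip"))
        if self.time < 0 or not np.isfinite(self.time):
            raise ValueError(f"time must be finite and >= 0, got {self.time}")
        if np.array_equal(self.donor_tip, self.donor_center):
            raise DegenerateGeometryError("donor dipole has zero length (tip == center)")
        if np.array_equal(self.acceptor_tip, self.acceptor_center):
            raise DegenerateGeometryError("acceptor dipole has zero length (tip == center)")
        if self.ca_coords is not None:
            ca = np.asarray(self.ca_coords, dtype=float)
            if ca.ndim != 2 or ca.shape[1] != 3:
                raise ValueError("ca_coords must have shape (n_atoms, 3)")
            object.__setattr__(self, "ca_coords", ca)


@dataclass(frozen=True)
class FretObservables:
    """Per-frame FRET observables: time (ns), distance D (nm), kappa^2, efficiency E."""

    time: float
    distance: float
    kappa2: float
    efficiency: float

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        if not (0.0 <= self.kappa2 <= 4.0 + 1e-12):
            raise ValueError(f"kappa2 out of [0, 4]: {self.kappa2}")
        if not (0.0 <= self.efficiency <= 1.0):
            raise ValueError(f"efficiency out of [0, 1]: {self.efficiency}")


def separation(frame: LabeledFrame) -> tuple[float, np.ndarray]:
    """Distance between the two module centers and the donor->acceptor unit vector.

    Returns
    -------
    (distance, direction)
        ``distance`` in nm; ``direction`` the normalized donor->acceptor vector.

    Raises
    ------
    DegenerateGeometryError
        If the two centers coincide.
    """
    r = frame.acceptor_center - frame.donor_center
    d = float(np.linalg.norm(r))
    if d == 0.0:
        raise DegenerateGeometryError("donor and acceptor centers coincide")
    return d, r / d


def dipole_direction(center, tip) -> np.ndarray:
    """Unit vector from a module's geometric center to its Ser147 C-alpha."""
    c = _as_vec3(center, "center")
    t = _as_vec3(tip, "tip")
    v = t - c
    n = float(np.linalg.norm(v))
    if n == 0.0:
        raise DegenerateGeometryError("zero-length dipole (tip == center)")
    return v / n


def _check_unit(v: np.ndarray, name: str) -> np.ndarray:
    v = _as_vec3(v, name)
    if abs(np.linalg.norm(v) - 1.0) > UNIT_NORM_TOL:
        raise ValueError(f"{name} must be unit-norm within {UNIT_NORM_TOL}")
    return v


def kappa_squared(donor_dipole, acceptor_dipole, separation_direction) -> float:
    """Orientation factor kappa^2 from unit dipole and separation directions.

    ``kappa = cos(theta_T) - 3 cos(theta_D) cos(theta_A)`` with theta_T the
    inter-dipole angle and theta_D / theta_A the angles against the
    donor->acceptor direction. The result lies in [0, 4] and is invariant
    under a sign flip of any input (only the squared value is physical).
    """
    d = _check_unit(donor_dipole, "donor_dipole")
    a = _check_unit(acceptor_dipole, "acceptor_dipole")
    r = _check_unit(separation_direction, "separation_direction")
    kappa = float(d @ a - 3.0 * (d @ r) * (a @ r))
    k2 = kappa * kappa
    # clip numerical overshoot at the supremum
    return min(k2, 4.0)


def fret_efficiency(distance, kappa2, params: ForsterParams) -> float | np.ndarray:
    """Foerster transfer efficiency for given distance (nm) and kappa^2.

    Uses the algebraically equivalent, numerically safe form
    ``E = q / (q + 2)`` with ``q = 3 kappa^2 (R0/D)^6``, so ``kappa2 = 0``
    yields exactly 0 without dividing by zero. Accepts scalars or arrays.
    """
    d = np.asarray(distance, dtype=float)
    k2 = np.asarray(kappa2, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distance must be positive")
    if np.any((k2 < 0) | (k2 > 4.0 + 1e-9)):
        raise ValueError("kappa2 must lie in [0, 4]")
    q = 3.0 * k2 * (params.r0_iso / d) ** 6
    e = q / (q + 2.0)
    if np.isscalar(distance) and np.isscalar(kappa2):
        return float(e)
    return e


def frame_observables(frame: LabeledFrame, params: ForsterParams) -> FretObservables:
    """Compute (D, kappa^2, E) for one labeled frame."""
    d, rhat = separation(frame)
    dd = dipole_direction(frame.donor_center, frame.donor_tip)
    ad = dipole_direction(frame.acceptor_center, frame.acceptor_tip)
    k2 = kappa_squared(dd, ad, rhat)
    e = fret_efficiency(d, k2, params)
    return FretObservables(time=frame.time, distance=d, kappa2=k2, efficiency=float(e))


def batch_observables(
    times: np.ndarray,
    donor_centers: np.ndarray,
    donor_tips: np.ndarray,
    acceptor_centers: np.ndarray,
    acceptor_tips: np.ndarray,
    params: ForsterParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (D, kappa^2, E) over (n, 3) coordinate arrays.

    Equivalent frame-by-frame to :func:`frame_observables`; used for long
    trajectories where per-frame Python overhead matters.
    """
    dc = np.asarray(donor_centers, dtype=float)
    dt = np.asarray(donor_tips, dtype=float)
    ac = np.asarray(acceptor_centers, dtype=float)
    at = np.asarray(acceptor_tips, dtype=float)
    r = ac - dc
    dist = np.linalg.norm(r, axis=1)
    if np.any(dist == 0):
        raise DegenerateGeometryError("coincident centers in batch")
    rhat = r / dist[:, None]
    dvec = dt - dc
    avec = at - ac
    dn = np.linalg.norm(dvec, axis=1)
    an = np.linalg.norm(avec, axis=1)
    if np.any(dn == 0) or np.any(an == 0):
        raise DegenerateGeometryError("zero-length dipole in batch")
    dhat = dvec / dn[:, None]
    ahat = avec / an[:, None]
    kappa = np.einsum("ij,ij->i", dhat, ahat) - 3.0 * np.einsum(
        "ij,ij->i", dhat, rhat
    ) * np.einsum("ij,ij->i", ahat, rhat)
    k2 = np.minimum(kappa * kappa, 4.0)
    e = fret_efficiency(dist, k2, params)
    return dist, k2, np.asarray(e)


def kappa2_orientation_scan(n_polar: int = 101, n_azimuth: int = 181) -> tuple[float, float]:
    """(min, max) of kappa^2 over a dense grid of dipole orientations.

    The scan reduces the four orientational degrees of freedom to the
    sufficient coordinates (cos theta_D, cos theta_A, relative azimuth) and
    includes the collinear endpoints, where the supremum kappa^2 = 4 is
    attained (both dipoles along the separation axis: kappa = 1 - 3 = -2).
    """
    u = np.linspace(-1.0, 1.0, n_polar)  # cos(theta_D)
    v = np.linspace(-1.0, 1.0, n_polar)  # cos(theta_A)
    phi = np.linspace(0.0, 2.0 * np.pi, n_azimuth, endpoint=False)
    uu, vv, pp = np.meshgrid(u, v, phi, indexing="ij", sparse=True)
    s = np.sqrt((1.0 - uu**2) * (1.0 - vv**2))
    kappa = (uu * vv + s * np.cos(pp)) - 3.0 * uu * vv
    k2 = kappa**2
    return float(k2.min()), float(k2.max())
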
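"""Monte-Carlo forward simulation of the FRET process for a structure.

For each simulated excitation both dyes start at uniformly random
positions inside their accessible volumes and with transition-dipole
orientations drawn uniformly inside a cone about the AV principal axis
(wobbling-in-cone model).  During the donor excited state the dyes
perform a reflected random walk inside their AVs (translational
diffusion) and rotational diffusion inside their cones; at every time
step the transfer rate is

    k_T = (3 kappa^2 / 2) * (1/tau) * (R_iso / R)^6

with kappa^2 from the instantaneous dipole orientations and R the
instantaneous center distance.  The excitation terminates stochastically
by donor decay (rate 1/tau) or transfer (rate k_T); the simulated
efficiency is the transferred fraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy.optimize import brentq

from .accessible_volume import AccessibleVolume

KAPPA_DYNAMIC = 1    # kappa^2 re-evaluated every time step (default)
KAPPA_STATIC = 2     # kappa^2 frozen per excitation (comparison mode)
KAPPA_ISOTROPIC = 0  # kappa^2 = 2/3 (fast-rotation limit)

_KAPPA_MODES = {"dynamic": KAPPA_DYNAMIC, "static": KAPPA_STATIC,
                "isotropic": KAPPA_ISOTROPIC}


def forster_efficiency(distance: float, r0: float) -> float:
    """E = 1 / (1 + (R/R0)^6) for donor-acceptor distance R."""
    if distance <= 0 or r0 <= 0:
        raise ValueError("distance and R0 must be > 0")
    return 1.0 / (1.0 + (distance / r0) ** 6)


def cone_semiangle_from_anisotropy(r_inf: float, r0: float = 0.4) -> float:
    """Wobbling-in-cone semi-angle (deg) from the residual anisotropy.

    Solves r_inf / r0 = [cos(a) (1 + cos(a)) / 2]^2 for the semi-angle a.
    A fully hindered dye (r_inf = r0) gives 0 deg; a free dye (r_inf = 0)
    gives 90 deg, the cone convention for unrestricted rotation.
    """
    if not 0 <= r_inf <= r0:
        raise ValueError("need 0 <= r_inf <= r0")
    ratio = r_inf / r0
    if ratio == 1.0:
        return 0.0
    if ratio == 0.0:
        return 90.0

    def f(a):
        c = math.cos(a)
        return (c * (1 + c) / 2) ** 2 - ratio

    return math.degrees(brentq(f, 0.0, math.pi / 2))


@dataclass(frozen=True)
class PhotophysicsParameters:
    """Dye photophysics and simulation settings.

    ``r_inf``/``r0_fundamental`` set the wobbling cone via the
    wobbling-in-cone relation unless ``cone_semiangle_deg`` overrides it;
    the rotational diffusion coefficient is D_rot = 1/(6 rho) with rho
    the rotational correlation time.
    """

    r_iso: float = 70.0              # isotropic Förster radius, Å
    delta_r_iso: float = 2.0         # its uncertainty, Å
    donor_lifetime: float = 3.5      # tau, ns
    rotational_correlation: float = 0.5  # rho, ns
    r_inf: float = 0.1               # residual anisotropy
    r0_fundamental: float = 0.4      # fundamental anisotropy
    cone_semiangle_deg: float | None = None
    diffusion_coefficient: float = 10.0  # Å^2/ns, translational
    time_step: float = 0.05          # ns
    n_excitations: int = 50_000
    seed: int = 0
    kappa_mode: str = "dynamic"

    def __post_init__(self):
        if not 0 <= self.r_inf <= self.r0_fundamental:
            raise ValueError("need 0 <= r_inf <= r0_fundamental")
        if self.r_iso <= 0 or self.n_excitations < 1:
            raise ValueError("r_iso must be > 0 and n_excitations >= 1")

    @property
    def semiangle_deg(self) -> float:
        if self.cone_semiangle_deg is not None:
            return self.cone_semiangle_deg
        return cone_semiangle_from_anisotropy(self.r_inf, self.r0_fundamental)

    @property
    def rotational_diffusion(self) -> float:
        """D_rot = 1/(6 rho), rad^2/ns."""
        return 1.0 / (6.0 * self.rotational_correlation)


@dataclass(frozen=True)
class SimulationResult:
    efficiency_mean: float
    efficiency_sd: float  # binomial SD of the mean
    n_excitations: int
    structure_id: int | None = None

    def __post_init__(self):
        if not 0 <= self.efficiency_mean <= 1 or self.efficiency_sd < 0:
            raise ValueError("inconsistent simulation result")


@njit(cache=True, fastmath=True)
def _sample_cone(axis, e1, e2, cos_alpha):
    """Uniform direction within the cone of half-opening alpha."""
    c = cos_alpha + np.random.random() * (1.0 - cos_alpha)
    s = math.sqrt(max(0.0, 1.0 - c * c))
    phi = 2.0 * math.pi * np.random.random()
    return (c * axis + s * math.cos(phi) * e1 + s * math.sin(phi) * e2)


@njit(cache=True, fastmath=True)
def _inside(occ, origin, spacing, p):
    i = int(round((p[0] - origin[0]) / spacing))
    j = int(round((p[1] - origin[1]) / spacing))
    k = int(round((p[2] - origin[2]) / spacing))
    if (i < 0 or j < 0 or k < 0 or i >= occ.shape[0]
            or j >= occ.shape[1] or k >= occ.shape[2]):
        return False
    return occ[i, j, k]


@njit(cache=True, fastmath=True)
def _kappa_sq(dvec, avec, rhat):
    cos_t = dvec[0] * avec[0] + dvec[1] * avec[1] + dvec[2] * avec[2]
    cos_d = dvec[0] * rhat[0] + dvec[1] * rhat[1] + dvec[2] * rhat[2]
    cos_a = avec[0] * rhat[0] + avec[1] * rhat[1] + avec[2] * rhat[2]
    k = cos_t - 3.0 * cos_d * cos_a
    return k * k


@njit(cache=True, fastmath=True)
def _mc_transfer_count(
    d_pts, a_pts,
    d_occ, d_origin, a_occ, a_origin, spacing,
    d_axis, d_e1, d_e2, a_axis, a_e1, a_e2,
    cos_alpha_d, cos_alpha_a,
    r0, tau, d_trans, d_rot, dt, n_exc, kappa_mode, seed,
):
    np.random.seed(seed)
    sig_t = math.sqrt(2.0 * d_trans * dt)
    sig_r = math.sqrt(2.0 * d_rot * dt)
    k_decay = 1.0 / tau
    r0_sq = r0 * r0
    transferred = 0
    pd = np.empty(3)
    pa = np.empty(3)
    trial = np.empty(3)
    rhat = np.empty(3)
    for _ in range(n_exc):
        id0 = np.random.randint(0, d_pts.shape[0])
        ia0 = np.random.randint(0, a_pts.shape[0])
        for c in range(3):
            pd[c] = d_pts[id0, c]
            pa[c] = a_pts[ia0, c]
        dvec = _sample_cone(d_axis, d_e1, d_e2, cos_alpha_d)
        avec = _sample_cone(a_axis, a_e1, a_e2, cos_alpha_a)
        while True:
            dx = pa[0] - pd[0]
            dy = pa[1] - pd[1]
            dz = pa[2] - pd[2]
            r_sq = dx * dx + dy * dy + dz * dz
            if kappa_mode == 0:
                kappa = 2.0 / 3.0
            else:
                inv_r = 1.0 / math.sqrt(r_sq)
                rhat[0] = dx * inv_r
                rhat[1] = dy * inv_r
                rhat[2] = dz * inv_r
                kappa = _kappa_sq(dvec, avec, rhat)
            ratio = r0_sq / r_sq
            k_t = 1.5 * kappa * k_decay * ratio * ratio * ratio
            k_tot = k_decay + k_t
            if np.random.random() < 1.0 - math.exp(-k_tot * dt):
                if np.random.random() < k_t / k_tot:
                    transferred += 1
                break
            # translational diffusion, reflecting boundary via rejection
            for c in range(3):
                trial[c] = pd[c] + sig_t * np.random.normal()
            if _inside(d_occ, d_origin, spacing, trial):
                for c in range(3):
                    pd[c] = trial[c]
            for c in range(3):
                trial[c] = pa[c] + sig_t * np.random.normal()
            if _inside(a_occ, a_origin, spacing, trial):
                for c in range(3):
                    pa[c] = trial[c]
            if kappa_mode == 1:
                # rotational diffusion in the cone, reflection by rejection
                dvec = _rot_step(dvec, sig_r, d_axis, cos_alpha_d)
                avec = _rot_step(avec, sig_r, a_axis, cos_alpha_a)
    return transferred


@njit(cache=True, fastmath=True)
def _rot_step(v, sig_r, axis, cos_alpha):
    gx = np.random.normal()
    gy = np.random.normal()
    gz = np.random.normal()
    dot = gx * v[0] + gy * v[1] + gz * v[2]
    nx = v[0] + sig_r * (gx - dot * v[0])
    ny = v[1] + sig_r * (gy - dot * v[1])
    nz = v[2] + sig_r * (gz - dot * v[2])
    inv = 1.0 / math.sqrt(nx * nx + ny * ny + nz * nz)
    nx *= inv
    ny *= inv
    nz *= inv
    if nx * axis[0] + ny * axis[1] + nz * axis[2] < cos_alpha:
        return v  # reflected (rejected) at the cone boundary
    out = np.empty(3)
    out[0] = nx
    out[1] = ny
    out[2] = nz
    return out


def _orthonormal_frame(axis: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return axis, e1, e2


def simulate_efficiency(av_donor: AccessibleVolume,
                        av_acceptor: AccessibleVolume,
                        phys: PhotophysicsParameters,
                        structure_id: int | None = None) -> SimulationResult:
    """Simulated smFRET efficiency of one structure (see module docstring)."""
    if len(av_donor.points) == 0 or len(av_acceptor.points) == 0:
        raise ValueError("both accessible volumes must be non-empty")
    if av_donor.grid_spacing != av_acceptor.grid_spacing:
        raise ValueError("AV grid spacings must match")
    if phys.time_step > phys.donor_lifetime / 10.0:
        warnings.warn("time step exceeds donor_lifetime/10; the "
                      "decay/transfer competition may be under-resolved")
    cos_alpha = math.cos(math.radians(phys.semiangle_deg))
    d_axis, d_e1, d_e2 = _orthonormal_frame(av_donor.principal_axis)
    a_axis, a_e1, a_e2 = _orthonormal_frame(av_acceptor.principal_axis)
    n = int(phys.n_excitations)
    count = _mc_transfer_count(
        av_donor.points, av_acceptor.points,
        av_donor.occupancy, av_donor.origin,
        av_acceptor.occupancy, av_acceptor.origin,
        av_donor.grid_spacing,
        d_axis, d_e1, d_e2, a_axis, a_e1, a_e2,
        cos_alpha, cos_alpha,
        phys.r_iso, phys.donor_lifetime, phys.diffusion_coefficient,
        phys.rotational_diffusion, phys.time_step, n,
        _KAPPA_MODES[phys.kappa_mode], phys.seed % (2 ** 31),
    )
    e_mean = count / n
    e_sd = math.sqrt(max(e_mean * (1 - e_mean), 1.0 / n) / n)
    return SimulationResult(e_mean, e_sd, n, structure_id)


def propagate_r0_uncertainty(
    efficiency: float,
    r_iso: float,
    delta_r_iso: float,
    mode: str = "closed-form",
    av_donor: AccessibleVolume | None = None,
    av_acceptor: AccessibleVolume | None = None,
    phys: PhotophysicsParameters | None = None,
) -> float:
    """Uncertainty of the simulated efficiency due to the R_iso uncertainty.

    ``closed-form`` returns the first-order bound 6 E (1-E) dR0/R0;
    ``resimulate`` reruns the Monte-Carlo simulation at R_iso +/- dR0 and
    returns half the spread of the two efficiencies.
    """
    if mode == "closed-form":
        if not 0 <= efficiency <= 1:
            raise ValueError("efficiency must be in [0, 1]")
        return 6.0 * efficiency * (1 - efficiency) * delta_r_iso / r_iso
    if mode == "resimulate":
        if av_donor is None or av_acceptor is None or phys is None:
            raise ValueError("resimulation needs both AVs and parameters")
        lo = simulate_efficiency(
            av_donor, av_acceptor, replace(phys, r_iso=r_iso - delta_r_iso))
        hi = simulate_efficiency(
            av_donor, av_acceptor, replace(phys, r_iso=r_iso + delta_r_iso))
        return abs(hi.efficiency_mean - lo.efficiency_mean) / 2.0
    raise ValueError(f"unknown mode {mode!r}")
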
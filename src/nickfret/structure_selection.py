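"""FRET-based structure selection and kink-angle statistics.

Ensemble members whose simulated efficiency falls within the combined
experimental + simulation uncertainty of a measured efficiency are
selected; the angle between the two stem axes (each axis from a PCA of
the stem pseudo-atoms, oriented from the nick toward the respective
tetraloop) is the kink angle theta, with 180 deg = straight.  Because a
single donor-acceptor distance carries no information about the azimuth
phi of the 5' stem about the 3' axis, selected structures form rings on
the unit sphere and the reported statistics are computed from
solid-angle-corrected (sin-theta-reweighted) histograms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .dna_models import (LOOP3, LOOP5, ROLE_B, ROLE_P, ROLE_S, STEM3, STEM5,
                         StructureModel)
from .fret_forward import SimulationResult

# Each pseudo-atom stands for a group of heavy atoms; stem-axis PCA over
# "all atoms of the stem" is mimicked by weighting each group with the
# number of heavy atoms it represents (phosphate PO4 + esters, ribose,
# mean purine/pyrimidine base).
PCA_WEIGHTS = {ROLE_P: 5.0, ROLE_S: 6.0, ROLE_B: 10.0}


@dataclass(frozen=True)
class SelectionCriterion:
    """|E_sim - E_exp| <= tolerance, tolerance from quadrature by default."""

    e_exp: float
    delta_e_exp: float = 0.03
    delta_e_sim: float = 0.04
    tolerance: float | None = None

    def __post_init__(self):
        if not 0 <= self.e_exp <= 1:
            raise ValueError("e_exp must be in [0, 1]")
        if self.tolerance is None:
            object.__setattr__(
                self, "tolerance",
                math.sqrt(self.delta_e_exp ** 2 + self.delta_e_sim ** 2))


def select_structures(results: list[SimulationResult],
                      criterion: SelectionCriterion) -> list[int]:
    """Ids of ensemble members matching the measured efficiency."""
    selected = [r.structure_id for r in results
                if abs(r.efficiency_mean - criterion.e_exp)
                <= criterion.tolerance]
    if not selected:
        warnings.warn(
            f"no structure within {criterion.tolerance:.3f} of "
            f"E_exp = {criterion.e_exp:.2f}")
    return sorted(selected)


def _stem_atoms_for_axis(model: StructureModel, stem: str) -> np.ndarray:
    """Stem pseudo-atoms omitting the tetraloop and its adjacent base pair
    (both nucleotides of that pair)."""
    if stem == STEM5:
        pairs = model.design.stem5_pairs
    elif stem == STEM3:
        pairs = model.design.stem3_pairs
    else:
        raise ValueError(f"unknown stem {stem!r}")
    if len(pairs) < 5:
        raise ValueError("stem must keep >= 4 base pairs after omissions")
    kept = pairs[:-1]  # pairs are ordered nick -> loop
    nts = {k for p in kept for k in p}
    mask = model.atom_mask(nucleotides=nts)
    weights = np.array([PCA_WEIGHTS[r] for r in model.role[mask]])
    return model.coords[mask], weights, kept


def stem_axis(model: StructureModel, stem: str
              ) -> tuple[np.ndarray, np.ndarray]:
    """(unit axis, anchor point) of a stem.

    The axis is the largest-variance principal component of the stem's
    pseudo-atoms (group-size weighted, see ``PCA_WEIGHTS``), sign-fixed
    to point from the nick toward the loop.
    """
    coords, weights, kept = _stem_atoms_for_axis(model, stem)
    anchor = np.average(coords, axis=0, weights=weights)
    centered = coords - anchor
    cov = (centered * weights[:, None]).T @ centered / weights.sum()
    w, v = np.linalg.eigh(cov)
    if w[-1] <= 1e-12:
        raise ValueError("degenerate stem geometry: no principal axis")
    axis = v[:, -1]
    # orient from the nick-proximal pair toward the loop-proximal pair
    nick_pair, loop_pair = kept[0], kept[-1]
    c_nick = np.mean([model.atom_coord(k, r)
                      for k in nick_pair for r in (0, 1, 2)], axis=0)
    c_loop = np.mean([model.atom_coord(k, r)
                      for k in loop_pair for r in (0, 1, 2)], axis=0)
    if np.dot(axis, c_loop - c_nick) < 0:
        axis = -axis
    return axis, anchor


def kink_angle(model: StructureModel) -> float:
    """Angle (deg) between the nick->loop axes of the two stems.

    A straight coaxial model gives close to (but not exactly) 180 deg:
    the finite number of base pairs makes each PCA axis deviate slightly
    from the helix axis.  Sharp hairpin-like folds give small angles.
    """
    u5, _ = stem_axis(model, STEM5)
    u3, _ = stem_axis(model, STEM3)
    return math.degrees(math.acos(np.clip(np.dot(u5, u3), -1.0, 1.0)))


# Azimuths within this of theta = 0/180 are reported as NaN: the PCA-axis
# tilt of even the perfectly straight model (~6 deg) leaves no structural
# azimuth information that close to the pole.
POLE_TOLERANCE_DEG = 8.0


def to_spherical(ensemble: list[StructureModel],
                 reference: StructureModel | None = None,
                 rmsd_tol: float = 0.1
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(theta, phi, tip positions) of each member about the 3' stem axis.

    All members are rigidly aligned onto the reference 3' stem (optimal
    superposition; an alignment RMSD above ``rmsd_tol`` means the stems
    were not rigid and raises).  theta is the polar angle of the 5' stem
    axis about the 3' axis and equals :func:`kink_angle`; phi is the
    azimuth about the 3' axis (NaN when degenerate near the poles).  The
    tip position is the aligned centroid of the 5' tetraloop.
    """
    if reference is None:
        reference = ensemble[0]
    ref_mask = reference.atom_mask(regions={STEM3, LOOP3})
    ref_coords = reference.coords[ref_mask]
    ref_cen = ref_coords.mean(axis=0)
    u3, _ = stem_axis(reference, STEM3)
    # reference frame: polar axis u3, azimuth measured from e1
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, u3)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u3, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u3, e1)

    thetas, phis, tips = [], [], []
    for member in ensemble:
        mob = member.coords[member.atom_mask(regions={STEM3, LOOP3})]
        if mob.shape != ref_coords.shape:
            raise ValueError("ensemble members must share the 3' topology")
        R, t, rmsd = _kabsch(mob, ref_coords)
        if rmsd > rmsd_tol:
            raise ValueError(
                f"3' stem alignment RMSD {rmsd:.2e} Å exceeds {rmsd_tol}; "
                "the stems were not rigid")
        aligned = member.copy()
        aligned.coords = member.coords @ R.T + t
        u5, _ = stem_axis(aligned, STEM5)
        ct = np.clip(np.dot(u5, u3), -1.0, 1.0)
        theta = math.degrees(math.acos(ct))
        if theta < POLE_TOLERANCE_DEG or theta > 180.0 - POLE_TOLERANCE_DEG:
            phi = math.nan
        else:
            phi = math.degrees(math.atan2(np.dot(u5, e2), np.dot(u5, e1)))
        loop_mask = aligned.atom_mask(regions={LOOP5})
        thetas.append(theta)
        phis.append(phi)
        tips.append(aligned.coords[loop_mask].mean(axis=0))
    return np.array(thetas), np.array(phis), np.array(tips)


def _kabsch(mobile: np.ndarray, target: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray, float]:
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    H = (mobile - cm).T @ (target - ct)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    rmsd = math.sqrt(np.mean(np.sum((mobile @ R.T + t - target) ** 2, axis=1)))
    return R, t, rmsd


@dataclass
class KinkAngleDistribution:
    """Solid-angle-corrected kink-angle statistics of a sub-ensemble."""

    angles: np.ndarray         # theta per structure, deg
    azimuths: np.ndarray       # phi per structure, deg (NaN near poles)
    bin_edges: np.ndarray      # deg
    corrected_freq: np.ndarray  # sums to 1
    mean: float                # deg
    sd: float                  # deg
    scenario: str              # "cone" | "sector"
    suggested_scenario: str


def _ring_areas(edges_deg: np.ndarray) -> np.ndarray:
    """Exact area of each spherical ring between consecutive theta edges,
    2 pi (cos(lo) - cos(hi)); regular at the poles by construction."""
    e = np.radians(edges_deg)
    return 2.0 * math.pi * (np.cos(e[:-1]) - np.cos(e[1:]))


def angle_statistics(thetas: np.ndarray,
                     phis: np.ndarray | None = None,
                     bin_width: float = 5.0,
                     scenario: str | None = None) -> KinkAngleDistribution:
    """Corrected histogram and mean/SD of kink angles.

    Each equal-width theta bin's raw frequency is divided by the exact
    ring surface on the unit sphere and renormalized, removing the
    sin-theta bias of uniform orientations.  ``sector`` treats the
    orientations as an axially degenerate ring about the 3' axis (mean =
    corrected-histogram mean polar angle); ``cone`` uses the normalized
    vector sum as mean axis and the corrected histogram of angles about
    it for the SD.  If no scenario is given, ``sector`` is suggested
    unless the vector-sum direction lies within 10 deg of the 3' axis.
    """
    thetas = np.asarray(thetas, dtype=float)
    if thetas.size == 0:
        raise ValueError("no orientations given")
    if phis is None:
        phis = np.full_like(thetas, np.nan)
    edges = np.arange(0.0, 180.0 + bin_width / 2, bin_width)
    if edges[-1] < 180.0:
        edges = np.append(edges, 180.0)

    # orientation unit vectors in the aligned frame (phi NaN -> on-axis)
    tr = np.radians(thetas)
    pr = np.radians(np.where(np.isnan(phis), 0.0, phis))
    vecs = np.column_stack([np.sin(tr) * np.cos(pr),
                            np.sin(tr) * np.sin(pr),
                            np.cos(tr)])
    mean_vec = vecs.mean(axis=0)
    norm = np.linalg.norm(mean_vec)
    axis_angle = (math.degrees(math.acos(np.clip(mean_vec[2] / norm, -1, 1)))
                  if norm > 1e-12 else 0.0)
    on_axis = axis_angle <= 10.0 or axis_angle >= 170.0
    suggested = "sector" if on_axis else "cone"
    if scenario is None:
        scenario = suggested
    if scenario not in ("cone", "sector"):
        raise ValueError("scenario must be 'cone' or 'sector'")

    def corrected(values):
        counts, _ = np.histogram(values, bins=edges)
        freq = counts / _ring_areas(edges)
        total = freq.sum()
        return freq / total if total > 0 else freq

    centers = 0.5 * (edges[:-1] + edges[1:])
    if scenario == "sector":
        freq = corrected(thetas)
        mean = float(np.sum(freq * centers))
        sd = float(math.sqrt(np.sum(freq * (centers - mean) ** 2)))
    else:
        mean_axis = mean_vec / norm
        rel = np.degrees(np.arccos(np.clip(vecs @ mean_axis, -1.0, 1.0)))
        freq = corrected(thetas)
        rel_freq = corrected(rel)
        mean = axis_angle
        sd = float(math.sqrt(np.sum(rel_freq * centers ** 2)))
    return KinkAngleDistribution(
        angles=thetas, azimuths=phis, bin_edges=edges,
        corrected_freq=freq, mean=mean, sd=sd,
        scenario=scenario, suggested_scenario=suggested)
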
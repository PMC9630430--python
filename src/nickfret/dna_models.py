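"""Coarse-grained models of the nicked-DNA dumbbell ligand.

A single DNA strand folds back on itself into two hairpin-capped B-form
stems whose 5' and 3' termini juxtapose in the middle of the molecule,
creating a ligatable single-strand break (nick).  Opposite the nick the
backbone is continuous; this short stretch is the only flexible joint
between the two otherwise rigid stems.

Each nucleotide is represented by three pseudo-atoms (phosphate, sugar,
base centroid) placed on an idealized fiber B-form helix: rise 3.4 Å,
twist 36 deg/bp, base-pair centers on the helix axis, phosphates at
radius 9.4 Å.  Conformational ensembles are generated by rigid-body
re-orientation of the 5' half about the linker phosphate with steric
clash rejection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

# pseudo-atom roles
ROLE_P = 0  # phosphate
ROLE_S = 1  # sugar
ROLE_B = 2  # base centroid
ROLE_NAMES = {ROLE_P: "P", ROLE_S: "S", ROLE_B: "B"}
ROLE_FROM_NAME = {v: k for k, v in ROLE_NAMES.items()}

# cylindrical placement of the pseudo-atoms (radius Å, azimuth offset deg
# relative to the base-pair pseudo-dyad; sign flips between the strands)
RADIUS_P = 9.4
RADIUS_S = 6.9
RADIUS_B = 2.5
AZ_P = 77.0
AZ_S = 60.0
AZ_B = 90.0  # +/-90 deg puts the pair midpoint exactly on the axis

# loop-cap geometry (compact 4-residue arc above the last base pair)
LOOP_RADIUS = {ROLE_P: 7.5, ROLE_S: 6.0, ROLE_B: 4.0}
LOOP_CAP_HEIGHT = 4.5

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

STEM5, LOOP5, STEM3, LOOP3 = "stem5", "loop5", "stem3", "loop3"


class DesignError(ValueError):
    """Raised when a sequence/pairing layout is not a valid dumbbell."""


@dataclass(frozen=True)
class HelixParams:
    rise: float = 3.4      # Å per base pair
    twist: float = 36.0    # deg per base pair


@dataclass(frozen=True)
class SequenceDesign:
    """Sequence plus secondary-structure annotation of a dumbbell ligand.

    ``stem5_pairs`` and ``stem3_pairs`` are 1-based (i, j) base pairs
    ordered from the nick toward the respective tetraloop.  ``loop5`` /
    ``loop3`` are the four unpaired nucleotides of each tetraloop.
    ``acceptor_site`` / ``donor_site`` are the labeled thymidines.
    """

    sequence: str
    stem5_pairs: tuple[tuple[int, int], ...]
    stem3_pairs: tuple[tuple[int, int], ...]
    loop5: tuple[int, int, int, int]
    loop3: tuple[int, int, int, int]
    acceptor_site: int = 18
    donor_site: int = 37

    def __post_init__(self):
        self.validate()

    @property
    def pairings(self) -> tuple[tuple[int, int], ...]:
        return self.stem5_pairs + self.stem3_pairs

    def validate(self) -> None:
        seq = self.sequence.upper()
        n = len(seq)
        if set(seq) - set("ACGT"):
            raise DesignError("sequence contains non-ACGT characters")
        seen: set[int] = set()
        for i, j in self.pairings:
            if not (1 <= i <= n and 1 <= j <= n):
                raise DesignError(f"pair ({i},{j}) outside sequence")
            if i in seen or j in seen:
                raise DesignError(f"index in pair ({i},{j}) used twice")
            seen.update((i, j))
            if _COMPLEMENT[seq[i - 1]] != seq[j - 1]:
                raise DesignError(
                    f"pair ({i},{j}) = {seq[i-1]}-{seq[j-1]} is not Watson-Crick"
                )
        loop_idx = set(self.loop5) | set(self.loop3)
        if seen & loop_idx:
            raise DesignError("loop nucleotides overlap paired nucleotides")
        if seen | loop_idx != set(range(1, n + 1)):
            raise DesignError("stems and loops do not partition the sequence")
        for site, name in ((self.acceptor_site, "acceptor"),
                           (self.donor_site, "donor")):
            if seq[site - 1] != "T":
                raise DesignError(f"{name} label site {site} is not a thymine")

    @classmethod
    def infer(cls, sequence: str, acceptor_site: int = 18,
              donor_site: int = 37) -> "SequenceDesign":
        """Derive the dumbbell layout by self-complementarity scan.

        Tries every split of the strand into two hairpins, each a stem of
        ``k`` base pairs closed by a 4-nt loop, and returns the (unique)
        split for which all pairs are Watson-Crick.
        """
        seq = sequence.upper()
        n = len(seq)
        if (n - 8) % 2:
            raise DesignError("length incompatible with two 4-nt-loop hairpins")
        for k1 in range(4, (n - 8) // 2 - 3):
            k2 = (n - 8) // 2 - k1
            if k2 < 4:
                continue
            b1 = 2 * k1 + 4  # length of the 5' hairpin block
            p5 = tuple((i, b1 + 1 - i) for i in range(1, k1 + 1))
            p3 = tuple((b1 + m, n + 1 - m) for m in range(1, k2 + 1))
            ok = all(_COMPLEMENT[seq[i - 1]] == seq[j - 1] for i, j in p5 + p3)
            if ok:
                return cls(
                    sequence=seq,
                    stem5_pairs=tuple((i, b1 + 1 - i) for i in range(1, k1 + 1)),
                    stem3_pairs=p3,
                    loop5=tuple(range(k1 + 1, k1 + 5)),
                    loop3=tuple(range(b1 + k2 + 1, b1 + k2 + 5)),
                    acceptor_site=acceptor_site,
                    donor_site=donor_site,
                )
        raise DesignError("no self-consistent dumbbell layout found")


# the ligand used throughout: 62-nt dumbbell, acceptor at T18, donor at T37
LIGAND_SEQUENCE = (
    "GCTGGCTGATCGTAAGATCAGCCAGCCGCGGTCGGCTGTCAGCTTGCTGACAGCCGACCGCG"
)


def ligand_design() -> SequenceDesign:
    """Layout of the 62-nt nicked dumbbell (11-bp and 16-bp stems)."""
    return SequenceDesign.infer(LIGAND_SEQUENCE)


@dataclass
class StructureModel:
    """Pseudo-atom model: one row per pseudo-atom.

    ``nuc_index`` (1-based), ``role`` (ROLE_P/S/B), ``coords`` (N, 3) in Å.
    ``stem_assignment`` maps each nucleotide to stem5/loop5/stem3/loop3.
    """

    design: SequenceDesign
    nuc_index: np.ndarray
    role: np.ndarray
    coords: np.ndarray
    stem_assignment: dict[int, str]
    provenance: str = "straight"
    member_id: int | None = None

    def copy(self) -> "StructureModel":
        return StructureModel(self.design, self.nuc_index.copy(),
                              self.role.copy(), self.coords.copy(),
                              dict(self.stem_assignment), self.provenance,
                              self.member_id)

    def atom_mask(self, regions: set[str] | None = None,
                  nucleotides: set[int] | None = None) -> np.ndarray:
        mask = np.ones(len(self.nuc_index), dtype=bool)
        if regions is not None:
            reg = np.array([self.stem_assignment[i] for i in self.nuc_index])
            mask &= np.isin(reg, sorted(regions))
        if nucleotides is not None:
            mask &= np.isin(self.nuc_index, sorted(nucleotides))
        return mask

    def atom_coord(self, nucleotide: int, role: int) -> np.ndarray:
        sel = (self.nuc_index == nucleotide) & (self.role == role)
        idx = np.flatnonzero(sel)
        if len(idx) != 1:
            raise KeyError(f"no unique atom (nt {nucleotide}, role {role})")
        return self.coords[idx[0]]

    @property
    def five_prime_nucleotides(self) -> set[int]:
        return {i for i, s in self.stem_assignment.items() if s in (STEM5, LOOP5)}

    @property
    def three_prime_nucleotides(self) -> set[int]:
        return {i for i, s in self.stem_assignment.items() if s in (STEM3, LOOP3)}

    @property
    def linker_pivot(self) -> np.ndarray:
        """Phosphate bridging the continuous backbone between the stems."""
        first_stem3 = min(i for i, j in self.design.stem3_pairs)
        return self.atom_coord(first_stem3, ROLE_P)


def _cyl(radius: float, az_deg: float, z: float) -> tuple[float, float, float]:
    a = math.radians(az_deg)
    return (radius * math.cos(a), radius * math.sin(a), z)


def build_dumbbell(design: SequenceDesign,
                   helix: HelixParams = HelixParams()) -> StructureModel:
    """Build the straight (coaxial-stem) model of a dumbbell ligand.

    The composite helix runs along z: the 5' stem occupies z > 0, the 3'
    stem z < 0, with the nick (and the continuous linker backbone) at
    z = 0.  Helical phase is continuous across the junction so that the
    intact strand's backbone geometry is preserved.
    """
    rise, twist = helix.rise, helix.twist
    n = len(design.sequence)
    phase = twist / rise  # deg per Å of z

    # per-nucleotide placement: (z, strand sign); strand sign +1 for the
    # continuous strand (runs through the linker), -1 for the nicked strand
    z_of: dict[int, float] = {}
    sign_of: dict[int, int] = {}
    assign: dict[int, str] = {}
    for k, (i, j) in enumerate(design.stem5_pairs, start=1):
        z = (k - 0.5) * rise
        z_of[i], sign_of[i] = z, -1   # nicked strand (starts at 5' terminus)
        z_of[j], sign_of[j] = z, +1   # continuous strand
        assign[i] = assign[j] = STEM5
    for m, (i, j) in enumerate(design.stem3_pairs, start=1):
        z = -(m - 0.5) * rise
        z_of[i], sign_of[i] = z, +1   # continuous strand
        z_of[j], sign_of[j] = z, -1   # nicked strand (ends at 3' terminus)
        assign[i] = assign[j] = STEM3
    for i in design.loop5:
        assign[i] = LOOP5
    for i in design.loop3:
        assign[i] = LOOP3

    nuc_index, role, coords = [], [], []

    def add(i: int, r: int, xyz) -> None:
        nuc_index.append(i)
        role.append(r)
        coords.append(xyz)

    for i in range(1, n + 1):
        if assign[i] in (STEM5, STEM3):
            z, s = z_of[i], sign_of[i]
            az0 = phase * z
            add(i, ROLE_P, _cyl(RADIUS_P, az0 + s * AZ_P, z))
            add(i, ROLE_S, _cyl(RADIUS_S, az0 + s * AZ_S, z))
            add(i, ROLE_B, _cyl(RADIUS_B, az0 + s * AZ_B, z))

    # tetraloop caps: 4 residues on a compact arc between the strand exit
    # (nicked strand, azimuth az0 - AZ_P) and re-entry (continuous strand,
    # azimuth az0 + AZ_P), bulging LOOP_CAP_HEIGHT beyond the last pair
    def add_loop(members: tuple[int, ...], z_end: float, outward: float,
                 az_start: float, az_stop: float) -> None:
        for j, i in enumerate(members, start=1):
            t = j / (len(members) + 1)
            az = az_start + t * (az_stop - az_start)
            z = z_end + outward * LOOP_CAP_HEIGHT * math.sin(math.pi * t)
            for r in (ROLE_P, ROLE_S, ROLE_B):
                add(i, r, _cyl(LOOP_RADIUS[r], az, z))

    k1 = len(design.stem5_pairs)
    z_top = (k1 - 0.5) * rise
    az_top = phase * z_top
    # backbone order inside loop5 runs nicked strand -> continuous strand
    add_loop(design.loop5, z_top, +1.0, az_top - AZ_P, az_top + AZ_P)

    k2 = len(design.stem3_pairs)
    z_bot = -(k2 - 0.5) * rise
    az_bot = phase * z_bot
    # backbone order inside loop3 runs continuous strand -> nicked strand
    add_loop(design.loop3, z_bot, -1.0, az_bot + AZ_P, az_bot - AZ_P)

    order = np.lexsort((np.array(role), np.array(nuc_index)))
    return StructureModel(
        design=design,
        nuc_index=np.array(nuc_index)[order],
        role=np.array(role)[order],
        coords=np.array(coords, dtype=float)[order],
        stem_assignment=assign,
        provenance="straight",
    )


@dataclass(frozen=True)
class EnsembleSpec:
    """Sampling settings for the rigid-body nick ensemble."""

    n_structures: int = 1000
    seed: int = 0
    clash_radius: float = 4.0        # Å between non-bonded pseudo-atoms
    max_rotation_deg: float = 180.0  # 0 -> identity members (no perturbation)
    attempt_budget: int = 200_000

    def __post_init__(self):
        if self.n_structures < 1:
            raise ValueError("n_structures must be >= 1")
        if self.clash_radius <= 0:
            raise ValueError("clash_radius must be > 0")


def clash_check(model: StructureModel, clash_radius: float,
                max_pairs: int = 50) -> tuple[bool, list[tuple[int, int]]]:
    """True iff no 5'-side pseudo-atom lies within ``clash_radius`` of any
    3'-side pseudo-atom.  Cross-pairs between the four junction
    nucleotides -- the covalently linked linker neighbors and the
    juxtaposed (base-stacked) nick termini -- are in native contact in the
    straight model and are excluded from the check."""
    idx5_all = [k for p in model.design.stem5_pairs for k in p]
    idx3_all = [k for p in model.design.stem3_pairs for k in p]
    junction5 = {max(idx5_all), min(idx5_all)}  # linker nt 26, 5' end nt 1
    junction3 = {min(idx3_all), max(idx3_all)}  # linker nt 27, 3' end nt 62
    m5 = model.atom_mask(regions={STEM5, LOOP5})
    m3 = model.atom_mask(regions={STEM3, LOOP3})
    if not m5.any() or not m3.any():
        return True, []
    t5 = cKDTree(model.coords[m5])
    t3 = cKDTree(model.coords[m3])
    pairs = t5.query_ball_tree(t3, r=clash_radius)
    idx5 = np.flatnonzero(m5)
    idx3 = np.flatnonzero(m3)
    offending = []
    for a, hits in enumerate(pairs):
        for b in hits:
            ia, ib = int(idx5[a]), int(idx3[b])
            if (model.nuc_index[ia] in junction5
                    and model.nuc_index[ib] in junction3):
                continue
            offending.append((ia, ib))
    return len(offending) == 0, offending[:max_pairs]


def _random_rotation(rng: np.random.Generator,
                     max_angle_deg: float) -> np.ndarray:
    """Rotation matrix drawn from the Haar measure on SO(3), truncated to
    rotation angle <= max_angle_deg (0 gives the identity)."""
    if max_angle_deg <= 0:
        return np.eye(3)
    amax = math.radians(min(max_angle_deg, 180.0))
    # Haar density of the rotation angle is (1 - cos a) / pi on [0, pi]
    while True:
        a = rng.uniform(0.0, amax)
        if rng.uniform(0.0, 2.0) <= 1.0 - math.cos(a):
            break
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(a) * K + (1 - math.cos(a)) * (K @ K)


def sample_nick_ensemble(
    straight: StructureModel, spec: EnsembleSpec
) -> tuple[list[StructureModel], int]:
    """Rigid-body conformational ensemble of the nicked dumbbell.

    Each member keeps both stems internally identical to the straight
    model and differs only by a uniform random rotation of the whole 5'
    half about the linker phosphate (the pivot), with clash rejection.
    Returns (members, number_of_rejected_attempts).
    """
    rng = np.random.default_rng(spec.seed)
    pivot = straight.linker_pivot
    mask5 = straight.atom_mask(regions={STEM5, LOOP5})
    members: list[StructureModel] = []
    rejected = 0
    attempts = 0
    while len(members) < spec.n_structures:
        if attempts >= spec.attempt_budget:
            raise RuntimeError(
                f"no clash-free member found within {spec.attempt_budget} "
                f"attempts at clash radius {spec.clash_radius} Å"
            )
        attempts += 1
        member = straight.copy()
        if spec.max_rotation_deg > 0:
            R = _random_rotation(rng, spec.max_rotation_deg)
            member.coords[mask5] = (member.coords[mask5] - pivot) @ R.T + pivot
        ok, _ = clash_check(member, spec.clash_radius)
        if not ok:
            rejected += 1
            continue
        member.provenance = (
            f"ensemble-member(seed={spec.seed}, "
            f"max_rotation={spec.max_rotation_deg})"
        )
        member.member_id = len(members)
        members.append(member)
    return members, rejected


# ---------------------------------------------------------------------------
# PDB input/output (pseudo-atoms written as CA-style coarse-grain records)

_CHAIN_OF = {STEM5: "A", LOOP5: "B", STEM3: "C", LOOP3: "D"}
_ATOM_NAME = {ROLE_P: "P", ROLE_S: "S", ROLE_B: "B"}
_ELEMENT = {ROLE_P: "P", ROLE_S: "C", ROLE_B: "N"}


def write_pdb(model: StructureModel, path: str) -> None:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = len(model.nuc_index)
    arr = struc.AtomArray(n)
    arr.coord = model.coords.astype(np.float32)
    arr.chain_id = np.array(
        [_CHAIN_OF[model.stem_assignment[i]] for i in model.nuc_index])
    arr.res_id = model.nuc_index.astype(int)
    arr.res_name = np.array(
        ["D" + model.design.sequence[i - 1] for i in model.nuc_index])
    arr.atom_name = np.array([_ATOM_NAME[r] for r in model.role])
    arr.element = np.array([_ELEMENT[r] for r in model.role])
    arr.hetero = np.zeros(n, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(arr)
    remark = f"REMARK 999 NICKFRET PROVENANCE {model.provenance}"
    pdb.lines = [remark] + pdb.lines
    pdb.write(path)


def read_pdb(path: str, design: SequenceDesign) -> StructureModel:
    """Read a pseudo-atom or all-atom model, mapping atoms to roles.

    All-atom nucleotides are reduced to phosphate (P), sugar (mean of the
    primed ribose atoms) and base centroid (mean of the remaining base
    atoms).  Pseudo-atom files written by :func:`write_pdb` round-trip.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    arr = PDBFile.read(path).get_structure(model=1)
    nuc_index, role, coords = [], [], []
    for res_id in np.unique(arr.res_id):
        sub = arr[arr.res_id == res_id]
        names = sub.atom_name
        if set(names) <= {"P", "S", "B"}:  # our own coarse format
            for nm, r in (("P", ROLE_P), ("S", ROLE_S), ("B", ROLE_B)):
                sel = sub[names == nm]
                if len(sel):
                    nuc_index.append(int(res_id))
                    role.append(r)
                    coords.append(sel.coord[0])
            continue
        p = sub[names == "P"]
        sugar = sub[np.array(["'" in nm for nm in names])]
        base = sub[np.array(["'" not in nm and nm not in ("P", "OP1", "OP2")
                             for nm in names])]
        for sel, r in ((p, ROLE_P), (sugar, ROLE_S), (base, ROLE_B)):
            if len(sel):
                nuc_index.append(int(res_id))
                role.append(r)
                coords.append(sel.coord.mean(axis=0))
    # reconstruct stem assignment from the design
    assign: dict[int, str] = {}
    for i, j in design.stem5_pairs:
        assign[i] = assign[j] = STEM5
    for i, j in design.stem3_pairs:
        assign[i] = assign[j] = STEM3
    for i in design.loop5:
        assign[i] = LOOP5
    for i in design.loop3:
        assign[i] = LOOP3
    return StructureModel(
        design=design,
        nuc_index=np.array(nuc_index),
        role=np.array(role),
        coords=np.array(coords, dtype=float),
        stem_assignment=assign,
        provenance=f"read:{path}",
    )
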
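"""Geometric protein-DNA interaction detectors and occupancy accounting.

Hydrogen bonds are detected from donor/acceptor heavy-atom geometry using
residue role templates; cation-π and methyl-π contacts from ring-centroid
distance and ring-normal angle; van der Waals contacts as heavy-atom pairs
within a cutoff.  Occupancies are satisfied-frame fractions over a declared
window, and per residue-nucleotide "total HB numbers" are sums of
donor-acceptor pair occupancies (so a total may exceed 1).

Numeric criteria (donor-acceptor cutoff 3.5 Å, D-H...A angle >= 135 deg,
cation-π 6.0 Å / methyl-π 4.6 Å with a 45 deg ring-normal cone) are
conventional trajectory-analysis defaults and are all configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateGeometryError, PorescanError
from .trajio import (
    DNA_RESNAMES,
    BASE_ATOM_NAMES,
    TimeSeries,
    Topology,
    Trajectory,
)

__all__ = [
    "HBondCriterion",
    "HBondPairOccupancy",
    "ResidueNucleotideHBTotal",
    "PiContact",
    "assign_roles",
    "detect_hbonds",
    "hbond_occupancy",
    "total_hb_number",
    "panel_total",
    "pi_contact_series",
    "vdw_contact_series",
    "is_abolished",
]

VDW_CONTACT_CUTOFF = 4.5      # Å, heavy-atom contact distance
CATION_PI_CUTOFF = 6.0        # Å, cation to ring centroid
METHYL_PI_CUTOFF = 4.6        # Å, methyl carbon to ring centroid
PI_AXIS_MAX_ANGLE = 45.0      # deg, ring normal vs centroid->atom vector


# ---------------------------------------------------------------------------
# donor / acceptor role templates
# ---------------------------------------------------------------------------

# side-chain donors per residue template (atom names)
_PROTEIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"},
    "TYR": {"OH"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "CYS": {"SG"},
}
_PROTEIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
    "MET": {"SD"},
}
_DNA_BACKBONE_ACCEPTORS = {"OP1", "OP2", "OP3", "O5'", "O3'", "O4'"}
_DNA_BASE_DONORS = {
    "DA": {"N6"}, "DT": {"N3"}, "DG": {"N1", "N2"}, "DC": {"N4"},
}
_DNA_BASE_ACCEPTORS = {
    "DA": {"N1", "N3", "N7"},
    "DT": {"O2", "O4"},
    "DG": {"O6", "N3", "N7"},
    "DC": {"O2", "N3"},
}
# the 6-4PP lesion residue: both rings' O2/O4 (and ring N3) act as
# acceptors, N3-H as donor, addressed through the 5T/3T name prefixes
_LESION_DONORS = {"5TN3", "3TN3"}
_LESION_ACCEPTORS = {"5TO2", "5TO4", "3TO2", "3TO4", "5TN1", "3TN1"}


def _atom_roles(top: Topology, i: int) -> tuple[bool, bool]:
    """(is_donor, is_acceptor) for atom i from the residue templates."""
    name = top.names[i]
    resname = top.resnames[i]
    if resname == "T64":
        if name in _LESION_DONORS:
            return True, False
        if name in _LESION_ACCEPTORS:
            return False, True
        if name in _DNA_BACKBONE_ACCEPTORS:
            return False, True
        return False, False
    if resname in DNA_RESNAMES:
        base = resname.rstrip("35")
        don = name in _DNA_BASE_DONORS.get(base, set())
        acc = (name in _DNA_BACKBONE_ACCEPTORS
               or name in _DNA_BASE_ACCEPTORS.get(base, set()))
        return don, acc
    # protein: backbone amide N donates, carbonyl O accepts
    don = name == "N" or name in _PROTEIN_DONORS.get(resname, set())
    acc = name in ("O", "OXT") or name in _PROTEIN_ACCEPTORS.get(resname, set())
    return don, acc


def assign_roles(
    top: Topology, atoms: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Split candidate atoms into donors and acceptors via the templates.

    Atoms matching no template are excluded with a warning, never silently
    promoted to a role.
    """
    donors, acceptors, unknown = [], [], []
    for i in np.asarray(atoms, dtype=int):
        don, acc = _atom_roles(top, int(i))
        if don:
            donors.append(int(i))
        if acc:
            acceptors.append(int(i))
        if not don and not acc and top.elements[i] in ("N", "O", "S"):
            unknown.append(top.names[i])
    if unknown:
        warnings.warn(
            f"no donor/acceptor template for atoms {sorted(set(unknown))}; "
            "excluded from hydrogen-bond detection",
            stacklevel=2,
        )
    return np.array(donors, dtype=int), np.array(acceptors, dtype=int)


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond criterion.

    ``hydrogen_mode``: ``explicit`` uses real D-H...A angles; ``inferred``
    places the hydrogen on the D->A axis at 1.0 Å so the angle test passes
    trivially and the check reduces to the donor-acceptor distance;
    ``auto`` picks explicit when the topology contains hydrogens.
    """

    da_cutoff: float = 3.5
    dha_min_angle: float = 135.0
    hydrogen_mode: str = "auto"

    def __post_init__(self):
        if self.da_cutoff <= 0:
            raise ValueError("da_cutoff must be positive")
        if not (0 <= self.dha_min_angle <= 180):
            raise ValueError("dha_min_angle must be within [0, 180] degrees")
        if self.hydrogen_mode not in ("explicit", "inferred", "auto"):
            raise ValueError(f"unknown hydrogen_mode {self.hydrogen_mode!r}")

    def resolved_mode(self, top: Topology) -> str:
        if self.hydrogen_mode != "auto":
            return self.hydrogen_mode
        return "explicit" if (top.elements == "H").any() else "inferred"


@dataclass(frozen=True)
class HBondPairOccupancy:
    donor: int
    acceptor: int
    occupancy: float

    def __post_init__(self):
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError("occupancy must lie in [0, 1]")


@dataclass(frozen=True)
class ResidueNucleotideHBTotal:
    """Summed pair occupancies for one residue-nucleotide-moiety group."""

    residue: int
    nucleotide: int
    moiety: str  # backbone | base
    total_hb: float
    n_pairs: int


@dataclass
class PiContact:
    """A cation-π or methyl-π contact series."""

    kind: str
    atom: int
    ring_residue: int
    ring_atoms: np.ndarray
    distances: TimeSeries
    satisfied: np.ndarray
    satisfied_fraction: float

    def __post_init__(self):
        if not (0.0 <= self.satisfied_fraction <= 1.0):
            raise ValueError("satisfied_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def _donor_hydrogens(top: Topology, coords: np.ndarray, donor: int):
    """Hydrogens covalently attached to a donor (same residue, <= 1.25 Å)."""
    same_res = np.flatnonzero(
        (top.resids == top.resids[donor]) & (top.elements == "H")
    )
    if same_res.size == 0:
        return same_res
    d = np.linalg.norm(coords[same_res] - coords[donor], axis=1)
    return same_res[d <= 1.25]


def detect_hbonds(
    topology: Topology,
    coords: np.ndarray,
    donors: np.ndarray,
    acceptors: np.ndarray,
    criterion: HBondCriterion | None = None,
) -> list[tuple[int, int]]:
    """Donor-acceptor pairs satisfying the geometric criterion in one frame.

    A pair is satisfied iff the D-A heavy-atom distance is <= ``da_cutoff``
    and, in explicit-hydrogen mode, some attached hydrogen gives a D-H...A
    angle >= ``dha_min_angle``.  Intra-residue pairs are never reported.
    """
    criterion = criterion or HBondCriterion()
    donors = np.asarray(donors, dtype=int)
    acceptors = np.asarray(acceptors, dtype=int)
    if donors.size == 0 or acceptors.size == 0:
        return []
    mode = criterion.resolved_mode(topology)
    dmat = cdist(coords[donors], coords[acceptors])
    out: list[tuple[int, int]] = []
    for di, d_idx in enumerate(donors):
        for ai, a_idx in enumerate(acceptors):
            if d_idx == a_idx:
                continue
            if topology.resids[d_idx] == topology.resids[a_idx]:
                continue
            if dmat[di, ai] > criterion.da_cutoff:
                continue
            if mode == "explicit":
                hyds = _donor_hydrogens(topology, coords, int(d_idx))
                if hyds.size == 0:
                    continue
                hd = coords[int(d_idx)] - coords[hyds]          # H->D
                ha = coords[int(a_idx)] - coords[hyds]          # H->A
                cosang = np.sum(hd * ha, axis=1) / (
                    np.linalg.norm(hd, axis=1) * np.linalg.norm(ha, axis=1)
                )
                ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if not (ang >= criterion.dha_min_angle).any():
                    continue
            out.append((int(d_idx), int(a_idx)))
    return out


def hbond_occupancy(
    traj: Trajectory,
    donors: np.ndarray,
    acceptors: np.ndarray,
    criterion: HBondCriterion | None = None,
    window: tuple[float, float] | None = None,
) -> list[HBondPairOccupancy]:
    """Satisfied-frame fraction per donor-acceptor pair over a window.

    Pairs never satisfied in the window are omitted.  Results are ordered
    by (donor, acceptor) atom index.
    """
    criterion = criterion or HBondCriterion()
    frames = (traj.window_indices(window) if window is not None
              else np.arange(traj.n_frames))
    if frames.size == 0:
        raise PorescanError("window contains no frames")
    counts: dict[tuple[int, int], int] = {}
    for f in frames:
        for pair in detect_hbonds(traj.topology, traj.coords[f],
                                  donors, acceptors, criterion):
            counts[pair] = counts.get(pair, 0) + 1
    n = float(frames.size)
    return [
        HBondPairOccupancy(d, a, counts[(d, a)] / n)
        for d, a in sorted(counts)
    ]


def _moiety_of(top: Topology, atom: int) -> str:
    name = top.names[atom]
    if name in BASE_ATOM_NAMES or name[:2] in ("5T", "3T"):
        return "base"
    return "backbone"


def total_hb_number(
    topology: Topology,
    occupancies: list[HBondPairOccupancy],
) -> list[ResidueNucleotideHBTotal]:
    """Sum pair occupancies within each residue x nucleotide x moiety group.

    Every pair must involve exactly one protein atom and one DNA atom; the
    moiety (backbone | base) is that of the DNA-side atom.  A total is the
    plain sum of its member occupancies and may exceed 1.
    """
    groups: dict[tuple[int, int, str], list[float]] = {}
    for occ in occupancies:
        sides = [occ.donor, occ.acceptor]
        dna = [i for i in sides if topology.is_dna_atom(i)]
        prot = [i for i in sides if not topology.is_dna_atom(i)]
        if len(dna) != 1 or len(prot) != 1:
            names = [f"{topology.resnames[i]}{topology.resids[i]}:"
                     f"{topology.names[i]}" for i in sides]
            raise PorescanError(
                f"pair {names[0]} - {names[1]} does not map to exactly one "
                "protein residue and one nucleotide"
            )
        key = (
            int(topology.resids[prot[0]]),
            int(topology.resids[dna[0]]),
            _moiety_of(topology, dna[0]),
        )
        groups.setdefault(key, []).append(occ.occupancy)
    return [
        ResidueNucleotideHBTotal(res, nuc, moi, float(sum(vals)), len(vals))
        for (res, nuc, moi), vals in sorted(groups.items())
    ]


def panel_total(
    totals: list[ResidueNucleotideHBTotal],
    residues: set[int] | None = None,
    nucleotides: set[int] | None = None,
    moiety: str | None = None,
) -> float:
    """Sum of group totals over a residue list / nucleotide list / moiety,
    mirroring the per-panel total-HB numbers of the interaction schematics."""
    total = 0.0
    for t in totals:
        if residues is not None and t.residue not in residues:
            continue
        if nucleotides is not None and t.nucleotide not in nucleotides:
            continue
        if moiety is not None and t.moiety != moiety:
            continue
        total += t.total_hb
    return total


# ---------------------------------------------------------------------------
# pi and van der Waals contacts
# ---------------------------------------------------------------------------

def _ring_geometry(ring_coords: np.ndarray):
    """Ring centroid and unit normal (SVD plane fit); collinear -> error."""
    centroid = ring_coords.mean(axis=0)
    centered = ring_coords - centroid
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise DegenerateGeometryError("ring atoms are collinear; no normal")
    _, _, vt = np.linalg.svd(centered)
    return centroid, vt[2]


def pi_contact_series(
    traj: Trajectory,
    kind: str,
    atom: int,
    ring_atoms: np.ndarray,
    cutoff: float | None = None,
    max_angle: float = PI_AXIS_MAX_ANGLE,
) -> PiContact:
    """Cation-π or methyl-π contact between one atom and an aromatic ring.

    A frame is satisfied iff the atom lies within ``cutoff`` of the ring
    centroid and within ``max_angle`` of the ring normal (the axial cone
    that excludes in-plane approaches).
    """
    if kind not in ("cation_pi", "methyl_pi"):
        raise ValueError(f"unknown pi-contact kind {kind!r}")
    ring_atoms = np.asarray(ring_atoms, dtype=int)
    if ring_atoms.size < 5:
        raise ValueError("ring needs at least 5 atoms")
    top = traj.topology
    name = top.names[atom]
    if kind == "cation_pi" and name not in ("CZ", "NZ"):
        raise ValueError(
            f"cation-pi atom must be Arg CZ or Lys NZ, got {name!r}"
        )
    if kind == "methyl_pi" and top.elements[atom] != "C":
        raise ValueError("methyl-pi atom must be a carbon")
    if cutoff is None:
        cutoff = CATION_PI_CUTOFF if kind == "cation_pi" else METHYL_PI_CUTOFF

    dists = np.empty(traj.n_frames)
    satisfied = np.zeros(traj.n_frames, dtype=bool)
    for f in range(traj.n_frames):
        centroid, normal = _ring_geometry(traj.coords[f, ring_atoms])
        v = traj.coords[f, atom] - centroid
        dist = float(np.linalg.norm(v))
        dists[f] = dist
        if dist > cutoff or dist == 0.0:
            continue
        cosang = abs(float(np.dot(v / dist, normal)))  # normal sign-free
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        satisfied[f] = angle <= max_angle
    return PiContact(
        kind=kind,
        atom=int(atom),
        ring_residue=int(top.resids[ring_atoms[0]]),
        ring_atoms=ring_atoms,
        distances=TimeSeries(traj.times.copy(), dists,
                             name=f"{kind}_centroid_distance", units="Å"),
        satisfied=satisfied,
        satisfied_fraction=float(satisfied.mean()),
    )


def vdw_contact_series(
    traj: Trajectory,
    group_a: np.ndarray,
    group_b: np.ndarray,
    cutoff: float = VDW_CONTACT_CUTOFF,
) -> TimeSeries:
    """Per-frame count of heavy-atom cross pairs within the contact cutoff."""
    heavy = traj.topology.heavy_mask()
    ga = np.asarray(group_a, dtype=int)
    gb = np.asarray(group_b, dtype=int)
    ga = ga[heavy[ga]]
    gb = gb[heavy[gb]]
    if ga.size == 0 or gb.size == 0:
        raise ValueError("both groups need at least one heavy atom")
    counts = np.array([
        int((cdist(traj.coords[f, ga], traj.coords[f, gb]) <= cutoff).sum())
        for f in range(traj.n_frames)
    ], dtype=float)
    return TimeSeries(traj.times.copy(), counts,
                      name="vdw_contacts", units="count")


def is_abolished(series: TimeSeries, window: tuple[float, float]) -> bool:
    """Contacts count as abolished when the windowed mean drops below 1."""
    mask = (series.times >= window[0]) & (series.times <= window[1])
    if not mask.any():
        raise PorescanError("window contains no frames")
    return float(series.values[mask].mean()) < 1.0
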
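"""Synthetic pore-ssDNA trajectories with planted, analytically known events.

The generator emulates the three-domain entry-pore scaffold of an XPD-type
helicase: rigid FeS, Arch and ATPase-lobe-1 pseudo-domain clusters carrying
the named pore residues (R112, K128, H135, ..., R380, N402) with Cα and
minimal side-chain pseudo-atoms, plus a 4-nt ssDNA track (dA0-dT3, or a T64
6-4PP lesion variant) at ideal B-form spacing.  By construction the
reference frame reproduces the cryo-EM-derived pore geometry: a
Cα(H135)-Cα(L220) width of 16.7 Å and a 2.8 Å closest approach between the
R380 side chain and D219/L220.

Scripted events move designated atoms along linear 50-frame transitions:

* ``hop`` - the tracked nucleotide's phosphate steps exactly one B-form
  P-P spacing (7.0 Å) along the strand axis (backbone translocation);
* ``base_flip`` - the base ring translates into the pore prism while the
  phosphate stays put (base translocation);
* ``pore_open`` / ``pore_close`` - the lobe-1 helix translates 3.6 Å away
  from / back toward the FeS helix (the 20.3 - 16.7 Å width change);
* entrapment scenarios schedule no event.

Planted hydrogen-bond occupancies are realised per frame by Bernoulli
draws: the designated donor pseudo-atom is placed at 2.9 Å from the (noise-
perturbed) acceptor on satisfied frames and at 5.2 Å otherwise, so the
empirical satisfied fraction is an exact binomial realisation of the
planted probability even under coordinate noise.  Gaussian noise of
``noise_sigma`` Å is added independently per coordinate per frame to all
other atoms.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ScheduleConflictError
from .geometry import BFormParams, helix_points
from .trajio import Topology, Trajectory, resolve_selection, write_pdb, write_xyz
from .translocation import PoreConfig

__all__ = [
    "ScenarioSpec",
    "Event",
    "PlantedHBond",
    "ContactEpoch",
    "GroundTruth",
    "generate_scaffold",
    "generate_trajectory",
    "write_fixture_set",
    "default_fixture_specs",
]

SCENARIO_KINDS = (
    "backbone_translocation", "base_flip", "entrapment",
    "pore_open_close", "custom",
)

#: scenario kind -> behavior label the pipeline should recover
KIND_LABELS = {
    "backbone_translocation": "backbone_translocation",
    "base_flip": "base_translocation",
    "entrapment": "blocked",
    "pore_open_close": "blocked",
    "custom": "blocked",
}

PORE_WIDTH = 16.7          # Å, planted Cα(H135)-Cα(L220)
CLOSEST_APPROACH = 2.8     # Å, planted R380 side chain to D219/L220
PORE_OPENING = 3.6         # Å, lobe-1 displacement on pore_open (20.3-16.7)
HELIX_AXIS = (3.8, 0.3)    # xy of the DNA axis, near the pore-prism centroid

_HBOND_ON_DIST = 2.9
_HBOND_OFF_DIST = 5.2
_CONTACT_ON_DIST = 3.0


@dataclass(frozen=True)
class Event:
    """A scripted conformational event starting at ``time_ns``."""

    kind: str  # hop | base_flip | pore_open | pore_close
    time_ns: float


@dataclass(frozen=True)
class PlantedHBond:
    """A donor-acceptor pair with a planted per-frame satisfaction
    probability (the occupancy the detector should recover)."""

    donor_resid: int
    donor_name: str
    acceptor_resid: int
    acceptor_name: str
    occupancy: float

    def __post_init__(self):
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError("planted occupancy must lie in [0, 1]")


@dataclass(frozen=True)
class ContactEpoch:
    """Planted contact intervals for one residue-nucleotide pair.

    During each (t_on, t_off) interval the residue's CM marker atom sits
    3.0 Å from the nucleotide's phosphate, creating a heavy-atom contact;
    outside the intervals it rests on a perch far from the DNA.
    """

    residue: int
    nucleotide: int
    intervals: tuple[tuple[float, float], ...]


@dataclass(frozen=True)
class ScenarioSpec:
    """Complete recipe for one synthetic replica."""

    kind: str = "entrapment"
    n_frames: int = 200
    frame_interval_ns: float = 10.0
    noise_sigma: float = 0.5
    seed: int = 0
    transition_frames: int = 50
    event_schedule: tuple[Event, ...] | None = None
    planted_hbonds: tuple[PlantedHBond, ...] = ()
    contact_epochs: tuple[ContactEpoch, ...] = ()
    lesion: bool = False
    tracked_nucleotide: int = 1

    def __post_init__(self):
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(
                f"unknown scenario kind {self.kind!r}; "
                f"allowed: {', '.join(SCENARIO_KINDS)}"
            )
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        t_max = (self.n_frames - 1) * self.frame_interval_ns
        for ev in self.event_schedule or ():
            if not (0 <= ev.time_ns <= t_max):
                raise ValueError(
                    f"event at {ev.time_ns} ns outside trajectory [0, {t_max}]"
                )

    @property
    def duration_ns(self) -> float:
        return (self.n_frames - 1) * self.frame_interval_ns

    def resolved_events(self) -> tuple[Event, ...]:
        if self.event_schedule is not None:
            return self.event_schedule
        t = self.duration_ns
        if self.kind == "backbone_translocation":
            return (Event("hop", 0.3 * t),)
        if self.kind == "base_flip":
            return (Event("base_flip", 0.3 * t),)
        if self.kind == "pore_open_close":
            return (Event("pore_open", 0.5 * t),)
        return ()


@dataclass
class GroundTruth:
    """What the generator planted, for verifying the pipeline against."""

    label: str
    stage_boundaries: list[float]
    planted_displacements: dict
    planted_occupancies: dict
    pore_width_initial: float
    pore_width_final: float
    closest_approach: float
    event_times: dict
    seed: int

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "stage_boundaries": self.stage_boundaries,
            "planted_displacements": self.planted_displacements,
            "planted_occupancies": self.planted_occupancies,
            "pore_width_initial": self.pore_width_initial,
            "pore_width_final": self.pore_width_final,
            "closest_approach": self.closest_approach,
            "event_times": self.event_times,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**d)


# ---------------------------------------------------------------------------
# scaffold construction
# ---------------------------------------------------------------------------

def _hexagon(center, normal_axis="z", radius=1.4, names=None, element="C"):
    """Six ring pseudo-atoms around a centroid in the plane normal to an axis."""
    center = np.asarray(center, dtype=float)
    ang = np.deg2rad(np.arange(6) * 60.0)
    if normal_axis == "z":
        offs = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(6)])
    elif normal_axis == "y":
        offs = np.column_stack([np.cos(ang), np.zeros(6), np.sin(ang)])
    else:
        offs = np.column_stack([np.zeros(6), np.cos(ang), np.sin(ang)])
    return [(n, element if not n.startswith(("N", "O")) else n[0],
             center + radius * o) for n, o in zip(names, offs)]


def _pentagon(center, normal_axis="y", radius=1.15, names=None):
    center = np.asarray(center, dtype=float)
    ang = np.deg2rad(np.arange(5) * 72.0)
    if normal_axis == "y":
        offs = np.column_stack([np.cos(ang), np.zeros(5), np.sin(ang)])
    else:
        offs = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(5)])
    return [(n, n[0], center + radius * o) for n, o in zip(names, offs)]


_HIS_RING = ("CG", "ND1", "CE1", "NE2", "CD2")
_PHE_RING = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")


def _protein_residues(width: float, closest: float):
    """(resid, resname, domain, atoms[(name, element, xyz)]) for the three
    pseudo-domain clusters.  Planted geometry is exact by construction."""
    half = width / 2.0
    ca = {
        # FeS cluster (+y side)
        112: ("ARG", (-4.0, 11.0, -1.0)),
        128: ("LYS", (3.0, 10.0, 2.0)),
        135: ("HIS", (0.0, half, 0.0)),
        139: ("ALA", (2.0, 9.0, -2.5)),
        140: ("SER", (4.5, 9.5, -0.5)),
        141: ("TYR", (6.0, 10.5, 1.5)),
        158: ("TYR", (-6.0, 9.5, 2.0)),
        161: ("PHE", (-7.5, 10.5, -0.5)),
        192: ("TYR", (-3.0, 9.0, 3.5)),
        193: ("PHE", (-1.5, 10.5, 4.5)),
        196: ("ARG", (-5.0, 8.5, -3.0)),
        # ATPase lobe 1 helix (-y side), residues 215-221 (PKIADLV)
        215: ("PRO", (-4.5, -9.0, 1.0)),
        216: ("LYS", (-3.0, -9.5, -0.5)),
        217: ("ILE", (-1.5, -10.0, 1.0)),
        218: ("ALA", (1.5, -9.0, -1.0)),
        219: ("ASP", (3.0, -8.8, 0.5)),
        220: ("LEU", (0.0, -half, 0.0)),
        221: ("VAL", (4.5, -9.5, -0.8)),
        # Arch cluster (+x side)
        377: ("GLU", (10.0, 1.5, 1.0)),
        380: ("ARG", (9.0, -1.5, 0.0)),
        384: ("HIS", (11.0, 3.0, -1.5)),
        402: ("ASN", (12.5, 0.0, 2.0)),
    }

    def domain_of(resid):
        if resid < 200:
            return "FeS"
        if resid < 350:
            return "ATPase1"
        return "Arch"

    residues = []
    cb_l220 = np.array([0.8, -half + 1.05, 0.3])
    for resid in sorted(ca):
        resname, pos = ca[resid]
        pos = np.array(pos, dtype=float)
        ysign = 1.0 if pos[1] >= 0 else -1.0
        atoms = [
            ("N", "N", pos + np.array([-0.6, 1.2 * ysign, 0.3])),
            ("CA", "C", pos),
            ("O", "O", pos + np.array([1.1, 0.8 * ysign, 0.5])),
        ]
        if resname == "ARG" and resid == 380:
            # side chain planted to touch L220 CB at exactly `closest` Å
            v = pos - cb_l220
            u = v / np.linalg.norm(v)
            nh1 = cb_l220 + closest * u
            cz = cb_l220 + (closest + 1.3) * u
            ne = cb_l220 + (closest + 2.7) * u
            atoms += [
                ("NE", "N", ne),
                ("CZ", "C", cz),
                ("NH1", "N", nh1),
                ("NH2", "N", cz + np.array([0.8, 1.0, 0.9])),
            ]
        elif resname == "ARG":
            cz = pos + np.array([0.5, -2.2 * ysign, 0.2])
            atoms += [
                ("NE", "N", pos + np.array([0.3, -1.2 * ysign, 0.1])),
                ("CZ", "C", cz),
                ("NH1", "N", cz + np.array([1.0, -0.7 * ysign, 0.3])),
                ("NH2", "N", cz + np.array([-1.0, -0.7 * ysign, -0.3])),
            ]
        elif resname == "LYS":
            atoms.append(("NZ", "N", pos + np.array([0.5, -1.9 * ysign, -0.5])))
        elif resname == "HIS":
            center = pos + np.array([0.0, -1.55 * ysign, 0.0]) \
                if resid == 135 else pos + np.array([-1.5, 0.0, 0.0])
            axis = "y" if resid == 135 else "z"
            atoms += _pentagon(center, normal_axis=axis, names=_HIS_RING)
        elif resname in ("TYR", "PHE"):
            center = pos + np.array([0.0, -2.0 * ysign, 0.0])
            atoms += _hexagon(center, normal_axis="z", names=_PHE_RING)
            if resname == "TYR":
                atoms.append(("OH", "O",
                              center + np.array([0.0, -2.4 * ysign, 0.0])))
        elif resname == "SER":
            atoms.append(("OG", "O", pos + np.array([0.4, -1.3 * ysign, 0.2])))
        elif resname == "ASP":
            # points away from the pore so the planted R380 closest
            # approach at L220 CB stays the unique minimum
            atoms += [
                ("CG", "C", pos + np.array([0.2, -1.1, 0.1])),
                ("OD1", "O", pos + np.array([-0.3, -1.5, 1.0])),
                ("OD2", "O", pos + np.array([0.9, -1.2, -0.9])),
            ]
        elif resname == "GLU":
            atoms += [
                ("CD", "C", pos + np.array([0.2, -1.4 * ysign, 0.1])),
                ("OE1", "O", pos + np.array([-0.4, -1.9 * ysign, 0.9])),
                ("OE2", "O", pos + np.array([1.0, -1.6 * ysign, -0.8])),
            ]
        elif resname == "ASN":
            atoms += [
                ("CG", "C", pos + np.array([0.2, -1.2 * ysign, 0.1])),
                ("OD1", "O", pos + np.array([-0.3, -1.7 * ysign, 0.8])),
                ("ND2", "N", pos + np.array([0.9, -1.5 * ysign, -0.7])),
            ]
        elif resname in ("ALA", "PRO", "ILE", "VAL"):
            # fixed -y so the lobe-1 CB atoms stay clear of the planted
            # R380-L220 closest approach
            atoms.append(("CB", "C", pos + np.array([0.0, -1.5, 0.0])))
        if resname == "LEU" and resid == 220:
            atoms += [
                ("CB", "C", cb_l220),
                ("CD1", "C", pos + np.array([0.2, 1.85 * 1.0, -0.7])),
            ]
        # contact-marker pseudo-atom, perched well away from the DNA
        atoms.append(("CM", "C", pos + np.array([0.0, 0.0, 6.0])))
        residues.append((resid, resname, domain_of(resid), atoms))
    return residues


_PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")


def _dna_residues(lesion: bool, params: BFormParams):
    """ssDNA track pseudo-atoms on an ideal B-form helix along -z.

    Nucleotide k sits at helix step k; the 5' terminus (dA0) carries no
    phosphate.  The lesion variant replaces dT1 with a single T64 residue
    whose two crosslinked thymine rings carry 5T/3T atom-name prefixes.
    """
    n = 4
    origin = (HELIX_AXIS[0], HELIX_AXIS[1], -6.7)
    p_pos = helix_points(n, params.twist, params.rise, params.p_radius,
                         phase_deg=90.0, origin=origin, axis_z_sign=-1.0)
    sugar = helix_points(n, params.twist, params.rise, 7.0,
                         phase_deg=100.0, origin=origin, axis_z_sign=-1.0)
    base_c = helix_points(n, params.twist, params.rise, 4.0,
                          phase_deg=110.0, origin=origin, axis_z_sign=-1.0)

    def pyrimidine_atoms(center, prefix=""):
        names = tuple(prefix + nm for nm in _PYRIMIDINE_RING)
        atoms = _hexagon(center, normal_axis="z", radius=1.3, names=names)
        atoms = [(nm, nm[len(prefix)], xyz) for nm, _, xyz in atoms]
        radial = center - np.array([HELIX_AXIS[0], HELIX_AXIS[1], center[2]])
        radial = radial / np.linalg.norm(radial)
        atoms += [
            (prefix + "O2", "O", center + 2.3 * radial),
            (prefix + "O4", "O", center - 2.3 * radial),
            (prefix + "C7", "C", center + np.array([0.0, 0.0, 1.6])),
        ]
        return atoms

    residues = []
    for k in range(n):
        atoms = []
        if k > 0:
            atoms += [
                ("P", "P", p_pos[k]),
                ("OP1", "O", p_pos[k] + np.array([0.0, 0.0, 1.75])),
                ("OP2", "O", p_pos[k] + np.array([0.0, 0.0, -1.75])),
            ]
        atoms.append(("C4'", "C", sugar[k]))
        if k == 0:
            names = _PYRIMIDINE_RING  # purine modelled as one 6-ring
            ring = _hexagon(base_c[k], normal_axis="z", radius=1.3,
                            names=names)
            atoms += [(nm, nm[0], xyz) for nm, _, xyz in ring]
            residues.append((k, "DA", "DNA", atoms))
        elif k == 1 and lesion:
            atoms += pyrimidine_atoms(base_c[k], prefix="5T")
            atoms += pyrimidine_atoms(
                base_c[k] + np.array([0.0, 0.0, -1.8]), prefix="3T")
            residues.append((k, "T64", "DNA", atoms))
        else:
            atoms += pyrimidine_atoms(base_c[k])
            residues.append((k, "DT", "DNA", atoms))
    return residues


def generate_scaffold(
    lesion: bool = False,
    width: float = PORE_WIDTH,
    closest_approach: float = CLOSEST_APPROACH,
    bform: BFormParams | None = None,
) -> tuple[Topology, np.ndarray]:
    """Build the pseudo-atom pore scaffold and its reference coordinates.

    The returned frame reproduces, by construction, the planted reference
    geometry: ``width`` between Cα(H135) and Cα(L220) and
    ``closest_approach`` between the R380 side chain and D219/L220.
    """
    bform = bform or BFormParams()
    residues = _protein_residues(width, closest_approach)
    residues += _dna_residues(lesion, bform)

    names, elements, resnames, resids, chains, coords = [], [], [], [], [], []
    domain_ranges = {"FeS": (100, 199), "ATPase1": (200, 349),
                     "Arch": (350, 450), "DNA": (0, 10)}
    for resid, resname, domain, atoms in residues:
        for name, element, xyz in atoms:
            names.append(name)
            elements.append(element)
            resnames.append(resname)
            resids.append(resid)
            chains.append("D" if domain == "DNA" else "A")
            coords.append(np.asarray(xyz, dtype=float))
    topology = Topology(
        names=np.array(names),
        elements=np.array(elements),
        resnames=np.array(resnames),
        resids=np.array(resids, dtype=int),
        chains=np.array(chains),
        domain_map=tuple((lo, hi, tag) for tag, (lo, hi)
                         in domain_ranges.items()),
        lesion_residues=frozenset({1}) if lesion else frozenset(),
    )
    ref = np.array(coords, dtype=float)

    # construction self-checks (planted geometry must be exact)
    ca135 = ref[resolve_selection(topology, "name CA and resid 135")[0]]
    ca220 = ref[resolve_selection(topology, "name CA and resid 220")[0]]
    assert abs(np.linalg.norm(ca135 - ca220) - width) < 1e-9
    side = resolve_selection(topology, "resid 380 and not name N CA C O CM")
    near = resolve_selection(topology, "resid 219 220")
    helix = resolve_selection(topology, "resid 215-221")
    from scipy.spatial.distance import cdist

    assert abs(cdist(ref[side], ref[near]).min() - closest_approach) < 1e-9
    assert abs(cdist(ref[side], ref[helix]).min() - closest_approach) < 1e-9
    return topology, ref


# ---------------------------------------------------------------------------
# trajectory generation
# ---------------------------------------------------------------------------

def _event_atoms(spec: ScenarioSpec, topology: Topology, kind: str):
    nuc = spec.tracked_nucleotide
    if kind == "hop":
        return resolve_selection(
            topology, f"resid {nuc} and name P OP1 OP2")
    if kind == "base_flip":
        return resolve_selection(topology, f"resid {nuc} and base")
    if kind in ("pore_open", "pore_close"):
        return resolve_selection(topology, "resid 215-221")
    raise ValueError(f"unknown event kind {kind!r}")


def _event_delta(kind: str, topology: Topology, ref: np.ndarray,
                 config: PoreConfig, spec: ScenarioSpec) -> np.ndarray:
    if kind == "hop":
        # one B-form step along the strand axis, in the 3'->5' (+z) direction
        return np.array([0.0, 0.0, config.bdna_spacing])
    if kind == "base_flip":
        from .translocation import _anchor_centroids

        anchors = _anchor_centroids(topology, ref, config)
        target = anchors.mean(axis=0)
        base_idx = _event_atoms(spec, topology, "base_flip")
        return target - ref[base_idx].mean(axis=0)
    if kind == "pore_open":
        return np.array([0.0, -PORE_OPENING, 0.0])
    if kind == "pore_close":
        return np.array([0.0, PORE_OPENING, 0.0])
    raise ValueError(f"unknown event kind {kind!r}")


def generate_trajectory(
    spec: ScenarioSpec,
    config: PoreConfig | None = None,
) -> tuple[Trajectory, GroundTruth]:
    """Emit one synthetic replica plus its ground truth.

    Deterministic given ``spec.seed``: the same spec always yields a
    bit-identical trajectory.
    """
    config = config or PoreConfig()
    topology, ref = generate_scaffold(lesion=spec.lesion)
    n_atoms = topology.n_atoms
    times = np.arange(spec.n_frames) * spec.frame_interval_ns

    # --- event displacement profiles -----------------------------------
    events = spec.resolved_events()
    profiles = []  # (atom_idx, delta, ramp per frame in [0,1])
    spans = []
    for ev in events:
        atoms = _event_atoms(spec, topology, ev.kind)
        delta = _event_delta(ev.kind, topology, ref, config, spec)
        f0 = int(round(ev.time_ns / spec.frame_interval_ns))
        f1 = min(spec.n_frames - 1, f0 + spec.transition_frames)
        ramp = np.zeros(spec.n_frames)
        ramp[f1:] = 1.0
        if f1 > f0:
            ramp[f0:f1] = np.linspace(0.0, 1.0, f1 - f0, endpoint=False)
        for a_prev, s_prev in spans:
            if (set(atoms) & set(a_prev)) and not (
                    f1 <= s_prev[0] or s_prev[1] <= f0):
                raise ScheduleConflictError(
                    f"events move shared atoms during overlapping "
                    f"transitions (frames {f0}-{f1} vs {s_prev})"
                )
        spans.append((atoms, (f0, f1)))
        profiles.append((atoms, delta, ramp))

    base = np.broadcast_to(ref, (spec.n_frames, n_atoms, 3)).copy()
    for atoms, delta, ramp in profiles:
        base[:, atoms] += ramp[:, None, None] * delta[None, None, :]

    rng = np.random.default_rng(spec.seed)
    coords = base
    if spec.noise_sigma > 0:
        coords = base + rng.normal(0.0, spec.noise_sigma, size=base.shape)

    # --- planted hydrogen-bond occupancies (exact Bernoulli) -----------
    axis = np.array([HELIX_AXIS[0], HELIX_AXIS[1]])
    occupancies = {}
    for j, hb in enumerate(spec.planted_hbonds):
        d_idx = int(resolve_selection(
            topology, f"resid {hb.donor_resid} and name {hb.donor_name}")[0])
        a_idx = int(resolve_selection(
            topology,
            f"resid {hb.acceptor_resid} and name {hb.acceptor_name}")[0])
        on = rng.random(spec.n_frames) < hb.occupancy
        acc = coords[:, a_idx]
        radial = acc[:, :2] - axis
        norms = np.linalg.norm(radial, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        ang = np.deg2rad(20.0 * j)  # separate directions per planted pair
        rot = np.array([[np.cos(ang), -np.sin(ang)],
                        [np.sin(ang), np.cos(ang)]])
        u2 = (radial / norms) @ rot.T
        u = np.column_stack([u2, np.zeros(spec.n_frames)])
        dist = np.where(on, _HBOND_ON_DIST, _HBOND_OFF_DIST)
        coords[:, d_idx] = acc + dist[:, None] * u
        key = (f"{hb.donor_resid}:{hb.donor_name}-"
               f"{hb.acceptor_resid}:{hb.acceptor_name}")
        occupancies[key] = {
            "planted": hb.occupancy,
            "realized": float(on.mean()),
        }

    # --- planted contact epochs (CM marker atoms) ----------------------
    boundaries: set[float] = set()
    for ep in spec.contact_epochs:
        cm_idx = int(resolve_selection(
            topology, f"resid {ep.residue} and name CM")[0])
        p_idx = topology.p_atom(ep.nucleotide)
        if p_idx is None:
            raise ValueError(
                f"contact epoch targets 5'-terminal nucleotide "
                f"{ep.nucleotide} without a phosphate"
            )
        on = np.zeros(spec.n_frames, dtype=bool)
        for t0, t1 in ep.intervals:
            on |= (times >= t0) & (times < t1)
            for t in (t0, t1):
                if 0 < t <= times[-1]:
                    boundaries.add(float(t))
        coords[on, cm_idx] = (coords[on, p_idx]
                              + np.array([0.0, 0.0, _CONTACT_ON_DIST]))

    traj = Trajectory(topology, coords, times.astype(float))

    hop = any(ev.kind == "hop" for ev in events)
    opened = any(ev.kind == "pore_open" for ev in events)
    closed = any(ev.kind == "pore_close" for ev in events)
    truth = GroundTruth(
        label=KIND_LABELS[spec.kind],
        stage_boundaries=sorted(boundaries),
        planted_displacements={
            f"P_res{spec.tracked_nucleotide}":
                config.bdna_spacing if hop else 0.0,
        },
        planted_occupancies=occupancies,
        pore_width_initial=PORE_WIDTH,
        pore_width_final=(
            PORE_WIDTH + PORE_OPENING if (opened and not closed) else PORE_WIDTH
        ),
        closest_approach=CLOSEST_APPROACH,
        event_times={ev.kind: ev.time_ns for ev in events},
        seed=spec.seed,
    )
    return traj, truth


# ---------------------------------------------------------------------------
# fixture sets
# ---------------------------------------------------------------------------

def default_fixture_specs(
    n_per_class: int = 10,
    noise_sigma: float = 0.5,
    seed_start: int = 1,
    n_frames: int = 200,
) -> list[ScenarioSpec]:
    """The default replica panel: equal thirds of backbone-translocation,
    base-flip and entrapment scenarios with consecutive seeds."""
    kinds = ["backbone_translocation", "base_flip", "entrapment"]
    specs = []
    seed = seed_start
    for kind in kinds:
        for _ in range(n_per_class):
            specs.append(ScenarioSpec(
                kind=kind, noise_sigma=noise_sigma, seed=seed,
                n_frames=n_frames,
            ))
            seed += 1
    return specs


def write_fixture_set(
    specs: list[ScenarioSpec],
    out_dir,
    formats: tuple[str, ...] = ("pdb",),
) -> Path:
    """Write each scenario as multi-model PDB (and/or XYZ) plus a ground-
    truth JSON, and a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, spec in enumerate(specs):
        traj, truth = generate_trajectory(spec)
        stem = f"scenario_{i:03d}_{spec.kind}_seed{spec.seed}"
        files = {}
        if "pdb" in formats:
            path = out_dir / f"{stem}.pdb"
            write_pdb(traj.topology, traj.coords, path)
            files["pdb"] = path.name
        if "xyz" in formats:
            path = out_dir / f"{stem}.xyz"
            write_xyz(traj.topology, traj.coords, path)
            files["xyz"] = path.name
        truth_path = out_dir / f"{stem}.truth.json"
        with open(truth_path, "w") as fh:
            json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        entries.append({
            "index": i,
            "kind": spec.kind,
            "seed": spec.seed,
            "label": truth.label,
            "n_frames": spec.n_frames,
            "n_atoms": traj.topology.n_atoms,
            "frame_interval_ns": spec.frame_interval_ns,
            "noise_sigma": spec.noise_sigma,
            "files": files,
            "truth": truth_path.name,
        })
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump({"n_scenarios": len(entries), "scenarios": entries},
                  fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest_path
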
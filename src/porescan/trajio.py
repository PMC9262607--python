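"""Structure, topology and trajectory I/O plus atom selections.

The in-memory containers are deliberately lightweight: a :class:`Topology`
holds per-atom identity arrays plus a residue-range -> domain map (FeS, Arch,
ATPase lobes, DNA), and a :class:`Trajectory` holds a ``(frames, atoms, 3)``
coordinate block in Å with strictly increasing frame times in ns.  File
parsing and writing (PDB v3.3, AMBER NetCDF + PRMTOP, XYZ) is delegated to
MDAnalysis; this module only adapts between MDAnalysis universes and the
porescan containers.

Units are fixed package-wide: coordinates in Å, times in ns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    PDBParseError,
    SelectionError,
    TopologyError,
    TrajectoryError,
)

__all__ = [
    "Topology",
    "Trajectory",
    "TimeSeries",
    "load_structure",
    "load_trajectory",
    "resolve_selection",
    "write_pdb",
    "write_xyz",
]

#: residue names recognised as nucleic acids ("T64" is the 6-4PP lesion,
#: a single residue whose two crosslinked thymine rings carry 5T/3T atom
#: name prefixes).
DNA_RESNAMES = frozenset(
    {"DA", "DT", "DG", "DC", "DU", "DA5", "DT5", "DG5", "DC5",
     "DA3", "DT3", "DG3", "DC3", "A", "T", "G", "C", "U", "T64"}
)

#: unprefixed nucleobase atom names (purine + pyrimidine rings and their
#: exocyclic substituents).
BASE_ATOM_NAMES = frozenset(
    {"N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9",
     "O2", "O4", "O6", "N2", "N4", "N6", "C7", "C5M"}
)

#: DNA sugar-phosphate backbone atom names.
DNA_BACKBONE_NAMES = frozenset(
    {"P", "OP1", "OP2", "OP3", "O5'", "C5'", "C4'", "C3'", "O3'"}
)

PROTEIN_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

_TWO_LETTER_ELEMENTS = frozenset(
    {"FE", "ZN", "MG", "MN", "CL", "BR", "NA", "CA", "CU", "NI", "SE"}
)


def element_from_name(name: str) -> str:
    """Best-effort element guess from a PDB atom name.

    Handles primed sugar names (``C4'``), phosphate oxygens (``OP1``) and
    the 6-4PP lesion's ``5T``/``3T`` ring-prefixed names (``5TN3`` -> N).
    Returns the empty string when no guess can be made.
    """
    name = name.strip().upper()
    if not name:
        return ""
    if name[:2] in ("5T", "3T") and len(name) > 2:
        name = name[2:]
    # strip any remaining leading digits (e.g. "1HB")
    while name and name[0].isdigit():
        name = name[1:]
    if not name:
        return ""
    if name[:2] in _TWO_LETTER_ELEMENTS and name not in ("CA",):
        # bare two-letter ion names; "CA" in a protein context is C-alpha
        return name[0] + name[1].lower()
    return name[0]


@dataclass(frozen=True)
class Topology:
    """Per-atom identity records plus domain and lesion annotations.

    ``domain_map`` maps inclusive residue-number ranges to domain tags
    (``FeS | Arch | ATPase1 | ATPase2 | DNA``); ranges must not overlap.
    Residues whose name is nucleic are implicitly tagged ``DNA`` even
    without an explicit range.
    """

    names: np.ndarray
    elements: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    chains: np.ndarray
    domain_map: tuple[tuple[int, int, str], ...] = ()
    lesion_residues: frozenset[int] = frozenset()

    def __post_init__(self):
        n = len(self.names)
        for attr in ("elements", "resnames", "resids", "chains"):
            if len(getattr(self, attr)) != n:
                raise TopologyError(f"{attr} length != number of atoms ({n})")
        # every residue number belongs to exactly one chain
        seen: dict[int, str] = {}
        for rid, ch in zip(self.resids.tolist(), self.chains.tolist()):
            if rid in seen and seen[rid] != ch:
                raise TopologyError(
                    f"residue {rid} appears in chains {seen[rid]!r} and {ch!r}"
                )
            seen[rid] = ch
        # non-overlapping domain ranges
        ranges = sorted((lo, hi) for lo, hi, _ in self.domain_map)
        for (lo1, hi1), (lo2, hi2) in zip(ranges, ranges[1:]):
            if hi1 < lo1:
                raise TopologyError(f"bad domain range {lo1}-{hi1}")
            if lo2 <= hi1:
                raise TopologyError(
                    f"domain ranges {lo1}-{hi1} and {lo2}-{hi2} overlap"
                )
        # every DNA residue except a 5' terminus carries exactly one P atom
        dna_rids = [r for r in np.unique(self.resids)
                    if self.resnames[self.resids == r][0] in DNA_RESNAMES]
        for i, rid in enumerate(sorted(dna_rids)):
            n_p = int(np.sum((self.resids == rid) & (self.names == "P")))
            if i == 0:  # 5' terminus may lack the phosphate
                if n_p > 1:
                    raise TopologyError(f"residue {rid} has {n_p} P atoms")
            elif n_p != 1:
                raise TopologyError(
                    f"DNA residue {rid} has {n_p} P atoms (expected 1)"
                )

    # -- basic derived views -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def domain_of(self, resid: int) -> str | None:
        """Domain tag for a residue number, or ``None`` when untagged."""
        for lo, hi, tag in self.domain_map:
            if lo <= resid <= hi:
                return tag
        mask = self.resids == resid
        if mask.any() and self.resnames[mask][0] in DNA_RESNAMES:
            return "DNA"
        return None

    def is_dna_atom(self, i: int) -> bool:
        return self.resnames[i] in DNA_RESNAMES

    def heavy_mask(self) -> np.ndarray:
        """Boolean mask of non-hydrogen atoms.

        Atoms with an unknown element are treated as heavy, with a warning.
        """
        unknown = self.elements == ""
        if unknown.any():
            warnings.warn(
                f"{int(unknown.sum())} atoms have unknown element; "
                "treating them as heavy",
                stacklevel=2,
            )
        return self.elements != "H"

    def residue_atoms(self, resid: int) -> np.ndarray:
        """Atom indices of one residue, in file order."""
        idx = np.flatnonzero(self.resids == resid)
        if idx.size == 0:
            raise SelectionError(f"no residue with number {resid}")
        return idx

    def p_atom(self, resid: int) -> int | None:
        """Index of the residue's phosphorus, ``None`` for a 5' terminus."""
        idx = np.flatnonzero((self.resids == resid) & (self.names == "P"))
        return int(idx[0]) if idx.size else None

    def with_domains(self, domain_map, lesion_residues=frozenset()) -> "Topology":
        return replace(
            self,
            domain_map=tuple(tuple(r) for r in domain_map),
            lesion_residues=frozenset(lesion_residues),
        )


@dataclass
class Trajectory:
    """Frames x atoms x 3 coordinates (Å) with per-frame times (ns)."""

    topology: Topology
    coords: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[0] < 1:
            raise TrajectoryError("trajectory must contain at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise TrajectoryError(
                f"coordinate block has {self.coords.shape[1]} atoms but "
                f"topology has {self.topology.n_atoms}"
            )
        if len(self.times) != len(self.coords):
            raise TrajectoryError("times length != frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise TrajectoryError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def window_indices(self, window: tuple[float, float]) -> np.ndarray:
        """Frame indices with t_start <= t <= t_end (closed interval)."""
        t0, t1 = window
        return np.flatnonzero((self.times >= t0) & (self.times <= t1))


@dataclass
class TimeSeries:
    """A named scalar time series (times in ns)."""

    times: np.ndarray
    values: np.ndarray
    name: str = "value"
    units: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")

    def __len__(self) -> int:
        return len(self.times)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# {self.name} [{self.units}]\n")
            pd.DataFrame({"time_ns": self.times, "value": self.values}).to_csv(
                fh, index=False
            )

    @classmethod
    def from_csv(cls, path) -> "TimeSeries":
        with open(path) as fh:
            header = fh.readline().strip()
            df = pd.read_csv(fh)
        name, units = "value", ""
        if header.startswith("#"):
            body = header.lstrip("# ")
            if "[" in body:
                name, rest = body.split("[", 1)
                name, units = name.strip(), rest.rstrip("]").strip()
            else:
                name = body
        return cls(df["time_ns"].to_numpy(), df["value"].to_numpy(),
                   name=name, units=units)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _validate_pdb_records(path: Path) -> None:
    """Light syntactic validation of PDB coordinate records.

    Raises :class:`PDBParseError` with the 1-based line number for a
    malformed ATOM/HETATM record, and :class:`TopologyError` for duplicate
    atom serials within one MODEL.
    """
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                seen.clear()
            elif rec in ("ATOM", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise PDBParseError(
                        f"truncated {rec} record", line_number=lineno
                    )
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                    int(line[22:26])
                except ValueError as exc:
                    raise PDBParseError(
                        f"malformed {rec} record: {exc}", line_number=lineno
                    ) from None
                serial = line[6:11].strip()
                if serial and serial in seen:
                    raise TopologyError(
                        f"duplicate atom serial {serial} at line {lineno}"
                    )
                seen.add(serial)


def _topology_from_universe(u) -> Topology:
    atoms = u.atoms
    names = atoms.names.astype(str)
    if hasattr(atoms, "elements"):
        elements = np.array(
            [e.capitalize() if e else element_from_name(n)
             for e, n in zip(atoms.elements, names)]
        )
    else:
        elements = np.array([element_from_name(n) for n in names])
    if hasattr(atoms, "chainIDs"):
        chains = atoms.chainIDs.astype(str)
    elif hasattr(atoms, "segids"):
        chains = atoms.segids.astype(str)
    else:
        chains = np.full(len(names), "A")
    chains = np.array([c if c.strip() else "A" for c in chains])
    return Topology(
        names=names,
        elements=elements,
        resnames=atoms.resnames.astype(str),
        resids=atoms.resids.astype(int),
        chains=chains,
    )


def load_structure(path) -> tuple[Topology, Trajectory]:
    """Read a PDB file into a topology plus (possibly multi-frame) trajectory.

    Multi-model files yield one frame per MODEL with synthetic times
    0, 1, 2, ... ns.  Atom order follows file order; coordinates are Å.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise PDBParseError(f"no such file: {path}")
    _validate_pdb_records(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        topology = _topology_from_universe(u)
        coords = np.array([ts.positions.copy() for ts in u.trajectory],
                          dtype=float)
    times = np.arange(len(coords), dtype=float)
    return topology, Trajectory(topology, coords, times)


def _read_coordinate_file(path: Path, n_atoms_expected: int):
    """Return (coords (F,N,3), times_ns or None) for one trajectory file."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.TRJ import NCDFReader
    from MDAnalysis.coordinates.XYZ import XYZReader

    suffix = path.suffix.lower()
    try:
        if suffix in (".nc", ".ncdf", ".netcdf", ".crd"):
            reader = NCDFReader(str(path))
            fmt = "AMBER NetCDF"
        elif suffix == ".xyz":
            reader = XYZReader(str(path))
            fmt = "XYZ"
        elif suffix in (".pdb", ".ent"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reader = mda.coordinates.PDB.PDBReader(str(path))
            fmt = "PDB"
        else:
            raise TrajectoryError(
                f"unreadable trajectory format {suffix!r} for {path}"
            )
    except TrajectoryError:
        raise
    except Exception as exc:
        raise TrajectoryError(f"could not read {path} as trajectory: {exc}")

    if reader.n_atoms != n_atoms_expected:
        raise TrajectoryError(
            f"{fmt} file {path.name} has {reader.n_atoms} atoms but the "
            f"topology has {n_atoms_expected}"
        )
    coords, times = [], []
    has_time = fmt == "AMBER NetCDF"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in reader:
            coords.append(ts.positions.copy())
            if has_time:
                times.append(ts.time / 1000.0)  # MDAnalysis time is ps
    reader.close()
    return np.array(coords, dtype=float), (np.array(times) if has_time else None)


def load_trajectory(
    topology: Topology,
    paths: Sequence,
    frame_interval_ns: float = 1.0,
) -> Trajectory:
    """Read one or more trajectory files and concatenate them in path order.

    Supported formats: AMBER NetCDF (times read from the file), multi-model
    PDB and XYZ (times synthesized from ``frame_interval_ns``).  Later files
    are time-shifted so the concatenated times stay strictly increasing.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    all_coords, all_times = [], []
    t_last = None
    for p in paths:
        coords, times = _read_coordinate_file(Path(p), topology.n_atoms)
        if times is None:
            times = np.arange(len(coords)) * frame_interval_ns
        if t_last is not None and times[0] <= t_last:
            times = times + (t_last + frame_interval_ns - times[0])
        all_coords.append(coords)
        all_times.append(times)
        t_last = times[-1]
    return Trajectory(
        topology,
        np.concatenate(all_coords, axis=0),
        np.concatenate(all_times),
    )


def load_amber(prmtop_path, netcdf_paths) -> Trajectory:
    """Read an AMBER PRMTOP topology plus NetCDF trajectory file(s)."""
    import MDAnalysis as mda

    if isinstance(netcdf_paths, (str, Path)):
        netcdf_paths = [netcdf_paths]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(prmtop_path), *(str(p) for p in netcdf_paths))
        topology = _topology_from_universe(u)
        coords, times = [], []
        for ts in u.trajectory:
            coords.append(ts.positions.copy())
            times.append(ts.time / 1000.0)
    times = np.asarray(times)
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        times = np.arange(len(coords), dtype=float)
    return Trajectory(topology, np.array(coords, dtype=float), times)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _to_universe(topology: Topology, coords: np.ndarray):
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    coords = np.asarray(coords, dtype=np.float32)
    if coords.ndim == 2:
        coords = coords[None]
    # group consecutive (chain, resid) runs into residues
    resindex = np.zeros(topology.n_atoms, dtype=int)
    res_keys = []
    current = None
    for i in range(topology.n_atoms):
        key = (topology.chains[i], int(topology.resids[i]))
        if key != current:
            res_keys.append(i)
            current = key
        resindex[i] = len(res_keys) - 1
    n_res = len(res_keys)
    u = mda.Universe.empty(
        n_atoms=topology.n_atoms,
        n_residues=n_res,
        atom_resindex=resindex,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", topology.names)
    u.add_TopologyAttr("elements", topology.elements)
    u.add_TopologyAttr("chainIDs", [c[:1] for c in topology.chains])
    u.add_TopologyAttr("resnames", [topology.resnames[i] for i in res_keys])
    u.add_TopologyAttr("resids", [int(topology.resids[i]) for i in res_keys])
    u.add_TopologyAttr("occupancies", np.ones(topology.n_atoms))
    u.add_TopologyAttr("tempfactors", np.zeros(topology.n_atoms))
    u.load_new(coords, format=MemoryReader, order="fac")
    return u


def write_pdb(topology: Topology, coords: np.ndarray, path) -> None:
    """Write coordinates as a (multi-model, for >1 frame) PDB v3.3 file."""
    import MDAnalysis as mda

    u = _to_universe(topology, coords)
    multiframe = len(u.trajectory) > 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), multiframe=multiframe,
                        n_atoms=topology.n_atoms) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def write_xyz(topology: Topology, coords: np.ndarray, path) -> None:
    """Write coordinates in XYZ format (atom names as element labels)."""
    import MDAnalysis as mda

    u = _to_universe(topology, coords)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=topology.n_atoms, format="XYZ") as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as multi-model PDB or XYZ based on file suffix."""
    suffix = Path(path).suffix.lower()
    if suffix == ".xyz":
        write_xyz(traj.topology, traj.coords, path)
    else:
        write_pdb(traj.topology, traj.coords, path)


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

_KEYWORDS = frozenset({"name", "resname", "resid", "chain", "element", "domain"})
_CLASSES = frozenset({"heavy", "hydrogen", "p", "ca", "calpha", "base",
                      "backbone", "all"})
_OPERATORS = frozenset({"and", "or", "not", "(", ")"})


@dataclass(frozen=True)
class SelectionExpr:
    """A parsed selection expression.

    The grammar combines keyword clauses (``name``, ``resname``, ``resid``
    with ranges like ``215-221``, ``chain``, ``element``, ``domain``) and
    atom-class terms (``heavy``, ``hydrogen``, ``P``, ``CA``, ``base``,
    ``backbone``, ``base:5T``/``base:3T`` for the lesion ring moieties) with
    ``and``/``or``/``not`` and parentheses.  ``chain`` also matches domain
    tags so that ``chain DNA`` addresses the nucleic strand.
    """

    text: str

    def __str__(self) -> str:
        return self.text


def _tokenize(text: str) -> list[str]:
    out: list[str] = []
    for raw in text.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


class _Parser:
    """Recursive-descent parser producing a boolean mask over atoms."""

    def __init__(self, tokens: list[str], topology: Topology):
        self.tokens = tokens
        self.pos = 0
        self.top = topology
        self.empty_clauses: list[str] = []

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.parse_or()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def parse_or(self) -> np.ndarray:
        mask = self.parse_and()
        while self.peek() == "or":
            self.next()
            mask = mask | self.parse_and()
        return mask

    def parse_and(self) -> np.ndarray:
        mask = self.parse_not()
        while self.peek() == "and":
            self.next()
            mask = mask & self.parse_not()
        return mask

    def parse_not(self) -> np.ndarray:
        if self.peek() == "not":
            self.next()
            return ~self.parse_not()
        return self.parse_term()

    def parse_term(self) -> np.ndarray:
        tok = self.next()
        low = tok.lower()
        if tok == "(":
            mask = self.parse_or()
            if self.next() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        if low in _KEYWORDS:
            values = self._collect_values()
            if not values:
                raise SelectionError(f"keyword {tok!r} requires values")
            return self._keyword_mask(low, values, f"{tok} {' '.join(values)}")
        if low in _CLASSES or low.startswith("base:"):
            return self._class_mask(low, tok)
        raise SelectionError(f"unknown selection token {tok!r}")

    def _collect_values(self) -> list[str]:
        # values stop at keywords/operators/parens only; bare class names
        # (CA, P, base, ...) are valid *values* right after a keyword
        values = []
        while True:
            tok = self.peek()
            if tok is None or tok.lower() in _KEYWORDS | _OPERATORS:
                break
            values.append(self.next())
        return values

    def _record(self, mask: np.ndarray, clause: str) -> np.ndarray:
        if not mask.any():
            self.empty_clauses.append(clause)
        return mask

    def _keyword_mask(self, key: str, values: list[str], clause: str):
        top = self.top
        if key == "name":
            mask = np.isin(top.names, values)
        elif key == "resname":
            mask = np.isin(top.resnames, values)
        elif key == "element":
            wanted = [v.capitalize() for v in values]
            mask = np.isin(top.elements, wanted)
        elif key == "chain":
            mask = np.isin(top.chains, values)
            tags = {top.domain_of(int(r)) for r in np.unique(top.resids)}
            for v in values:
                if v in tags:  # allow "chain DNA" style domain addressing
                    dom = np.array([top.domain_of(int(r)) == v
                                    for r in top.resids])
                    mask = mask | dom
        elif key == "domain":
            mask = np.array([top.domain_of(int(r)) in values
                             for r in top.resids])
        elif key == "resid":
            mask = np.zeros(top.n_atoms, dtype=bool)
            for v in values:
                v = v.replace(":", "-")
                if "-" in v[1:]:
                    head, tail = v[1:].split("-", 1)
                    lo, hi = int(v[0] + head), int(tail)
                    mask |= (top.resids >= lo) & (top.resids <= hi)
                else:
                    mask |= top.resids == int(v)
        else:  # pragma: no cover - guarded by _KEYWORDS
            raise SelectionError(f"unknown keyword {key!r}")
        return self._record(mask, clause)

    def _class_mask(self, low: str, clause: str) -> np.ndarray:
        top = self.top
        if low == "all":
            return np.ones(top.n_atoms, dtype=bool)
        if low == "heavy":
            return self._record(top.heavy_mask(), clause)
        if low == "hydrogen":
            return self._record(top.elements == "H", clause)
        if low == "p":
            dna = np.array([rn in DNA_RESNAMES for rn in top.resnames])
            return self._record((top.names == "P") & dna, clause)
        if low in ("ca", "calpha"):
            protein = np.array([rn not in DNA_RESNAMES for rn in top.resnames])
            return self._record((top.names == "CA") & protein, clause)
        if low == "backbone":
            dna = np.array([rn in DNA_RESNAMES for rn in top.resnames])
            bb_dna = np.isin(top.names, list(DNA_BACKBONE_NAMES)) & dna
            bb_prot = np.isin(top.names, list(PROTEIN_BACKBONE_NAMES)) & ~dna
            return self._record(bb_dna | bb_prot, clause)
        if low == "base":
            return self._record(_base_mask(top), clause)
        if low.startswith("base:"):
            prefix = clause.split(":", 1)[1].upper()
            mask = np.array([n.upper().startswith(prefix) for n in top.names])
            return self._record(mask & _base_mask(top), clause)
        raise SelectionError(f"unknown atom class {clause!r}")


def _base_mask(top: Topology) -> np.ndarray:
    dna = np.array([rn in DNA_RESNAMES for rn in top.resnames])
    plain = np.isin(top.names, list(BASE_ATOM_NAMES))
    prefixed = np.array([n[:2] in ("5T", "3T") for n in top.names])
    return dna & (plain | prefixed)


def resolve_selection(topology: Topology, expr) -> np.ndarray:
    """Resolve a selection expression to sorted, unique atom indices.

    An expression that matches zero atoms raises :class:`SelectionError`
    naming the clause(s) that matched nothing; an empty result is never
    silently returned.
    """
    text = expr.text if isinstance(expr, SelectionExpr) else str(expr)
    tokens = _tokenize(text)
    if not tokens:
        raise SelectionError("empty selection expression")
    parser = _Parser(tokens, topology)
    mask = parser.parse()
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        detail = (
            f" (no atoms matched: {'; '.join(parser.empty_clauses)})"
            if parser.empty_clauses else ""
        )
        raise SelectionError(f"selection {text!r} matched zero atoms{detail}")
    return idx
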